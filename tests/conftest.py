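import numpy as np
import pytest

from pigbel.core_data import AA_CODES, Dataset, Observation
from pigbel.synthetic_data import GeneratorConfig, generate


def make_dataset(ibw, bel_cp=None, fi_mfi=None, feed_intake=None,
                 diet_me=None, **aa_columns) -> Dataset:
    """Build a Dataset from parallel value lists; None entries are missing."""
    n = len(ibw)

    def at(seq, i):
        if seq is None:
            return None
        v = seq[i]
        return None if v is None or (isinstance(v, float) and np.isnan(v)) else float(v)

    obs = []
    for i in range(n):
        bel_aa = {}
        for aa in AA_CODES:
            v = at(aa_columns.get(aa.lower()), i)
            if v is not None:
                bel_aa[aa] = v
        obs.append(Observation(
            study_id=f"s{i}", ibw=float(ibw[i]),
            feed_intake=at(feed_intake, i), diet_me=at(diet_me, i),
            fi_mfi=at(fi_mfi, i), bel_cp=at(bel_cp, i), bel_aa=bel_aa,
        ))
    return Dataset(obs)


@pytest.fixture(scope="session")
def big_synthetic() -> Dataset:
    """One large draw from the default generator, shared across tests."""
    return generate(GeneratorConfig(n=50_000, seed=11))
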