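"""Maintenance-intake derivation and FI:MFI capping.

Feeding level is expressed as FI:MFI, the ratio of feed intake to the
maintenance feed intake.  Maintenance feed intake is the maintenance
metabolizable-energy requirement, 197 x BW^0.60 kcal/d, divided by the
diet's ME concentration (kcal/kg DM).  FI:MFI values above the expected
voluntary intake are not considered practical for crossbred pigs and are
capped (default ceiling 3.0; a body-weight-specific intake lookup can be
injected instead).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable

from .core_data import Dataset, Observation


@dataclass(frozen=True)
class MaintenanceModel:
    """Maintenance-energy model and FI:MFI cap policy.

    Attributes
    ----------
    coefficient : float
        kcal/d per kg^exponent; default 197.
    exponent : float
        Metabolic body-weight exponent; default 0.60.
    fi_mfi_cap : float
        Dimensionless ceiling applied to FI:MFI; default 3.0.
    intake_lookup : callable, optional
        BW (kg) -> expected feed intake (kg DM/d).  When set, the cap for
        an observation with known diet ME is ``lookup(ibw) / MFI`` instead
        of the constant ceiling.
    """

    coefficient: float = 197.0
    exponent: float = 0.60
    fi_mfi_cap: float = 3.0
    intake_lookup: Callable[[float], float] | None = None

    def __post_init__(self) -> None:
        if self.coefficient <= 0:
            raise ValueError("coefficient must be positive")
        if not 0 < self.exponent < 1:
            raise ValueError("exponent must lie in (0, 1)")
        if self.fi_mfi_cap <= 0:
            raise ValueError("fi_mfi_cap must be positive")


DEFAULT_MAINTENANCE = MaintenanceModel()


def maintenance_me(ibw: float, model: MaintenanceModel = DEFAULT_MAINTENANCE) -> float:
    """Maintenance metabolizable-energy requirement, kcal/d.

    ``coefficient * ibw ** exponent`` (197 x BW^0.60 by default).
    """
    if not ibw > 0:
        raise ValueError(f"ibw must be positive, got {ibw}")
    return model.coefficient * ibw ** model.exponent


def maintenance_feed_intake(
    ibw: float, diet_me: float, model: MaintenanceModel = DEFAULT_MAINTENANCE
) -> float:
    """Maintenance feed intake, kg DM/d: maintenance ME over diet ME."""
    if not diet_me > 0:
        raise ValueError(f"diet_me must be positive, got {diet_me}")
    return maintenance_me(ibw, model) / diet_me


def compute_fi_mfi(
    feed_intake: float,
    ibw: float,
    diet_me: float,
    model: MaintenanceModel = DEFAULT_MAINTENANCE,
) -> float:
    """Raw (uncapped) feed-intake-to-maintenance-feed-intake ratio."""
    if not feed_intake > 0:
        raise ValueError(f"feed_intake must be positive, got {feed_intake}")
    return feed_intake / maintenance_feed_intake(ibw, diet_me, model)


def cap_fi_mfi(
    raw: float,
    model: MaintenanceModel = DEFAULT_MAINTENANCE,
    *,
    ibw: float | None = None,
    diet_me: float | None = None,
) -> float:
    """Apply the cap policy to a raw FI:MFI value.  Idempotent.

    With the default constant policy this is ``min(raw, cap)``.  With an
    intake lookup and both ``ibw`` and ``diet_me`` supplied, the ceiling is
    the expected intake at that body weight expressed in maintenance units.
    """
    cap = model.fi_mfi_cap
    if model.intake_lookup is not None and ibw is not None and diet_me is not None:
        cap = model.intake_lookup(ibw) / maintenance_feed_intake(ibw, diet_me, model)
    return min(raw, cap)


def derive_features(
    dataset: Dataset, model: MaintenanceModel = DEFAULT_MAINTENANCE
) -> Dataset:
    """Fill FI:MFI for every observation where it can be obtained.

    A reported fi_mfi takes precedence over derivation; otherwise the ratio
    is computed from feed_intake, ibw and diet_me when all are present.
    The cap applies on both paths.  Observations with insufficient fields
    keep fi_mfi absent and are flagged in the provenance log.  Returns a
    new Dataset; the input is not mutated.
    """
    out: list[Observation] = []
    underivable: list[str] = []
    for obs in dataset:
        if obs.fi_mfi is not None:
            raw = obs.fi_mfi
        elif obs.feed_intake is not None and obs.diet_me is not None:
            raw = compute_fi_mfi(obs.feed_intake, obs.ibw, obs.diet_me, model)
        else:
            underivable.append(obs.study_id)
            out.append(replace(obs, bel_aa=dict(obs.bel_aa)))
            continue
        capped = cap_fi_mfi(raw, model, ibw=obs.ibw, diet_me=obs.diet_me)
        out.append(replace(obs, fi_mfi=capped, bel_aa=dict(obs.bel_aa)))
    provenance = dataset.provenance + [
        f"derive_features: coefficient={model.coefficient}, "
        f"exponent={model.exponent}, cap={model.fi_mfi_cap}"
    ]
    if underivable:
        provenance.append(
            "derive_features: fi_mfi unavailable for "
            f"{len(underivable)} observation(s): {', '.join(underivable)}"
        )
    return Dataset(out, provenance)
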