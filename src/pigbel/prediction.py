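"""Prediction API for the published BEL equations.

Exposes the published equations as callables: BEL of crude protein
(g/kg DMI) from initial body weight via a linear, exponential or
one-slope broken-line model, and BEL of each of 18 amino acids from BEL
of CP via simple linear equations.  The coefficients live in a checked-in
constants file (``data/published_equations.json``) loaded once at import.

Amino-acid equations with a negative intercept (Pro, Gly, Arg) can return
negative values at low BEL of CP; endogenous losses cannot be negative, so
such predictions are clipped to zero and flagged rather than raised.
Predictions outside the body-weight range of the underlying data
([9.2, 109.8] kg) warn but proceed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from importlib import resources

from .core_data import AA_CODES

CP_MODELS = ("linear", "exponential", "broken_line")


class ExtrapolationWarning(UserWarning):
    """Body weight outside the range of the data behind the equations."""


@dataclass(frozen=True)
class EquationRegistry:
    """Published coefficients for the CP and amino-acid equations."""

    cp_linear: dict
    cp_exponential: dict
    cp_broken_line: dict
    aa_equations: dict[str, dict]
    ibw_range: tuple[float, float]

    @classmethod
    def published(cls) -> "EquationRegistry":
        raw = json.loads(
            resources.files("pigbel.data").joinpath("published_equations.json")
            .read_text()
        )
        missing = set(AA_CODES) - set(raw["aa_equations"])
        if missing:
            raise ValueError(f"registry missing amino acids: {sorted(missing)}")
        return cls(
            cp_linear=raw["cp_linear"],
            cp_exponential=raw["cp_exponential"],
            cp_broken_line=raw["cp_broken_line"],
            aa_equations=raw["aa_equations"],
            ibw_range=tuple(raw["ibw_range"]),
        )


_REGISTRY: EquationRegistry | None = None


def default_registry() -> EquationRegistry:
    global _REGISTRY
    if _REGISTRY is None:
        _REGISTRY = EquationRegistry.published()
    return _REGISTRY


@dataclass(frozen=True)
class Prediction:
    """One predicted BEL value with clipping provenance."""

    nutrient: str
    value: float        # g/kg DMI, after clipping
    raw: float          # unclipped equation output
    model: str
    clipped: bool = False


def predict_bel_cp(
    ibw: float,
    model: str = "linear",
    registry: EquationRegistry | None = None,
) -> float:
    """Predicted BEL of crude protein, g/kg DMI, at body weight ``ibw`` kg.

    ``model`` selects among 'linear' (20.36 - 0.077*IBW), 'exponential'
    (20.80*exp(-0.00475*IBW)) and 'broken_line' (14.78 + 0.102*(62.0 - BW)
    below 62.0 kg, constant 14.78 above).  Warns outside the observed
    body-weight range.
    """
    registry = registry or default_registry()
    if not ibw > 0:
        raise ValueError(f"ibw must be positive, got {ibw}")
    lo, hi = registry.ibw_range
    if not lo <= ibw <= hi:
        warnings.warn(
            f"body weight {ibw} kg is outside the range [{lo}, {hi}] kg of "
            "the data behind the published equations; extrapolating",
            ExtrapolationWarning, stacklevel=2,
        )
    import math
    if model == "linear":
        eq = registry.cp_linear
        return eq["C1"] + eq["C2"] * ibw
    if model == "exponential":
        eq = registry.cp_exponential
        return eq["C1"] * math.exp(eq["C2"] * ibw)
    if model == "broken_line":
        eq = registry.cp_broken_line
        return eq["plateau"] + eq["slope"] * max(eq["breakpoint"] - ibw, 0.0)
    raise ValueError(f"unknown model {model!r}; choose from {CP_MODELS}")


def predict_bel_aa(
    bel_cp: float,
    aa: str,
    registry: EquationRegistry | None = None,
) -> Prediction:
    """Predicted BEL of one amino acid, g/kg DMI, from BEL of CP.

    Negative raw predictions are clipped to zero with ``clipped=True``.
    """
    registry = registry or default_registry()
    if bel_cp < 0:
        raise ValueError(f"bel_cp must be non-negative, got {bel_cp}")
    if aa not in registry.aa_equations:
        raise KeyError(
            f"unknown amino-acid code {aa!r}; valid codes: "
            f"{', '.join(sorted(registry.aa_equations))}"
        )
    eq = registry.aa_equations[aa]
    raw = eq["intercept"] + eq["slope"] * bel_cp
    clipped = raw < 0
    return Prediction(
        nutrient=aa, value=max(raw, 0.0), raw=raw, model="aa_linear",
        clipped=bool(clipped),
    )


def predict_profile(
    ibw: float,
    model: str = "linear",
    registry: EquationRegistry | None = None,
) -> dict[str, Prediction]:
    """Full BEL profile at one body weight: CP plus all 18 amino acids.

    The CP prediction is computed first and then fed into every amino-acid
    equation; the returned map records it under the key ``"CP"``.
    """
    registry = registry or default_registry()
    cp = predict_bel_cp(ibw, model, registry)
    out = {"CP": Prediction(nutrient="CP", value=cp, raw=cp, model=model)}
    for aa in AA_CODES:
        out[aa] = predict_bel_aa(cp, aa, registry)
    return out
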