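"""Observation data model and CSV interchange.

The pipeline operates on flat tables of literature-style records: one row
per experiment/observation on pigs fed a nitrogen-free diet, carrying the
initial body weight (IBW, kg), feed intake (kg DM/d), the diet's
metabolizable-energy concentration (kcal/kg DM), the feed-intake-to-
maintenance-feed-intake ratio (FI:MFI), and basal endogenous losses (BEL)
of crude protein and up to 18 amino acids, all in g/kg DMI.

Interchange format: UTF-8 CSV, comma-separated, header row, empty cell =
missing.  Units are fixed by convention (kg, kg/d, kcal/kg DM, g/kg DMI);
there is no unit-conversion layer.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Three-letter amino-acid codes, indispensable first, in conventional order.
AA_CODES: tuple[str, ...] = (
    "Arg", "His", "Ile", "Leu", "Lys", "Met", "Phe", "Thr", "Trp", "Val",
    "Ala", "Asp", "Cys", "Glu", "Gly", "Pro", "Ser", "Tyr",
)

#: Canonical CSV column order.
CSV_COLUMNS: tuple[str, ...] = (
    "study_id", "ibw", "feed_intake", "diet_me", "fi_mfi", "bel_cp",
    *(aa.lower() for aa in AA_CODES),
)

_NUMERIC_COLUMNS = ("ibw", "feed_intake", "diet_me", "fi_mfi", "bel_cp")


class DataError(ValueError):
    """Raised for malformed input tables (missing columns, bad cells)."""


@dataclass
class Observation:
    """One literature record.

    Parameters
    ----------
    study_id : str
        Opaque label; several observations may share one (a paper can
        contribute more than one record).
    ibw : float
        Initial body weight, kg.  Required and positive.
    feed_intake, diet_me, fi_mfi, bel_cp : float or None
        Optional measurements (kg DM/d, kcal/kg DM, dimensionless,
        g/kg DMI respectively).
    bel_aa : dict
        Map from amino-acid code (see :data:`AA_CODES`) to BEL, g/kg DMI.
        Absent keys mean the value was not reported.
    """

    study_id: str
    ibw: float
    feed_intake: float | None = None
    diet_me: float | None = None
    fi_mfi: float | None = None
    bel_cp: float | None = None
    bel_aa: dict[str, float] = field(default_factory=dict)


@dataclass
class Dataset:
    """Ordered collection of observations plus free-text provenance."""

    observations: list[Observation] = field(default_factory=list)
    provenance: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.observations)

    def __iter__(self) -> Iterator[Observation]:
        return iter(self.observations)

    def __getitem__(self, i: int) -> Observation:
        return self.observations[i]

    def column(self, name: str) -> np.ndarray:
        """Return one variable as a float array with NaN for missing."""
        name = name.lower()
        out = np.full(len(self.observations), np.nan)
        for i, obs in enumerate(self.observations):
            if name in _NUMERIC_COLUMNS:
                v = getattr(obs, name)
            else:
                v = obs.bel_aa.get(name.capitalize())
            if v is not None:
                out[i] = v
        return out

    def to_frame(self) -> pd.DataFrame:
        """Render as a DataFrame in canonical column order (NaN = missing)."""
        rows = []
        for obs in self.observations:
            row: dict[str, object] = {"study_id": obs.study_id}
            for c in _NUMERIC_COLUMNS[1:]:
                row[c] = getattr(obs, c)
            row["ibw"] = obs.ibw
            for aa in AA_CODES:
                row[aa.lower()] = obs.bel_aa.get(aa)
            rows.append(row)
        frame = pd.DataFrame(rows, columns=list(CSV_COLUMNS))
        return frame.astype({c: float for c in CSV_COLUMNS if c != "study_id"})

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, provenance: Sequence[str] = ()) -> "Dataset":
        """Build a Dataset from a DataFrame using canonical column names."""
        observations = []
        for i, row in frame.iterrows():
            def get(col: str) -> float | None:
                if col not in frame.columns:
                    return None
                v = row[col]
                return None if pd.isna(v) else float(v)

            bel_aa = {}
            for aa in AA_CODES:
                v = get(aa.lower())
                if v is not None:
                    bel_aa[aa] = v
            sid = str(row["study_id"]) if "study_id" in frame.columns else f"row{i}"
            ibw = get("ibw")
            if ibw is None:
                raise DataError(f"row {i}: missing required value 'ibw'")
            observations.append(Observation(
                study_id=sid, ibw=ibw, feed_intake=get("feed_intake"),
                diet_me=get("diet_me"), fi_mfi=get("fi_mfi"),
                bel_cp=get("bel_cp"), bel_aa=bel_aa,
            ))
        return cls(observations, list(provenance))


def read_observations(path: str | Path, dialect: Mapping[str, object] | None = None) -> Dataset:
    """Read a Dataset from a CSV file.

    Column names are matched case-insensitively; amino acids by their
    3-letter code.  Unknown columns are ignored with a warning.  Empty
    cells become absent values.

    Raises
    ------
    DataError
        If the required ``ibw`` column is absent or a cell is non-numeric.
    """
    path = Path(path)
    opts = dict(dialect or {})
    raw = pd.read_csv(path, dtype=str, keep_default_na=False, **opts)

    colmap: dict[str, str] = {}
    known = {c.lower(): c for c in CSV_COLUMNS}
    for col in raw.columns:
        key = col.strip().lower()
        if key in known:
            colmap[col] = known[key]
        else:
            logger.warning("ignoring unrecognized column %r in %s", col, path.name)
    if "ibw" not in colmap.values():
        raise DataError(f"{path}: required column 'ibw' is missing")

    observations = []
    for i in range(len(raw)):
        values: dict[str, float] = {}
        for col, canon in colmap.items():
            cell = str(raw.iloc[i][col]).strip()
            if canon == "study_id" or cell == "":
                continue
            try:
                values[canon] = float(cell)
            except ValueError:
                raise DataError(
                    f"{path}: non-numeric cell {cell!r} at row {i + 2}, column {col!r}"
                ) from None
        if "ibw" not in values:
            raise DataError(f"{path}: empty 'ibw' cell at row {i + 2}")
        sid_col = next((c for c, canon in colmap.items() if canon == "study_id"), None)
        sid = str(raw.iloc[i][sid_col]).strip() if sid_col else f"row{i}"
        bel_aa = {aa: values[aa.lower()] for aa in AA_CODES if aa.lower() in values}
        observations.append(Observation(
            study_id=sid or f"row{i}",
            ibw=values["ibw"],
            feed_intake=values.get("feed_intake"),
            diet_me=values.get("diet_me"),
            fi_mfi=values.get("fi_mfi"),
            bel_cp=values.get("bel_cp"),
            bel_aa=bel_aa,
        ))
    return Dataset(observations, [f"read from {path}"])


def write_observations(dataset: Dataset, path: str | Path) -> None:
    """Write a Dataset as CSV.  Round-trips values and missingness exactly.

    Raises
    ------
    ValueError
        If the dataset is empty.
    """
    if len(dataset) == 0:
        raise ValueError("refusing to write an empty dataset")
    dataset.to_frame().to_csv(path, index=False)


@dataclass(frozen=True)
class ValidationIssue:
    """One invariant violation found by :func:`validate_dataset`."""

    index: int
    study_id: str
    field: str
    message: str


def validate_dataset(dataset: Dataset) -> list[ValidationIssue]:
    """Check dataset invariants; returns one issue per violation.

    Checks: ibw > 0; feed_intake, diet_me, fi_mfi > 0 when present; all
    BEL values >= 0 when present.  An empty list means the dataset is
    clean.  Reporting, not raising.
    """
    issues = []

    def add(i: int, obs: Observation, fld: str, msg: str) -> None:
        issues.append(ValidationIssue(i, obs.study_id, fld, msg))

    for i, obs in enumerate(dataset):
        if not obs.ibw > 0:
            add(i, obs, "ibw", f"ibw must be positive, got {obs.ibw}")
        for fld in ("feed_intake", "diet_me", "fi_mfi"):
            v = getattr(obs, fld)
            if v is not None and not v > 0:
                add(i, obs, fld, f"{fld} must be positive when present, got {v}")
        if obs.bel_cp is not None and obs.bel_cp < 0:
            add(i, obs, "bel_cp", f"bel_cp must be non-negative, got {obs.bel_cp}")
        for aa, v in obs.bel_aa.items():
            if aa not in AA_CODES:
                add(i, obs, aa, f"unknown amino-acid code {aa!r}")
            elif v < 0:
                add(i, obs, aa, f"BEL of {aa} must be non-negative, got {v}")
    return issues
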