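"""Domain types, scale validation, clinical cut-offs and panel I/O.

The analysis variables are four clinical rating scales recorded once per
annual visit:

========  =====================================  ======  ==================
column    scale                                  range   role
========  =====================================  ======  ==================
rbdsq     REM-sleep behavior disorder screening  0–13    exposure X
gds15     Geriatric Depression Scale (15 item)   0–15    mediator M1
moca      Montreal Cognitive Assessment          0–30    mediator M2
updrs2    MDS-UPDRS Part II (ADL limitation)     0–52    outcome Y
========  =====================================  ======  ==================

Panels are long format: one row per subject-visit, visits indexed 0..8
(baseline plus eight annual follow-ups).  Baseline covariates are categorical
bands, fixed per subject.  Study time is the min–max normalized visit index,
so visit k of a 9-visit design maps to t = k/8 in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: inclusive score ranges for each analysis scale
SCALE_RANGES: dict[str, tuple[int, int]] = {
    "rbdsq": (0, 13),
    "gds15": (0, 15),
    "moca": (0, 30),
    "updrs2": (0, 52),
}

SCORE_COLUMNS = tuple(SCALE_RANGES)

#: admissible labels for each baseline covariate
COVARIATE_LEVELS: dict[str, tuple[str, ...]] = {
    "sex": ("female", "male"),
    "age_band": ("<56", "56-65", ">65"),
    "edu_band": ("<13", "13-23", ">23"),
    "race": ("White", "Black", "Asian", "other"),
    "family_history": ("first-degree", "non-first-degree", "none"),
    "duration_band": ("<5", "5-10", ">10"),
}

COVARIATE_COLUMNS = tuple(COVARIATE_LEVELS)

REQUIRED_COLUMNS = ("subject_id", "visit") + SCORE_COLUMNS + COVARIATE_COLUMNS

DEFAULT_N_VISITS = 9


class SchemaError(ValueError):
    """A required column is missing or has the wrong dtype."""


class ValidationError(ValueError):
    """A row violates a scale-range, visit-range or uniqueness invariant."""


@dataclass(frozen=True)
class FilterReport:
    """Counts of rows removed by a filtering step, keyed by reason/variable."""

    removed: dict[str, int] = field(default_factory=dict)

    @property
    def n_removed(self) -> int:
        return sum(self.removed.values())


@dataclass
class CohortPanel:
    """A validated long-format repeated-measures panel.

    Wraps a :class:`pandas.DataFrame` with the documented schema.  Construct
    through :func:`load_cohort`, :func:`from_dataframe` or the synthetic
    generator; the constructor itself does not re-validate.
    """

    df: pd.DataFrame
    n_visits: int = DEFAULT_N_VISITS

    @property
    def n_subjects(self) -> int:
        return self.df["subject_id"].nunique()

    @property
    def n_rows(self) -> int:
        return len(self.df)

    def baseline(self) -> pd.DataFrame:
        """Rows at visit 0."""
        return self.df[self.df["visit"] == 0]

    def times(self) -> np.ndarray:
        """Normalized study time for every row."""
        return normalize_time(self.df["visit"].to_numpy(), self.n_visits)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"CohortPanel(n_subjects={self.n_subjects}, "
            f"n_visits={self.n_visits}, n_rows={self.n_rows})"
        )


def normalize_time(visit, n_visits: int = DEFAULT_N_VISITS):
    """Min–max normalize a visit index onto [0, 1].

    Visit k of an ``n_visits``-point design maps to ``k / (n_visits - 1)``;
    for the 9-visit design the second, fourth and sixth follow-ups map to
    0.25, 0.50 and 0.75.

    Parameters
    ----------
    visit : int or array-like of int
    n_visits : total number of visits in the design (>= 2)

    Returns
    -------
    float or ndarray in [0, 1]
    """
    if n_visits < 2:
        raise ValueError(f"n_visits must be >= 2, got {n_visits}")
    v = np.asarray(visit)
    if np.any(v < 0) or np.any(v > n_visits - 1):
        raise ValueError(
            f"visit index out of range 0..{n_visits - 1}: {visit!r}"
        )
    t = v / (n_visits - 1)
    return float(t) if np.isscalar(visit) else t


def categorize_depression(gds15: int) -> str:
    """GDS-15 severity band: <5 none, 5–9 mild, >=10 moderate_severe."""
    lo, hi = SCALE_RANGES["gds15"]
    if not lo <= gds15 <= hi:
        raise ValueError(f"gds15 score out of range {lo}..{hi}: {gds15}")
    if gds15 < 5:
        return "none"
    if gds15 < 10:
        return "mild"
    return "moderate_severe"


def categorize_cognition(moca: int) -> str:
    """MoCA band: >=26 normal, otherwise impaired."""
    lo, hi = SCALE_RANGES["moca"]
    if not lo <= moca <= hi:
        raise ValueError(f"moca score out of range {lo}..{hi}: {moca}")
    return "normal" if moca >= 26 else "impaired"


def _validate_frame(
    df: pd.DataFrame, n_visits: int, strict: bool
) -> tuple[pd.DataFrame, FilterReport]:
    """Apply the panel invariants; drop or abort on violations."""
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")

    df = df.copy()
    removed: dict[str, int] = {}
    bad = pd.Series(False, index=df.index)

    visit = pd.to_numeric(df["visit"], errors="coerce")
    bad_visit = visit.isna() | (visit < 0) | (visit > n_visits - 1)
    if bad_visit.any():
        if strict:
            i = df.index[bad_visit][0]
            raise ValidationError(
                f"row {i}: visit={df.loc[i, 'visit']!r} outside 0..{n_visits - 1}"
            )
        removed["visit"] = int(bad_visit.sum())
        bad |= bad_visit
    df["visit"] = visit.fillna(-1).astype(int)

    for col, (lo, hi) in SCALE_RANGES.items():
        x = pd.to_numeric(df[col], errors="coerce")
        out = x.notna() & ((x < lo) | (x > hi))
        if out.any():
            if strict:
                i = df.index[out][0]
                raise ValidationError(
                    f"row {i}: {col}={df.loc[i, col]!r} outside {lo}..{hi}"
                )
            removed[col] = int(out.sum())
            bad |= out
        df[col] = x

    for col, levels in COVARIATE_LEVELS.items():
        vals = df[col].astype("string")
        out = vals.notna() & ~vals.isin(levels)
        if out.any():
            if strict:
                i = df.index[out][0]
                raise ValidationError(
                    f"row {i}: {col}={df.loc[i, col]!r} not in {levels}"
                )
            removed[col] = int(out.sum())
            bad |= out

    df = df[~bad]

    dup = df.duplicated(subset=["subject_id", "visit"], keep="first")
    if dup.any():
        if strict:
            i = df.index[dup][0]
            raise ValidationError(
                f"row {i}: duplicate (subject_id, visit)="
                f"({df.loc[i, 'subject_id']!r}, {df.loc[i, 'visit']!r})"
            )
        removed["duplicate"] = int(dup.sum())
        df = df[~dup]

    return df.reset_index(drop=True), FilterReport(removed)


def from_dataframe(
    df: pd.DataFrame,
    n_visits: int = DEFAULT_N_VISITS,
    strict: bool = True,
) -> CohortPanel | tuple[CohortPanel, FilterReport]:
    """Validate an in-memory frame into a :class:`CohortPanel`.

    In strict mode any invariant violation raises and the panel alone is
    returned; in lenient mode offending rows are dropped and a
    :class:`FilterReport` accompanies the panel.
    """
    clean, report = _validate_frame(df, n_visits, strict)
    panel = CohortPanel(clean, n_visits=n_visits)
    return panel if strict else (panel, report)


def load_cohort(
    path: str | Path,
    strict: bool = True,
    n_visits: int = DEFAULT_N_VISITS,
):
    """Read and validate a long-format cohort CSV.

    Missing values are empty fields.  See :func:`from_dataframe` for the
    strict/lenient contract.
    """
    df = pd.read_csv(path, dtype={"subject_id": str}, keep_default_na=True)
    return from_dataframe(df, n_visits=n_visits, strict=strict)


def write_cohort(panel: CohortPanel, path: str | Path) -> None:
    """Write a panel as CSV with the documented schema (round-trip safe)."""
    out = panel.df.loc[:, list(REQUIRED_COLUMNS)].copy()
    for col in SCORE_COLUMNS:
        vals = pd.to_numeric(out[col])
        # integer scores with missing values -> pandas nullable ints;
        # unclipped (continuous) panels are left as-is
        if (vals.dropna() % 1 == 0).all():
            out[col] = vals.astype("Int64")
    out.to_csv(path, index=False)


def complete_case_filter(
    panel: CohortPanel,
) -> tuple[CohortPanel, FilterReport]:
    """Drop subject-visits missing any analysis variable.

    Returns the filtered panel plus per-variable removal counts (a row
    missing several variables is counted once per variable).  Raises if
    nothing survives.
    """
    df = panel.df
    removed: dict[str, int] = {}
    bad = pd.Series(False, index=df.index)
    for col in SCORE_COLUMNS + COVARIATE_COLUMNS:
        miss = df[col].isna()
        if miss.any():
            removed[col] = int(miss.sum())
        bad |= miss
    kept = df[~bad].reset_index(drop=True)
    if kept.empty:
        raise ValueError(
            "no analyzable data: every row is missing at least one "
            "analysis variable"
        )
    return CohortPanel(kept, n_visits=panel.n_visits), FilterReport(removed)
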