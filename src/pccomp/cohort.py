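"""Reading paired-platform concentration tables and data-level QC filters.

Concentration tables are wide delimited text: one row per sample, one column
per analyte (μmol/L), plus named metadata columns.  The two platforms differ
only in the label dialect of their analyte columns (kit sum labels vs
fatty-acid-level labels).

QC mirrors standard targeted-metabolomics practice on reference-plasma
replicates: analytes with CV > 25% are dropped, as are analytes with
CV > 20% that additionally correlate with the run day.  Coverage filtering
keeps analytes quantified in at least a minimum fraction of study samples.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats

from .nomenclature import parse_lipid_name

#: Metadata columns recognized in input tables, in canonical order.
METADATA_COLUMNS = (
    "sample_id",
    "subject",
    "timepoint",
    "cohort",
    "challenge",
    "phase",
    "sex",
    "group",
    "run_day",
)

CHALLENGES = ("FASTING", "SLD", "OGTT", "PAT", "OLTT", "STRESS")
PHASES = ("baseline", "intervention")


@dataclass
class ConcentrationMatrix:
    """Samples × analytes concentrations with per-sample metadata.

    ``values`` is indexed by sample_id; missing measurements are NaN.
    ``meta`` is aligned on the same index and carries subject / timepoint /
    cohort / challenge / phase / sex / group / run_day columns (absent ones
    filled with NA).
    """

    values: pd.DataFrame
    meta: pd.DataFrame
    platform: str  # "species_level_kit" | "fatty_acid_level"

    def __post_init__(self) -> None:
        if self.platform not in ("species_level_kit", "fatty_acid_level"):
            raise ValueError(f"unknown platform {self.platform!r}")
        if not self.values.index.equals(self.meta.index):
            raise ValueError("values and meta must share the sample index")
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()].tolist()
            raise ValueError(f"duplicate sample_id: {dup}")
        with np.errstate(invalid="ignore"):
            if (self.values.to_numpy(dtype=float) < 0).any():
                raise ValueError("negative concentrations present")
        for col in METADATA_COLUMNS[1:]:
            if col not in self.meta.columns:
                self.meta[col] = pd.NA
        key = self.meta[["cohort", "subject", "timepoint"]].astype("string")
        if key.dropna(how="any").duplicated().any():
            raise ValueError("(subject, timepoint) not unique within cohort")

    @property
    def analytes(self) -> List[str]:
        return list(self.values.columns)

    @property
    def sample_ids(self) -> List[str]:
        return list(self.values.index)

    @property
    def missing_mask(self) -> pd.DataFrame:
        return self.values.isna()

    def subset_samples(self, sample_ids: Sequence) -> "ConcentrationMatrix":
        ids = [s for s in sample_ids if s in self.values.index]
        return ConcentrationMatrix(
            self.values.loc[ids].copy(), self.meta.loc[ids].copy(), self.platform
        )

    def subset_analytes(self, analytes: Sequence[str]) -> "ConcentrationMatrix":
        return ConcentrationMatrix(
            self.values[list(analytes)].copy(), self.meta.copy(), self.platform
        )

    def write(self, path: Union[str, Path]) -> None:
        sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
        out = pd.concat([self.meta[list(METADATA_COLUMNS[1:])], self.values], axis=1)
        out.index.name = "sample_id"
        out.to_csv(path, sep=sep)


@dataclass(frozen=True)
class QCConfig:
    cv_exclude_threshold: float = 0.25
    cv_runday_threshold: float = 0.20
    runday_alpha: float = 0.05
    coverage_min: float = 0.25

    def __post_init__(self) -> None:
        for name in (
            "cv_exclude_threshold",
            "cv_runday_threshold",
            "runday_alpha",
            "coverage_min",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


def read_concentration_table(
    path: Union[str, Path],
    platform: str,
    metadata_columns: Sequence[str] = METADATA_COLUMNS,
) -> ConcentrationMatrix:
    """Read a wide TSV/CSV concentration table into a ConcentrationMatrix.

    Every non-metadata column header must parse as a lipid label of the
    platform's dialect; blank and NA cells become missing values.
    """
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep, dtype={"sample_id": str})
    if "sample_id" not in df.columns:
        raise ValueError("table must contain a 'sample_id' column")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"duplicate sample_id rows: {dup}")
    df = df.set_index("sample_id")
    meta_cols = [c for c in metadata_columns if c in df.columns and c != "sample_id"]
    analyte_cols = [c for c in df.columns if c not in meta_cols]
    renames = {}
    for col in analyte_cols:
        try:
            renames[col] = parse_lipid_name(col).label
        except Exception as exc:
            raise ValueError(f"unparseable analyte column {col!r}: {exc}") from exc
    if len(set(renames.values())) != len(renames):
        seen: dict = {}
        for orig, canon in renames.items():
            if canon in seen:
                raise ValueError(
                    f"columns {seen[canon]!r} and {orig!r} are the same analyte "
                    f"({canon})"
                )
            seen[canon] = orig
    values = (
        df[analyte_cols]
        .apply(pd.to_numeric, errors="coerce")
        .astype(float)
        .rename(columns=renames)  # chain order normalized to canonical labels
    )
    meta = df[meta_cols].copy()
    return ConcentrationMatrix(values=values, meta=meta, platform=platform)


def _cv(series: pd.Series) -> float:
    vals = series.dropna().to_numpy(dtype=float)
    if len(vals) < 2 or vals.mean() == 0:
        return np.nan
    return float(vals.std(ddof=1) / vals.mean())


def qc_filter(
    matrix: ConcentrationMatrix,
    reference_sample_values: pd.DataFrame,
    config: QCConfig = QCConfig(),
    run_day: Optional[pd.Series] = None,
    apply_runday_rule: bool = True,
) -> Tuple[ConcentrationMatrix, pd.DataFrame]:
    """Drop analytes that fail reference-replicate QC; report each decision.

    Rule 1: reference CV > ``cv_exclude_threshold``.
    Rule 2: reference CV > ``cv_runday_threshold`` *and* a significant rank
    correlation (two-sided Spearman at ``runday_alpha``) of the reference
    values with the run-day index.

    ``reference_sample_values`` holds replicate measurements of a reference
    sample (rows = replicates, columns = analytes).  ``run_day`` aligns a
    run-day index to those replicates; required when the run-day rule is on.
    """
    if reference_sample_values is None:
        raise ValueError("reference-sample replicate values are required for QC")
    if apply_runday_rule and run_day is None:
        raise ValueError("run_day index required when the run-day rule is applied")
    rows = []
    keep: List[str] = []
    for analyte in matrix.analytes:
        if analyte not in reference_sample_values.columns:
            raise ValueError(f"no reference replicates for analyte {analyte!r}")
        ref = reference_sample_values[analyte]
        cv = _cv(ref)
        runday_p = np.nan
        decision, reason = "keep", ""
        if np.isnan(cv):
            decision, reason = "keep", "CV not estimable"
        elif cv > config.cv_exclude_threshold:
            decision = "remove"
            reason = f"CV>{config.cv_exclude_threshold:.0%}"
        elif apply_runday_rule and cv > config.cv_runday_threshold:
            paired = pd.concat([ref, run_day.reindex(ref.index)], axis=1).dropna()
            if len(paired) >= 3:
                rho, runday_p = stats.spearmanr(
                    paired.iloc[:, 0], paired.iloc[:, 1]
                )
                if runday_p < config.runday_alpha:
                    decision = "remove"
                    reason = (
                        f"CV>{config.cv_runday_threshold:.0%} and run-day "
                        f"correlation p={runday_p:.3g}"
                    )
        if decision == "keep":
            keep.append(analyte)
        rows.append(
            {
                "analyte": analyte,
                "cv": cv,
                "runday_p": runday_p,
                "decision": decision,
                "reason": reason,
            }
        )
    report = pd.DataFrame(rows)
    return matrix.subset_analytes(keep), report


def coverage_filter(
    matrix: ConcentrationMatrix, coverage_min: float = 0.25
) -> ConcentrationMatrix:
    """Keep analytes quantified in at least ``coverage_min`` of samples
    (inclusive threshold)."""
    frac = matrix.values.notna().mean(axis=0)
    keep = [a for a in matrix.analytes if frac[a] >= coverage_min]
    return matrix.subset_analytes(keep)
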