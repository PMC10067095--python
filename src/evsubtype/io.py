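"""Quantitative abundance tables and clinical annotations.

The central container is :class:`AbundanceMatrix`, a validated features x
samples table of non-negative quantities with an explicit missing marker
(``NaN`` in memory, empty cell or ``NA`` on disk).  Missingness is semantic
in targeted proteomics — a cell below the detection limit is *unquantified*,
never zero — so readers and writers round-trip the missingness pattern
exactly and zero is never used as a sentinel.

Annotations are one row per sample: cohort, clinical group (healthy-control
batches HC1/HC2 or tumor Stage I-IV), demographics, overall-survival time
and event indicator, curative-resection status and an eligibility flag.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "AbundanceMatrix",
    "load_abundance_matrix",
    "write_abundance_matrix",
    "apply_quantification_limit",
    "drop_unquantified_features",
    "collapse_peptides_to_proteins",
    "load_annotations",
    "write_annotations",
    "GROUPS",
    "STAGE_GROUPS",
    "HC_GROUPS",
]

#: Recognized clinical group labels.
HC_GROUPS = ("HC1", "HC2")
STAGE_GROUPS = ("StageI", "StageII", "StageIII", "StageIV")
GROUPS = HC_GROUPS + STAGE_GROUPS

#: Missing-value sentinel used in TSV files (besides the empty cell).
NA_TOKEN = "NA"

ANNOTATION_COLUMNS = [
    "sample_id",
    "cohort",
    "group",
    "age",
    "sex",
    "os_time",
    "os_event",
    "curative_resection",
    "eligible",
]


@dataclasses.dataclass
class AbundanceMatrix:
    """Features x samples quantitative table with explicit missingness.

    Parameters
    ----------
    data : pandas.DataFrame
        Rows are features (peptides or proteins), columns are samples.
        Values are non-negative floats; ``NaN`` marks a missing
        (unquantified) cell.
    level : {"peptide", "protein"}
        Quantification level of the rows.
    feature_to_protein : mapping, optional
        Peptide id -> protein accession.  Required (and complete) when
        ``level == "peptide"``.
    """

    data: pd.DataFrame
    level: str = "protein"
    feature_to_protein: dict[str, str] | None = None

    def __post_init__(self) -> None:
        if self.level not in ("peptide", "protein"):
            raise ValueError(f"level must be 'peptide' or 'protein', got {self.level!r}")
        if not isinstance(self.data, pd.DataFrame):
            self.data = pd.DataFrame(self.data)
        self.data = self.data.astype(float)
        self.data.index.name = "feature_id"
        self.data.columns.name = None
        dup_f = self.data.index[self.data.index.duplicated()].unique().tolist()
        if dup_f:
            raise ValueError(f"duplicated feature ids: {dup_f}")
        dup_s = self.data.columns[self.data.columns.duplicated()].unique().tolist()
        if dup_s:
            raise ValueError(f"duplicated sample ids: {dup_s}")
        neg = np.argwhere(self.data.to_numpy() < 0)
        if neg.size:
            i, j = neg[0]
            raise ValueError(
                "negative value at feature "
                f"{self.data.index[i]!r}, sample {self.data.columns[j]!r}"
            )
        if self.level == "peptide":
            if not self.feature_to_protein:
                raise ValueError("peptide-level matrix requires a feature_to_protein map")
            unmapped = [f for f in self.data.index if f not in self.feature_to_protein]
            if unmapped:
                raise ValueError(f"peptides without protein mapping: {unmapped}")

    # -- convenience -------------------------------------------------------

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    def missing_mask(self) -> pd.DataFrame:
        return self.data.isna()

    @property
    def n_missing(self) -> int:
        return int(self.data.isna().to_numpy().sum())

    def subset_samples(self, sample_ids) -> "AbundanceMatrix":
        return AbundanceMatrix(
            self.data.loc[:, list(sample_ids)].copy(),
            level=self.level,
            feature_to_protein=dict(self.feature_to_protein) if self.feature_to_protein else None,
        )

    def subset_features(self, feature_ids) -> "AbundanceMatrix":
        return AbundanceMatrix(
            self.data.loc[list(feature_ids)].copy(),
            level=self.level,
            feature_to_protein=dict(self.feature_to_protein) if self.feature_to_protein else None,
        )

    def copy(self) -> "AbundanceMatrix":
        return AbundanceMatrix(
            self.data.copy(),
            level=self.level,
            feature_to_protein=dict(self.feature_to_protein) if self.feature_to_protein else None,
        )

    def __eq__(self, other) -> bool:  # pragma: no cover - convenience
        if not isinstance(other, AbundanceMatrix):
            return NotImplemented
        return (
            self.level == other.level
            and self.data.equals(other.data)
            and (self.feature_to_protein or {}) == (other.feature_to_protein or {})
        )


def load_abundance_matrix(
    path: str | Path,
    level: str = "protein",
    feature_to_protein: Mapping[str, str] | None = None,
) -> AbundanceMatrix:
    """Read a TSV abundance table (features in rows, samples in columns).

    The first column holds feature ids, the header row sample ids.  Empty
    cells and the token ``NA`` denote missing values and are preserved as
    missing — never coerced to zero.  Duplicate ids or negative values are
    hard errors naming the offender.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    dup = sorted({s for s in header if header.count(s) > 1})
    if dup:
        raise ValueError(f"duplicated sample ids: {dup}")
    df = pd.read_csv(
        path,
        sep="\t",
        index_col=0,
        na_values=[NA_TOKEN, ""],
        keep_default_na=False,
    )
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return AbundanceMatrix(
        df,
        level=level,
        feature_to_protein=dict(feature_to_protein) if feature_to_protein else None,
    )


def write_abundance_matrix(m: AbundanceMatrix, path: str | Path) -> None:
    """Write a TSV table; missing cells are written as ``NA``."""
    m.data.to_csv(path, sep="\t", na_rep=NA_TOKEN, index_label="feature_id")


def apply_quantification_limit(
    m: AbundanceMatrix, limit: float
) -> tuple[AbundanceMatrix, int]:
    """Censor values below the quantification limit to missing.

    Signals below ``limit`` are unreliable in targeted MS and are treated
    as unquantified.  Values ``>= limit`` pass through unchanged; already
    missing cells stay missing.  Returns the censored matrix and the count
    of newly censored cells.  Idempotent, and monotone in ``limit``.
    """
    if limit < 0:
        raise ValueError("quantification limit must be >= 0")
    vals = m.data.to_numpy(copy=True)
    newly = (vals < limit) & ~np.isnan(vals)
    vals[newly] = np.nan
    out = AbundanceMatrix(
        pd.DataFrame(vals, index=m.data.index, columns=m.data.columns),
        level=m.level,
        feature_to_protein=dict(m.feature_to_protein) if m.feature_to_protein else None,
    )
    return out, int(newly.sum())


def drop_unquantified_features(m: AbundanceMatrix) -> tuple[AbundanceMatrix, int]:
    """Remove features with no present value in any sample.

    A feature never quantified in the current sample set carries no
    information and cannot be imputed; such features arise when the whole
    abundance range sits below the detection limit.  Returns the filtered
    matrix and the number of dropped features.
    """
    keep = ~m.data.isna().all(axis=1)
    return m.subset_features(m.data.index[keep]), int((~keep).sum())


def collapse_peptides_to_proteins(m: AbundanceMatrix) -> AbundanceMatrix:
    """Roll a peptide-level matrix up to protein level.

    Per protein and sample, the value is the mean of the *present* peptide
    values; the cell is missing only if every peptide of the protein is
    missing in that sample.  Mean of present peptides is the conventional
    SRM roll-up.
    """
    if m.level != "peptide":
        raise ValueError("collapse requires a peptide-level matrix")
    if not m.feature_to_protein:
        raise ValueError("empty peptide->protein mapping")
    groups = pd.Series({f: m.feature_to_protein[f] for f in m.feature_ids})
    collapsed = m.data.groupby(groups).mean()  # skipna=True: mean of present values
    collapsed = collapsed.sort_index()
    return AbundanceMatrix(collapsed, level="protein")


# ---------------------------------------------------------------------------
# annotations
# ---------------------------------------------------------------------------

def _validate_annotations(df: pd.DataFrame) -> pd.DataFrame:
    missing_cols = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"annotation table lacks columns: {missing_cols}")
    dup = df["sample_id"][df["sample_id"].duplicated()].unique().tolist()
    if dup:
        raise ValueError(f"duplicated sample ids in annotations: {dup}")
    bad_group = sorted(set(df["group"]) - set(GROUPS))
    if bad_group:
        raise ValueError(f"unknown group labels: {bad_group}")
    bad_cohort = sorted(set(df["cohort"]) - {"cohort1", "cohort2"})
    if bad_cohort:
        raise ValueError(f"unknown cohort labels: {bad_cohort}")
    is_hc = df["group"].isin(HC_GROUPS)
    if df.loc[is_hc, "os_time"].notna().any() or df.loc[is_hc, "os_event"].notna().any():
        raise ValueError("healthy-control samples must not carry survival fields")
    pat = df.loc[~is_hc]
    if (pat["os_time"].dropna() < 0).any():
        raise ValueError("os_time must be >= 0")
    bad_ev = set(pat["os_event"].dropna().unique()) - {0, 1}
    if bad_ev:
        raise ValueError(f"os_event must be 0 or 1, got {sorted(bad_ev)}")
    return df.set_index("sample_id", drop=False)


def load_annotations(path: str | Path) -> pd.DataFrame:
    """Read the per-sample clinical annotation TSV and validate it."""
    df = pd.read_csv(
        path,
        sep="\t",
        na_values=[NA_TOKEN, ""],
        keep_default_na=False,
        dtype={"sample_id": str, "cohort": str, "group": str, "sex": str},
    )
    if "eligible" in df.columns:
        df["eligible"] = df["eligible"].map(
            {"True": True, "False": False, True: True, False: False, 1: True, 0: False}
        )
    if "curative_resection" in df.columns:
        df["curative_resection"] = df["curative_resection"].where(
            df["curative_resection"].notna(), None
        )
    return _validate_annotations(df)


def write_annotations(ann: pd.DataFrame, path: str | Path) -> None:
    ann.to_csv(path, sep="\t", na_rep=NA_TOKEN, index=False)
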