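"""Cohort-1 biomarker-candidate screening.

The screening stage combines three routes to a candidate list:

* target-set logic — proteins found both in the literature-search set and
  in either the experimental discovery set or the public EV-protein
  database, plus manual additions (:func:`select_targets`);
* a three-comparison Mann-Whitney-Wilcoxon screen: Stage I vs HC1 (A),
  Stage IV vs HC2 (B), Stage I vs Stage IV (C), each at raw p < alpha
  (:func:`mww_screen`);
* Breiman-style unsupervised random forests on two sample sets — patients
  only (run D) and patients plus controls (run E) — whose top-N features
  by importance join the candidate list (:func:`unsupervised_rf`,
  :func:`assemble_candidates`).

Per-feature provenance letters A-E record which route(s) selected each
feature; a feature is a candidate iff its provenance is non-empty.
"""

from __future__ import annotations

import dataclasses
import itertools
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from .io import AbundanceMatrix

__all__ = [
    "MWWResult",
    "CandidateSelection",
    "RFResult",
    "ScreenResult",
    "select_targets",
    "mww_test",
    "mww_screen",
    "unsupervised_rf",
    "mds_embed",
    "assemble_candidates",
    "screen_cohort1",
]

#: Largest per-group size for which the exact permutation null is used.
EXACT_N_MAX = 8

COMPARISONS = {
    "A": ("StageI", "HC1"),
    "B": ("StageIV", "HC2"),
    "C": ("StageI", "StageIV"),
}


def select_targets(
    ls: Iterable[str],
    ep: Iterable[str],
    pb: Iterable[str],
    manual: Iterable[str] = (),
) -> set[str]:
    """Combine candidate sources into the target panel.

    Keeps proteins present in both the literature set and either the
    experimental or the public-database set, then adds manual picks:
    ``(ls & pb) | (ls & ep) | manual``.
    """
    ls, ep, pb, manual = set(ls), set(ep), set(pb), set(manual)
    return (ls & pb) | (ls & ep) | manual


@dataclasses.dataclass(frozen=True)
class MWWResult:
    """Mann-Whitney U statistic and two-sided p; NaN = not computable."""

    u: float
    p: float

    @property
    def computable(self) -> bool:
        return not np.isnan(self.p)


def _exact_mww(x: np.ndarray, y: np.ndarray) -> MWWResult:
    """Exact two-sided MWW by full enumeration of group assignments.

    Handles ties correctly (midranks), unlike shift-algorithm exact
    methods; feasible because both groups have <= 8 observations.  The
    two-sided p is the probability, under random relabelling, of a U at
    least as far from its null mean n1*n2/2 as the observed one.
    """
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    offset = n1 * (n1 + 1) / 2.0
    u_obs = ranks[:n1].sum() - offset
    combos = np.array(
        list(itertools.combinations(range(n1 + n2), n1)), dtype=np.intp
    )
    u_all = ranks[combos].sum(axis=1) - offset
    mu = n1 * n2 / 2.0
    p = float(np.mean(np.abs(u_all - mu) >= np.abs(u_obs - mu) - 1e-9))
    return MWWResult(u=float(u_obs), p=p)


def mww_test(x, y) -> MWWResult:
    """Two-sided Mann-Whitney-Wilcoxon test on present values.

    Missing values are dropped first.  If either group is then empty the
    result is marked not computable (NaN) rather than raising, so a
    feature-by-feature screen can continue past unquantifiable features.
    For small samples (both groups <= 8) the exact permutation null is
    enumerated; otherwise the normal approximation with tie correction
    and continuity correction is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x = x[~np.isnan(x)]
    y = y[~np.isnan(y)]
    if x.size == 0 or y.size == 0:
        return MWWResult(u=np.nan, p=np.nan)
    if x.size <= EXACT_N_MAX and y.size <= EXACT_N_MAX:
        return _exact_mww(x, y)
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    p = float(min(max(res.pvalue, np.nextafter(0, 1)), 1.0))
    return MWWResult(u=float(res.statistic), p=p)


def _geometric_mean(v: np.ndarray) -> float:
    v = v[~np.isnan(v)]
    if v.size == 0:
        return np.nan
    return float(np.exp(np.mean(np.log(v))))


class CandidateSelection:
    """Per-feature screening record.

    Wraps a table with MWW p-values and fold changes for comparisons
    A/B/C, importance ranks for the two RF runs (D, E), the provenance
    letter set and the selected flag.  ``selected`` is true iff the
    provenance set is non-empty.
    """

    def __init__(self, table: pd.DataFrame, feature_to_protein: dict | None = None):
        self.table = table
        self.feature_to_protein = feature_to_protein
        self._check()

    def _check(self) -> None:
        for col in ("p_A", "p_B", "p_C"):
            pv = self.table[col].dropna()
            if ((pv < 0) | (pv > 1)).any():
                raise ValueError(f"{col} outside [0, 1]")
        prov_nonempty = self.table["provenance"].map(bool)
        if not (self.table["selected"] == prov_nonempty).all():
            raise ValueError("selected flag must equal provenance non-emptiness")
        for col in ("rank_D", "rank_E"):
            r = self.table[col].dropna()
            if r.size and (r.duplicated().any() or (r < 1).any()):
                raise ValueError(f"{col} must be unique positive ranks")

    @classmethod
    def empty(cls, feature_ids, feature_to_protein=None) -> "CandidateSelection":
        tbl = pd.DataFrame(
            {
                "p_A": np.nan, "p_B": np.nan, "p_C": np.nan,
                "fc_A": np.nan, "fc_B": np.nan, "fc_C": np.nan,
                "rank_D": np.nan, "rank_E": np.nan,
                "provenance": [frozenset() for _ in feature_ids],
                "selected": False,
            },
            index=pd.Index(feature_ids, name="feature_id"),
        )
        return cls(tbl, feature_to_protein)

    @property
    def selected_features(self) -> list[str]:
        return list(self.table.index[self.table["selected"]])

    @property
    def n_selected_features(self) -> int:
        return int(self.table["selected"].sum())

    @property
    def selected_proteins(self) -> list[str]:
        feats = self.selected_features
        if self.feature_to_protein:
            return sorted({self.feature_to_protein[f] for f in feats})
        return sorted(feats)

    @property
    def n_selected_proteins(self) -> int:
        return len(self.selected_proteins)

    def to_frame(self) -> pd.DataFrame:
        out = self.table.copy()
        out["provenance"] = out["provenance"].map(lambda s: ",".join(sorted(s)))
        return out

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", na_rep="NA")

    def summary(self) -> str:
        lines = [
            "Candidate screen",
            f"  features screened:  {len(self.table)}",
            f"  selected features:  {self.n_selected_features}",
            f"  selected proteins:  {self.n_selected_proteins}",
        ]
        for letter in "ABCDE":
            n = int(self.table["provenance"].map(lambda s, L=letter: L in s).sum())
            lines.append(f"  provenance {letter}:       {n}")
        return "\n".join(lines)


def mww_screen(
    m: AbundanceMatrix, annotations: pd.DataFrame, alpha: float = 0.05
) -> CandidateSelection:
    """Three-comparison MWW screen over every feature.

    Runs comparisons A (Stage I vs HC1), B (Stage IV vs HC2) and C
    (Stage I vs Stage IV) on present values only; a feature gains
    provenance letter L iff ``p_L < alpha``.  A comparison with an empty
    group for some feature is marked not computable for that feature;
    a required group absent from the annotations entirely is an error.
    """
    ann = annotations.loc[annotations["sample_id"].isin(m.sample_ids)]
    group_samples: dict[str, list[str]] = {}
    for grp in ("StageI", "StageIV", "HC1", "HC2"):
        ids = ann.loc[ann["group"] == grp, "sample_id"].tolist()
        if not ids:
            raise ValueError(f"required group {grp!r} has no samples")
        group_samples[grp] = ids

    sel = CandidateSelection.empty(m.feature_ids, m.feature_to_protein)
    tbl = sel.table
    provenance = {feat: set() for feat in m.feature_ids}
    for letter, (g1, g2) in COMPARISONS.items():
        v1 = m.data[group_samples[g1]].to_numpy()
        v2 = m.data[group_samples[g2]].to_numpy()
        pvals, fcs = [], []
        for i, feat in enumerate(m.feature_ids):
            res = mww_test(v1[i], v2[i])
            pvals.append(res.p)
            fcs.append(_geometric_mean(v1[i]) / _geometric_mean(v2[i]))
            if res.computable and res.p < alpha:
                provenance[feat].add(letter)
        tbl[f"p_{letter}"] = pvals
        tbl[f"fc_{letter}"] = fcs
    tbl["provenance"] = [frozenset(provenance[f]) for f in m.feature_ids]
    tbl["selected"] = tbl["provenance"].map(bool)
    return CandidateSelection(tbl, m.feature_to_protein)


@dataclasses.dataclass
class RFResult:
    """Unsupervised random-forest output for one sample set."""

    importance: pd.Series  # feature -> importance score
    proximity: np.ndarray  # samples x samples, fraction of shared leaves
    sample_ids: list[str]


def _half_min_impute_rows(values: np.ndarray) -> np.ndarray:
    """Row-wise half-minimum imputation on a features x samples array."""
    out = values.copy()
    for i in range(out.shape[0]):
        row = out[i]
        mask = np.isnan(row)
        if mask.all():
            raise ValueError(f"feature row {i} has no present values")
        if mask.any():
            row[mask] = np.nanmin(row) / 2.0
    return out


def unsupervised_rf(
    m: AbundanceMatrix | pd.DataFrame,
    n_trees: int = 1000,
    seed: int | None = None,
    importance: str = "impurity",
) -> RFResult:
    """Breiman-style unsupervised random forest.

    A synthetic contrast class is built by independently permuting each
    feature column (destroying the joint structure while keeping the
    marginals); a forest then classifies real vs synthetic samples.
    Feature importance is the mean impurity decrease (``importance=
    "permutation"`` switches to permutation importance), and
    ``proximity[i, j]`` is the fraction of trees in which real samples i
    and j fall in the same terminal node (diagonal 1).

    Missing cells are imputed with the per-feature half-minimum rule
    before fitting, consistent with the clustering stage.
    """
    from sklearn.ensemble import RandomForestClassifier

    data = m.data if isinstance(m, AbundanceMatrix) else m
    if data.shape[1] < 4:
        raise ValueError("unsupervised RF needs at least 4 samples")
    # a feature never quantified in this sample subset carries no signal
    data = data.loc[~data.isna().all(axis=1)]
    rng = np.random.default_rng(seed)
    X = _half_min_impute_rows(data.to_numpy()).T  # samples x features
    n, p = X.shape
    synth = np.column_stack([rng.permutation(X[:, j]) for j in range(p)])
    X_all = np.vstack([X, synth])
    y = np.r_[np.zeros(n, dtype=int), np.ones(n, dtype=int)]
    clf = RandomForestClassifier(
        n_estimators=n_trees,
        random_state=int(rng.integers(2**31 - 1)),
        n_jobs=1,
    )
    clf.fit(X_all, y)
    if importance == "impurity":
        imp = clf.feature_importances_
    elif importance == "permutation":
        from sklearn.inspection import permutation_importance

        imp = permutation_importance(
            clf, X_all, y, n_repeats=5,
            random_state=int(rng.integers(2**31 - 1)),
        ).importances_mean
    else:
        raise ValueError(f"unknown importance kind {importance!r}")
    leaves = clf.apply(X)  # n x n_trees terminal-node ids
    prox = (leaves[:, None, :] == leaves[None, :, :]).mean(axis=2)
    np.fill_diagonal(prox, 1.0)
    return RFResult(
        importance=pd.Series(imp, index=data.index, name="importance"),
        proximity=prox,
        sample_ids=list(data.columns),
    )


def mds_embed(proximity: np.ndarray, n_components: int = 2) -> np.ndarray:
    """Classical (Torgerson) MDS of ``1 - proximity`` dissimilarities.

    Double-centers the squared dissimilarity matrix and returns the
    coordinates of the top eigenpairs (negative eigenvalues clipped to
    zero, as usual for non-Euclidean inputs).
    """
    P = np.asarray(proximity, dtype=float)
    if P.ndim != 2 or P.shape[0] != P.shape[1]:
        raise ValueError("proximity must be square")
    if not np.allclose(P, P.T, atol=1e-10):
        raise ValueError("proximity must be symmetric")
    D = 1.0 - P
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    evals, evecs = np.linalg.eigh(B)
    order = np.argsort(evals)[::-1][:n_components]
    lam = np.clip(evals[order], 0.0, None)
    return evecs[:, order] * np.sqrt(lam)


def _ranks_from_importance(imp: pd.Series) -> pd.Series:
    """Unique 1-based ranks, largest importance first, stable on ties."""
    order = np.argsort(-imp.to_numpy(), kind="stable")
    ranks = np.empty(len(imp), dtype=int)
    ranks[order] = np.arange(1, len(imp) + 1)
    return pd.Series(ranks, index=imp.index)


def assemble_candidates(
    screen: CandidateSelection,
    importance_d: pd.Series | None,
    importance_e: pd.Series | None,
    top_n: int = 50,
) -> CandidateSelection:
    """Merge the MWW screen with the top-N features of each RF run.

    The selected set becomes (MWW-selected) U (top-N of run D) U (top-N
    of run E); provenance letters accumulate per feature.
    """
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    tbl = screen.table.copy()
    for letter, imp in (("D", importance_d), ("E", importance_e)):
        if imp is None:
            continue
        ranks = _ranks_from_importance(imp)
        tbl.loc[ranks.index, f"rank_{letter}"] = ranks
        top = ranks.index[ranks <= top_n]
        tbl.loc[top, "provenance"] = tbl.loc[top, "provenance"].map(
            lambda s, L=letter: s | {L}
        )
    tbl["selected"] = tbl["provenance"].map(bool)
    return CandidateSelection(tbl, screen.feature_to_protein)


@dataclasses.dataclass
class ScreenResult:
    """Full cohort-1 screening output."""

    candidates: CandidateSelection
    rf_patients: RFResult  # run D: Stage I and IV samples
    rf_all: RFResult  # run E: Stage I, IV, HC1 and HC2 samples
    mds_patients: pd.DataFrame
    mds_all: pd.DataFrame

    def summary(self) -> str:
        return self.candidates.summary()


def screen_cohort1(
    m: AbundanceMatrix,
    annotations: pd.DataFrame,
    alpha: float = 0.05,
    top_n: int = 50,
    n_trees: int = 1000,
    seed: int | None = None,
    importance: str = "impurity",
) -> ScreenResult:
    """Run the complete cohort-1 screening stage.

    MWW screen over comparisons A/B/C, then unsupervised RF on the
    patient samples (run D: Stage I + IV) and on patients plus controls
    (run E: Stage I, IV, HC1, HC2), MDS embeddings of both proximity
    matrices, and candidate assembly with the top-``top_n`` rule.
    """
    ss = np.random.SeedSequence(seed) if seed is not None else np.random.SeedSequence()
    seed_d, seed_e = (int(c.generate_state(1)[0] % (2**31 - 1)) for c in ss.spawn(2))

    screen = mww_screen(m, annotations, alpha=alpha)
    ann = annotations.loc[annotations["sample_id"].isin(m.sample_ids)]
    pat_ids = ann.loc[ann["group"].isin(["StageI", "StageIV"]), "sample_id"].tolist()
    all_ids = ann.loc[
        ann["group"].isin(["StageI", "StageIV", "HC1", "HC2"]), "sample_id"
    ].tolist()
    rf_d = unsupervised_rf(m.subset_samples(pat_ids), n_trees, seed_d, importance)
    rf_e = unsupervised_rf(m.subset_samples(all_ids), n_trees, seed_e, importance)
    mds_d = pd.DataFrame(
        mds_embed(rf_d.proximity), index=rf_d.sample_ids, columns=["mds1", "mds2"]
    )
    mds_e = pd.DataFrame(
        mds_embed(rf_e.proximity), index=rf_e.sample_ids, columns=["mds1", "mds2"]
    )
    candidates = assemble_candidates(screen, rf_d.importance, rf_e.importance, top_n)
    return ScreenResult(candidates, rf_d, rf_e, mds_d, mds_e)
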