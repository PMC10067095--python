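"""Consensus-clustering subtype discovery (Monti resampling scheme).

The patient x protein table is repeatedly subsampled; each subsample is
partitioned by an inner clusterer, and the consensus index

    M(i, j) = (# rounds i and j co-cluster) / (# rounds both are drawn)

summarizes how reliably two samples travel together.  Stability of a
candidate cluster number k is read off the empirical CDF of the
off-diagonal consensus indices through the proportion of ambiguous
clustering, PAC = CDF(x2) - CDF(x1) with the conventional interval
(0.1, 0.9): a near-bimodal consensus distribution (entries near 0 or 1)
gives a low PAC, and the k minimizing PAC is selected.  Final subtype
labels come from average-linkage agglomeration of the 1 - M
dissimilarity.

`ConsensusSubtyper` is the model object (data + resampling scheme);
`fit()` returns a :class:`ConsensusRun` results object carrying per-k
consensus matrices, CDFs, PAC values, the chosen k and the labels.

Upstream of clustering, :func:`impute_missing` fills detection-limit
(missing-not-at-random) cells; the default replaces a feature's missing
cells with half its minimum observed level, the standard MNAR rule for
targeted proteomics.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from statsmodels.distributions.empirical_distribution import ECDF

from .io import AbundanceMatrix

__all__ = [
    "impute_missing",
    "ConsensusMatrix",
    "ConsensusRun",
    "ConsensusSubtyper",
    "consensus_cluster",
    "consensus_cdf",
    "pac",
    "select_k",
    "final_labels",
]


# ---------------------------------------------------------------------------
# imputation
# ---------------------------------------------------------------------------

def impute_missing(m: AbundanceMatrix, method: str = "half_min") -> AbundanceMatrix:
    """Fill missing cells; present values are never altered.

    Methods
    -------
    half_min
        Per feature, missing <- (minimum present value) / 2.  The default
        detection-limit surrogate: a cell is missing because the level
        was below what the instrument quantifies.
    min
        Per feature, missing <- minimum present value.
    knn
        Feature-space k-nearest-neighbour average (k = 5) on log scale:
        features with similar profiles across samples lend their values.

    A feature with zero present values cannot be imputed and raises an
    error naming it.
    """
    vals = m.data.to_numpy(copy=True)
    all_missing = np.isnan(vals).all(axis=1)
    if all_missing.any():
        bad = [m.feature_ids[i] for i in np.flatnonzero(all_missing)]
        raise ValueError(f"features with no present values cannot be imputed: {bad}")
    if method in ("half_min", "min"):
        factor = 0.5 if method == "half_min" else 1.0
        row_min = np.nanmin(vals, axis=1)
        rows, cols = np.nonzero(np.isnan(vals))
        vals[rows, cols] = row_min[rows] * factor
    elif method == "knn":
        from sklearn.impute import KNNImputer

        if (vals[~np.isnan(vals)] <= 0).any():
            raise ValueError("knn imputation requires positive present values")
        log_vals = np.log(vals)
        imputer = KNNImputer(n_neighbors=min(5, vals.shape[0] - 1))
        vals = np.exp(imputer.fit_transform(log_vals))
        # restore present values exactly (imputer leaves them, but guard fp)
        present = ~m.data.isna().to_numpy()
        vals[present] = m.data.to_numpy()[present]
    else:
        raise ValueError(f"unknown imputation method {method!r}")
    return AbundanceMatrix(
        pd.DataFrame(vals, index=m.data.index, columns=m.data.columns),
        level=m.level,
        feature_to_protein=dict(m.feature_to_protein) if m.feature_to_protein else None,
    )


# ---------------------------------------------------------------------------
# consensus machinery
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class ConsensusMatrix:
    """Consensus indices with their co-cluster / co-draw counts."""

    sample_ids: list[str]
    M: np.ndarray
    co_count: np.ndarray
    joint_count: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.sample_ids)
        for name in ("M", "co_count", "joint_count"):
            a = getattr(self, name)
            if a.shape != (n, n):
                raise ValueError(f"{name} must be {n}x{n}")
            if not np.allclose(a, a.T, atol=1e-12):
                raise ValueError(f"{name} must be symmetric")
        if (self.co_count > self.joint_count).any():
            raise ValueError("co_count must be <= joint_count elementwise")
        if ((self.M < -1e-12) | (self.M > 1 + 1e-12)).any():
            raise ValueError("consensus indices must lie in [0, 1]")
        if not np.allclose(np.diag(self.M), 1.0):
            raise ValueError("consensus matrix diagonal must be 1")

    def upper_triangle(self) -> np.ndarray:
        iu = np.triu_indices(len(self.sample_ids), k=1)
        return self.M[iu]


def consensus_cdf(cm: ConsensusMatrix) -> ECDF:
    """Right-continuous empirical CDF of the upper-triangle indices.

    ``CDF(c)`` is the fraction of sample pairs with consensus index
    ``<= c``; ``CDF(1) = 1``.
    """
    return ECDF(cm.upper_triangle())


def pac(cm: ConsensusMatrix, x1: float = 0.1, x2: float = 0.9) -> float:
    """Proportion of ambiguous clustering: ``CDF(x2) - CDF(x1)``.

    The fraction of sample pairs whose consensus index falls in the
    intermediate interval (x1, x2] — pairs the resampling could not
    commit to either co-clustering or separating.  Low PAC = stable k.
    """
    if not x1 < x2:
        raise ValueError("pac bounds must satisfy x1 < x2")
    cdf = consensus_cdf(cm)
    return float(cdf(x2) - cdf(x1))


def select_k(pac_values: "Mapping[int, float] | ConsensusRun") -> int:
    """The k minimizing PAC; ties break toward the smallest k."""
    if isinstance(pac_values, ConsensusRun):
        pac_values = pac_values.pac_values
    best_k, best = None, math.inf
    for k in sorted(pac_values):
        if pac_values[k] < best - 1e-15:
            best_k, best = k, pac_values[k]
    return best_k


def final_labels(cm: ConsensusMatrix, k: int) -> pd.Series:
    """Cut the consensus dissimilarity into k groups.

    Average-linkage agglomerative clustering on ``1 - M``; labels are
    1..k ordered by decreasing group size so that "cluster 1" is the
    largest and stable across runs.
    """
    from sklearn.cluster import AgglomerativeClustering

    n = len(cm.sample_ids)
    if not 2 <= k <= n - 1:
        raise ValueError("k must satisfy 2 <= k <= n_samples - 1")
    D = 1.0 - cm.M
    np.fill_diagonal(D, 0.0)
    raw = AgglomerativeClustering(
        n_clusters=k, metric="precomputed", linkage="average"
    ).fit_predict(D)
    sizes = pd.Series(raw).value_counts()
    if len(sizes) < k:
        raise ValueError("empty cluster after cut")
    # stable relabel: decreasing size, ties by first appearance
    order = sorted(sizes.index, key=lambda c: (-sizes[c], int(np.argmax(raw == c))))
    remap = {old: new + 1 for new, old in enumerate(order)}
    return pd.Series([remap[c] for c in raw], index=cm.sample_ids, name="subtype")


def _standardize(data: pd.DataFrame, transform: str | None) -> np.ndarray:
    """Features x samples -> samples x features array ready for clustering."""
    X = data.to_numpy().T.astype(float)
    if np.isnan(X).any():
        raise ValueError("consensus clustering requires a complete matrix")
    if transform == "log2_zscore":
        if (X <= 0).any():
            raise ValueError("log2 transform requires positive values")
        X = np.log2(X)
    elif transform not in ("zscore", None):
        raise ValueError(f"unknown transform {transform!r}")
    if transform in ("log2_zscore", "zscore"):
        mu = X.mean(axis=0)
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0  # constant features carry no signal; leave centered
        X = (X - mu) / sd
    return X


def _make_inner(
    inner: str | Callable, rng: np.random.Generator
) -> Callable[[np.ndarray, int], np.ndarray]:
    if callable(inner):
        return inner
    if inner == "kmeans":
        from sklearn.cluster import KMeans

        def fit(X: np.ndarray, k: int) -> np.ndarray:
            rs = int(rng.integers(2**31 - 1))
            return KMeans(n_clusters=k, n_init=10, random_state=rs).fit_predict(X)

        return fit
    if inner == "ward":
        from sklearn.cluster import AgglomerativeClustering

        def fit(X: np.ndarray, k: int) -> np.ndarray:
            return AgglomerativeClustering(n_clusters=k, linkage="ward").fit_predict(X)

        return fit
    raise ValueError(f"unknown inner clusterer {inner!r}")


@dataclasses.dataclass
class ConsensusRun:
    """Results of a consensus-clustering fit.

    Carries the per-k consensus matrices, CDFs and PAC values, the PAC
    interval, the selected k and the final subtype labels.
    """

    sample_ids: list[str]
    k_range: list[int]
    matrices: dict[int, ConsensusMatrix]
    cdfs: dict[int, ECDF]
    pac_values: dict[int, float]
    pac_bounds: tuple[float, float]
    chosen_k: int | None = None
    labels: pd.Series | None = None

    def cluster_sizes(self) -> dict[int, int]:
        if self.labels is None:
            return {}
        return self.labels.value_counts().sort_index().to_dict()

    def summary(self) -> str:
        x1, x2 = self.pac_bounds
        lines = [
            "Consensus clustering",
            f"  samples: {len(self.sample_ids)}   "
            f"PAC interval: ({x1:g}, {x2:g})",
            "  k    PAC",
        ]
        for k in self.k_range:
            mark = "  <- selected" if k == self.chosen_k else ""
            lines.append(f"  {k:<4d} {self.pac_values[k]:.4f}{mark}")
        if self.labels is not None:
            sizes = ", ".join(f"{c}: n={n}" for c, n in self.cluster_sizes().items())
            lines.append(f"  subtype sizes: {sizes}")
        return "\n".join(lines)

    def plot_cdf(self, ax=None):
        """Overlay the per-k consensus-index CDFs (diagnostic plot)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        grid = np.linspace(0, 1, 201)
        for k in self.k_range:
            ax.step(grid, self.cdfs[k](grid), where="post", label=f"k={k}")
        ax.set_xlabel("consensus index")
        ax.set_ylabel("CDF")
        ax.legend(fontsize=8)
        return ax

    def write_tables(self, outdir) -> None:
        from pathlib import Path

        outdir = Path(outdir)
        pd.DataFrame(
            {"k": self.k_range, "pac": [self.pac_values[k] for k in self.k_range]}
        ).to_csv(outdir / "pac.tsv", sep="\t", index=False)
        for k, cm in self.matrices.items():
            pd.DataFrame(cm.M, index=cm.sample_ids, columns=cm.sample_ids).to_csv(
                outdir / f"consensus_k{k}.tsv", sep="\t"
            )
        if self.labels is not None:
            self.labels.rename("subtype").to_csv(outdir / "labels.tsv", sep="\t")


def consensus_cluster(
    data: AbundanceMatrix | pd.DataFrame,
    k_range: Sequence[int] | tuple[int, int] = (2, 8),
    n_resamples: int = 1000,
    subsample_fraction: float = 0.8,
    inner: str | Callable = "kmeans",
    seed: int | None = None,
    subsamples: Sequence[np.ndarray] | None = None,
    pac_bounds: tuple[float, float] = (0.1, 0.9),
    transform: str | None = "log2_zscore",
) -> ConsensusRun:
    """Build per-k consensus matrices by repeated subsampling.

    Features are standardized (log2 then per-feature z-score by default),
    then for each k and each round a fraction of samples is drawn without
    replacement and partitioned by the inner clusterer; co-clustering and
    co-draw counts accumulate into the consensus matrix.  ``subsamples``
    may supply an explicit list of sample-index arrays (used for every k)
    in place of random draws — e.g. an exhaustive enumeration for exact
    oracle checks.

    The returned run has PAC computed for every k but no chosen k; use
    :func:`select_k` / :func:`final_labels` or :class:`ConsensusSubtyper`.
    """
    df = data.data if isinstance(data, AbundanceMatrix) else data
    sample_ids = list(df.columns)
    n = len(sample_ids)
    if len(k_range) == 2 and not isinstance(k_range, list):
        ks = list(range(int(k_range[0]), int(k_range[1]) + 1))
    else:
        ks = sorted(int(k) for k in k_range)
    if n < max(ks) + 2:
        raise ValueError("need at least max(k_range) + 2 samples")
    if not 0 < subsample_fraction < 1:
        raise ValueError("subsample_fraction must be in (0, 1)")
    X = _standardize(df, transform)
    rng = np.random.default_rng(seed)
    cluster = _make_inner(inner, rng)
    m_sub = math.ceil(subsample_fraction * n)

    matrices: dict[int, ConsensusMatrix] = {}
    cdfs: dict[int, ECDF] = {}
    pac_values: dict[int, float] = {}
    offdiag = ~np.eye(n, dtype=bool)
    for k in ks:
        co = np.zeros((n, n))
        joint = np.zeros((n, n))
        if subsamples is not None:
            draws = [np.asarray(s, dtype=np.intp) for s in subsamples]
        else:
            draws = [rng.choice(n, size=m_sub, replace=False) for _ in range(n_resamples)]
        for idx in draws:
            labels = np.asarray(cluster(X[idx], k))
            block = np.ix_(idx, idx)
            joint[block] += 1
            co[block] += labels[:, None] == labels[None, :]
        if (joint[offdiag] == 0).any():
            raise ValueError(
                "some sample pairs were never co-drawn; increase n_resamples"
            )
        with np.errstate(invalid="ignore"):
            M = np.where(joint > 0, co / np.maximum(joint, 1), 0.0)
        np.fill_diagonal(M, 1.0)
        cm = ConsensusMatrix(sample_ids, M, co, joint)
        matrices[k] = cm
        cdfs[k] = consensus_cdf(cm)
        pac_values[k] = pac(cm, *pac_bounds)
    return ConsensusRun(
        sample_ids=sample_ids,
        k_range=ks,
        matrices=matrices,
        cdfs=cdfs,
        pac_values=pac_values,
        pac_bounds=tuple(pac_bounds),
    )


class ConsensusSubtyper:
    """Consensus-clustering subtype model.

    Parameters
    ----------
    data : AbundanceMatrix or DataFrame
        Features x samples quantitative table.  Missing cells are filled
        with the configured imputation method at fit time.
    k_range, n_resamples, subsample_fraction, inner, pac_bounds
        Resampling scheme; see :func:`consensus_cluster`.
    imputation : {"half_min", "min", "knn"}

    Examples
    --------
    >>> model = ConsensusSubtyper.from_abundance(matrix, k_range=(2, 6))
    >>> run = model.fit(seed=7)
    >>> run.chosen_k, run.labels.value_counts()  # doctest: +SKIP
    """

    def __init__(
        self,
        data: AbundanceMatrix | pd.DataFrame,
        k_range: tuple[int, int] = (2, 8),
        n_resamples: int = 1000,
        subsample_fraction: float = 0.8,
        inner: str | Callable = "kmeans",
        pac_bounds: tuple[float, float] = (0.1, 0.9),
        imputation: str = "half_min",
        transform: str | None = "log2_zscore",
    ):
        if isinstance(data, pd.DataFrame):
            data = AbundanceMatrix(data)
        self.data = data
        self.k_range = k_range
        self.n_resamples = n_resamples
        self.subsample_fraction = subsample_fraction
        self.inner = inner
        self.pac_bounds = pac_bounds
        self.imputation = imputation
        self.transform = transform

    @classmethod
    def from_abundance(cls, m: AbundanceMatrix, **kwargs) -> "ConsensusSubtyper":
        return cls(m, **kwargs)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "ConsensusSubtyper":
        return cls(AbundanceMatrix(df), **kwargs)

    def fit(
        self,
        seed: int | None = None,
        subsamples: Sequence[np.ndarray] | None = None,
    ) -> ConsensusRun:
        """Run the resampling, select k by minimum PAC, extract labels."""
        m = self.data
        if m.n_missing:
            m = impute_missing(m, self.imputation)
        run = consensus_cluster(
            m,
            k_range=self.k_range,
            n_resamples=self.n_resamples,
            subsample_fraction=self.subsample_fraction,
            inner=self.inner,
            seed=seed,
            subsamples=subsamples,
            pac_bounds=self.pac_bounds,
            transform=self.transform,
        )
        run.chosen_k = select_k(run.pac_values)
        run.labels = final_labels(run.matrices[run.chosen_k], run.chosen_k)
        return run
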