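"""Compositional transforms, ordination, distance-based testing, diversity.

Peak-area and count tables are compositional: only relative information is
meaningful.  The robust centered log-ratio (rclr) transform maps each
sample's observed (non-zero) entries to log abundances centered on the
geometric mean of those observed entries, records the zeros in a mask, and
leaves them at 0 — the convention that makes downstream Euclidean
distances an Aitchison geometry on the observed parts.

PERMANOVA tests group-centroid separation on those distances with a
permutation pseudo-F; Shannon diversity is computed on (optionally
rarefied) proportions in natural-log units.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from sklearn.decomposition import PCA

from .datasets import TaxonTable, TransformedMatrix
from .qc import rarefy as _rarefy

__all__ = [
    "rclr",
    "pca",
    "permanova",
    "PermanovaResult",
    "shannon",
    "wilcoxon_rank_sum",
]


def rclr(
    matrix: np.ndarray,
    sample_ids: list[str] | None = None,
    feature_ids: list[str] | None = None,
) -> TransformedMatrix:
    """Robust centered log-ratio transform of a samples x features matrix.

    Per sample: observed entries become ln(x) minus the mean log over that
    sample's positive entries; zeros are masked and set to 0.  Scale
    invariant per sample; requires >= 2 positive entries per sample.
    """
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2:
        raise ValueError("expected a 2-D samples x features matrix")
    if np.any(x < 0):
        raise ValueError("negative entries are not compositional")
    zero_mask = x == 0
    n_pos = (~zero_mask).sum(axis=1)
    if np.any(n_pos < 2):
        bad = int(np.argmin(n_pos))
        raise ValueError(f"sample index {bad} has fewer than 2 positive entries")
    out = np.zeros_like(x)
    logs = np.where(zero_mask, 0.0, np.log(np.where(zero_mask, 1.0, x)))
    row_mean = logs.sum(axis=1) / n_pos
    out = np.where(zero_mask, 0.0, logs - row_mean[:, None])
    n_s, n_f = x.shape
    return TransformedMatrix(
        values=out,
        sample_ids=sample_ids or [f"s{i}" for i in range(n_s)],
        feature_ids=feature_ids or [f"f{i}" for i in range(n_f)],
        zero_mask=zero_mask,
        transform="rclr",
    )


def pca(
    t: TransformedMatrix, n_components: int = 2
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Centered-SVD principal components: (scores, loadings, explained
    variance fractions)."""
    x = t.values
    if x.shape[0] < 2:
        raise ValueError("PCA needs at least 2 samples")
    rank = int(np.linalg.matrix_rank(x - x.mean(axis=0)))
    if n_components > rank:
        raise ValueError(f"n_components={n_components} exceeds rank {rank}")
    model = PCA(n_components=n_components, svd_solver="full")
    scores = model.fit_transform(x)
    return scores, model.components_.T, model.explained_variance_ratio_


@dataclass(frozen=True)
class PermanovaResult:
    pseudo_f: float
    p_value: float
    n_permutations: int
    grouping: str = ""


def _pseudo_f(d2: np.ndarray, labels: np.ndarray) -> float:
    """Permutational pseudo-F from squared distances (Anderson's identity:
    sums of squares from pairwise distances within groups)."""
    n = d2.shape[0]
    groups = np.unique(labels)
    a = groups.size
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    for g in groups:
        idx = np.flatnonzero(labels == g)
        if idx.size < 1:
            raise ValueError(f"empty group {g!r}")
        sub = d2[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(idx.size, 1)].sum() / idx.size
    ss_between = ss_total - ss_within
    return (ss_between / (a - 1)) / (ss_within / (n - a))


def permanova(
    t: TransformedMatrix,
    groups,
    n_permutations: int = 999,
    seed: int = 0,
    grouping: str = "",
) -> PermanovaResult:
    """PERMANOVA on Euclidean distances of the transformed matrix.

    With an rclr input this is a test in Aitchison geometry.  The p-value
    is (1 + #{permuted F >= observed}) / (n_permutations + 1), so it can
    never be 0.
    """
    labels = np.asarray(groups)
    x = t.values
    if np.unique(labels).size < 2:
        raise ValueError("PERMANOVA needs >= 2 groups")
    if x.shape[0] < 3:
        raise ValueError("PERMANOVA needs >= 3 samples")
    if labels.size != x.shape[0]:
        raise ValueError("label length does not match sample count")
    d2 = squareform(pdist(x, metric="sqeuclidean"))
    f_obs = _pseudo_f(d2, labels)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_permutations):
        perm = rng.permutation(labels)
        if _pseudo_f(d2, perm) >= f_obs:
            exceed += 1
    p = (1 + exceed) / (n_permutations + 1)
    return PermanovaResult(
        pseudo_f=float(f_obs),
        p_value=float(p),
        n_permutations=n_permutations,
        grouping=grouping,
    )


def shannon(
    table: TaxonTable, rarefied: bool = True, seed: int = 0
) -> np.ndarray:
    """Per-sample Shannon diversity H = -sum p ln p (natural-log units).

    With ``rarefied=True`` (the alpha-diversity convention here), counts
    are first subsampled without replacement to the minimum sample depth.
    """
    depths = table.depths
    if np.any(depths == 0):
        raise ValueError("sample with zero depth")
    if rarefied:
        table = _rarefy(table, int(depths.min()), seed=seed)
    props = table.proportions()
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(props > 0, props * np.log(props), 0.0)
    return -terms.sum(axis=0)


def wilcoxon_rank_sum(x, y) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Exact enumeration for small samples (<= 25 total) without ties; normal
    approximation with tie correction otherwise.  Identical multisets give
    p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups need at least one value")
    if x.size == y.size and np.array_equal(np.sort(x), np.sort(y)):
        return 1.0
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (pooled.size <= 25 and not has_ties) else "asymptotic"
    return float(
        stats.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue
    )
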