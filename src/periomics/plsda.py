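"""Two-class PLS-DA with VIP scores and leave-one-out cross-validation.

Partial least squares discriminant analysis regresses a {0, 1} class
indicator on the (centered, unit-variance scaled) feature matrix with a
small number of latent components.  Per-feature importance is the VIP
(variable importance in projection) score

    VIP_j = sqrt( p * sum_k [ SS_k (w_jk / ||w_k||)^2 ] / sum_k SS_k )

with ``p`` the number of features, ``w_k`` the component weight vectors
and ``SS_k`` the class variance explained by component ``k``.  The
definition forces mean(VIP^2) = 1, so VIP > 1 marks features contributing
more than average to the discrimination.

Model quality is the leave-one-out classification error rate (CER);
models with CER < 0.5 beat label-permutation chance and are considered
discriminatory, with an optional permutation p-value.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.cross_decomposition import PLSRegression

from .datasets import TransformedMatrix

__all__ = ["PlsdaModel", "CvReport", "fit_plsda", "cross_validate", "select_vip"]

log = logging.getLogger("periomics")


@dataclass
class PlsdaModel:
    n_components: int
    weights: np.ndarray  # features x components
    loadings: np.ndarray
    scores: np.ndarray  # samples x components
    vip: np.ndarray  # per retained feature
    feature_ids: list[str]
    classes: tuple[str, str]
    class_means: np.ndarray  # 2 x features, on the scaled data
    dropped_features: list[str] = field(default_factory=list)


def _encode_labels(labels) -> tuple[np.ndarray, tuple[str, str]]:
    labels = np.asarray(labels)
    classes = tuple(sorted(map(str, np.unique(labels))))
    if len(classes) != 2:
        raise ValueError(f"PLS-DA requires exactly two classes, got {classes}")
    y = (labels.astype(str) == classes[1]).astype(float)
    if y.sum() < 2 or (1 - y).sum() < 2:
        raise ValueError("each class needs at least 2 samples")
    return y, classes  # type: ignore[return-value]


def _scale(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    keep = x.std(axis=0) > 0
    xs = x[:, keep]
    xs = (xs - xs.mean(axis=0)) / xs.std(axis=0)
    return xs, keep


def _vip(pls: PLSRegression) -> np.ndarray:
    w = pls.x_weights_  # p x k
    t = pls.x_scores_  # n x k
    q = pls.y_loadings_  # 1 x k
    p, k = w.shape
    ss = (q[0] ** 2) * (t**2).sum(axis=0)  # class variance per component
    w_norm = w / np.linalg.norm(w, axis=0, keepdims=True)
    return np.sqrt(p * (w_norm**2 @ ss) / ss.sum())


def fit_plsda(
    t: TransformedMatrix, labels, n_components: int = 2
) -> PlsdaModel:
    """Fit a two-class PLS-DA model and compute VIP scores.

    Features are centered and unit-variance scaled; constant features are
    dropped with a warning.  Deterministic given input order.
    """
    y, classes = _encode_labels(labels)
    x = t.values
    xs, keep = _scale(x)
    dropped = [f for f, k in zip(t.feature_ids, keep) if not k]
    if dropped:
        log.warning("dropping %d constant feature(s) before PLS-DA", len(dropped))
    n_components = min(n_components, xs.shape[0] - 1, xs.shape[1])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pls = PLSRegression(n_components=n_components, scale=False)
        pls.fit(xs, y)
    means = np.vstack(
        [xs[np.asarray(labels).astype(str) == c].mean(axis=0) for c in classes]
    )
    return PlsdaModel(
        n_components=n_components,
        weights=pls.x_weights_,
        loadings=pls.x_loadings_,
        scores=pls.x_scores_,
        vip=_vip(pls),
        feature_ids=[f for f, k in zip(t.feature_ids, keep) if k],
        classes=classes,
        class_means=means,
        dropped_features=dropped,
    )


@dataclass(frozen=True)
class CvReport:
    cer: float
    scheme: str
    n_permutations: int
    permutation_p: float | None


def _loo_cer(x: np.ndarray, y: np.ndarray, n_components: int) -> float:
    n = x.shape[0]
    errors = 0
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        y_tr = y[mask]
        if y_tr.min() == y_tr.max():  # a fold lost a class entirely
            errors += 1
            continue
        x_tr = x[mask]
        mu = x_tr.mean(axis=0)
        sd = x_tr.std(axis=0)
        sd[sd == 0] = 1.0
        k = min(n_components, x_tr.shape[0] - 1, x_tr.shape[1])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pls = PLSRegression(n_components=k, scale=False)
            pls.fit((x_tr - mu) / sd, y_tr)
            pred = float(np.ravel(pls.predict(((x[i] - mu) / sd)[None, :]))[0])
        if (pred >= 0.5) != bool(y[i]):
            errors += 1
    return errors / n


def cross_validate(
    t: TransformedMatrix,
    labels,
    n_components: int = 2,
    n_permutations: int = 999,
    seed: int = 0,
) -> CvReport:
    """Leave-one-out CER with an optional label-permutation p-value.

    The permutation p is (1 + #{permuted CER <= observed}) / (n_perm + 1);
    pass ``n_permutations=0`` to skip it.
    """
    y, _ = _encode_labels(labels)
    x = t.values[:, t.values.std(axis=0) > 0]
    if x.shape[0] < 6:
        raise ValueError("leave-one-out CV needs >= 6 samples")
    cer = _loo_cer(x, y, n_components)
    perm_p: float | None = None
    if n_permutations > 0:
        rng = np.random.default_rng(seed)
        hits = 0
        for _ in range(n_permutations):
            if _loo_cer(x, rng.permutation(y), n_components) <= cer:
                hits += 1
        perm_p = (1 + hits) / (n_permutations + 1)
    return CvReport(
        cer=float(cer),
        scheme="leave-one-out",
        n_permutations=n_permutations,
        permutation_p=perm_p,
    )


def select_vip(
    model: PlsdaModel, threshold: float = 1.0, treated_class: str | None = None
) -> dict[str, str]:
    """Label features by discriminative importance and direction.

    Features with VIP > ``threshold`` are ``up``/``down`` by the sign of
    (treated mean - control mean) on the scaled data; ties and the rest
    are ``ns``.  ``treated_class`` defaults to the second (sorted) class
    label — pass ``"AMP"`` explicitly for study data.
    """
    treated = treated_class if treated_class is not None else model.classes[1]
    if treated not in model.classes:
        raise ValueError(f"unknown class {treated!r}")
    ti = model.classes.index(treated)
    diff = model.class_means[ti] - model.class_means[1 - ti]
    out: dict[str, str] = {}
    for fid, vip, d in zip(model.feature_ids, model.vip, diff):
        if vip > threshold and d > 0:
            out[fid] = "up"
        elif vip > threshold and d < 0:
            out[fid] = "down"
        else:
            out[fid] = "ns"
    for fid in model.dropped_features:
        out[fid] = "ns"
    return out
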