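"""Class-conditional diagonal GMMs and pairwise likelihood-ratio decisions.

Each perceptual level 0-3 gets its own Gaussian mixture
``p(x|Theta_i) = sum_r lambda_r N(x; mu_r, Sigma_r)`` fitted by EM.
A file is scored against a model by the mean per-frame log-likelihood,
and every unordered class pair (i, j) carries a threshold Gamma on the
log-likelihood ratio, fixed at the equal-error-rate point of the
training-file scores. The predicted class is the one with most pairwise
wins (ties: largest total score margin, then lowest class index).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp
from sklearn.cluster import KMeans

COV_FLOOR_REL = 1e-6
EM_TOL = 1e-5
EM_MAX_ITER = 200


@dataclass
class GmmModel:
    weights: np.ndarray           # (g,), positive, sums to 1
    means: np.ndarray             # (g, d)
    covariances: np.ndarray       # (g, d) diagonal entries
    class_label: int | None = None
    loglik_history: list = field(default_factory=list, repr=False)

    @property
    def g(self) -> int:
        return len(self.weights)

    @property
    def d(self) -> int:
        return self.means.shape[1]


def _component_logpdfs(m: GmmModel, X: np.ndarray) -> np.ndarray:
    """log N(x; mu_r, diag Sigma_r) for all rows and components, (n, g)."""
    const = -0.5 * (m.d * np.log(2.0 * np.pi)
                    + np.log(m.covariances).sum(axis=1))
    diff = X[:, None, :] - m.means[None, :, :]
    quad = 0.5 * (diff ** 2 / m.covariances[None, :, :]).sum(axis=2)
    return const[None, :] - quad


def loglik(m: GmmModel, x: np.ndarray) -> np.ndarray | float:
    """log p(x|Theta) via log-sum-exp; accepts a vector or a row matrix."""
    X = np.atleast_2d(np.asarray(x, dtype=np.float64))
    if X.shape[1] != m.d:
        raise ValueError(f"dimension mismatch: model d={m.d}, "
                         f"input d={X.shape[1]}")
    ll = logsumexp(_component_logpdfs(m, X) + np.log(m.weights)[None, :],
                   axis=1)
    return float(ll[0]) if np.ndim(x) == 1 else ll


def fit_gmm(frames: np.ndarray, g: int, seed: int = 0,
            tol: float = EM_TOL, max_iter: int = EM_MAX_ITER,
            class_label: int | None = None) -> GmmModel:
    """EM-fitted diagonal GMM, initialized from k-means.

    Stops when the mean log-likelihood improves by less than ``tol`` or
    after ``max_iter`` iterations. Covariances are floored at
    ``1e-6 * var(feature)`` so no component collapses. If fewer than
    ``5*g`` frames are available, g is lowered with a warning.
    """
    X = np.asarray(frames, dtype=np.float64)
    if X.ndim != 2 or X.shape[0] == 0:
        raise ValueError("need a non-empty (n_frames, d) matrix")
    n, d = X.shape
    if n < 5 * g:
        g_new = max(1, n // 5)
        warnings.warn(f"only {n} frames for g={g}; lowering to g={g_new}")
        g = g_new

    feat_var = X.var(axis=0)
    floor = COV_FLOOR_REL * np.maximum(feat_var, np.finfo(float).tiny)

    km = KMeans(n_clusters=g, n_init=3, random_state=seed).fit(X)
    assign = km.labels_
    weights = np.array([max((assign == r).sum(), 1) for r in range(g)],
                       dtype=np.float64)
    weights /= weights.sum()
    means = km.cluster_centers_.copy()
    covs = np.empty((g, d))
    for r in range(g):
        sel = assign == r
        covs[r] = X[sel].var(axis=0) if sel.sum() > 1 else feat_var
    covs = np.maximum(covs, floor)

    model = GmmModel(weights, means, covs, class_label)
    prev = -np.inf
    for _ in range(max_iter):
        # E step
        weighted = _component_logpdfs(model, X) + np.log(model.weights)
        norm = logsumexp(weighted, axis=1)
        model.loglik_history.append(float(norm.mean()))
        resp = np.exp(weighted - norm[:, None])
        if model.loglik_history[-1] - prev < tol and prev > -np.inf:
            break
        prev = model.loglik_history[-1]
        # M step
        nk = resp.sum(axis=0) + 1e-12
        model.weights = nk / nk.sum()
        model.means = (resp.T @ X) / nk[:, None]
        diff2 = (X[:, None, :] - model.means[None, :, :]) ** 2
        model.covariances = np.maximum(
            (resp[:, :, None] * diff2).sum(axis=0) / nk[:, None], floor)
    return model


def file_score(m: GmmModel, frames: np.ndarray) -> float:
    """Mean per-frame log-likelihood of one file under a model."""
    X = np.atleast_2d(np.asarray(frames, dtype=np.float64))
    if X.shape[0] == 0:
        raise ValueError("file has no frames")
    return float(np.mean(loglik(m, X)))


def eer_threshold(scores_pos, scores_neg) -> float:
    """Threshold where false-acceptance equals false-rejection.

    ``scores_pos`` are likelihood ratios of true class-i files (should
    exceed the threshold), ``scores_neg`` of class-j files. The sweep
    evaluates FAR/FRR at midpoints between consecutive pooled scores and
    interpolates linearly where FAR - FRR changes sign; perfectly
    separated sets yield the midpoint of the separating gap.
    """
    pos = np.sort(np.asarray(scores_pos, dtype=np.float64))
    neg = np.sort(np.asarray(scores_neg, dtype=np.float64))
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both score lists must be non-empty")
    all_scores = np.unique(np.concatenate([pos, neg]))
    if len(all_scores) == 1:
        return float(all_scores[0])
    cand = np.concatenate([[all_scores[0] - 1.0],
                           0.5 * (all_scores[:-1] + all_scores[1:]),
                           [all_scores[-1] + 1.0]])
    far = np.array([(neg > c).mean() for c in cand])     # accepted impostors
    frr = np.array([(pos <= c).mean() for c in cand])    # rejected genuines
    diff = frr - far                                     # increasing in c
    k = int(np.searchsorted(diff >= 0, True))
    if k == 0:
        return float(cand[0])
    if k == len(cand):
        return float(cand[-1])
    if diff[k] == 0:
        return float(cand[k])
    x0, x1 = cand[k - 1], cand[k]
    y0, y1 = diff[k - 1], diff[k]
    return float(x0 - y0 * (x1 - x0) / (y1 - y0))


def classify_file(models: dict[int, GmmModel],
                  thresholds: dict[tuple[int, int], float],
                  frames: np.ndarray) -> int:
    """4-class decision by pairwise likelihood-ratio votes.

    For each pair (i, j) with i < j, class i wins when
    ``score_i - score_j >= Gamma_ij``. The class with most wins is
    returned; ties break on the total score margin, then on the lowest
    class index.
    """
    labels = sorted(models)
    scores = {c: file_score(models[c], frames) for c in labels}
    wins = {c: 0 for c in labels}
    for a in range(len(labels)):
        for b in range(a + 1, len(labels)):
            i, j = labels[a], labels[b]
            if (i, j) in thresholds:
                gamma = thresholds[(i, j)]
            elif (j, i) in thresholds:
                gamma = -thresholds[(j, i)]
            else:
                raise KeyError(f"missing threshold for class pair ({i},{j})")
            if scores[i] - scores[j] >= gamma:
                wins[i] += 1
            else:
                wins[j] += 1
    margin = {c: sum(scores[c] - scores[o] for o in labels if o != c)
              for c in labels}
    return min(labels, key=lambda c: (-wins[c], -margin[c], c))
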