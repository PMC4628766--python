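"""Leave-one-out evaluation: folds, confusion metrics, kappa, agreement filter.

The full experiment mirrors a supervised perceptual-emulation setup:
per LOO fold, the dimensionality reduction and the four class GMMs are
refitted on the training files only, pairwise likelihood-ratio
thresholds are fixed at the equal-error-rate point of the training file
scores, and the held-out file is classified. Fold confusion matrices
are summed; efficiency (percent correct) comes with a 95% binomial
confidence half-width, and Cohen's kappa is interpreted on the Altman
scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import ExperimentConfig
from .dimreduction import apply as project
from .dimreduction import fit_lda, fit_pca
from .gmm import classify_file, eer_threshold, fit_gmm, loglik

N_LEVELS = 4

ALTMAN_SCALE = [(0.20, "Poor"), (0.40, "Fair"), (0.60, "Medium"),
                (0.80, "Good"), (1.00, "Excellent")]


# ---------------------------------------------------------------------------
# label table and agreement subsets

def load_label_table(path) -> pd.DataFrame:
    """Read a per-file rating table (columns file, G1..G3, R1..R3).

    Missing ratings may be empty cells or a dash; they become NaN.
    """
    df = pd.read_csv(path, dtype={"file": str})
    needed = {"file", "G1", "G2", "G3", "R1", "R2", "R3"}
    missing = needed - set(df.columns)
    if missing:
        raise ValueError(f"label table lacks columns: {sorted(missing)}")
    if df["file"].duplicated().any():
        raise ValueError("duplicate file ids in label table")
    for col in needed - {"file"}:
        df[col] = pd.to_numeric(
            df[col].replace({"—": None, "-": None, "": None}),
            errors="coerce")
    return df


def agreement_subset(table: pd.DataFrame, trait: str) -> pd.DataFrame:
    """Files whose three ratings of a trait are present and identical.

    Returns a frame with columns ``file`` and ``label``.
    """
    if trait not in ("G", "R"):
        raise ValueError("trait must be 'G' or 'R'")
    cols = [f"{trait}{i}" for i in (1, 2, 3)]
    sub = table[["file"] + cols].dropna()
    agree = (sub[cols[0]] == sub[cols[1]]) & (sub[cols[1]] == sub[cols[2]])
    out = sub.loc[agree, ["file", cols[0]]].rename(columns={cols[0]: "label"})
    out["label"] = out["label"].astype(int)
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# confusion metrics

@dataclass
class ConfusionMatrix:
    counts: np.ndarray = field(
        default_factory=lambda: np.zeros((N_LEVELS, N_LEVELS), dtype=int))

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != (N_LEVELS, N_LEVELS) or (self.counts < 0).any():
            raise ValueError("confusion matrix must be 4x4 with counts >= 0")

    def add(self, target: int, predicted: int) -> None:
        self.counts[target, predicted] += 1

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def per_class_recall(self) -> np.ndarray:
        row = self.counts.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(row > 0, np.diag(self.counts) / row, np.nan)


def efficiency(cm: ConfusionMatrix) -> tuple[float, float]:
    """Percent correct and the 95% binomial CI half-width (both in %)."""
    n = cm.total
    if n == 0:
        raise ValueError("empty confusion matrix")
    p = np.trace(cm.counts) / n
    half = 1.96 * np.sqrt(p * (1.0 - p) / n)
    return 100.0 * p, 100.0 * half


def cohens_kappa(cm: ConfusionMatrix) -> float:
    """Chance-corrected agreement between targets and predictions."""
    n = cm.total
    if n == 0:
        raise ValueError("empty confusion matrix")
    po = np.trace(cm.counts) / n
    pe = float((cm.counts.sum(axis=1) * cm.counts.sum(axis=0)).sum()) / n ** 2
    if pe == 1.0:
        if po == 1.0:
            return 1.0
        raise ValueError("kappa undefined: expected agreement is 1")
    return (po - pe) / (1.0 - pe)


def altman(kappa: float) -> str:
    """Altman interpretation of a kappa value (rounded to 2 decimals)."""
    if not -1.0 <= kappa <= 1.0:
        raise ValueError("kappa must lie in [-1, 1]")
    k = round(kappa, 2)
    for upper, label in ALTMAN_SCALE:
        if k <= upper:
            return label
    return "Excellent"


# ---------------------------------------------------------------------------
# cross-validation driver

def loo_folds(n: int):
    """Yield (test_index, train_indices) for leave-one-out over n files."""
    if n < 2:
        raise ValueError("need at least 2 files for LOO")
    idx = np.arange(n)
    for k in range(n):
        yield k, idx[idx != k]


def kfold_folds(n: int, k: int, seed: int = 0):
    """Yield (test_indices, train_indices) for shuffled k-fold CV."""
    if not 2 <= k <= n:
        raise ValueError("need 2 <= k <= n")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    for part in np.array_split(perm, k):
        train = np.setdiff1d(perm, part)
        yield part, train


@dataclass
class EvalResult:
    efficiency: float             # %
    ci_halfwidth: float           # %
    kappa: float
    altman_label: str
    confusion: ConfusionMatrix
    predictions: np.ndarray       # per file, aligned with the input order
    targets: np.ndarray


def _fit_fold(train_feats, train_labels, cfg: ExperimentConfig, seed: int):
    """Fit standardization + reduction + per-class GMMs + EER thresholds.

    Features are z-scored with training-fold statistics first: the raw
    morphological features mix units (dB, pitch ratios, counts) whose
    variances differ by orders of magnitude, which would otherwise
    decide the principal components by scale instead of structure.
    """
    X = np.vstack(train_feats)
    frame_labels = np.concatenate(
        [np.full(len(f), lab) for f, lab in zip(train_feats, train_labels)])

    mu = X.mean(axis=0)
    sigma = X.std(axis=0)
    sigma[sigma <= 0] = 1.0
    Xs = (X - mu) / sigma

    if cfg.reduction == "pca":
        proj = fit_pca(Xs, cfg.pca_reduction_pct)
    elif cfg.reduction == "lda":
        proj = fit_lda(Xs, frame_labels)
    else:
        proj = None

    if proj is not None:
        tx = lambda M: project(proj, (np.atleast_2d(M) - mu) / sigma)
    else:
        tx = lambda M: (np.atleast_2d(M) - mu) / sigma

    class_rows = {c: tx(X[frame_labels == c]) for c in range(N_LEVELS)}
    models = {c: fit_gmm(class_rows[c], cfg.g, seed=seed + c, class_label=c)
              for c in range(N_LEVELS)}

    # pairwise EER thresholds from the training *frame* log-likelihood
    # ratios: the quantity thresholded at test time is the per-file mean
    # LR, but a LOO training fold holds too few files per class for a
    # stable EER estimate, so the crossing point is located on the much
    # larger frame-level LR distributions instead
    ll = {(c, m): loglik(models[m], class_rows[c])
          for c in range(N_LEVELS) for m in range(N_LEVELS)}
    thresholds = {}
    for i in range(N_LEVELS):
        for j in range(i + 1, N_LEVELS):
            pos = ll[(i, i)] - ll[(i, j)]
            neg = ll[(j, i)] - ll[(j, j)]
            thresholds[(i, j)] = eer_threshold(pos, neg)
    return tx, models, thresholds


def run_experiment(feature_matrices, labels, cfg: ExperimentConfig,
                   cv: str = "loo", k: int = 6) -> EvalResult:
    """Cross-validated 4-class evaluation over per-file feature matrices.

    ``feature_matrices`` is a list of (n_frames, d) arrays (one per
    file) and ``labels`` the per-file target levels 0-3. Reduction and
    GMMs are refitted inside every fold; fold confusion matrices are
    summed into one 4x4 table.
    """
    labels = np.asarray(labels, dtype=int)
    n = len(feature_matrices)
    if n != len(labels):
        raise ValueError("one label per feature matrix required")
    if set(np.unique(labels)) - set(range(N_LEVELS)):
        raise ValueError("labels must be in 0..3")

    folds = (loo_folds(n) if cv == "loo"
             else kfold_folds(n, k, seed=cfg.seed))
    cm = ConfusionMatrix()
    predictions = np.full(n, -1)
    for fold_no, (test_idx, train_idx) in enumerate(folds):
        train_feats = [feature_matrices[i] for i in train_idx]
        train_labels = labels[train_idx]
        if len(np.unique(train_labels)) < N_LEVELS:
            raise ValueError("a fold lost an entire class; "
                             "use more files per class")
        tx, models, thresholds = _fit_fold(
            train_feats, train_labels, cfg, seed=cfg.seed + 1000 * fold_no)
        for t in np.atleast_1d(test_idx):
            pred = classify_file(models, thresholds, tx(feature_matrices[t]))
            predictions[t] = pred
            cm.add(labels[t], pred)

    eff, ci = efficiency(cm)
    kap = cohens_kappa(cm)
    return EvalResult(efficiency=eff, ci_halfwidth=ci, kappa=kap,
                      altman_label=altman(kap), confusion=cm,
                      predictions=predictions, targets=labels)
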