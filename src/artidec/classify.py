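"""Template-matching classification of movement trials.

The high-frequency-band envelope is smoothed with a centered 0.5 s moving
average, z-scored per electrode over the full run, and epoched into 2 s
trials starting at cue onset.  A per-class template is the mean over
training trials — either a per-electrode vector after time-averaging
(*spatial* mode) or the full electrode × time matrix (*spatio-temporal*
mode).  A test trial is assigned to the class whose template it correlates
with best (Pearson, winner-takes-all; ties go to the lowest class index).

Cross-validation is stratified 10-fold (with 20 trials per class each fold
holds 2 trials of every class); electrode selection (permutation r² + FDR)
is re-run inside every fold on training trials only, so the test fold never
influences feature selection.  Leave-one-trial-out cross-validation, used by
the localization procedures, takes the electrode subset as given.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .hfb import HfbEnvelope
from .select import permutation_fdr, trial_means
from .sim import permute_movement_labels

__all__ = [
    "TrialTensor",
    "TemplateSet",
    "CvResult",
    "moving_average",
    "smooth_zscore_epoch",
    "build_templates",
    "classify_trial",
    "stratified_folds",
    "crossvalidate",
    "loocv",
    "accuracy_significance",
]


# ---------------------------------------------------------------------------
# smoothing, z-scoring, epoching
# ---------------------------------------------------------------------------

def moving_average(x: np.ndarray, window_samples: int) -> np.ndarray:
    """Centered moving average along the last axis, truncated at the edges
    (each output sample is the mean of the window samples that exist)."""
    if window_samples < 1:
        raise ValueError("window_samples must be >= 1")
    n = x.shape[-1]
    h_left = (window_samples - 1) // 2
    h_right = window_samples // 2
    c = np.cumsum(x, axis=-1, dtype=np.float64)
    c = np.concatenate([np.zeros(x.shape[:-1] + (1,)), c], axis=-1)
    i = np.arange(n)
    lo = np.maximum(i - h_left, 0)
    hi = np.minimum(i + h_right, n - 1) + 1
    return (c[..., hi] - c[..., lo]) / (hi - lo)


@dataclass(frozen=True)
class TrialTensor:
    """Epoched, smoothed, z-scored movement trials (rest excluded)."""

    data: np.ndarray        # (n_trials, n_electrodes, n_times)
    labels: np.ndarray      # class label strings per trial
    electrodes: np.ndarray  # channel indices the electrode axis refers to
    sampling_rate_hz: float
    smoothing_s: float
    epoch_s: float

    def __post_init__(self) -> None:
        d = np.asarray(self.data, dtype=np.float64)
        if d.ndim != 3:
            raise ValueError("data must be (trials, electrodes, times)")
        if d.shape[0] != len(self.labels):
            raise ValueError("one label per trial required")
        if d.shape[1] != len(self.electrodes):
            raise ValueError("electrode axis does not match electrode list")
        object.__setattr__(self, "data", d)
        object.__setattr__(self, "labels", np.asarray(self.labels, dtype=object))
        object.__setattr__(self, "electrodes",
                           np.asarray(self.electrodes, dtype=np.int64))

    @property
    def classes(self) -> list[str]:
        return sorted(set(self.labels))

    def features(self, mode: str, electrode_cols: np.ndarray | None = None) -> np.ndarray:
        """Per-trial feature matrix: spatial → time-averaged electrode
        vector; spatiotemporal → flattened electrode × time."""
        d = self.data if electrode_cols is None else self.data[:, electrode_cols, :]
        if mode == "spatial":
            return d.mean(axis=2)
        if mode == "spatiotemporal":
            return d.reshape(d.shape[0], -1)
        raise ValueError("mode must be 'spatial' or 'spatiotemporal'")


def smooth_zscore_epoch(env: HfbEnvelope, electrodes: np.ndarray | None = None,
                        smoothing_s: float = 0.5, epoch_s: float = 2.0) -> TrialTensor:
    """Moving-average smooth, z-score per electrode over the full run, then
    epoch the movement trials (rest trials are not epoched).

    A zero-variance electrode z-scores to all-zero.  Raises if an epoch
    would extend past the end of the run.
    """
    fs = env.sampling_rate_hz
    if electrodes is None:
        electrodes = np.arange(env.n_channels)
    electrodes = np.asarray(electrodes, dtype=np.int64)
    if len(electrodes) == 0:
        raise ValueError("electrodes must be nonempty")
    w = max(1, int(round(smoothing_s * fs)))
    sm = moving_average(env.power[electrodes], w)
    mu = sm.mean(axis=1, keepdims=True)
    sd = sm.std(axis=1, keepdims=True)
    z = np.where(sd > 0, (sm - mu) / np.where(sd > 0, sd, 1.0), 0.0)

    ev = env.events
    n_t = int(round(epoch_s * fs))
    mov = np.flatnonzero(ev.movement_mask)
    data = np.empty((len(mov), len(electrodes), n_t))
    for row, i in enumerate(mov):
        start = int(ev.onset_sample[i])
        if start + n_t > env.n_samples:
            raise ValueError(f"epoch of trial {i} extends past the end of the run")
        data[row] = z[:, start:start + n_t]
    return TrialTensor(data, ev.label[mov], electrodes, fs, smoothing_s, epoch_s)


# ---------------------------------------------------------------------------
# templates and winner-takes-all correlation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TemplateSet:
    """One template per class: electrode vector (spatial) or electrode ×
    time matrix (spatiotemporal)."""

    mode: str
    classes: tuple[str, ...]
    templates: np.ndarray  # (n_classes, ...) matching the trial features


def build_templates(tensor: TrialTensor, train_idx: np.ndarray,
                    mode: str = "spatial") -> TemplateSet:
    """Class templates = mean over that class's training trials."""
    train_idx = np.asarray(train_idx)
    classes = tensor.classes
    labels = tensor.labels[train_idx]
    if mode == "spatial":
        feats = tensor.data.mean(axis=2)[train_idx]
    elif mode == "spatiotemporal":
        feats = tensor.data[train_idx]  # keep electrode × time shape
    else:
        raise ValueError("mode must be 'spatial' or 'spatiotemporal'")
    out = []
    for cls in classes:
        rows = labels == cls
        if not rows.any():
            raise ValueError(f"no training trial of class {cls!r}")
        out.append(feats[rows].mean(axis=0))
    return TemplateSet(mode, tuple(classes), np.stack(out))


def _pearson_rows(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pearson correlation between each row of `a` and each row of `b`;
    zero-variance rows correlate 0."""
    ac = a - a.mean(axis=1, keepdims=True)
    bc = b - b.mean(axis=1, keepdims=True)
    na = np.linalg.norm(ac, axis=1)
    nb = np.linalg.norm(bc, axis=1)
    denom = np.outer(na, nb)
    num = ac @ bc.T
    out = np.zeros_like(num)
    np.divide(num, denom, out=out, where=denom > 0)
    return out


def classify_trial(trial: np.ndarray, templates: TemplateSet) -> str:
    """Winner-takes-all: the class whose template best correlates with the
    trial's feature vector (ties → lowest class index)."""
    feat = np.asarray(trial, dtype=np.float64).ravel()[None, :]
    temp = templates.templates.reshape(len(templates.classes), -1)
    corr = _pearson_rows(feat, temp)[0]
    return templates.classes[int(np.argmax(corr))]


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CvResult:
    """Accuracy per fold, summary statistics, and the confusion matrix."""

    fold_accuracies: np.ndarray
    mean_accuracy: float
    sd_accuracy: float
    confusion: np.ndarray  # (n_classes, n_classes), rows = true class
    classes: tuple[str, ...]
    n_folds: int
    p_value: float | None = None
    fold_electrodes: tuple = field(default=(), repr=False)

    def to_dict(self) -> dict:
        d = {
            "fold_accuracies": [float(a) for a in self.fold_accuracies],
            "mean_accuracy": float(self.mean_accuracy),
            "sd_accuracy": float(self.sd_accuracy),
            "confusion": self.confusion.tolist(),
            "classes": list(self.classes),
            "n_folds": int(self.n_folds),
        }
        if self.p_value is not None:
            d["p_value"] = float(self.p_value)
        return d


def stratified_folds(labels: np.ndarray, k: int, seed: int = 0) -> list[np.ndarray]:
    """Split trials into k folds with an equal share of every class.

    With 20 trials per class and k=10 each fold holds 2 trials per class.
    Raises if any class count is not divisible by k.
    """
    labels = np.asarray(labels, dtype=object)
    rng = np.random.default_rng(seed)
    per_fold: list[list[int]] = [[] for _ in range(k)]
    for cls in sorted(set(labels)):
        idx = np.flatnonzero(labels == cls)
        if len(idx) % k != 0:
            raise ValueError(
                f"class {cls!r} has {len(idx)} trials, not divisible into {k} folds"
            )
        idx = idx[rng.permutation(len(idx))]
        for f, chunk in enumerate(np.split(idx, k)):
            per_fold[f].extend(chunk.tolist())
    return [np.array(sorted(f), dtype=np.int64) for f in per_fold]


def _confusion(true: np.ndarray, pred: np.ndarray, classes: list[str]) -> np.ndarray:
    lut = {c: i for i, c in enumerate(classes)}
    cm = np.zeros((len(classes), len(classes)), dtype=np.int64)
    for t, p in zip(true, pred):
        cm[lut[t], lut[p]] += 1
    return cm


def crossvalidate(env: HfbEnvelope, mode: str = "spatial", k: int = 10,
                  seed: int = 0, electrodes: np.ndarray | None = None,
                  n_perm_select: int = 10000, alpha: float = 0.05,
                  smoothing_s: float = 0.5, epoch_s: float = 2.0,
                  select_electrodes: bool = True) -> CvResult:
    """Stratified k-fold template-matching classification with per-fold
    electrode selection.

    Per fold: permutation-r²/FDR selection on training trials only (movement
    trials outside the fold plus all rest trials) → templates from training
    trials → winner-takes-all classification of the held-out trials.  If the
    selection is empty, all included electrodes are used for that fold.
    """
    if electrodes is None:
        electrodes = np.arange(env.n_channels)
    electrodes = np.asarray(electrodes, dtype=np.int64)
    tensor = smooth_zscore_epoch(env, electrodes, smoothing_s, epoch_s)
    means, mlabels = trial_means(env)
    means = means[:, electrodes]
    mov_rows = np.flatnonzero(env.events.movement_mask)  # means-row per tensor trial
    rest_rows = np.flatnonzero(~env.events.movement_mask)

    # fold assignment reproducible via stratified_folds(labels, k, seed)
    folds = stratified_folds(tensor.labels, k, seed)
    perm_seeds = [int(s.generate_state(1)[0] % (2**31 - 1))
                  for s in np.random.SeedSequence(seed).spawn(k)]
    classes = tensor.classes
    accs, preds_all, true_all, fold_sel = [], [], [], []
    all_trials = np.arange(len(tensor.labels))
    for f, test_idx in enumerate(folds):
        train_idx = np.setdiff1d(all_trials, test_idx)
        if select_electrodes:
            sel_rows = np.concatenate([mov_rows[train_idx], rest_rows])
            sel = permutation_fdr(means[sel_rows], mlabels[sel_rows],
                                  n_perm=n_perm_select, alpha=alpha,
                                  seed=perm_seeds[f])
            cols = np.flatnonzero(sel.selected)
            if len(cols) == 0:
                cols = np.arange(len(electrodes))  # fallback: all included
        else:
            cols = np.arange(len(electrodes))
        fold_sel.append(cols)
        feats = tensor.features(mode, cols)
        sub = TrialTensor(tensor.data[:, cols, :], tensor.labels,
                          tensor.electrodes[cols], tensor.sampling_rate_hz,
                          tensor.smoothing_s, tensor.epoch_s)
        templates = build_templates(sub, train_idx, mode)
        pred = [classify_trial(feats[t], templates) for t in test_idx]
        true = tensor.labels[test_idx]
        accs.append(float(np.mean(np.asarray(pred, dtype=object) == true)))
        preds_all.extend(pred)
        true_all.extend(true)
    accs = np.array(accs)
    return CvResult(
        fold_accuracies=accs, mean_accuracy=float(accs.mean()),
        sd_accuracy=float(accs.std(ddof=1)) if k > 1 else 0.0,
        confusion=_confusion(np.array(true_all, object), np.array(preds_all, object),
                             classes),
        classes=tuple(classes), n_folds=k,
        fold_electrodes=tuple(tuple(c.tolist()) for c in fold_sel),
    )


def _loocv_predictions(X: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Vectorized leave-one-trial-out winner-takes-all predictions.

    ``X``: (n_trials, n_features).  Each trial is correlated with per-class
    mean templates computed from all other trials.
    """
    labels = np.asarray(labels, dtype=object)
    classes = sorted(set(labels))
    onehot = np.stack([(labels == c).astype(float) for c in classes], axis=1)
    counts = onehot.sum(axis=0)  # (K,)
    if (counts < 2).any():
        raise ValueError("leave-one-out needs at least 2 trials per class")
    sums = onehot.T @ X  # (K, F)
    # leave-one-out template: own-class template drops the held-out trial
    T = (sums[None, :, :] - onehot[:, :, None] * X[:, None, :]) / (
        counts[None, :, None] - onehot[:, :, None]
    )
    Xc = X - X.mean(axis=1, keepdims=True)
    Tc = T - T.mean(axis=2, keepdims=True)
    num = np.einsum("nf,nkf->nk", Xc, Tc)
    denom = np.linalg.norm(Xc, axis=1)[:, None] * np.linalg.norm(Tc, axis=2)
    corr = np.zeros_like(num)
    np.divide(num, denom, out=corr, where=denom > 0)
    return np.array([classes[i] for i in corr.argmax(axis=1)], dtype=object)


def loocv(tensor: TrialTensor, mode: str = "spatial",
          electrode_cols: np.ndarray | None = None) -> CvResult:
    """Leave-one-trial-out cross-validation with a fixed electrode subset
    (no inner selection); one fold per trial."""
    X = tensor.features(mode, electrode_cols)
    pred = _loocv_predictions(X, tensor.labels)
    correct = (pred == tensor.labels).astype(float)
    classes = tensor.classes
    return CvResult(
        fold_accuracies=correct, mean_accuracy=float(correct.mean()),
        sd_accuracy=float(correct.std(ddof=1)) if len(correct) > 1 else 0.0,
        confusion=_confusion(tensor.labels, pred, classes),
        classes=tuple(classes), n_folds=len(correct),
    )


def loocv_accuracy(X: np.ndarray, labels: np.ndarray) -> float:
    """Leave-one-trial-out accuracy of a plain feature matrix (used by the
    localization procedures' inner loop)."""
    pred = _loocv_predictions(X, labels)
    return float(np.mean(pred == np.asarray(labels, dtype=object)))


def accuracy_significance(env: HfbEnvelope, mode: str = "spatial", k: int = 10,
                          n_perm: int = 1000, seed: int = 0,
                          **cv_kwargs) -> tuple[float, CvResult, np.ndarray]:
    """Permutation test of cross-validated accuracy.

    The full cross-validation (including per-fold electrode selection) is
    repeated with movement labels permuted; p = (1 + #{permuted mean
    accuracy ≥ observed}) / (n_perm + 1).
    """
    if n_perm < 99:
        raise ValueError("n_perm must be at least 99")
    observed = crossvalidate(env, mode=mode, k=k, seed=seed, **cv_kwargs)
    ss = np.random.SeedSequence([seed, 0x5EED])
    perm_seeds = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(n_perm)]
    null = np.empty(n_perm)
    for i, ps in enumerate(perm_seeds):
        pe = permute_movement_labels(env.events, ps)
        null[i] = crossvalidate(env.with_events(pe), mode=mode, k=k, seed=seed,
                                **cv_kwargs).mean_accuracy
    p = float((1 + (null >= observed.mean_accuracy).sum()) / (n_perm + 1))
    return p, observed, null
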