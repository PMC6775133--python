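"""Electrode responsiveness: per-movement r² with permutation significance
and false-discovery-rate correction.

For each electrode and each movement, the per-trial mean high-frequency-band
power (over the cue period) of that movement's trials and the rest trials is
correlated with the binary active-vs-rest design; r² is the squared Pearson
correlation.  Significance comes from a Monte-Carlo null built by shuffling
the active/rest labels (add-one permutation p-values), followed by
Benjamini–Hochberg FDR across electrodes within each movement.  An electrode
is *selected* when significant for at least one movement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .hfb import HfbEnvelope
from .sim import REST_LABEL

__all__ = [
    "SelectionResult",
    "trial_means",
    "movement_r2",
    "permutation_fdr",
]


@dataclass(frozen=True)
class SelectionResult:
    """Per-electrode, per-movement responsiveness and significance."""

    r2: np.ndarray        # (n_electrodes, n_movements) in [0, 1]
    pvals: np.ndarray     # (n_electrodes, n_movements) in (0, 1]
    sig: np.ndarray       # bool, after FDR at `alpha`
    selected: np.ndarray  # bool per electrode: significant for ≥1 movement
    movements: tuple[str, ...]
    alpha: float
    n_perm: int

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for e in range(self.r2.shape[0]):
            for m, mov in enumerate(self.movements):
                rows.append((e, mov, self.r2[e, m], self.pvals[e, m],
                             bool(self.sig[e, m])))
        return pd.DataFrame(rows, columns=["electrode", "movement", "r2", "p", "sig"])


def trial_means(env: HfbEnvelope,
                trial_indices: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Per-trial, per-electrode mean envelope over the cue period.

    Returns ``(means, labels)`` with ``means`` of shape (n_trials,
    n_electrodes).  The active window of a trial is [onset, onset +
    cue duration).
    """
    ev = env.events
    idx = np.arange(len(ev)) if trial_indices is None else np.asarray(trial_indices)
    means = np.empty((len(idx), env.n_channels))
    for row, i in enumerate(idx):
        start = int(ev.onset_sample[i])
        stop = start + int(ev.duration_samples[i])
        if stop <= start:
            raise ValueError(f"trial {i} has an empty active window")
        if stop > env.n_samples:
            raise ValueError(f"trial {i} extends past the end of the recording")
        means[row] = env.power[:, start:stop].mean(axis=1)
    return means, ev.label[idx]


def _design_r2(X: np.ndarray, designs: np.ndarray) -> np.ndarray:
    """Squared Pearson correlation between each design row and each column
    of X.  ``X``: (n, E); ``designs``: (P, n).  Returns (P, E); zero-variance
    columns or designs give 0."""
    Xc = X - X.mean(axis=0, keepdims=True)
    Dc = designs - designs.mean(axis=1, keepdims=True)
    ssx = (Xc**2).sum(axis=0)
    ssd = (Dc**2).sum(axis=1)
    num = Dc @ Xc
    denom = np.outer(ssd, ssx)
    out = np.zeros_like(num)
    np.divide(num**2, denom, out=out, where=denom > 0)
    return out


def movement_r2(means: np.ndarray, labels: np.ndarray, movement: str) -> np.ndarray:
    """Per-electrode r² for one movement-vs-rest contrast.

    Trials of other movements are excluded; the design is 1 for the
    movement's trials and 0 for rest trials.
    """
    labels = np.asarray(labels, dtype=object)
    keep = (labels == movement) | (labels == REST_LABEL)
    if (labels == movement).sum() < 2 or (labels == REST_LABEL).sum() < 2:
        raise ValueError("need at least 2 movement trials and 2 rest trials")
    X = np.asarray(means)[keep]
    design = (labels[keep] == movement).astype(float)
    return _design_r2(X, design[None, :])[0]


def permutation_fdr(means: np.ndarray, labels: np.ndarray,
                    movements: list[str] | None = None, n_perm: int = 10000,
                    alpha: float = 0.05, seed: int = 0,
                    fdr_family: str = "per_movement") -> SelectionResult:
    """Permutation p-values for every electrode × movement r², FDR-corrected.

    The active/rest design of each movement contrast is shuffled ``n_perm``
    times; p = (1 + #{permuted r² ≥ observed}) / (n_perm + 1).
    Benjamini–Hochberg is applied across electrodes within each movement
    (``fdr_family='per_movement'``, default) or over the full electrode ×
    movement family (``'joint'``).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    if fdr_family not in ("per_movement", "joint"):
        raise ValueError("fdr_family must be 'per_movement' or 'joint'")
    labels = np.asarray(labels, dtype=object)
    if movements is None:
        movements = sorted(set(labels) - {REST_LABEL})
    rng = np.random.default_rng(seed)
    n_e = np.asarray(means).shape[1]
    r2 = np.empty((n_e, len(movements)))
    pvals = np.empty_like(r2)
    for m, mov in enumerate(movements):
        keep = (labels == mov) | (labels == REST_LABEL)
        X = np.asarray(means)[keep]
        design = (labels[keep] == mov).astype(float)
        obs = _design_r2(X, design[None, :])[0]
        perms = rng.permuted(np.tile(design, (n_perm, 1)), axis=1)
        null = _design_r2(X, perms)
        pvals[:, m] = (1 + (null >= obs[None, :]).sum(axis=0)) / (n_perm + 1)
        r2[:, m] = obs
    if fdr_family == "joint":
        sig = multipletests(pvals.ravel(), alpha=alpha, method="fdr_bh")[0]
        sig = sig.reshape(pvals.shape)
    else:
        sig = np.column_stack([
            multipletests(pvals[:, m], alpha=alpha, method="fdr_bh")[0]
            for m in range(len(movements))
        ])
    return SelectionResult(
        r2=r2, pvals=pvals, sig=sig, selected=sig.any(axis=1),
        movements=tuple(movements), alpha=alpha, n_perm=n_perm,
    )
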