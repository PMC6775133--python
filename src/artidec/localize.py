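"""Anatomical localization of informative electrodes.

Two complementary procedures, both scored with spatial-mode
leave-one-trial-out template matching (designed to work with little data):

* **Random-search importance** — draw random electrode subsets many times
  (default 5000), classify with each, and credit the subset's accuracy to
  every member electrode.  The per-electrode mean accuracy-when-included,
  z-scored across electrodes, highlights informative hotspots.  A
  convergence diagnostic tracks how much the importance pattern still
  changes as iterations accumulate.

* **Searchlight** — slide square k×k windows (k = 1, 2, 3, … up to the full
  grid) over the electrode grid, compute the accuracy inside each window,
  and report the per-size maximum.  A k×k window at spacing s covers a
  (k·s)² area, so the per-size maxima give the minimal cortical patch
  needed to reach a target accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .classify import TrialTensor, loocv_accuracy
from .sim import GridLayout

__all__ = [
    "ImportanceMap",
    "SearchlightResult",
    "random_search_importance",
    "importance_convergence",
    "searchlight",
    "min_area_for_accuracy",
]


@dataclass(frozen=True)
class ImportanceMap:
    """Per-electrode importance from the random-search procedure."""

    mean_acc_when_included: np.ndarray  # nan where never included
    z: np.ndarray                       # z-scored across included electrodes
    inclusion_counts: np.ndarray
    n_iter: int
    convergence: np.ndarray             # length n_iter - 1
    convergence_skipped: int            # correlations undefined and skipped


@dataclass(frozen=True)
class SearchlightResult:
    """Accuracy of every k×k window position, per window size."""

    sizes: tuple[int, ...]
    accuracy_maps: dict              # size -> (R-k+1, C-k+1) array (nan = no electrodes)
    max_accuracy: dict               # size -> float
    argmax_position: dict            # size -> (row, col) of the window's top-left
    area_cm2: dict                   # size -> (k * spacing / 10)**2
    layout: GridLayout


def _convergence_curve(credit: np.ndarray, included: np.ndarray) -> tuple[np.ndarray, int]:
    """curve[i] = mean Pearson correlation of the importance pattern after
    iterations 1..i+1 with the patterns after 1..j+1 for all j > i.

    Patterns are cumulative mean-accuracy-when-included vectors; electrodes
    not yet included are filled with the mean of the defined entries (neutral
    under correlation).  Zero-variance patterns yield undefined correlations,
    which are skipped and counted.
    """
    n_iter, n_e = credit.shape
    csum = np.cumsum(credit, axis=0)
    ccount = np.cumsum(included, axis=0)
    patterns = np.full((n_iter, n_e), np.nan)
    np.divide(csum, ccount, out=patterns, where=ccount > 0)
    defined = ccount > 0
    fill = np.nanmean(np.where(defined, patterns, np.nan), axis=1)
    patterns = np.where(defined, patterns, fill[:, None])

    centered = patterns - patterns.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    valid = norms > 0
    unit = np.zeros_like(centered)
    unit[valid] = centered[valid] / norms[valid, None]
    corr = unit @ unit.T  # rows with zero variance give 0 rows; masked below

    curve = np.empty(n_iter - 1)
    skipped = 0
    for i in range(n_iter - 1):
        later = np.arange(i + 1, n_iter)
        ok = valid[later] & valid[i]
        skipped += int((~ok).sum())
        curve[i] = corr[i, later[ok]].mean() if ok.any() else np.nan
    return curve, skipped


def random_search_importance(tensor: TrialTensor, n_iter: int = 5000,
                             subset_size_rule: str = "uniform",
                             seed: int = 0) -> ImportanceMap:
    """Random-subset electrode importance.

    Per iteration: draw a subset size (uniform on [1, N] for the default
    rule, or a fixed fraction N/2 for ``'half'``), then a uniform random
    subset of that size; score it with spatial leave-one-trial-out template
    matching; credit the accuracy to each member.  Identical seeds reproduce
    the map bit-for-bit.
    """
    n_e = tensor.data.shape[1]
    if n_e < 2:
        raise ValueError("need at least 2 electrodes")
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    if subset_size_rule not in ("uniform", "half"):
        raise ValueError("subset_size_rule must be 'uniform' or 'half'")
    rng = np.random.default_rng(seed)
    X = tensor.features("spatial")
    labels = tensor.labels
    credit = np.zeros((n_iter, n_e))
    included = np.zeros((n_iter, n_e), dtype=bool)
    for i in range(n_iter):
        size = (int(rng.integers(1, n_e + 1)) if subset_size_rule == "uniform"
                else max(1, n_e // 2))
        subset = rng.choice(n_e, size=size, replace=False)
        acc = loocv_accuracy(X[:, subset], labels)
        credit[i, subset] = acc
        included[i, subset] = True

    counts = included.sum(axis=0)
    mean_acc = np.full(n_e, np.nan)
    np.divide(credit.sum(axis=0), counts, out=mean_acc, where=counts > 0)
    have = counts > 0
    z = np.full(n_e, np.nan)
    sd = mean_acc[have].std()
    if have.sum() > 1 and sd > 0:
        z[have] = (mean_acc[have] - mean_acc[have].mean()) / sd
    elif have.any():
        z[have] = 0.0

    if n_iter >= 2:
        curve, skipped = _convergence_curve(credit, included)
    else:
        curve, skipped = np.empty(0), 0
    return ImportanceMap(mean_acc, z, counts, n_iter, curve, skipped)


def importance_convergence(imap: ImportanceMap) -> np.ndarray:
    """The convergence curve of an importance map (length n_iter − 1)."""
    if imap.n_iter < 2:
        raise ValueError("convergence needs at least 2 iterations")
    return imap.convergence


def searchlight(tensor: TrialTensor, layout: GridLayout) -> SearchlightResult:
    """Accuracy of every square window position at every window size.

    The electrode axis of ``tensor`` holds the *included* channels;
    excluded channels inside a window are simply absent from its feature
    vector.  A window containing no included electrode is recorded as NaN.
    """
    X = tensor.features("spatial")
    labels = tensor.labels
    rows, cols = zip(*(layout.rowcol(ch) for ch in tensor.electrodes))
    rows = np.asarray(rows)
    cols = np.asarray(cols)
    sizes = tuple(range(1, min(layout.n_rows, layout.n_cols) + 1))
    acc_maps, max_acc, argmax_pos, areas = {}, {}, {}, {}
    for k in sizes:
        amap = np.full((layout.n_rows - k + 1, layout.n_cols - k + 1), np.nan)
        for r0 in range(amap.shape[0]):
            for c0 in range(amap.shape[1]):
                inside = ((rows >= r0) & (rows < r0 + k)
                          & (cols >= c0) & (cols < c0 + k))
                if not inside.any():
                    continue
                amap[r0, c0] = loocv_accuracy(X[:, inside], labels)
        acc_maps[k] = amap
        if np.isfinite(amap).any():
            flat = np.nanargmax(amap)
            max_acc[k] = float(np.nanmax(amap))
            argmax_pos[k] = tuple(int(v) for v in np.unravel_index(flat, amap.shape))
        else:
            max_acc[k] = float("nan")
            argmax_pos[k] = None
        areas[k] = (k * layout.spacing_mm / 10.0) ** 2
    return SearchlightResult(sizes, acc_maps, max_acc, argmax_pos, areas, layout)


def min_area_for_accuracy(result: SearchlightResult,
                          threshold: float) -> float | None:
    """Smallest searchlight area (cm²) whose best position exceeds the
    accuracy threshold; None when no size reaches it."""
    if not 0 <= threshold < 1:
        raise ValueError("threshold must be in [0, 1)")
    for k in result.sizes:
        acc = result.max_accuracy[k]
        if np.isfinite(acc) and acc > threshold:
            return result.area_cm2[k]
    return None
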