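"""Oddball ERP contrasts and temporal-generalization decoding.

ERPs are trimmed means (80%) across trials per channel and timepoint.
The group contrast of interest is the double difference
(deviant - standard) after minus before stimulation, compared between
responders and non-responders by spatiotemporal cluster permutation.

Temporal generalization trains a linear SVM on the channel vector at each
timepoint to separate deviant from standard trials, and evaluates it at
every other timepoint; performance is AUC averaged over 10 iterations of
stratified 5-fold cross-validation.  A sustained, square above-chance
region off the diagonal indicates metastable activity (the late P3b-like
signature); a purely diagonal pattern indicates transient coding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import LinearSVC

from .core import DEVIANT, STANDARD, EpochSet
from .markers import trimmed_mean_80

MIN_TRIALS = 5


@dataclass
class ERPWave:
    data: np.ndarray  # (n_channels, n_times), μV
    times: np.ndarray  # seconds
    condition: str
    n_trials: int
    insufficient: bool = False


@dataclass
class GeneralizationMatrix:
    auc: np.ndarray  # (n_times, n_times), train x test
    times: np.ndarray
    n_iterations: int
    n_folds: int
    flagged: bool = False


def erp_average(ep: EpochSet, condition: str) -> ERPWave:
    """80% trimmed-mean ERP across retained trials of one condition."""
    keep = ep.retained_epochs
    sel = keep[ep.labels[keep] == condition]
    n = len(sel)
    if n == 0:
        return ERPWave(
            np.zeros((ep.n_channels, ep.n_samples)), ep.times, condition, 0, True
        )
    wave = trimmed_mean_80(ep.data[sel], axis=0)
    return ERPWave(wave, ep.times, condition, n, insufficient=n < MIN_TRIALS)


def double_difference(
    pre: EpochSet, post: EpochSet
) -> tuple[np.ndarray, bool]:
    """[(deviant - standard) post] - [(deviant - standard) pre] per subject.

    Returns the (channels, times) array and a validity flag (False when a
    condition cell has fewer than 5 usable trials in either session).
    """
    waves = {}
    ok = True
    for name, ep in (("pre", pre), ("post", post)):
        for cond in (STANDARD, DEVIANT):
            w = erp_average(ep, cond)
            ok &= not w.insufficient
            waves[(name, cond)] = w.data
    dd = (waves[("post", DEVIANT)] - waves[("post", STANDARD)]) - (
        waves[("pre", DEVIANT)] - waves[("pre", STANDARD)]
    )
    return dd, ok


def interaction_contrast(
    subjects: list[dict],
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Group arrays for the responder-by-stimulation ERP interaction.

    ``subjects`` holds dicts with keys ``subject_id``, ``responder``,
    ``pre`` and ``post`` (task EpochSets).  Subjects with a missing or
    under-filled cell are excluded and listed in the returned log.
    Returns ``(rplus, rminus, excluded_ids)`` where the group arrays are
    (n_subjects, channels, times).
    """
    rplus, rminus, excluded = [], [], []
    for sub in subjects:
        pre, post = sub.get("pre"), sub.get("post")
        if pre is None or post is None or pre.failed or post.failed:
            excluded.append(sub["subject_id"])
            continue
        dd, ok = double_difference(pre, post)
        if not ok:
            excluded.append(sub["subject_id"])
            continue
        (rplus if sub["responder"] else rminus).append(dd)
    as_arr = lambda v: np.stack(v) if v else np.zeros((0, 0, 0))
    return as_arr(rplus), as_arr(rminus), excluded


def _fold_auc(scores: np.ndarray, y: np.ndarray) -> np.ndarray:
    """AUC per column of a (trials, times) score matrix (rank formula)."""
    n1 = int(y.sum())
    n0 = len(y) - n1
    ranks = rankdata(scores, axis=0)
    u = ranks[y == 1].sum(axis=0) - n1 * (n1 + 1) / 2.0
    return u / (n1 * n0)


def tg_decode(
    ep: EpochSet,
    seed: int = 0,
    n_iterations: int = 10,
    n_folds: int = 5,
    decim: int = 1,
    C: float = 1.0,
) -> GeneralizationMatrix:
    """Train-time x test-time AUC matrix for deviant-vs-standard decoding.

    Features at a timepoint are the raw voltages across channels,
    standardized with training-fold statistics.  ``decim`` subsamples the
    time axis (every ``decim``-th sample) to keep the matrix tractable.
    """
    keep = ep.retained_epochs
    labels = ep.labels[keep]
    y = (labels == DEVIANT).astype(int)
    n_dev, n_std = int(y.sum()), int((1 - y).sum())
    times = ep.times[::decim]
    n_t = len(times)
    if min(n_dev, n_std) < MIN_TRIALS:
        return GeneralizationMatrix(
            np.full((n_t, n_t), 0.5), times, n_iterations, n_folds, flagged=True
        )
    X = ep.data[keep][:, :, ::decim]  # (trials, channels, times)

    acc = np.zeros((n_t, n_t))
    n_used = 0
    for it in range(n_iterations):
        skf = StratifiedKFold(n_folds, shuffle=True, random_state=seed * 1009 + it)
        for train_idx, test_idx in skf.split(X[:, :, 0], y):
            Xtr, Xte = X[train_idx], X[test_idx]
            ytr, yte = y[train_idx], y[test_idx]
            if len(np.unique(yte)) < 2 or len(np.unique(ytr)) < 2:
                continue
            mu = Xtr.mean(axis=0)
            sd = Xtr.std(axis=0)
            sd[sd == 0] = 1.0
            Xtr = (Xtr - mu) / sd
            Xte = (Xte - mu) / sd
            fold = np.empty((n_t, n_t))
            for t in range(n_t):
                clf = LinearSVC(C=C, dual=True, max_iter=5000, random_state=0)
                clf.fit(Xtr[:, :, t], ytr)
                scores = np.einsum("c,ict->it", clf.coef_[0], Xte) + clf.intercept_[0]
                fold[t] = _fold_auc(scores, yte)
            acc += fold
            n_used += 1
    auc = acc / max(n_used, 1)
    return GeneralizationMatrix(auc, times, n_iterations, n_folds)


def square_pattern_ratio(
    gm: GeneralizationMatrix, window: tuple[float, float], chance: float = 0.5, margin: float = 0.05
) -> float:
    """Off-diagonal vs diagonal extent of above-chance decoding in a window.

    Values near 1 indicate a square (metastable/sustained) pattern; values
    near 0 a diagonal (transient) chain of momentary patterns.
    """
    sel = (gm.times >= window[0]) & (gm.times <= window[1])
    sub = gm.auc[np.ix_(sel, sel)]
    above = sub > chance + margin
    n = sub.shape[0]
    if n < 3:
        return 0.0
    diag = np.eye(n, dtype=bool) | np.eye(n, k=1, dtype=bool) | np.eye(n, k=-1, dtype=bool)
    diag_frac = above[diag].mean()
    off_frac = above[~diag].mean()
    return float(off_frac / diag_frac) if diag_frac > 0 else 0.0
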