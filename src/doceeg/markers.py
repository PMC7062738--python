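"""Resting-state EEG markers: spectral, complexity and connectivity domains.

Seventeen markers are computed per epoch and channel, then summarized over
epochs with the 80% trimmed mean (drop the lowest and highest 10%):

* raw and normalized band power in five bands (δ 1-4, θ 4-8, α 8-12,
  β 12-30, γ 30-45 Hz), from Welch spectra (512 ms segments, 400 ms
  overlap, Hann taper),
* spectral entropy (Shannon entropy of the normalized 1-45 Hz spectrum,
  scaled to [0, 1] by log of the bin count), median spectral frequency and
  90th/95th spectral edge frequencies (linear interpolation within bins),
* Kolmogorov-Chaitin complexity proxied by the deflate-compressed size of
  the 32-level discretized signal relative to its raw size,
* permutation entropy of k=3 ordinal patterns at τ = 32 ms (theta-alpha
  sensitive), normalized by log 6,
* weighted symbolic mutual information (wSMI) at τ = 32 ms between every
  channel pair, with identical and sign-opposite pattern pairs weighted
  out to suppress common-source coupling, reduced to a per-channel
  topography by the median over each channel's pairs ("degree").

The τ → band mapping follows the ordinal-pattern frequency-sensitivity
rule that makes τ = 32 ms theta-alpha (4-10 Hz); τ = 64 ms and τ = 16 ms
address delta-theta and alpha-beta respectively.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from itertools import permutations

import numpy as np
from scipy import signal as sps
from scipy.stats import trim_mean

from .core import EpochSet
from .synth import BANDS

N_SYMBOLS = 6  # k! for k = 3

MARKER_IDS = [
    "delta_raw",
    "delta_norm",
    "theta_raw",
    "theta_norm",
    "alpha_raw",
    "alpha_norm",
    "beta_raw",
    "beta_norm",
    "gamma_raw",
    "gamma_norm",
    "spectral_entropy",
    "msf",
    "sef90",
    "sef95",
    "kolmogorov",
    "pe_theta_alpha",
    "wsmi_theta_alpha_degree",
]


@dataclass
class Spectrum:
    frequencies: np.ndarray  # (n_freqs,) Hz
    power: np.ndarray  # (n_epochs, n_channels, n_freqs), μV²/Hz
    segment_ms: float
    overlap_ms: float


def trimmed_mean_80(values: np.ndarray, axis: int = 0) -> np.ndarray:
    """Mean after trimming the lowest 10% and highest 10% of values."""
    return trim_mean(values, 0.1, axis=axis)


def welch_psd(
    ep: EpochSet, segment_ms: float = 512.0, overlap_ms: float = 400.0
) -> Spectrum:
    """Per-epoch, per-channel Welch power spectral density (Hann taper)."""
    data = ep.retained_data()
    nperseg = int(round(segment_ms * ep.fs / 1000.0))
    noverlap = int(round(overlap_ms * ep.fs / 1000.0))
    if data.shape[-1] < nperseg:
        raise ValueError("epoch shorter than the Welch segment length")
    freqs, power = sps.welch(
        data,
        fs=ep.fs,
        window="hann",
        nperseg=nperseg,
        noverlap=noverlap,
        detrend="constant",
        scaling="density",
        axis=-1,
    )
    return Spectrum(freqs, power, segment_ms, overlap_ms)


def band_powers(sp: Spectrum) -> dict[str, np.ndarray]:
    """Raw (integrated μV²) and normalized band power per epoch x channel.

    Bands are half-open ``[lo, hi)`` except the top band which includes its
    upper edge; normalization divides each band by the sum over the five.
    """
    df = sp.frequencies[1] - sp.frequencies[0]
    raw = {}
    top = max(hi for _, hi in BANDS.values())
    for band, (lo, hi) in BANDS.items():
        sel = (sp.frequencies >= lo) & (
            (sp.frequencies <= hi) if hi == top else (sp.frequencies < hi)
        )
        raw[band] = sp.power[..., sel].sum(axis=-1) * df
    total = np.sum([raw[b] for b in BANDS], axis=0)
    out = {}
    for band in BANDS:
        out[f"{band}_raw"] = raw[band]
        with np.errstate(invalid="ignore", divide="ignore"):
            out[f"{band}_norm"] = np.where(total > 0, raw[band] / total, 0.0)
    return out


def _band_limits() -> tuple[float, float]:
    los, his = zip(*BANDS.values())
    return min(los), max(his)


def spectral_summaries(sp: Spectrum) -> dict[str, np.ndarray]:
    """Spectral entropy and the 50/90/95% spectral quantile frequencies.

    Entropy treats the 1-45 Hz spectrum of each epoch x channel as a
    probability distribution over bins and is normalized by log(#bins).
    Quantiles spread each bin's mass uniformly over its width, so a
    single-line spectrum returns that bin's center frequency.
    """
    lo, hi = _band_limits()
    sel = (sp.frequencies >= lo) & (sp.frequencies <= hi)
    freqs = sp.frequencies[sel]
    p = sp.power[..., sel]
    total = p.sum(axis=-1)
    if np.any(total <= 0):
        raise ValueError("zero total power in the 1-45 Hz range")
    prob = p / total[..., None]
    with np.errstate(invalid="ignore", divide="ignore"):
        plogp = np.where(prob > 0, prob * np.log(prob), 0.0)
    se = -plogp.sum(axis=-1) / np.log(prob.shape[-1])

    df = freqs[1] - freqs[0]
    cum = np.cumsum(prob, axis=-1)
    cum0 = cum - prob  # cumulative mass before each bin
    out = {"spectral_entropy": se}
    for name, q in (("msf", 0.5), ("sef90", 0.9), ("sef95", 0.95)):
        idx = np.argmax(cum >= q - 1e-12, axis=-1)
        pi = np.take_along_axis(prob, idx[..., None], axis=-1)[..., 0]
        c0 = np.take_along_axis(cum0, idx[..., None], axis=-1)[..., 0]
        frac = np.where(pi > 0, (q - c0) / pi, 0.5)
        out[name] = freqs[idx] - df / 2 + df * np.clip(frac, 0, 1)
    return out


def kolmogorov_complexity(
    ep: EpochSet, n_bins: int = 32, level: int = 9
) -> np.ndarray:
    """Compressed-to-raw size ratio of the discretized signal.

    Each epoch x channel trace is quantized to ``n_bins`` equal-width
    amplitude levels between its min and max, serialized to one byte per
    sample and deflate-compressed.
    """
    data = ep.retained_data()
    n_ep, n_ch, n_s = data.shape
    out = np.empty((n_ep, n_ch))
    for e in range(n_ep):
        for c in range(n_ch):
            x = data[e, c]
            lo, hi = x.min(), x.max()
            if hi > lo:
                q = np.minimum((x - lo) / (hi - lo) * n_bins, n_bins - 1).astype(
                    np.uint8
                )
            else:
                q = np.zeros(n_s, np.uint8)
            out[e, c] = len(zlib.compress(q.tobytes(), level)) / n_s
    return out


# --- ordinal symbolization -------------------------------------------------

# rank-tuple -> symbol index, lexicographic over the 6 permutations of (0,1,2)
_PERMS = sorted(permutations(range(3)))
_RANK_TO_SYMBOL = {p: i for i, p in enumerate(_PERMS)}
_SYMBOL_LUT = np.full(27, -1, dtype=np.int64)
for _p, _i in _RANK_TO_SYMBOL.items():
    _SYMBOL_LUT[_p[0] * 9 + _p[1] * 3 + _p[2]] = _i
# sign-opposite symbol: ranks r -> 2 - r
OPPOSITE_SYMBOL = np.array(
    [_RANK_TO_SYMBOL[tuple(2 - r for r in p)] for p in _PERMS], dtype=np.int64
)


def tau_samples(tau_ms: float, fs: float) -> int:
    t = tau_ms * fs / 1000.0
    if abs(t - round(t)) > 1e-9:
        raise ValueError(f"tau of {tau_ms} ms is not an integer number of samples at {fs} Hz")
    return int(round(t))


def ordinal_symbols(x: np.ndarray, tau: int, k: int = 3) -> np.ndarray:
    """Ordinal-pattern symbol sequence(s) of τ-spaced k-tuples.

    Works on the last axis of ``x``.  Ranks are assigned by stable sort, so
    ties are broken by order of occurrence.  Only k = 3 is supported; the
    sequence length is ``n - (k-1)·τ``.
    """
    if k != 3:
        raise ValueError("only k = 3 ordinal patterns are supported")
    n = x.shape[-1]
    L = n - (k - 1) * tau
    if L < 1:
        raise ValueError("epoch too short for the requested tau")
    triples = np.stack([x[..., 0:L], x[..., tau : tau + L], x[..., 2 * tau : 2 * tau + L]], axis=-1)
    order = np.argsort(triples, axis=-1, kind="stable")
    ranks = np.empty_like(order)
    np.put_along_axis(ranks, order, np.broadcast_to(np.arange(3), order.shape), axis=-1)
    code = ranks[..., 0] * 9 + ranks[..., 1] * 3 + ranks[..., 2]
    return _SYMBOL_LUT[code]


def symbol_counts(symbols: np.ndarray) -> np.ndarray:
    """Counts of the 6 symbols along the last axis."""
    flat = symbols.reshape(-1, symbols.shape[-1])
    counts = np.zeros((flat.shape[0], N_SYMBOLS), np.int64)
    for s in range(N_SYMBOLS):
        counts[:, s] = (flat == s).sum(axis=1)
    return counts.reshape(symbols.shape[:-1] + (N_SYMBOLS,))


def permutation_entropy(ep: EpochSet, tau_ms: float = 32.0) -> np.ndarray:
    """Normalized permutation entropy per epoch x channel, in [0, 1]."""
    data = ep.retained_data()
    tau = tau_samples(tau_ms, ep.fs)
    sym = ordinal_symbols(data, tau)
    counts = symbol_counts(sym)
    p = counts / counts.sum(axis=-1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    return -plogp.sum(axis=-1) / np.log(N_SYMBOLS)


_W = np.ones((N_SYMBOLS, N_SYMBOLS))
np.fill_diagonal(_W, 0.0)
_W[np.arange(N_SYMBOLS), OPPOSITE_SYMBOL] = 0.0


def wsmi_weights() -> np.ndarray:
    """Symbol-pair weights: 0 for identical and sign-opposite patterns."""
    return _W.copy()


def wsmi_from_symbols(sa: np.ndarray, sb: np.ndarray) -> float:
    """wSMI of two symbol sequences, normalized by log(k!)."""
    joint = np.zeros((N_SYMBOLS, N_SYMBOLS))
    np.add.at(joint, (sa, sb), 1.0)
    joint /= joint.sum()
    pa = joint.sum(axis=1)
    pb = joint.sum(axis=0)
    mask = joint > 0
    out = 0.0
    ii, jj = np.nonzero(mask)
    for i, j in zip(ii, jj):
        if _W[i, j]:
            out += joint[i, j] * np.log(joint[i, j] / (pa[i] * pb[j]))
    return out / np.log(N_SYMBOLS)


def wsmi(ep: EpochSet, tau_ms: float = 32.0) -> tuple[np.ndarray, np.ndarray]:
    """Weighted symbolic mutual information over all channel pairs.

    Returns ``(per_epoch, pair_matrix)``: per-epoch values of shape
    ``(n_epochs, n_pairs)`` in upper-triangle order, and the symmetric
    channel x channel matrix of their 80% trimmed means (nan diagonal).
    """
    data = ep.retained_data()
    n_ep, n_ch, _ = data.shape
    if n_ch < 2:
        raise ValueError("wSMI needs at least 2 channels")
    tau = tau_samples(tau_ms, ep.fs)
    sym = ordinal_symbols(data, tau)  # (n_ep, n_ch, L)
    L = sym.shape[-1]
    counts = symbol_counts(sym).astype(float)  # (n_ep, n_ch, 6)
    marg = counts / L

    pairs = [(a, b) for a in range(n_ch) for b in range(a + 1, n_ch)]
    per_epoch = np.zeros((n_ep, len(pairs)))
    ep_offset = np.arange(n_ep)[:, None] * (N_SYMBOLS * N_SYMBOLS)
    logw = np.log(N_SYMBOLS)
    for pi, (a, b) in enumerate(pairs):
        idx = sym[:, a, :] * N_SYMBOLS + sym[:, b, :] + ep_offset
        joint = np.bincount(
            idx.ravel(), minlength=n_ep * N_SYMBOLS * N_SYMBOLS
        ).reshape(n_ep, N_SYMBOLS, N_SYMBOLS) / L
        outer = marg[:, a, :, None] * marg[:, b, None, :]
        with np.errstate(invalid="ignore", divide="ignore"):
            terms = np.where(joint > 0, joint * np.log(joint / outer), 0.0)
        per_epoch[:, pi] = (terms * _W).sum(axis=(1, 2)) / logw

    pm = np.full((n_ch, n_ch), np.nan)
    tm = trimmed_mean_80(per_epoch, axis=0)
    for pi, (a, b) in enumerate(pairs):
        pm[a, b] = pm[b, a] = tm[pi]
    return per_epoch, pm


def pair_index(n_channels: int) -> list[tuple[int, int]]:
    """Upper-triangle channel-pair enumeration, n(n-1)/2 entries."""
    return [(a, b) for a in range(n_channels) for b in range(a + 1, n_channels)]


def pair_degree_from_matrix(pm: np.ndarray) -> np.ndarray:
    """Per-channel median of its pair values (network degree reduction)."""
    n = pm.shape[0]
    if n < 3:
        raise ValueError("degree reduction needs at least 3 channels")
    out = np.empty(n)
    for c in range(n):
        row = np.delete(pm[c], c)
        out[c] = np.median(row)
    return out


def pair_degree_per_epoch(per_epoch: np.ndarray, n_ch: int) -> np.ndarray:
    """Per-epoch per-channel wSMI degree from upper-triangle pair values."""
    n_ep = per_epoch.shape[0]
    full = np.full((n_ep, n_ch, n_ch), np.nan)
    for pi, (a, b) in enumerate(pair_index(n_ch)):
        full[:, a, b] = full[:, b, a] = per_epoch[:, pi]
    out = np.empty((n_ep, n_ch))
    for c in range(n_ch):
        rows = np.delete(full[:, c, :], c, axis=1)
        out[:, c] = np.median(rows, axis=1)
    return out


def summarize_topography(per_epoch: np.ndarray) -> np.ndarray:
    """80% trimmed mean over epochs -> one scalar per channel."""
    return trimmed_mean_80(per_epoch, axis=0)


def compute_marker_epochs(
    ep: EpochSet, tau_ms: float = 32.0
) -> dict[str, np.ndarray]:
    """All 17 markers per epoch x channel for one epoch set.

    wSMI enters through its per-channel degree so every marker shares the
    (epochs, channels) shape needed by the feature builder.
    """
    sp = welch_psd(ep)
    out: dict[str, np.ndarray] = {}
    out.update(band_powers(sp))
    out.update(spectral_summaries(sp))
    out["kolmogorov"] = kolmogorov_complexity(ep)
    out["pe_theta_alpha"] = permutation_entropy(ep, tau_ms=tau_ms)
    per_epoch_pairs, _ = wsmi(ep, tau_ms=tau_ms)
    n_ch = ep.retained_data().shape[1]
    out["wsmi_theta_alpha_degree"] = pair_degree_per_epoch(per_epoch_pairs, n_ch)
    assert set(out) == set(MARKER_IDS)
    return out


def compute_topographies(
    epoch_sets: list[EpochSet], tau_ms: float = 32.0
) -> dict[str, np.ndarray]:
    """Marker topographies averaged across epoching iterations.

    Each iteration contributes the 80% trimmed mean over its epochs; the
    final topography is the plain mean over iterations.
    """
    acc: dict[str, list[np.ndarray]] = {m: [] for m in MARKER_IDS}
    for ep in epoch_sets:
        per = compute_marker_epochs(ep, tau_ms=tau_ms)
        for m in MARKER_IDS:
            acc[m].append(summarize_topography(per[m]))
    return {m: np.mean(acc[m], axis=0) for m in MARKER_IDS}


def compute_pair_topography(
    epoch_sets: list[EpochSet], tau_ms: float = 32.0
) -> np.ndarray:
    """wSMI pair values (upper-triangle vector) averaged across iterations."""
    vals = []
    for ep in epoch_sets:
        per_epoch_pairs, _ = wsmi(ep, tau_ms=tau_ms)
        vals.append(trimmed_mean_80(per_epoch_pairs, axis=0))
    return np.mean(vals, axis=0)


def topography_table(
    topographies: dict[str, np.ndarray], layout, subject_id: str, session: str
):
    """Tidy (subject, session, marker, channel, value) table of topographies."""
    import pandas as pd

    rows = [
        {
            "subject": subject_id,
            "session": session,
            "marker": marker,
            "channel": layout.channel_ids[c],
            "value": float(values[c]),
        }
        for marker, values in topographies.items()
        for c in range(len(values))
    ]
    return pd.DataFrame(rows, columns=["subject", "session", "marker", "channel", "value"])
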