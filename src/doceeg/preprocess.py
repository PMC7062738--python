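"""Hierarchical automated artifact removal and epoching.

The cascade follows a fixed order which is part of the contract:

1. band-pass the continuous data (0.5 Hz HP order 6, 45 Hz LP order 8,
   50/100 Hz notches; task data additionally low-passed at 20 Hz),
2. epoch (800 ms jittered epochs at rest; [-800, +740] ms around the
   fifth-tone onset for the task, baseline-corrected on [-800, 0) ms),
3. reject channels with >150 μV peak-to-peak in >50% of epochs,
4. reject channels with variance z-score > 4 across channels, twice,
5. reject epochs with >150 μV peak-to-peak in >10% of retained channels,
6. reject channels with high-pass (25 Hz) variance z-score > 4, twice,
7. re-reference to the average of retained channels, interpolate rejected
   channels, and apply the 75%-channels / 30%-epochs quality gate.

All filters are Butterworth, applied forward-backward (zero phase).
Epoch windows are half-open ``[start, end)`` with 0-based sample indices.
"""

from __future__ import annotations

import numpy as np
from scipy import signal as sps

from .core import DEVIANT, REST, STANDARD, EpochSet, PreprocessReport, Recording

PTP_THRESHOLD_UV = 150.0
VARIANCE_Z_THRESHOLD = 4.0
CHANNEL_PTP_EPOCH_FRACTION = 0.5
EPOCH_PTP_CHANNEL_FRACTION = 0.1
GATE_CHANNEL_FRACTION = 0.75
GATE_EPOCH_FRACTION = 0.30


def filter_continuous(rec: Recording, mode: str = "rest_task_common") -> Recording:
    """Zero-phase band-pass plus notch filtering of a continuous recording."""
    if mode not in ("rest_task_common", "task_extra"):
        raise ValueError(f"unknown filter mode {mode!r}")
    if rec.fs <= 2 * 100.0:
        raise ValueError("sampling rate too low for the 100 Hz notch filter")
    x = rec.data
    hp = sps.butter(6, 0.5, btype="highpass", fs=rec.fs, output="sos")
    lp = sps.butter(8, 45.0, btype="lowpass", fs=rec.fs, output="sos")
    x = sps.sosfiltfilt(hp, x, axis=-1)
    x = sps.sosfiltfilt(lp, x, axis=-1)
    for f0 in (50.0, 100.0):
        b, a = sps.iirnotch(f0, Q=30.0, fs=rec.fs)
        x = sps.filtfilt(b, a, x, axis=-1)
    if mode == "task_extra":
        lp20 = sps.butter(8, 20.0, btype="lowpass", fs=rec.fs, output="sos")
        x = sps.sosfiltfilt(lp20, x, axis=-1)
    return Recording(
        data=x,
        fs=rec.fs,
        layout=rec.layout,
        events=list(rec.events),
        subject_id=rec.subject_id,
        session=rec.session,
        kind=rec.kind,
    )


def _empty_epochs(rec: Recording, n_samples: int) -> EpochSet:
    return EpochSet(
        data=np.zeros((0, rec.n_channels, n_samples)),
        fs=rec.fs,
        layout=rec.layout,
        labels=np.array([], dtype="U16"),
        times=np.arange(n_samples) / rec.fs,
        failed=True,
        subject_id=rec.subject_id,
        session=rec.session,
    )


def epoch_resting(
    rec: Recording,
    seed: int,
    n_iterations: int = 100,
    epoch_ms: float = 800.0,
    jitter_ms: tuple[float, float] = (550.0, 850.0),
) -> list[EpochSet]:
    """Cut resting data into jittered 800 ms epochs, repeatedly.

    Each iteration draws independent inter-epoch gaps uniformly from
    ``jitter_ms`` and re-epochs the recording, so downstream markers can be
    averaged over epoch placements.
    """
    n_len = int(round(epoch_ms * rec.fs / 1000.0))
    if rec.n_samples < 2 * n_len:
        return [_empty_epochs(rec, n_len)]
    out = []
    for it in range(n_iterations):
        rng = np.random.default_rng([int(seed), it])
        onsets = []
        pos = 0
        while pos + n_len <= rec.n_samples:
            onsets.append(pos)
            gap_ms = rng.uniform(jitter_ms[0], jitter_ms[1])
            pos += n_len + int(round(gap_ms * rec.fs / 1000.0))
        data = np.stack([rec.data[:, o : o + n_len] for o in onsets], axis=0)
        out.append(
            EpochSet(
                data=data,
                fs=rec.fs,
                layout=rec.layout,
                labels=np.array([REST] * len(onsets), dtype="U16"),
                times=np.arange(n_len) / rec.fs,
                subject_id=rec.subject_id,
                session=rec.session,
            )
        )
    return out


def epoch_task(
    rec: Recording, tmin_s: float = -0.8, tmax_s: float = 0.74
) -> EpochSet:
    """Epoch the oddball task around the fifth-tone onsets.

    The window is ``[tmin, tmax)`` (385 samples at 250 Hz) and each epoch is
    baseline-corrected by its mean over ``[tmin, 0)``.
    """
    n_before = int(round(-tmin_s * rec.fs))
    n_after = int(round(tmax_s * rec.fs))
    n_len = n_before + n_after
    if not rec.events:
        return _empty_epochs(rec, n_len)
    epochs, labels = [], []
    for sample, code in rec.events:
        start, stop = sample - n_before, sample + n_after
        if start < 0 or stop > rec.n_samples:
            continue
        if code not in (STANDARD, DEVIANT):
            continue
        ep = rec.data[:, start:stop].copy()
        ep -= ep[:, :n_before].mean(axis=1, keepdims=True)
        epochs.append(ep)
        labels.append(code)
    if not epochs:
        return _empty_epochs(rec, n_len)
    return EpochSet(
        data=np.stack(epochs, axis=0),
        fs=rec.fs,
        layout=rec.layout,
        labels=np.array(labels, dtype="U16"),
        times=(np.arange(n_len) - n_before) / rec.fs,
        subject_id=rec.subject_id,
        session=rec.session,
    )


def _ptp(data: np.ndarray) -> np.ndarray:
    """Peak-to-peak per epoch x channel over the full epoch window."""
    return data.max(axis=-1) - data.min(axis=-1)


def _variance_z_reject(
    data: np.ndarray, retained_ch: np.ndarray, retained_ep: np.ndarray
) -> np.ndarray:
    """Channels (absolute indices) whose mean epoch variance has z > 4."""
    sub = data[np.ix_(retained_ep, retained_ch)]
    mean_var = sub.var(axis=-1).mean(axis=0)  # per channel
    sd = mean_var.std()
    if sd == 0:
        return np.array([], int)
    z = (mean_var - mean_var.mean()) / sd
    return retained_ch[z > VARIANCE_Z_THRESHOLD]


def reject_cascade(ep: EpochSet) -> tuple[EpochSet, PreprocessReport]:
    """Apply the four-stage channel/epoch rejection cascade in order."""
    if ep.n_channels < 2 or ep.n_epochs < 2:
        raise ValueError("need at least 2 channels and 2 epochs")
    out = ep.copy()
    report = PreprocessReport(
        params={
            "ptp_uV": PTP_THRESHOLD_UV,
            "variance_z": VARIANCE_Z_THRESHOLD,
            "channel_ptp_epoch_fraction": CHANNEL_PTP_EPOCH_FRACTION,
            "epoch_ptp_channel_fraction": EPOCH_PTP_CHANNEL_FRACTION,
        }
    )
    ptp = _ptp(out.data)  # (n_ep, n_ch)

    # (a) channel peak-to-peak rule
    ep_keep = out.retained_epochs
    frac = (ptp[ep_keep] > PTP_THRESHOLD_UV).mean(axis=0)
    bad = np.flatnonzero(frac > CHANNEL_PTP_EPOCH_FRACTION)
    bad = bad[~out.rejected_channels[bad]]
    out.rejected_channels[bad] = True
    report.add("channel_ptp", len(bad), 0)

    # (b) channel variance rule, twice
    for i in range(2):
        if out.retained_channels.size == 0:
            break
        bad = _variance_z_reject(out.data, out.retained_channels, out.retained_epochs)
        out.rejected_channels[bad] = True
        report.add(f"channel_variance_{i + 1}", len(bad), 0)

    # (c) epoch peak-to-peak rule against retained channels
    ch_keep = out.retained_channels
    if ch_keep.size:
        n_exceed = (ptp[:, ch_keep] > PTP_THRESHOLD_UV).sum(axis=1)
        bad_ep = np.flatnonzero(
            (n_exceed > EPOCH_PTP_CHANNEL_FRACTION * ch_keep.size)
            & ~out.rejected_epochs
        )
        out.rejected_epochs[bad_ep] = True
        report.add("epoch_ptp", 0, len(bad_ep))

    # (d) high-frequency (25 Hz HP) variance rule, twice
    if out.retained_channels.size and out.retained_epochs.size:
        hp = sps.butter(4, 25.0, btype="highpass", fs=out.fs, output="sos")
        hf = sps.sosfiltfilt(hp, out.data, axis=-1)
        for i in range(2):
            bad = _variance_z_reject(hf, out.retained_channels, out.retained_epochs)
            out.rejected_channels[bad] = True
            report.add(f"channel_hf_variance_{i + 1}", len(bad), 0)

    if out.retained_channels.size == 0 or out.retained_epochs.size == 0:
        out.failed = True
        report.passed = False
    return out, report


def _interpolate_channel(
    data: np.ndarray, ch: int, ep: EpochSet, retained: np.ndarray
) -> np.ndarray:
    """Inverse-distance weighting over adjacency neighbors (3-D positions)."""
    neighbors = [j for j in ep.layout.neighbors(ch) if j in set(retained.tolist())]
    sources = np.array(neighbors if neighbors else retained.tolist(), int)
    d = np.linalg.norm(
        ep.layout.positions_3d[sources] - ep.layout.positions_3d[ch], axis=1
    )
    w = 1.0 / np.maximum(d, 1e-12)
    w /= w.sum()
    return np.einsum("s,esn->en", w, data[:, sources, :])


def finalize(ep: EpochSet, report: PreprocessReport | None = None) -> EpochSet:
    """Average-reference, interpolate rejected channels, apply quality gate.

    The average reference is computed over retained channels only; rejected
    channels are then rebuilt from their retained neighbors and returned to
    service (tracked in ``interpolated_channels``).  The set is flagged
    failed unless at least 75% of channels and 30% of epochs survived.
    """
    out = ep.copy()
    retained = out.retained_channels
    if retained.size == 0:
        out.failed = True
        return out
    ref = out.data[:, retained, :].mean(axis=1, keepdims=True)
    out.data = out.data - ref
    out.reference = "average"

    rejected = np.flatnonzero(out.rejected_channels)
    for ch in rejected:
        out.data[:, ch, :] = _interpolate_channel(out.data, ch, out, retained)
    out.interpolated_channels = frozenset(int(c) for c in rejected)

    ch_ok = retained.size >= GATE_CHANNEL_FRACTION * out.n_channels
    ep_ok = out.retained_epochs.size >= GATE_EPOCH_FRACTION * out.n_epochs
    out.failed = out.failed or not (ch_ok and ep_ok)
    if report is not None:
        report.passed = not out.failed
    # interpolated channels are usable downstream
    out.rejected_channels = np.zeros(out.n_channels, bool)
    return out


def preprocess_task(rec: Recording) -> tuple[EpochSet, PreprocessReport]:
    """Full task pipeline: filter, epoch, reject, finalize."""
    filtered = filter_continuous(rec, "task_extra")
    ep = epoch_task(filtered)
    if ep.failed or ep.n_epochs < 2:
        return ep, PreprocessReport(passed=False)
    ep, report = reject_cascade(ep)
    ep = finalize(ep, report)
    return ep, report


def preprocess_resting(
    rec: Recording, seed: int, n_iterations: int = 100
) -> tuple[list[EpochSet], list[PreprocessReport]]:
    """Full resting pipeline over all epoching iterations."""
    filtered = filter_continuous(rec, "rest_task_common")
    sets, reports = [], []
    for ep in epoch_resting(filtered, seed=seed, n_iterations=n_iterations):
        if ep.failed or ep.n_epochs < 2:
            sets.append(ep)
            reports.append(PreprocessReport(passed=False))
            continue
        ep, report = reject_cascade(ep)
        ep = finalize(ep, report)
        sets.append(ep)
        reports.append(report)
    return sets, reports
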