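"""On-disk formats: EDF recordings, layout JSON sidecars, array containers.

EDF writing is deliberately minimal (EDF, not EDF+; one data record per
second; 16-bit integers scaled to each channel's physical range in μV).
Reading EDF back is delegated to whatever EDF reader the user prefers;
the test-suite round-trips through ``mne.io.read_raw_edf``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .core import EpochSet, Recording
from .layout import SensorLayout


def _ascii(value, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def write_edf(rec: Recording, path: str | Path) -> None:
    """Write a continuous recording as a 16-bit EDF file (physical unit μV).

    The sampling rate must be an integer; the signal is zero-padded to a
    whole number of 1-second data records.
    """
    fs = rec.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF export requires an integer sampling rate")
    fs = int(round(fs))
    n_ch = rec.n_channels
    n_records = int(np.ceil(rec.n_samples / fs))
    data = np.zeros((n_ch, n_records * fs))
    data[:, : rec.n_samples] = rec.data

    pmin = np.floor(data.min(axis=1))
    pmax = np.ceil(data.max(axis=1))
    same = pmax <= pmin
    pmax[same] = pmin[same] + 1.0
    dmin, dmax = -32768, 32767
    scale = (dmax - dmin) / (pmax - pmin)
    digital = np.rint((data - pmin[:, None]) * scale[:, None] + dmin).astype("<i2")

    header = b"".join(
        [
            _ascii(0, 8),  # version
            _ascii(f"subject {rec.subject_id or 'X'}", 80),
            _ascii(f"session {rec.session} kind {rec.kind}", 80),
            _ascii("01.01.00", 8),
            _ascii("00.00.00", 8),
            _ascii(256 * (1 + n_ch), 8),
            _ascii("", 44),
            _ascii(n_records, 8),
            _ascii(1, 8),  # record duration, seconds
            _ascii(n_ch, 4),
        ]
    )
    fields = [
        (rec.layout.channel_ids, 16),
        (["synthetic EEG"] * n_ch, 80),
        (["uV"] * n_ch, 8),
        ([f"{v:g}" for v in pmin], 8),
        ([f"{v:g}" for v in pmax], 8),
        ([dmin] * n_ch, 8),
        ([dmax] * n_ch, 8),
        ([""] * n_ch, 80),
        ([fs] * n_ch, 8),
        ([""] * n_ch, 32),
    ]
    sig_header = b"".join(
        b"".join(_ascii(v, w) for v in values) for values, w in fields
    )
    with open(path, "wb") as f:
        f.write(header + sig_header)
        for r in range(n_records):
            f.write(digital[:, r * fs : (r + 1) * fs].tobytes())


def save_layout(layout: SensorLayout, path: str | Path) -> None:
    Path(path).write_text(json.dumps(layout.to_json_dict(), indent=1))


def load_layout(path: str | Path) -> SensorLayout:
    return SensorLayout.from_json_dict(json.loads(Path(path).read_text()))


def save_epochs(ep: EpochSet, path: str | Path) -> None:
    """Store an epoch set in a compressed npz container."""
    np.savez_compressed(
        path,
        data=ep.data,
        fs=ep.fs,
        labels=ep.labels.astype("U16"),
        times=ep.times,
        rejected_channels=ep.rejected_channels,
        rejected_epochs=ep.rejected_epochs,
        interpolated=np.array(sorted(ep.interpolated_channels), int),
        reference=np.array(ep.reference),
        failed=np.array(ep.failed),
        subject_id=np.array(ep.subject_id),
        session=np.array(ep.session),
        layout=np.array(json.dumps(ep.layout.to_json_dict())),
    )


def load_epochs(path: str | Path) -> EpochSet:
    with np.load(path, allow_pickle=False) as z:
        layout = SensorLayout.from_json_dict(json.loads(str(z["layout"])))
        return EpochSet(
            data=z["data"],
            fs=float(z["fs"]),
            layout=layout,
            labels=z["labels"],
            times=z["times"],
            rejected_channels=z["rejected_channels"],
            rejected_epochs=z["rejected_epochs"],
            interpolated_channels=frozenset(int(i) for i in z["interpolated"]),
            reference=str(z["reference"]),
            failed=bool(z["failed"]),
            subject_id=str(z["subject_id"]),
            session=str(z["session"]),
        )
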