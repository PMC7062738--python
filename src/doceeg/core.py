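"""Core data containers shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .layout import SensorLayout

REST = "rest"
TASK = "task"
PRE = "pre"
POST = "post"

STANDARD = "standard"
DEVIANT = "deviant"


@dataclass
class Recording:
    """Continuous multichannel EEG in microvolts.

    ``events`` is a list of ``(sample_index, event_code)`` tuples; for the
    oddball task the code is ``standard`` or ``deviant`` and the index marks
    the onset of the fifth tone of the series.
    """

    data: np.ndarray  # (n_channels, n_samples), μV
    fs: float
    layout: SensorLayout
    events: list[tuple[int, str]] = field(default_factory=list)
    subject_id: str = ""
    session: str = PRE
    kind: str = REST

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def validate(self) -> None:
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.data.ndim != 2 or self.data.shape[0] != self.layout.n_channels:
            raise ValueError("data shape does not match layout")
        for s, _ in self.events:
            if not 0 <= s < self.n_samples:
                raise ValueError("event sample index out of range")


@dataclass
class EpochSet:
    """Epoched EEG with rejection bookkeeping.

    ``data`` keeps the full epochs x channels x samples array; rejection is
    represented by boolean masks so the cascade stays inspectable.  ``times``
    holds the epoch time axis in seconds relative to the epoch-defining event
    (0 at epoch start for resting data).
    """

    data: np.ndarray  # (n_epochs, n_channels, n_samples)
    fs: float
    layout: SensorLayout
    labels: np.ndarray  # (n_epochs,) of str: rest | standard | deviant
    times: np.ndarray  # (n_samples,) seconds
    rejected_channels: np.ndarray = None  # bool (n_channels,)
    rejected_epochs: np.ndarray = None  # bool (n_epochs,)
    interpolated_channels: frozenset = frozenset()
    reference: str = "vertex"
    failed: bool = False
    subject_id: str = ""
    session: str = PRE

    def __post_init__(self):
        if self.rejected_channels is None:
            self.rejected_channels = np.zeros(self.data.shape[1], bool)
        if self.rejected_epochs is None:
            self.rejected_epochs = np.zeros(self.data.shape[0], bool)

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def retained_channels(self) -> np.ndarray:
        return np.flatnonzero(~self.rejected_channels)

    @property
    def retained_epochs(self) -> np.ndarray:
        return np.flatnonzero(~self.rejected_epochs)

    def retained_data(self) -> np.ndarray:
        """Retained epochs over retained channels, (n_ep_kept, n_ch_kept, n_s)."""
        return self.data[np.ix_(self.retained_epochs, self.retained_channels)]

    def copy(self) -> "EpochSet":
        return EpochSet(
            data=self.data.copy(),
            fs=self.fs,
            layout=self.layout,
            labels=self.labels.copy(),
            times=self.times.copy(),
            rejected_channels=self.rejected_channels.copy(),
            rejected_epochs=self.rejected_epochs.copy(),
            interpolated_channels=self.interpolated_channels,
            reference=self.reference,
            failed=self.failed,
            subject_id=self.subject_id,
            session=self.session,
        )


@dataclass
class PreprocessReport:
    """Per-step rejection counts from the artifact cascade."""

    steps: list[dict] = field(default_factory=list)
    passed: bool = True
    params: dict = field(default_factory=dict)

    def add(self, name: str, n_channels_rejected: int, n_epochs_rejected: int) -> None:
        self.steps.append(
            {
                "step": name,
                "channels_rejected": int(n_channels_rejected),
                "epochs_rejected": int(n_epochs_rejected),
            }
        )

    @property
    def total_channels_rejected(self) -> int:
        return sum(s["channels_rejected"] for s in self.steps)

    @property
    def total_epochs_rejected(self) -> int:
        return sum(s["epochs_rejected"] for s in self.steps)
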