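import numpy as np
import pytest

from doceeg.core import REST, EpochSet
from doceeg.layout import make_layout
from doceeg.synth import CohortSpec


@pytest.fixture(scope="session")
def layout16():
    return make_layout(16, "spherical-cap", "delaunay")


@pytest.fixture(scope="session")
def clean_spec():
    """Small, artifact-free cohort spec shared across tests."""
    return CohortSpec(
        n_channels=8,
        rest_duration_s=25.0,
        n_task_trials=40,
        artifact_rate=0.0,
        noisy_channel_rate=0.0,
        seed=7,
    )


def make_epochs(data: np.ndarray, fs: float = 250.0, layout=None) -> EpochSet:
    """Wrap a raw (epochs, channels, samples) array into an EpochSet."""
    n_ch = data.shape[1]
    if layout is None or layout.n_channels != n_ch:
        if n_ch >= 3:
            layout = make_layout(n_ch, "ring", "k-nearest", k=2)
        else:
            from doceeg.layout import SensorLayout

            pos2 = np.arange(n_ch, dtype=float)[:, None] * [1.0, 0.0]
            adj = ~np.eye(n_ch, dtype=bool) if n_ch > 1 else np.zeros((1, 1), bool)
            layout = SensorLayout(
                [f"E{i + 1}" for i in range(n_ch)],
                pos2,
                np.column_stack([pos2, np.zeros(n_ch)]),
                adj,
            )
    return EpochSet(
        data=np.asarray(data, float),
        fs=fs,
        layout=layout,
        labels=np.array([REST] * data.shape[0], dtype="U16"),
        times=np.arange(data.shape[2]) / fs,
    )
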