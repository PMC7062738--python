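"""Synthetic EEG cohorts, reference databases and electric-field maps.

The generator emulates the structure of a pre/post stimulation study in
disorders of consciousness: a cohort split into behavioral responders (R+)
and non-responders (R-), each subject contributing resting-state and
auditory-oddball EEG before and after stimulation.  R+ subjects receive
planted post-session increments of theta/alpha band power, theta-alpha
lag-coupling (driving wSMI) and a sustained late P3-like task component;
R- subjects receive none.  All randomness flows from a single integer seed
through per-subject/session substreams, so an identical spec reproduces a
cohort bit for bit.

Oscillatory components are jittered-phase sinusoids on top of 1/f (pink)
background noise, so the planted band power of an amplitude-A component is
analytically A^2/2 μV^2.  Cross-channel coupling is a shared narrowband
(4-10 Hz) latent added to a designated set of posterior carrier channels
with per-channel lags, which yields nonzero weighted symbolic mutual
information without identical-pattern artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

from .core import DEVIANT, POST, PRE, REST, STANDARD, TASK, Recording
from .layout import SensorLayout, make_layout

BANDS = {
    "delta": (1.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 12.0),
    "beta": (12.0, 30.0),
    "gamma": (30.0, 45.0),
}

# carrier frequency used for each band's sinusoidal component
BAND_FREQS = {"delta": 2.5, "theta": 6.0, "alpha": 10.0, "beta": 20.0, "gamma": 35.0}

_SESSION_CODE = {PRE: 0, POST: 1}
_KIND_CODE = {REST: 0, TASK: 1}


@dataclass
class CohortSpec:
    """Study conditions for one synthetic cohort.

    Amplitudes are μV; the planted ``d_*`` increments apply to R+ subjects'
    post-stimulation sessions only.  Group sizes default to the 12/48
    responder split of a 60-patient cohort; geometry defaults to a desk
    scale of 32 channels.
    """

    n_rplus: int = 12
    n_rminus: int = 48
    n_channels: int = 32
    geometry: str = "spherical-cap"
    neighbor_rule: str = "delaunay"
    fs: float = 250.0
    rest_duration_s: float = 90.0
    n_task_trials: int = 150
    deviant_fraction: float = 0.2
    trial_period_s: float = 1.6

    band_amps: dict = field(
        default_factory=lambda: {
            "delta": 4.0,
            "theta": 2.0,
            "alpha": 2.0,
            "beta": 1.0,
            "gamma": 0.5,
        }
    )
    amp_subject_sd: float = 0.3
    pink_sd: float = 5.0
    pink_exponent: float = 1.0
    sensor_noise_sd: float = 1.0

    coupling_amp: float = 1.5
    coupling_lag_ms: float = 40.0
    coupling_n_channels: int = 6

    # planted R+ post-session increments
    d_theta_amp: float = 1.5
    d_alpha_amp: float = 1.5
    d_coupling_amp: float = 1.5
    d_p3_amp: float = 3.0

    # task ERP morphology
    erp_common_amp: float = 1.0
    mmn_amp: float = -2.0
    p3_amp: float = 1.0
    trial_noise_sd: float = 4.0

    artifact_rate: float = 0.02
    noisy_channel_rate: float = 0.02
    seed: int = 0

    def __post_init__(self):
        for name, rate in [
            ("deviant_fraction", self.deviant_fraction),
            ("artifact_rate", self.artifact_rate),
            ("noisy_channel_rate", self.noisy_channel_rate),
        ]:
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")

    def null(self) -> "CohortSpec":
        """Same cohort with every planted group effect removed."""
        return replace(
            self, d_theta_amp=0.0, d_alpha_amp=0.0, d_coupling_amp=0.0, d_p3_amp=0.0
        )

    def strong(self) -> "CohortSpec":
        """Strong-effect preset for planted-effect recovery studies.

        The coupling increment is larger than the spectral ones because
        symbolic mutual information estimates carry more sampling noise
        than Welch band power at matched recording length.
        """
        return replace(
            self, d_theta_amp=2.5, d_alpha_amp=2.5, d_coupling_amp=4.5, d_p3_amp=4.0
        )

    def make_layout(self) -> SensorLayout:
        return make_layout(self.n_channels, self.geometry, self.neighbor_rule)


@dataclass
class SubjectRecord:
    subject_id: str
    diagnosis: str  # VS/UWS | MCS | exit-MCS
    responder: bool
    crsr_pre: int
    crsr_post: int
    recordings: dict = field(default_factory=dict)  # (kind, session) -> Recording

    def __post_init__(self):
        for score in (self.crsr_pre, self.crsr_post):
            if not 0 <= score <= 23:
                raise ValueError("CRS-R scores must lie in [0, 23]")


@dataclass
class FieldMapSet:
    """Per-subject electric-field magnitude volumes on a shared grid (V/m)."""

    fields: np.ndarray  # (n_subjects, *grid_shape), >= 0
    outcomes: np.ndarray  # (n_subjects,) scalar EEG change per subject
    region: np.ndarray  # boolean grid: the planted hotspot

    @property
    def n_subjects(self) -> int:
        return self.fields.shape[0]


def _rng(spec: CohortSpec, subject_index: int, session: str, kind: str, stream: int):
    return np.random.default_rng(
        [int(spec.seed), int(subject_index), _SESSION_CODE[session], _KIND_CODE[kind], stream]
    )


def pink_noise(rng, n_samples: int, exponent: float, sd: float) -> np.ndarray:
    """1/f^exponent noise of a given standard deviation, via spectral shaping."""
    if sd == 0:
        return np.zeros(n_samples)
    white = rng.standard_normal(n_samples)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n_samples)
    shaping = np.ones_like(freqs)
    shaping[1:] = freqs[1:] ** (-exponent / 2.0)
    shaping[0] = 0.0
    x = np.fft.irfft(spec * shaping, n=n_samples)
    return x * (sd / x.std())


def posterior_channels(layout: SensorLayout, fraction: float = 1 / 3) -> np.ndarray:
    """Channels in the lowest-y third of the 2-D projection ("posterior")."""
    n = max(2, int(round(layout.n_channels * fraction)))
    return np.argsort(layout.positions_2d[:, 1], kind="stable")[:n]


def frontal_channels(layout: SensorLayout, fraction: float = 1 / 3) -> np.ndarray:
    n = max(2, int(round(layout.n_channels * fraction)))
    return np.argsort(layout.positions_2d[:, 1], kind="stable")[-n:]


def coupled_channels(spec: CohortSpec, layout: SensorLayout) -> np.ndarray:
    """Carrier channels of the shared theta-alpha latent (posterior subset)."""
    post = posterior_channels(layout)
    m = min(spec.coupling_n_channels, len(post))
    return post[:m]


def coupled_pairs(spec: CohortSpec, layout: SensorLayout) -> list[tuple[int, int]]:
    carriers = sorted(coupled_channels(spec, layout))
    return [
        (carriers[i], carriers[j])
        for i in range(len(carriers))
        for j in range(i + 1, len(carriers))
    ]


def _subject_band_amps(spec: CohortSpec, rng) -> dict:
    amps = {}
    for band, amp in spec.band_amps.items():
        amps[band] = max(0.0, amp + spec.amp_subject_sd * rng.standard_normal())
    return amps


def _narrowband_latent(rng, n_samples: int, fs: float, lo: float = 4.0, hi: float = 10.0):
    raw = rng.standard_normal(n_samples + int(fs))
    sos = sps.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    x = sps.sosfiltfilt(sos, raw)[int(fs) // 2 : int(fs) // 2 + n_samples]
    s = x.std()
    return x / s if s > 0 else x


def _inject_artifacts(spec: CohortSpec, rng, data: np.ndarray, fs: float) -> None:
    """Rectangular >=150 μV transients plus persistently noisy channels."""
    n_ch, n_s = data.shape
    block = int(fs)  # 1-s blocks
    n_blocks = n_s // block
    pulse_len = max(1, int(0.12 * fs))
    if spec.artifact_rate > 0:
        for b in range(n_blocks):
            if rng.random() < spec.artifact_rate:
                ch = rng.choice(n_ch, size=max(1, n_ch // 8), replace=False)
                start = b * block + int(rng.integers(0, block - pulse_len))
                data[np.ix_(ch, np.arange(start, start + pulse_len))] += 200.0
    if spec.noisy_channel_rate > 0:
        for ch in range(n_ch):
            if rng.random() < spec.noisy_channel_rate:
                for b in range(n_blocks):
                    if rng.random() < 0.65:
                        start = b * block + int(rng.integers(0, block - pulse_len))
                        data[ch, start : start + pulse_len] += 200.0


def simulate_resting(
    spec: CohortSpec,
    subject_index: int,
    session: str,
    responder: bool,
    layout: SensorLayout | None = None,
) -> Recording:
    """Resting-state recording with planted spectral and coupling structure."""
    layout = layout or spec.make_layout()
    fs = spec.fs
    n_s = int(round(spec.rest_duration_s * fs))
    n_ch = layout.n_channels
    t = np.arange(n_s) / fs

    amp_rng = _rng(spec, subject_index, PRE, REST, 0)  # per-subject traits
    band_amps = _subject_band_amps(spec, amp_rng)
    band_freq_jitter = {b: 0.3 * amp_rng.standard_normal() for b in BANDS}

    rng = _rng(spec, subject_index, session, REST, 1)
    data = np.zeros((n_ch, n_s))

    boosted = responder and session == POST
    planted = set(posterior_channels(layout).tolist())
    for band, amp in band_amps.items():
        freq = BAND_FREQS[band] + band_freq_jitter[band]
        for ch in range(n_ch):
            a = amp
            if boosted and ch in planted:
                if band == "theta":
                    a += spec.d_theta_amp
                elif band == "alpha":
                    a += spec.d_alpha_amp
            if a <= 0:
                continue
            phase = rng.uniform(0, 2 * np.pi)
            data[ch] += a * np.sin(2 * np.pi * freq * t + phase)

    c_amp = spec.coupling_amp + (spec.d_coupling_amp if boosted else 0.0)
    if c_amp > 0 and spec.coupling_n_channels >= 2:
        carriers = coupled_channels(spec, layout)
        lag = int(round(spec.coupling_lag_ms * fs / 1000.0))
        latent = _narrowband_latent(rng, n_s + lag * len(carriers), fs)
        for i, ch in enumerate(carriers):
            shift = i * lag
            data[ch] += c_amp * latent[shift : shift + n_s]

    if spec.pink_sd > 0:
        for ch in range(n_ch):
            data[ch] += pink_noise(rng, n_s, spec.pink_exponent, spec.pink_sd)
    if spec.sensor_noise_sd > 0:
        data += spec.sensor_noise_sd * rng.standard_normal((n_ch, n_s))

    _inject_artifacts(spec, rng, data, fs)

    rec = Recording(
        data=data,
        fs=fs,
        layout=layout,
        events=[],
        subject_id=f"S{subject_index:03d}",
        session=session,
        kind=REST,
    )
    rec.validate()
    return rec


def _erp_kernel(times: np.ndarray, kind: str) -> np.ndarray:
    """Unit-amplitude component waveforms on the epoch time axis (seconds)."""
    if kind == "common":  # early auditory response, both conditions
        return np.exp(-0.5 * ((times - 0.09) / 0.02) ** 2)
    if kind == "mmn":  # early biphasic deflection
        g1 = np.exp(-0.5 * ((times - 0.13) / 0.03) ** 2)
        g2 = np.exp(-0.5 * ((times - 0.21) / 0.04) ** 2)
        return g1 - 0.6 * g2
    if kind == "p3":  # late sustained plateau, 300-600 ms
        rise = 0.5 * (1 + np.tanh((times - 0.30) / 0.03))
        fall = 0.5 * (1 - np.tanh((times - 0.60) / 0.05))
        return rise * fall
    raise ValueError(kind)


def deviant_assignment(n_trials: int, fraction: float, rng) -> np.ndarray:
    """Boolean deviant mask with an exact floor(fraction * n) deviant count."""
    n_dev = int(np.floor(fraction * n_trials))
    mask = np.zeros(n_trials, bool)
    mask[rng.permutation(n_trials)[:n_dev]] = True
    return mask


def simulate_task(
    spec: CohortSpec,
    subject_index: int,
    session: str,
    responder: bool,
    layout: SensorLayout | None = None,
) -> Recording:
    """Auditory-oddball recording: 80/20 standard/deviant event stream.

    Events mark the onset of the fifth tone of each series.  Deviant trials
    carry an MMN-like biphasic deflection on frontal channels and a
    sustained P3-like plateau on posterior channels; R+ post sessions get
    the planted P3 amplitude increment.
    """
    layout = layout or spec.make_layout()
    fs = spec.fs
    n_ch = layout.n_channels
    lead_in = int(2.0 * fs)
    period = int(round(spec.trial_period_s * fs))
    n_s = lead_in + spec.n_task_trials * period + int(fs)

    rng = _rng(spec, subject_index, session, TASK, 1)
    data = np.zeros((n_ch, n_s))
    if spec.pink_sd > 0:
        for ch in range(n_ch):
            data[ch] += pink_noise(rng, n_s, spec.pink_exponent, spec.pink_sd)
    if spec.sensor_noise_sd > 0:
        data += spec.sensor_noise_sd * rng.standard_normal((n_ch, n_s))

    deviants = deviant_assignment(spec.n_task_trials, spec.deviant_fraction, rng)

    window = int(0.74 * fs)  # component support after fifth-tone onset
    times = np.arange(window) / fs
    common_wave = _erp_kernel(times, "common")
    mmn_wave = _erp_kernel(times, "mmn")
    p3_wave = _erp_kernel(times, "p3")
    frontal = frontal_channels(layout)
    posterior = posterior_channels(layout)
    p3_amp = spec.p3_amp + (spec.d_p3_amp if responder and session == POST else 0.0)

    events: list[tuple[int, str]] = []
    for trial in range(spec.n_task_trials):
        onset = lead_in + trial * period
        sl = slice(onset, onset + window)
        amp_jit = 1.0 + 0.15 * rng.standard_normal()
        data[frontal[:, None], sl] += spec.erp_common_amp * amp_jit * common_wave
        if deviants[trial]:
            data[frontal[:, None], sl] += spec.mmn_amp * amp_jit * mmn_wave
            data[posterior[:, None], sl] += p3_amp * amp_jit * p3_wave
            events.append((onset, DEVIANT))
        else:
            events.append((onset, STANDARD))
        # per-trial low-frequency variability on top of the background
        if spec.trial_noise_sd > 0:
            drift = pink_noise(rng, window, 1.5, spec.trial_noise_sd)
            data[:, sl] += drift[None, :] * rng.standard_normal((n_ch, 1)) * 0.2

    _inject_artifacts(spec, rng, data, fs)

    rec = Recording(
        data=data,
        fs=fs,
        layout=layout,
        events=events,
        subject_id=f"S{subject_index:03d}",
        session=session,
        kind=TASK,
    )
    rec.validate()
    return rec


class Cohort:
    """Lazily generated responder/non-responder cohort.

    Subject metadata (diagnosis, CRS-R scores, responder label) is built
    eagerly; EEG recordings are generated on demand so that full-scale
    cohorts never need to be resident in memory at once.
    """

    def __init__(self, spec: CohortSpec):
        self.spec = spec
        self.layout = spec.make_layout()
        rng = np.random.default_rng([int(spec.seed), 77])
        n = spec.n_rplus + spec.n_rminus
        responder = np.zeros(n, bool)
        responder[rng.permutation(n)[: spec.n_rplus]] = True
        self.subjects: list[SubjectRecord] = []
        for i in range(n):
            u = rng.random()
            if u < 0.40:
                diagnosis, lo, hi = "VS/UWS", 3, 8
            elif u < 0.93:
                diagnosis, lo, hi = "MCS", 7, 17
            else:
                diagnosis, lo, hi = "exit-MCS", 18, 22
            pre = int(rng.integers(lo, hi + 1))
            post = min(23, pre + int(rng.integers(1, 4))) if responder[i] else pre
            self.subjects.append(
                SubjectRecord(
                    subject_id=f"S{i:03d}",
                    diagnosis=diagnosis,
                    responder=bool(responder[i]),
                    crsr_pre=pre,
                    crsr_post=post,
                )
            )

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    def recording(self, subject_index: int, kind: str, session: str) -> Recording:
        sub = self.subjects[subject_index]
        fn = simulate_resting if kind == REST else simulate_task
        return fn(self.spec, subject_index, session, sub.responder, self.layout)

    def materialize(self, subject_index: int) -> SubjectRecord:
        sub = self.subjects[subject_index]
        for kind in (REST, TASK):
            for session in (PRE, POST):
                sub.recordings[(kind, session)] = self.recording(
                    subject_index, kind, session
                )
        return sub


def simulate_reference_database(
    n_vs: int = 75,
    n_mcs: int = 68,
    separation: float = 1.0,
    seed: int = 0,
    base_spec: CohortSpec | None = None,
) -> list[tuple[str, str, Recording]]:
    """Labeled VS/UWS-vs-MCS resting cohort for classifier training.

    MCS-labeled subjects carry systematically higher theta/alpha power and
    theta-alpha coupling than VS-labeled ones, scaled by ``separation``.
    Returns ``(subject_id, label, recording)`` triples.
    """
    if n_vs < 5 or n_mcs < 5:
        raise ValueError("need at least 5 subjects per class")
    base = base_spec or CohortSpec()
    layout = base.make_layout()
    out = []
    labels = ["VS"] * n_vs + ["MCS"] * n_mcs
    for i, label in enumerate(labels):
        bump = separation if label == "MCS" else 0.0
        amps = dict(base.band_amps)
        amps["theta"] = amps["theta"] + 1.0 * bump
        amps["alpha"] = amps["alpha"] + 1.0 * bump
        spec_i = replace(
            base,
            seed=int(np.random.SeedSequence([seed, i]).generate_state(1)[0] % 2**31),
            band_amps=amps,
            coupling_amp=base.coupling_amp + 1.0 * bump,
            d_theta_amp=0.0,
            d_alpha_amp=0.0,
            d_coupling_amp=0.0,
            d_p3_amp=0.0,
        )
        rec = simulate_resting(spec_i, i, PRE, responder=False, layout=layout)
        rec.subject_id = f"DB{i:03d}"
        out.append((rec.subject_id, label, rec))
    return out


def simulate_field_maps(
    n_subjects: int,
    grid_shape: tuple[int, int, int] = (12, 12, 12),
    hotspot_center: tuple[int, int, int] | None = None,
    hotspot_radius: float = 3.0,
    hotspot_mean: float = 0.7,
    corr_strength: float = 0.0,
    seed: int = 0,
    noise_sd: float = 0.15,
    smooth_sigma: float = 1.2,
    background: float = 0.2,
) -> FieldMapSet:
    """Smooth per-subject field-magnitude volumes with a planted hotspot.

    Inside the spherical hotspot the mean magnitude is ``hotspot_mean`` V/m
    and voxel values correlate with the per-subject scalar outcome at
    ``corr_strength`` (exactly 1 when ``corr_strength=1`` and
    ``noise_sd=0``).
    """
    from scipy.ndimage import gaussian_filter

    if any(d < 4 for d in grid_shape):
        raise ValueError("each grid dimension must be >= 4")
    rng = np.random.default_rng([int(seed), 11])
    center = hotspot_center or tuple(d // 2 for d in grid_shape)
    grids = np.meshgrid(*[np.arange(d) for d in grid_shape], indexing="ij")
    dist2 = sum((g - c) ** 2 for g, c in zip(grids, center))
    region = dist2 <= hotspot_radius**2

    outcomes = rng.standard_normal(n_subjects)
    fields = np.empty((n_subjects,) + tuple(grid_shape))
    c = float(np.clip(corr_strength, -1.0, 1.0))
    amp = 0.1  # V/m per unit of (standardized) outcome inside the hotspot
    for i in range(n_subjects):
        base = np.full(grid_shape, background)
        if noise_sd > 0:
            rough = rng.standard_normal(grid_shape)
            smooth = gaussian_filter(rough, smooth_sigma)
            s = smooth.std()
            if s > 0:
                base = base + smooth * (noise_sd / s)
        vol = base.copy()
        voxel_noise = rng.standard_normal(int(region.sum()))
        vol[region] = (
            hotspot_mean
            + amp * (c * outcomes[i] + np.sqrt(max(0.0, 1 - c**2)) * voxel_noise)
        )
        fields[i] = np.maximum(vol, 0.0)
    return FieldMapSet(fields=fields, outcomes=outcomes, region=region)
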