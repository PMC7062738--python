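import zlib

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from doceeg import markers as mk
from doceeg.core import PRE
from doceeg.markers import (
    MARKER_IDS,
    OPPOSITE_SYMBOL,
    Spectrum,
    band_powers,
    compute_marker_epochs,
    kolmogorov_complexity,
    ordinal_symbols,
    pair_degree_from_matrix,
    pair_index,
    permutation_entropy,
    spectral_summaries,
    summarize_topography,
    tau_samples,
    trimmed_mean_80,
    welch_psd,
    wsmi,
    wsmi_from_symbols,
)
from doceeg.preprocess import preprocess_resting
from doceeg.synth import CohortSpec, coupled_pairs, simulate_resting
from tests.conftest import make_epochs

FS = 250.0


def sine_epochs(freq, amp=1.0, n_ep=4, n_ch=2, n_s=200, phase=0.0):
    t = np.arange(n_s) / FS
    x = amp * np.sin(2 * np.pi * freq * t + phase)
    return make_epochs(np.tile(x, (n_ep, n_ch, 1)))


# --- Welch -----------------------------------------------------------------


def test_welch_sinusoid_peaks_at_its_frequency():
    sp = welch_psd(sine_epochs(10.0))
    peak = sp.frequencies[np.argmax(sp.power[0, 0])]
    assert abs(peak - 10.0) <= sp.frequencies[1]


def test_welch_zero_signal_zero_psd():
    sp = welch_psd(make_epochs(np.zeros((3, 2, 200))))
    assert np.all(sp.power == 0)


def test_welch_white_noise_flat_within_sampling_error():
    rng = np.random.default_rng(0)
    sp = welch_psd(make_epochs(rng.normal(0, 1, (100, 1, 200))))
    mean_psd = sp.power.mean(axis=(0, 1))
    sel = (sp.frequencies >= 1) & (sp.frequencies <= 45)
    ratio = mean_psd[sel].max() / mean_psd[sel].min()
    assert ratio < 1.5


def test_welch_epoch_too_short_rejected():
    with pytest.raises(ValueError):
        welch_psd(make_epochs(np.zeros((2, 2, 100))))


# --- band powers -----------------------------------------------------------


def test_pure_theta_line_dominates_normalized_theta():
    bp = band_powers(welch_psd(sine_epochs(6.0)))
    assert bp["theta_norm"].mean() > 0.8
    assert bp["gamma_norm"].mean() < 0.05


def test_flat_spectrum_norm_power_proportional_to_bandwidth():
    freqs = np.arange(0, 50, 250.0 / 128.0)
    power = np.ones((1, 1, freqs.size))
    bp = band_powers(Spectrum(freqs, power, 512.0, 400.0))
    widths = {"delta": 3, "theta": 4, "alpha": 4, "beta": 18, "gamma": 15}
    total_w = sum(widths.values())
    for band, w in widths.items():
        assert abs(bp[f"{band}_norm"][0, 0] - w / total_w) < 0.06


def test_normalized_powers_sum_to_one_per_epoch():
    rng = np.random.default_rng(1)
    bp = band_powers(welch_psd(make_epochs(rng.normal(0, 1, (5, 3, 200)))))
    total = sum(bp[f"{b}_norm"] for b in ["delta", "theta", "alpha", "beta", "gamma"])
    assert np.allclose(total, 1.0, atol=1e-6)


# --- spectral summaries ----------------------------------------------------


def _line_spectrum(weights_by_freq):
    freqs = np.arange(0, 50, 250.0 / 128.0)
    power = np.zeros((1, 1, freqs.size))
    for f0, w in weights_by_freq.items():
        power[0, 0, np.argmin(np.abs(freqs - f0))] = w
    return Spectrum(freqs, power, 512.0, 400.0)


def test_single_line_spectrum_entropy_zero_msf_at_line():
    sp = _line_spectrum({9.77: 1.0})
    out = spectral_summaries(sp)
    assert out["spectral_entropy"][0, 0] < 1e-12
    bin_freq = sp.frequencies[np.argmin(np.abs(sp.frequencies - 9.77))]
    assert abs(out["msf"][0, 0] - bin_freq) < 1e-9


def test_flat_spectrum_entropy_one_msf_at_midpoint():
    freqs = np.arange(0, 50, 250.0 / 128.0)
    sp = Spectrum(freqs, np.ones((1, 1, freqs.size)), 512.0, 400.0)
    out = spectral_summaries(sp)
    assert abs(out["spectral_entropy"][0, 0] - 1.0) < 1e-12
    sel = freqs[(freqs >= 1) & (freqs <= 45)]
    midpoint = (sel[0] + sel[-1]) / 2
    assert abs(out["msf"][0, 0] - midpoint) < 2.0


def test_two_line_spectrum_quantiles_cumulative_oracle():
    sp = _line_spectrum({3.9: 1.0, 40.0: 1.0})
    out = spectral_summaries(sp)
    assert 3.9 < out["msf"][0, 0] < 40.0
    assert out["sef95"][0, 0] >= 39.0


def test_zero_power_raises():
    freqs = np.arange(0, 50, 250.0 / 128.0)
    with pytest.raises(ValueError):
        spectral_summaries(Spectrum(freqs, np.zeros((1, 1, freqs.size)), 512.0, 400.0))


# --- complexity ------------------------------------------------------------


def test_constant_signal_near_compressor_floor():
    k = kolmogorov_complexity(make_epochs(np.ones((2, 2, 200))))
    assert np.all(k < 0.1)


def test_iid_noise_incompressible_relative_to_oracle():
    rng = np.random.default_rng(0)
    ep = make_epochs(rng.uniform(-1, 1, (3, 2, 400)))
    k = kolmogorov_complexity(ep)
    # oracle: deflate on the same 32-level alphabet of i.i.d. uniform bytes
    sym = rng.integers(0, 32, 400).astype(np.uint8)
    oracle = len(zlib.compress(sym.tobytes(), 9)) / 400
    assert np.all(k > 0.55)
    assert np.allclose(k, oracle, atol=0.1)


def test_periodic_less_complex_than_aperiodic():
    rng = np.random.default_rng(1)
    t = np.arange(400) / FS
    periodic = np.sin(2 * np.pi * 10 * t)
    aperiodic = rng.normal(0, periodic.std(), 400)
    k = kolmogorov_complexity(make_epochs(np.stack([[periodic, aperiodic]])))
    assert k[0, 0] < k[0, 1]


# --- ordinal symbols and permutation entropy -------------------------------


def brute_force_symbols(x, tau):
    """Independent oracle: explicit stable-rank patterns, lexicographic index."""
    from itertools import permutations

    perms = sorted(permutations(range(3)))
    out = []
    for t in range(len(x) - 2 * tau):
        triple = [x[t], x[t + tau], x[t + 2 * tau]]
        order = sorted(range(3), key=lambda i: (triple[i], i))
        ranks = [0] * 3
        for pos, i in enumerate(order):
            ranks[i] = pos
        out.append(perms.index(tuple(ranks)))
    return np.array(out)


def test_monotone_ramps_give_single_symbols():
    up = ordinal_symbols(np.arange(10.0), 1)
    down = ordinal_symbols(-np.arange(10.0), 1)
    assert len(set(up.tolist())) == 1
    assert len(set(down.tolist())) == 1
    assert up[0] != down[0]


def test_symbols_match_brute_force_enumeration():
    x = np.array([1.0, 3.0, 2.0, 5.0, 4.0, 0.5, 2.5])
    for tau in (1, 2):
        assert np.array_equal(ordinal_symbols(x, tau), brute_force_symbols(x, tau))


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.lists(st.floats(-100, 100), min_size=7, max_size=24), st.integers(1, 2))
def test_symbols_property_matches_oracle_and_negation_flips(xs, tau):
    x = np.asarray(xs)
    if len(x) - 2 * tau < 1:
        return
    sym = ordinal_symbols(x, tau)
    assert np.array_equal(sym, brute_force_symbols(x, tau))
    # negating a tie-free series yields the sign-opposite pattern
    if len(np.unique(x)) == len(x):
        assert np.array_equal(ordinal_symbols(-x, tau), OPPOSITE_SYMBOL[sym])


def test_non_integer_tau_rejected():
    with pytest.raises(ValueError):
        tau_samples(33.0, 250.0)
    assert tau_samples(32.0, 250.0) == 8


def test_pe_zero_for_ramp_and_high_for_noise():
    ramp = np.tile(np.arange(200.0), (1, 1, 1))
    assert permutation_entropy(make_epochs(ramp), tau_ms=32.0)[0, 0] == 0.0
    rng = np.random.default_rng(2)
    pe = permutation_entropy(make_epochs(rng.normal(0, 1, (1, 1, 4000))), tau_ms=4.0)
    assert pe[0, 0] > 0.95


def test_pe_stable_under_self_concatenation():
    # PE depends on symbol frequencies, not epoch length: repeating the
    # signal leaves the distribution unchanged up to the few boundary
    # patterns introduced at the seam
    rng = np.random.default_rng(3)
    x = rng.normal(0, 1, 200)
    one = permutation_entropy(make_epochs(x[None, None, :]), tau_ms=32.0)[0, 0]
    two = permutation_entropy(make_epochs(np.tile(x, 2)[None, None, :]), tau_ms=32.0)[0, 0]
    assert abs(one - two) < 0.05


# --- wSMI ------------------------------------------------------------------


def test_wsmi_of_exact_copy_is_zero():
    rng = np.random.default_rng(0)
    x = rng.normal(0, 1, (1, 1, 200))
    ep = make_epochs(np.concatenate([x, x], axis=1))
    _, pm = wsmi(ep)
    assert abs(pm[0, 1]) < 1e-12


def test_wsmi_copy_zero_by_brute_force_toy():
    # 5-sample toy, tau=1: identical channels -> all weight on the diagonal
    x = np.array([0.1, 0.9, 0.3, 0.7, 0.5])
    sa = ordinal_symbols(x, 1)
    assert wsmi_from_symbols(sa, sa) == 0.0


def test_wsmi_independent_channels_near_zero():
    rng = np.random.default_rng(1)
    vals = []
    for seed in range(20):
        r = np.random.default_rng(seed)
        ep = make_epochs(r.normal(0, 1, (10, 2, 200)))
        _, pm = wsmi(ep)
        vals.append(pm[0, 1])
    # positively biased at finite samples but small
    assert np.mean(vals) < 0.05


def test_wsmi_detects_lag_coupling_above_independent_null():
    # smooth 1/f background concentrates patterns on the two monotone
    # symbols, whose pairings carry zero weight, so single-pair estimates
    # are noisy; a long recording and a strong shared latent keep the
    # planted pair clear of the independent-pair null
    spec = CohortSpec(
        n_channels=8,
        rest_duration_s=60.0,
        coupling_amp=6.0,
        coupling_n_channels=2,
        pink_sd=2.0,
        sensor_noise_sd=0.3,
        artifact_rate=0.0,
        noisy_channel_rate=0.0,
    )
    layout = spec.make_layout()
    (a, b) = coupled_pairs(spec, layout)[0]
    coupled_vals, null_vals = [], []
    for seed in range(8):
        sp = CohortSpec(**{**spec.__dict__, "seed": seed})
        rec = simulate_resting(sp, 0, PRE, False, layout)
        sets, _ = preprocess_resting(rec, seed=seed, n_iterations=1)
        _, pm = wsmi(sets[0])
        coupled_vals.append(pm[a, b])
        iu = np.triu_indices_from(pm, 1)
        for i, j in zip(*iu):
            if (i, j) != (min(a, b), max(a, b)):
                null_vals.append(pm[i, j])
    assert np.median(coupled_vals) > np.percentile(null_vals, 95)


def test_wsmi_symmetric_and_pair_count():
    rng = np.random.default_rng(5)
    ep = make_epochs(rng.normal(0, 1, (4, 5, 200)))
    _, pm = wsmi(ep)
    assert np.allclose(pm, pm.T, equal_nan=True)
    assert len(pair_index(224)) == 224 * 223 // 2


# --- summaries -------------------------------------------------------------


def test_trimmed_mean_sort_and_slice_oracle():
    vals = np.arange(1.0, 11.0)[:, None]  # 1..10 -> drop 1 and 10 -> 5.5
    assert summarize_topography(vals)[0] == 5.5


def test_trimmed_mean_constant_and_outlier_insensitive():
    const = np.full((20, 1), 3.14)
    assert summarize_topography(const)[0] == pytest.approx(3.14)
    with_outlier = const.copy()
    with_outlier[0, 0] = 1e9
    assert summarize_topography(with_outlier)[0] == pytest.approx(3.14)


def test_pair_degree_constant_and_hub():
    n = 5
    pm = np.full((n, n), 2.0)
    np.fill_diagonal(pm, np.nan)
    assert np.allclose(pair_degree_from_matrix(pm), 2.0)
    pm[1, :] = pm[:, 1] = 9.0
    np.fill_diagonal(pm, np.nan)
    deg = pair_degree_from_matrix(pm)
    assert np.argmax(deg) == 1


def test_pair_degree_four_channels_is_middle_order_statistic():
    rng = np.random.default_rng(0)
    pm = rng.normal(size=(4, 4))
    pm = (pm + pm.T) / 2
    np.fill_diagonal(pm, np.nan)
    deg = pair_degree_from_matrix(pm)
    for c in range(4):
        row = np.sort(np.delete(pm[c], c))
        assert deg[c] == row[1]


# --- full marker computation ----------------------------------------------


def test_all_17_markers_computed_with_bounded_ranges():
    rng = np.random.default_rng(7)
    ep = make_epochs(rng.normal(0, 5, (12, 6, 200)))
    per = compute_marker_epochs(ep)
    assert set(per) == set(MARKER_IDS)
    for m in MARKER_IDS:
        assert per[m].shape == (12, 6)
        assert np.all(np.isfinite(per[m]))
    assert np.all((per["pe_theta_alpha"] >= 0) & (per["pe_theta_alpha"] <= 1))
    assert np.all((per["spectral_entropy"] >= 0) & (per["spectral_entropy"] <= 1))
    assert np.all((per["kolmogorov"] > 0) & (per["kolmogorov"] <= 1.1))


def test_planted_beta_power_recovered_within_10pct_noiseless():
    """Calibration: a planted in-band line reproduces its analytic power."""
    amp = 2.0
    spec = CohortSpec(
        n_channels=32,
        rest_duration_s=30.0,
        band_amps={"delta": 0, "theta": 0, "alpha": 0, "beta": amp, "gamma": 0},
        amp_subject_sd=0.0,
        pink_sd=0.0,
        sensor_noise_sd=0.0,
        coupling_amp=0.0,
        artifact_rate=0.0,
        noisy_channel_rate=0.0,
    )
    rec = simulate_resting(spec, 0, PRE, False)
    sets, _ = preprocess_resting(rec, seed=0, n_iterations=1)
    bp = band_powers(welch_psd(sets[0]))
    planted = amp**2 / 2
    assert np.abs(bp["beta_raw"].mean() - planted) / planted < 0.10
    total = sum(bp[f"{b}_raw"] for b in ["delta", "theta", "alpha", "beta", "gamma"])
    assert np.abs(total.mean() - planted) / planted < 0.10
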