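"""Tract-length and covariance dating, model selection, calendar arithmetic."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.optimize import minimize_scalar

import paleopulse as pp
from conftest import perfect_track


# ---------------------------------------------------------------------------
# Single pulse
# ---------------------------------------------------------------------------

def test_single_pulse_exact_hand_example():
    """100 segments of 1.45 cM with a 0.2 cM cutoff: mean excess is
    0.0125 Morgans, so t-hat is exactly 80."""
    fit = pp.fit_single_pulse(np.full(100, 1.45), cutoff_cM=0.2)
    assert fit.t_hat == pytest.approx(80.0, abs=1e-12)


def test_single_pulse_matches_grid_mle_oracle():
    rng = np.random.default_rng(70)
    lengths = 0.2 + rng.exponential(100.0 / 80.0, 10_000)
    fit = pp.fit_single_pulse(lengths, cutoff_cM=0.2)
    assert 77 < fit.t_hat < 83
    assert fit.ci[0] < 80 < fit.ci[1]

    # independent numeric MLE of the truncated exponential log-likelihood
    e = (lengths - 0.2) / 100.0
    grid = np.linspace(40, 160, 2401)
    ll = lengths.size * np.log(grid) - grid * e.sum()
    t0 = grid[np.argmax(ll)]
    res = minimize_scalar(lambda t: -(lengths.size * np.log(t) - t * e.sum()),
                          bounds=(t0 - 1, t0 + 1), method="bounded",
                          options={"xatol": 1e-10})
    assert fit.t_hat == pytest.approx(res.x, rel=1e-6)


def test_single_pulse_error_paths():
    with pytest.raises(pp.PaleopulseError, match="decay-curve"):
        pp.fit_single_pulse(np.array([1.0]), cutoff_cM=0.2)
    with pytest.raises(pp.PaleopulseError, match="cutoff"):
        pp.fit_single_pulse(np.linspace(0.05, 2, 50), cutoff_cM=0.2)


# ---------------------------------------------------------------------------
# Two-pulse mixture
# ---------------------------------------------------------------------------

def test_mixture_recovers_separated_pulses():
    rng = np.random.default_rng(71)
    lengths = 0.2 + np.concatenate([
        rng.exponential(100.0 / 40.0, 10_000),
        rng.exponential(100.0 / 200.0, 10_000)])
    fit = pp.fit_two_pulse_mixture(lengths, seed=1)
    assert fit.params["t1"] == pytest.approx(40.0, rel=0.10)
    assert fit.params["t2"] == pytest.approx(200.0, rel=0.10)
    assert fit.params["pi"] == pytest.approx(0.5, abs=0.05)


def test_mixture_degenerates_on_single_pulse_data():
    rng = np.random.default_rng(72)
    lengths = 0.2 + rng.exponential(100.0 / 80.0, 5_000)
    fit = pp.fit_two_pulse_mixture(lengths, seed=2)
    close = abs(fit.params["t2"] - fit.params["t1"]) / fit.params["t2"] < 0.05
    extreme_pi = fit.params["pi"] < 0.02 or fit.params["pi"] > 0.98
    assert fit.flags or close or extreme_pi


@given(st.integers(0, 10_000))
def test_em_loglik_nondecreasing(seed):
    """EM trace is monotone non-decreasing on arbitrary inputs."""
    rng = np.random.default_rng(seed)
    lengths = 0.2 + rng.exponential(rng.uniform(0.3, 3.0), 300)
    fit = pp.fit_two_pulse_mixture(lengths, n_restarts=2, seed=seed)
    trace = np.array(fit.params["loglik_trace"])
    assert np.all(np.diff(trace) >= -1e-7)


# ---------------------------------------------------------------------------
# Extended pulse
# ---------------------------------------------------------------------------

def test_extended_pulse_recovers_lomax():
    rng = np.random.default_rng(73)
    k, t_m = 5.0, 80.0
    T = rng.gamma(k, t_m / k, 30_000)
    lengths = rng.exponential(1.0 / T) * 100.0
    lengths = lengths[lengths >= 0.2]
    fit = pp.fit_extended_pulse(lengths, cutoff_cM=0.2)
    assert fit.t_hat == pytest.approx(t_m, rel=0.10)
    assert fit.ci[0] < fit.t_hat < fit.ci[1]


def test_extended_pulse_on_exponential_data_hits_bound():
    rng = np.random.default_rng(74)
    lengths = 0.2 + rng.exponential(100.0 / 80.0, 20_000)
    fit = pp.fit_extended_pulse(lengths)
    assert "indistinguishable from single pulse" in fit.flags
    assert fit.t_hat == pytest.approx(80.0, rel=0.05)


def test_lomax_density_converges_to_exponential():
    """As k grows, the extended-pulse density approaches Exp(t_m)."""
    l = np.linspace(0.001, 0.1, 50)  # Morgans
    want = np.log(80.0) - 80.0 * l
    got = pp.extended_pulse_logpdf(l, 80.0, 1e8)
    assert np.allclose(got, want, atol=1e-6)


def test_extended_loglik_dominates_single():
    """The extended pulse nests the single pulse (k -> inf), so its
    maximized log-likelihood cannot be lower."""
    rng = np.random.default_rng(75)
    lengths = 0.2 + rng.exponential(100.0 / 80.0, 2_000)
    f1 = pp.fit_single_pulse(lengths)
    fe = pp.fit_extended_pulse(lengths)
    assert fe.loglik >= f1.loglik - 1e-6


# ---------------------------------------------------------------------------
# Model selection
# ---------------------------------------------------------------------------

def test_select_single_on_single_data():
    rng = np.random.default_rng(76)
    lengths = 0.2 + rng.exponential(100.0 / 80.0, 5_000)
    fits = [pp.fit_single_pulse(lengths),
            pp.fit_two_pulse_mixture(lengths, seed=3)]
    assert pp.select_pulse_model(fits)["model"] == "single"


def test_select_two_on_separated_mixture():
    rng = np.random.default_rng(77)
    lengths = 0.2 + np.concatenate([
        rng.exponential(100.0 / 30.0, 8_000),
        rng.exponential(100.0 / 300.0, 8_000)])
    fits = [pp.fit_single_pulse(lengths),
            pp.fit_two_pulse_mixture(lengths, seed=4)]
    assert pp.select_pulse_model(fits)["model"] == "two"


def test_select_ties_resolve_to_simpler():
    a = pp.PulseFit("single", 80.0, (70, 90), -100.0, 1000, 0.2, n_params=1)
    b = pp.PulseFit("two", 80.0, (70, 90), -100.0, 1000, 0.2, n_params=3)
    assert pp.select_pulse_model([a, b])["model"] == "single"
    c = pp.PulseFit("two", 80.0, (70, 90), -100.0, 999, 0.2, n_params=3)
    with pytest.raises(pp.PaleopulseError, match="different data"):
        pp.select_pulse_model([a, c])


# ---------------------------------------------------------------------------
# Longest-100 decay curve
# ---------------------------------------------------------------------------

def test_decay_curve_longest_coverage():
    """CI from the longest-100 fit covers the truth in most replicates."""
    rng = np.random.default_rng(78)
    cover = 0
    for _ in range(60):
        lengths = rng.exponential(100.0 / 80.0, 2_000)
        fit, curve = pp.decay_curve_longest(lengths, n_top=100)
        cover += fit.ci[0] <= 80.0 <= fit.ci[1]
        assert curve["survival"].iloc[0] == pytest.approx(1.0)
    assert cover >= 52  # ~95% nominal coverage over 60 replicates


def test_decay_curve_error_paths():
    with pytest.raises(pp.PaleopulseError, match="n_top"):
        pp.decay_curve_longest(np.ones(50), n_top=100)
    with pytest.raises(pp.PaleopulseError, match="equal"):
        pp.decay_curve_longest(np.ones(200), n_top=100)


# ---------------------------------------------------------------------------
# Covariance dating
# ---------------------------------------------------------------------------

def test_covariance_dating_on_perfect_dosage(layout):
    """Mean over replicate genomes recovers the pulse time; a single
    diploid's ~170 tracts make the per-genome estimate noisy."""
    t_hats = []
    for rep in range(3):
        sites = pp.simulate_panel_frequencies(100_000, layout, seed=80 + 10 * rep)
        truth = pp.simulate_ancestry_mosaic(
            pp.PulseModel(kind="single", t_m=80.0, m=0.03), layout, 2,
            seed=81 + 10 * rep)
        reads = pp.simulate_reads(sites, truth, np.inf, 0.0, 0.0,
                                  seed=82 + 10 * rep)
        track = perfect_track(reads)
        fit = pp.date_by_ancestry_covariance(track, n_boot=0)
        t_hats.append(fit.t_hat)
    assert np.mean(t_hats) == pytest.approx(80.0, rel=0.15)

    # small-distance covariance approaches the Bernoulli ancestry variance
    # F(1-F)/2 per haplotype pair average; check the dosage variance scale
    F = reads.df["dosage_true"].mean()
    var = reads.df["dosage_true"].var()
    assert var == pytest.approx(F * (1 - F) / 2, rel=0.15)

    # destroying the distance structure kills the signal
    perm = track.df.copy()
    perm["dosage"] = np.random.default_rng(0).permutation(
        perm["dosage"].to_numpy())
    with pytest.raises(pp.PaleopulseError, match="signal"):
        pp.date_by_ancestry_covariance(
            pp.PosteriorTrack(perm, 0.0, pp.HmmParams()), n_boot=0)


def test_covariance_and_segment_dating_agree(layout):
    """The two dating routes agree on clean simulated mosaics."""
    sites = pp.simulate_panel_frequencies(100_000, layout, seed=83)
    truth = pp.simulate_ancestry_mosaic(
        pp.PulseModel(kind="single", t_m=80.0, m=0.03), layout, 4, seed=84)
    reads = pp.simulate_reads(sites, truth, np.inf, 0.0, 0.0, seed=85)
    t_cov = pp.date_by_ancestry_covariance(perfect_track(reads), n_boot=0).t_hat
    lengths = truth.lengths_cM
    t_seg = pp.fit_single_pulse(lengths[lengths >= 0.2]).t_hat
    assert abs(t_cov - t_seg) / t_seg < 0.20


# ---------------------------------------------------------------------------
# Calendar propagation
# ---------------------------------------------------------------------------

def test_generations_to_calendar_identity_and_arithmetic():
    cal = pp.generations_to_calendar((0, 0), 29.0, (43_400, 46_580))
    assert (cal.low, cal.high) == (43_400, 46_580)
    cal2 = pp.generations_to_calendar((10, 10), 30.0, (1_000, 1_000))
    assert (cal2.low, cal2.high) == (1_300, 1_300)
    with pytest.raises(pp.PaleopulseError):
        pp.generations_to_calendar((-1, 5), 29.0, (1_000, 2_000))


def test_union_of_intervals():
    assert pp.union_of_intervals([(60, 90), (56, 98)]) == (56, 98)
    assert pp.union_of_intervals([(1, 2)]) == (1, 2)
    with pytest.raises(pp.PaleopulseError):
        pp.union_of_intervals([])


def test_union_contains_each_methods_ci():
    rng = np.random.default_rng(86)
    lengths = 0.2 + rng.exponential(100.0 / 80.0, 3_000)
    fits = [pp.fit_single_pulse(lengths),
            pp.fit_two_pulse_mixture(lengths, seed=5),
            pp.fit_extended_pulse(lengths)]
    union = pp.union_of_intervals([f.ci for f in fits])
    for f in fits:
        assert union[0] <= f.ci[0] and union[1] >= f.ci[1]
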