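"""Simulators vs their closed-form expectations."""

import numpy as np
import pytest
from scipy import stats

import paleopulse as pp


# ---------------------------------------------------------------------------
# Ancestry mosaics
# ---------------------------------------------------------------------------

def test_mosaic_stationary_fraction(layout):
    """Mean archaic fraction over many haplotypes matches m (renewal
    stationarity / law of large numbers)."""
    model = pp.PulseModel(kind="single", t_m=80.0, m=0.03)
    segs = pp.simulate_ancestry_mosaic(model, layout, 2000, seed=1)
    frac = segs.total_cM / (2000 * layout.total_cM)
    # per-haplotype SD of the archaic fraction is ~0.3%, so 3 SE at n=2000
    assert frac == pytest.approx(0.03, abs=3 * 0.0032 / np.sqrt(2000))


def test_mosaic_no_admixture_is_empty(layout):
    model = pp.PulseModel(kind="single", t_m=80.0, m=0.0)
    assert len(pp.simulate_ancestry_mosaic(model, layout, 10, seed=2)) == 0


def test_mosaic_mean_tract_length(layout):
    """Single pulse t=80: mean archaic tract is 1/((1-m)·80) Morgans."""
    model = pp.PulseModel(kind="single", t_m=80.0, m=0.03)
    segs = pp.simulate_ancestry_mosaic(model, layout, 1000, seed=3)
    lengths = segs.lengths_cM / 100.0
    want = 1.0 / (0.97 * 80.0)
    se = lengths.std() / np.sqrt(lengths.size)
    assert lengths.mean() == pytest.approx(want, abs=3 * se)


def test_mosaic_extended_pulse_heavier_tail(layout):
    """Lomax tract lengths (k=2) exceed the exponential at the same mean
    time in the upper tail."""
    single = pp.simulate_ancestry_mosaic(
        pp.PulseModel(kind="single", t_m=80.0, m=0.03), layout, 400, seed=4)
    ext = pp.simulate_ancestry_mosaic(
        pp.PulseModel(kind="extended", t_m=80.0, m=0.03, k=2.0), layout, 400, seed=5)
    assert np.quantile(ext.lengths_cM, 0.99) > np.quantile(single.lengths_cM, 0.99)


def test_mosaic_two_pulse_mixture_mean(layout):
    model = pp.PulseModel(kind="two", t_m=120.0, m=0.03,
                          t1=40.0, t2=200.0, pi=0.5)
    segs = pp.simulate_ancestry_mosaic(model, layout, 800, seed=6)
    # mixture mean tract length: 0.5/((1-m)40) + 0.5/((1-m)200)
    want = (0.5 / (0.97 * 40) + 0.5 / (0.97 * 200)) * 100
    se = segs.lengths_cM.std() / np.sqrt(len(segs))
    assert segs.lengths_cM.mean() == pytest.approx(want, abs=4 * se)


def test_mosaic_warns_when_no_tracts_expected(layout):
    with pytest.warns(UserWarning, match="archaic tracts"):
        pp.simulate_ancestry_mosaic(
            pp.PulseModel(kind="single", t_m=1.0, m=1e-4), layout, 1, seed=7)


# ---------------------------------------------------------------------------
# Panel frequencies
# ---------------------------------------------------------------------------

def test_panel_no_ascertainment_keeps_everything(layout):
    sites = pp.simulate_panel_frequencies(
        5000, layout, seed=8, ascertainment_min_diff=0.0)
    assert len(sites) == 5000


def test_panel_no_divergence_no_informative_sites(layout):
    with pytest.raises(pp.PaleopulseError, match="ascertainment"):
        pp.simulate_panel_frequencies(
            1000, layout, seed=9, F_AFR=0.01, F_NEA=0.01,
            ascertainment_min_diff=0.3)


def test_panel_matches_balding_nichols_oracle(layout):
    """Simulated source frequencies match an independent Balding-Nichols
    sampler (two-sample KS)."""
    F = 0.2
    sites = pp.simulate_panel_frequencies(
        50_000, layout, seed=10, F_AFR=F, F_NEA=F, F_DEN=F,
        ascertainment_min_diff=0.0)
    rng = np.random.default_rng(999)
    p = rng.uniform(0.05, 0.95, 50_000)
    oracle = stats.beta.rvs(p * (1 - F) / F, (1 - p) * (1 - F) / F,
                            random_state=rng)
    res = stats.ks_2samp(sites.df["f_DEN"].to_numpy(), oracle)
    assert res.pvalue > 0.01


# ---------------------------------------------------------------------------
# Reads
# ---------------------------------------------------------------------------

def test_reads_perfect_signal(layout):
    """Error-free deep coverage on a fixed-difference site recovers truth."""
    sites = pp.simulate_panel_frequencies(200, layout, seed=11,
                                          ascertainment_min_diff=0.0)
    df = sites.df.copy()
    df["f_NEA"] = 1.0
    df["f_AFR"] = 0.0
    sites = pp.SiteTable(df)
    # near-1 admixture fraction makes almost every site homozygous archaic
    truth = pp.simulate_ancestry_mosaic(
        pp.PulseModel(kind="single", t_m=1.0, m=0.99), layout, 2, seed=12)
    reads = pp.simulate_reads(sites, truth, 1000.0, 0.0, 0.0, seed=13)
    hom_nea = reads.df["dosage_true"] == 1.0
    assert hom_nea.sum() > 50
    frac = reads.df.loc[hom_nea, "n_der"] / reads.df.loc[hom_nea, "n_total"]
    assert frac.mean() == pytest.approx(1.0, abs=1e-9)


def test_reads_poisson_depth(layout):
    sites = pp.simulate_panel_frequencies(100_000, layout, seed=14,
                                          ascertainment_min_diff=0.0)
    truth = pp.simulate_ancestry_mosaic(
        pp.PulseModel(kind="single", t_m=80.0, m=0.03), layout, 2, seed=15)
    low = pp.simulate_reads(sites, truth, 0.05, 0.001, 0.0, seed=16)
    assert (low.df["n_total"] == 0).mean() == pytest.approx(np.exp(-0.05), abs=0.01)
    mid = pp.simulate_reads(sites, truth, 2.0, 0.001, 0.0, seed=17)
    assert mid.df["n_total"].mean() == pytest.approx(2.0, rel=0.01)


def test_reads_genotype_mode(layout):
    sites = pp.simulate_panel_frequencies(500, layout, seed=18)
    truth = pp.simulate_ancestry_mosaic(
        pp.PulseModel(kind="single", t_m=80.0, m=0.03), layout, 2, seed=19)
    gts = pp.simulate_reads(sites, truth, np.inf, 0.0, 0.0, seed=20)
    assert gts.has_genotypes
    assert set(gts.df["gt"]) <= {0, 1, 2}


def test_reads_rejects_bad_contamination(layout):
    sites = pp.simulate_panel_frequencies(50, layout, seed=21)
    truth = pp.simulate_ancestry_mosaic(
        pp.PulseModel(kind="single", t_m=80.0, m=0.03), layout, 2, seed=22)
    with pytest.raises(pp.PaleopulseError, match="contamination"):
        pp.simulate_reads(sites, truth, 1.0, 0.0, 1.2, seed=23)


# ---------------------------------------------------------------------------
# Pedigree IBD
# ---------------------------------------------------------------------------

def test_pedigree_parent_offspring_full_genome(layout):
    segs = pp.simulate_pedigree_ibd(1, 1, layout, seed=24)
    assert segs.total_cM / 100.0 == pytest.approx(layout.r_total, abs=1e-9)


def test_pedigree_expectations_m6_a2(layout):
    """Mean total and count at (m=6, a=2) match a·r/2^(m-1) Morgans and
    a·(r·m + c_chr)/2^(m-1) segments."""
    n_rep = 800
    tots = np.empty(n_rep)
    cnts = np.empty(n_rep)
    for s in range(n_rep):
        segs = pp.simulate_pedigree_ibd(6, 2, layout, seed=30_000 + s)
        tots[s] = segs.total_cM / 100.0
        cnts[s] = len(segs)
    want = pp.expected_pedigree_ibd(6, 2, layout)
    assert tots.mean() == pytest.approx(
        want["total_morgans"], abs=3 * tots.std() / np.sqrt(n_rep))
    assert cnts.mean() == pytest.approx(
        want["count"], abs=3 * cnts.std() / np.sqrt(n_rep))


def test_pedigree_validation(layout):
    with pytest.raises(pp.PaleopulseError):
        pp.simulate_pedigree_ibd(0, 1, layout, seed=1)
    with pytest.raises(pp.PaleopulseError):
        pp.simulate_pedigree_ibd(3, 3, layout, seed=1)


# ---------------------------------------------------------------------------
# Pairwise coalescent
# ---------------------------------------------------------------------------

def test_coalescent_count_matches_intensity(layout):
    """Emitted segment count matches the end-corrected closed-form
    intensity within Monte Carlo error."""
    sc = pp.CoalescentScenario(N_e=160, G=15, n_pairs=4)
    cnts = np.array([
        len(pp.simulate_pairwise_coalescent_segments(sc, layout, 12.0, seed=s))
        for s in range(250)])
    lam = pp.expected_segment_count(160, 15, 4, layout, 12.0)
    assert cnts.mean() == pytest.approx(lam, abs=3 * cnts.std() / np.sqrt(len(cnts)))


def test_coalescent_huge_population_no_segments(layout):
    sc = pp.CoalescentScenario(N_e=1e7, G=15, n_pairs=4)
    segs = pp.simulate_pairwise_coalescent_segments(sc, layout, 12.0, seed=25)
    assert len(segs) == 0


def test_coalescent_roh_mode_matches_roh_intensity(layout):
    """n_pairs=1 reproduces the per-bin ROH intensity used by the
    ROH-based N_e estimator."""
    sc = pp.CoalescentScenario(N_e=300, G=50, n_pairs=1)
    counts = np.zeros((150, len(pp.ROH_BINS) - 1))
    for s in range(150):
        segs = pp.simulate_pairwise_coalescent_segments(sc, layout, 4.0, seed=40_000 + s)
        counts[s] = pp.summarize_roh(segs, layout).bin_counts
    lam = pp.roh_bin_intensity(300.0, 50, layout)
    for b in range(counts.shape[1]):
        se = counts[:, b].std() / np.sqrt(counts.shape[0])
        # first-order end correction leaves a small residual (bin migration
        # of truncated runs), allowed for alongside the MC error
        assert counts[:, b].mean() == pytest.approx(
            lam[b], abs=3 * se + 0.03 * lam[b])


def test_simulators_deterministic(layout):
    a = pp.simulate_pairwise_coalescent_segments(
        pp.CoalescentScenario(N_e=160, G=15, n_pairs=4), layout, 12.0, seed=7)
    b = pp.simulate_pairwise_coalescent_segments(
        pp.CoalescentScenario(N_e=160, G=15, n_pairs=4), layout, 12.0, seed=7)
    assert a.df.equals(b.df)
    c = pp.simulate_pairwise_coalescent_segments(
        pp.CoalescentScenario(N_e=160, G=15, n_pairs=4), layout, 12.0, seed=8)
    assert not a.df.equals(c.df)
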