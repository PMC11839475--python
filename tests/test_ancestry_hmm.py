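"""Six-state diploid ancestry HMM: emissions, decoding, calling, proportion."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import binom

import paleopulse as pp
from paleopulse.ancestry_hmm import viterbi_loglik


def _mini_sites(rows):
    df = pd.DataFrame(rows)
    for col, default in (("anc", "A"), ("der", "G"), ("cM", None), ("f_c", None)):
        if col not in df.columns:
            df[col] = df["pos"] / 1e6 if col == "cM" else (
                df["f_AFR"] if col == "f_c" else default)
    return pp.SiteTable(df)


def test_emission_fixed_difference_site():
    """5/5 derived reads at an AFR=0 / NEA=1 site: NEA maximal, AFR floored."""
    sites = _mini_sites([{"chrom": "chr1", "pos": 1000, "f_AFR": 0.0,
                          "f_NEA": 1.0, "f_DEN": 0.5, "n_der": 5, "n_total": 5}])
    em = pp.emission_loglik(sites, pp.HmmParams(error_rate=0.0))
    assert em["NEA"].iloc[0] == pytest.approx(0.0, abs=1e-12)
    assert em["AFR"].iloc[0] < -600  # log floor
    assert em["NEA"].iloc[0] == max(em[s].iloc[0] for s in pp.ANCESTRY_STATES)


def test_emission_zero_depth_uninformative():
    sites = _mini_sites([{"chrom": "chr1", "pos": 1000, "f_AFR": 0.1,
                          "f_NEA": 0.9, "f_DEN": 0.5, "n_der": 0, "n_total": 0}])
    em = pp.emission_loglik(sites, pp.HmmParams())
    vals = [em[s].iloc[0] for s in pp.ANCESTRY_STATES]
    assert np.allclose(vals, 0.0, atol=1e-12)


def test_emission_matches_enumeration_oracle(layout):
    """Emissions equal exhaustive enumeration over the 2x2 haplotype-allele
    space at every site and state."""
    sites = pp.simulate_panel_frequencies(200, layout, seed=51)
    truth = pp.simulate_ancestry_mosaic(
        pp.PulseModel(kind="single", t_m=80.0, m=0.05), layout, 2, seed=52)
    reads = pp.simulate_reads(sites, truth, 3.0, 0.002, 0.05, seed=53)
    params = pp.HmmParams(error_rate=0.002, contamination=0.05)
    em = pp.emission_loglik(reads, params)

    df = reads.df
    pairs = {"AFR": ("f_AFR", "f_AFR"), "NEA": ("f_NEA", "f_NEA"),
             "DEN": ("f_DEN", "f_DEN"), "AFRNEA": ("f_AFR", "f_NEA"),
             "AFRDEN": ("f_AFR", "f_DEN"), "NEADEN": ("f_NEA", "f_DEN")}
    e, c = params.error_rate, params.contamination
    for state, (ca, cb) in pairs.items():
        want = np.zeros(len(df))
        for i, row in df.iterrows():
            fa, fb, fc = row[ca], row[cb], row["f_c"]
            tot = 0.0
            for x in (0, 1):
                for y in (0, 1):
                    g = x + y
                    p_read = (1 - c) * ((g / 2) * (1 - e) + (1 - g / 2) * e) \
                        + c * (fc * (1 - e) + (1 - fc) * e)
                    pr = binom.pmf(row["n_der"], row["n_total"], p_read)
                    tot += (fa if x else 1 - fa) * (fb if y else 1 - fb) * pr
            want[i] = np.log(max(tot, 1e-300))
        assert np.allclose(em[state].to_numpy(), want, atol=1e-10)


def test_posteriors_normalized_and_q_zero_blocks_states(small_layout):
    sites = pp.simulate_panel_frequencies(3000, small_layout, seed=54)
    truth = pp.simulate_ancestry_mosaic(
        pp.PulseModel(kind="single", t_m=80.0, m=0.03), small_layout, 2, seed=55)
    reads = pp.simulate_reads(sites, truth, 5.0, 0.001, 0.0, seed=56)
    track = pp.decode_posterior(reads, pp.HmmParams(q=(0.97, 0.03, 0.0), rho=80.0))
    sums = track.df[list(pp.ANCESTRY_STATES)].sum(axis=1)
    assert np.allclose(sums, 1.0, atol=1e-8)
    assert track.df["dosage"].between(0, 1).all()

    # q_NEA = 0: NEA-containing states have zero posterior everywhere
    blocked = pp.decode_posterior(reads, pp.HmmParams(q=(1.0, 0.0, 0.0), rho=80.0))
    for s in ("NEA", "AFRNEA", "NEADEN"):
        assert np.allclose(blocked.df[s], 0.0, atol=1e-12)


def test_forward_backward_dominates_viterbi(small_layout):
    """Total (forward) likelihood upper-bounds the best single path."""
    sites = pp.simulate_panel_frequencies(400, small_layout, seed=57)
    truth = pp.simulate_ancestry_mosaic(
        pp.PulseModel(kind="single", t_m=80.0, m=0.03), small_layout, 2, seed=58)
    reads = pp.simulate_reads(sites, truth, 5.0, 0.001, 0.0, seed=59)
    params = pp.HmmParams(q=(0.97, 0.03, 0.0), rho=80.0)
    track = pp.decode_posterior(reads, params)
    assert track.loglik >= viterbi_loglik(reads, params) - 1e-6


def test_decode_state_accuracy_on_deep_data(deep_sim, deep_track):
    """At 20x and 100k sites, the argmax state agrees with the simulated
    truth on whether a site carries NEA ancestry at the great majority of
    sites."""
    st = deep_track.df[list(pp.ANCESTRY_STATES)].to_numpy().argmax(axis=1)
    names = np.array(pp.ANCESTRY_STATES)
    has_nea = np.isin(names[st], ["NEA", "AFRNEA", "NEADEN"])
    truth_nea = deep_sim["reads"].df["dosage_true"].to_numpy() > 0
    assert (has_nea == truth_nea).mean() > 0.96


def test_call_segments_empty_for_all_afr(small_layout):
    sites = pp.simulate_panel_frequencies(1000, small_layout, seed=60)
    truth = pp.simulate_ancestry_mosaic(
        pp.PulseModel(kind="single", t_m=80.0, m=0.0), small_layout, 2, seed=61)
    reads = pp.simulate_reads(sites, truth, 10.0, 0.001, 0.0, seed=62)
    track = pp.decode_posterior(reads, pp.HmmParams(q=(0.97, 0.03, 0.0), rho=80.0))
    segs = pp.call_segments(track, threshold=0.9)
    # no true archaic tracts: essentially nothing should be called
    assert segs.total_cM < 0.02 * small_layout.total_cM


def test_call_segments_single_confident_run():
    """30 consecutive high-posterior sites spanning 1 cM give one ~1 cM
    segment."""
    n = 90
    cm = np.arange(n) / 30.0  # 3 cM of sites
    df = pd.DataFrame({"chrom": "chr1", "pos": (cm * 1e6).astype(int), "cM": cm,
                       "informative": True})
    for s in pp.ANCESTRY_STATES:
        df[s] = 0.0
    hot = (cm >= 1.0) & (cm < 2.0)
    df.loc[hot, "AFRNEA"] = 0.99
    df.loc[hot, "AFR"] = 0.01
    df.loc[~hot, "AFR"] = 1.0
    df["dosage"] = df["NEA"] + 0.5 * (df["AFRNEA"] + df["NEADEN"])
    track = pp.PosteriorTrack(df, 0.0, pp.HmmParams())
    segs = pp.call_segments(track)
    assert len(segs) == 1
    assert segs.lengths_cM[0] == pytest.approx(1.0, abs=0.1)
    assert segs.df["state"].iloc[0] == "AFRNEA"


def test_call_segments_recall_on_deep_data(deep_sim, deep_track):
    """Recall of true tracts and boundary precision at the default caller
    settings (site-wise HMM on the ascertained grid)."""
    segs = pp.call_segments(deep_track)
    sdf = segs.df
    hit = tot = 0
    berr = []
    for row in deep_sim["truth"].df.itertuples():
        if row.end_cM - row.start_cM < 0.5:
            continue
        tot += 1
        ov = sdf[(sdf.chrom == row.chrom) & (sdf.end_cM > row.start_cM)
                 & (sdf.start_cM < row.end_cM)]
        if len(ov):
            hit += 1
            berr.append(abs(ov.start_cM.min() - row.start_cM))
            berr.append(abs(ov.end_cM.max() - row.end_cM))
    assert hit / tot > 0.75
    assert np.median(berr) < 0.2


def test_ancestry_proportion_constant_dosage():
    df = pd.DataFrame({"chrom": "chr1", "pos": np.arange(5000) * 1000,
                       "cM": np.arange(5000) / 28.0, "informative": True,
                       "dosage": 0.029})
    for s in pp.ANCESTRY_STATES:
        df[s] = 0.0
    res = pp.ancestry_proportion(pp.PosteriorTrack(df, 0.0, pp.HmmParams()),
                                 n_boot=100, seed=1)
    assert res["proportion"] == pytest.approx(0.029)
    assert res["ci"][1] - res["ci"][0] < 1e-12


def test_ancestry_proportion_needs_sites():
    df = pd.DataFrame({"chrom": "chr1", "pos": np.arange(50) * 1000,
                       "cM": np.arange(50) / 28.0, "informative": True,
                       "dosage": 0.5})
    for s in pp.ANCESTRY_STATES:
        df[s] = 0.0
    with pytest.raises(pp.PaleopulseError, match="informative"):
        pp.ancestry_proportion(pp.PosteriorTrack(df, 0.0, pp.HmmParams()))


def test_desert_overlap_matches_bruteforce(layout):
    rng = np.random.default_rng(63)
    truth = pp.simulate_ancestry_mosaic(
        pp.PulseModel(kind="single", t_m=80.0, m=0.05), layout, 1, seed=64)
    gmap = pp.GeneticMap.from_layout(layout)
    deserts = []
    for _ in range(8):
        name, bp_len, _cm = layout.chromosomes[rng.integers(layout.c_chr)]
        s = rng.integers(0, int(bp_len * 0.8))
        deserts.append((name, int(s), int(s + rng.integers(1e6, 2e7))))
    rep = pp.desert_overlap(truth, deserts, gmap)

    for k, (chrom, ds, de) in enumerate(deserts):
        want_bp = 0.0
        n_hit = 0
        for row in truth.df.itertuples():
            if row.chrom != chrom:
                continue
            ov = min(row.end_bp, de) - max(row.start_bp, ds)
            if ov > 0:
                want_bp += ov
                n_hit += 1
        assert rep["overlap_bp"].iloc[k] == pytest.approx(want_bp)
        assert rep["n_segments"].iloc[k] == n_hit


def test_desert_overlap_trivial_cases(layout):
    gmap = pp.GeneticMap.from_layout(layout)
    seg = pp.SegmentSet(pd.DataFrame([{
        "chrom": "chr1", "start_bp": 10_000_000, "end_bp": 12_000_000,
        "start_cM": 10.0, "end_cM": 12.0, "state": "NEA",
        "sample": "s", "posterior": 1.0}]), "ancestry")
    inside = pp.desert_overlap(seg, [("chr1", 5_000_000, 20_000_000)], gmap)
    assert inside["overlap_bp"].iloc[0] == 2_000_000
    assert inside["overlap_cM"].iloc[0] == pytest.approx(2.0)
    disjoint = pp.desert_overlap(seg, [("chr2", 0, 5_000_000)], gmap)
    assert disjoint["overlap_bp"].iloc[0] == 0.0
    with pytest.raises(pp.PaleopulseError, match="malformed"):
        pp.desert_overlap(seg, [("chr1", 10, 10)], gmap)
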