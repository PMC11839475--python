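import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import paleopulse as pp

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def layout():
    """Default 22-autosome, 35-Morgan toy layout."""
    return pp.default_layout()


@pytest.fixture(scope="session")
def small_layout():
    """A short 4-chromosome layout for fast HMM tests (~7 Morgans)."""
    return pp.default_layout(n_chrom=4, total_morgans=7.0)


@pytest.fixture(scope="session")
def deep_sim(layout):
    """One deep simulated diploid: 100k sites, 20x reads, t=85, m=0.029."""
    sites = pp.simulate_panel_frequencies(100_000, layout, seed=101)
    model = pp.PulseModel(kind="single", t_m=85.0, m=0.029)
    truth = pp.simulate_ancestry_mosaic(model, layout, 2, seed=102)
    reads = pp.simulate_reads(sites, truth, 20.0, 0.001, 0.0, seed=103)
    return {"sites": sites, "truth": truth, "reads": reads, "model": model}


@pytest.fixture(scope="session")
def deep_track(deep_sim):
    params = pp.HmmParams(q=(0.971, 0.029, 0.0), rho=85.0, error_rate=0.001)
    return pp.decode_posterior(deep_sim["reads"], params)


def perfect_track(reads):
    """Posterior track built from the simulator's true archaic dosage."""
    df = reads.df[["chrom", "pos", "cM"]].copy()
    df["informative"] = True
    df["dosage"] = reads.df["dosage_true"]
    for s in pp.ANCESTRY_STATES:
        df[s] = 0.0
    return pp.PosteriorTrack(df, 0.0, pp.HmmParams())
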