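"""paleopulse: archaic-ancestry calling, admixture dating, kinship and
recent effective population size for ancient genomes, with forward
simulators providing ground truth for every estimator."""

import logging

from .core_genome import (
    ANCESTRY_STATES,
    GeneticMap,
    GenomeLayout,
    PaleopulseError,
    SegmentSet,
    SiteTable,
    concat_segments,
    default_layout,
    load_genetic_map,
    read_segments,
    write_segments,
)
from .synthdata import (
    CoalescentScenario,
    PulseModel,
    expected_pedigree_ibd,
    expected_segment_count,
    simulate_ancestry_mosaic,
    simulate_pairwise_coalescent_segments,
    simulate_panel_frequencies,
    simulate_pedigree_ibd,
    simulate_reads,
)
from .ancestry_hmm import (
    HmmParams,
    PosteriorTrack,
    ancestry_proportion,
    call_segments,
    decode_posterior,
    desert_overlap,
    emission_loglik,
    fit_hmm_params,
)
from .admixture_dating import (
    CalendarInterval,
    PulseFit,
    date_by_ancestry_covariance,
    decay_curve_longest,
    extended_pulse_logpdf,
    fit_extended_pulse,
    fit_single_pulse,
    fit_two_pulse_mixture,
    generations_to_calendar,
    select_pulse_model,
    union_of_intervals,
)
from .relatedness import (
    KINSHIP_CLASSES,
    DegreeFit,
    NeEstimate,
    classify_kinship_pair,
    estimate_recent_ne_ibd,
    estimate_separation_posterior,
    expected_ibd_count,
    fit_distant_degree,
    ibd_intensity,
    simulate_kinship_windows,
)
from .fstats import (
    StatResult,
    compute_d,
    compute_f3,
    compute_f4,
    f3_matrix,
    f4_ratio,
    mds_from_f3,
    pseudo_haploid,
    weighted_block_jackknife,
)
from .diversity import (
    ROH_BINS,
    BranchShorteningInput,
    RohSummary,
    age_by_branch_shortening,
    detect_roh,
    estimate_ne_from_roh,
    heterozygosity,
    roh_bin_intensity,
    summarize_roh,
)
from .shared_introgression import (
    SharingResult,
    edge_sharing,
    segment_correlation,
)
from .pipeline import RunConfig, derive_seed, run_demo

__version__ = "0.1.0"


def setup_logging(level: str = "INFO") -> None:
    """Configure the package logger for script / CLI use."""
    logging.basicConfig(
        level=getattr(logging, level.upper()),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )
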