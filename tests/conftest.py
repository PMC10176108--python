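import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from ptyrlink import synthetic
from ptyrlink.types import BRIDGE, PlexDesign, PsmRecord

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_psm(
    peptide="PEPTIDE_Y1",
    run="run1",
    rank=1,
    score=50.0,
    interference=10.0,
    intensities=None,
    protein="PROT",
):
    if intensities is None:
        intensities = tuple(float(5000 + 100 * i) for i in range(10))
    return PsmRecord(
        peptide_id=peptide,
        run_id=run,
        search_rank=rank,
        ion_score=score,
        isolation_interference_pct=interference,
        reporter_intensity=tuple(intensities),
        protein_id=protein,
    )


def simple_design(run="run1", lines=None, timepoint=30, replicate=1,
                  bridge_channel=9):
    """One plex: 9 line samples at one timepoint plus a bridge channel."""
    lines = lines or [f"L{i}" for i in range(9)]
    cmap = {}
    ch = 0
    for line in lines:
        if ch == bridge_channel:
            ch += 1
        cmap[ch] = (line, timepoint, replicate)
        ch += 1
    cmap[bridge_channel] = BRIDGE
    return PlexDesign(run_id=run, channel_map=cmap)


@pytest.fixture(scope="session")
def small_study():
    """A modest noisy study shared by read-only tests."""
    cfg = synthetic.SyntheticStudyConfig(
        n_peptides=60, noise_sd_log2=0.05, junk_psm_fraction=0.1,
        phenotype_noise_sd=0.05, seed=11,
    )
    return synthetic.generate_study(cfg)


@pytest.fixture(scope="session")
def clean_study():
    """Noise-free, junk-free study for exact round-trip checks."""
    cfg = synthetic.SyntheticStudyConfig(
        n_peptides=40, noise_sd_log2=0.0, junk_psm_fraction=0.0,
        phenotype_noise_sd=0.0, psm_duplicate_prob=0.0, dropout_rate=0.0,
        seed=5,
    )
    return synthetic.generate_study(cfg)


def preprocess_study(study, thresholds=None, presence=None):
    """Run the standard preprocessing chain on a synthetic study."""
    from ptyrlink import preprocess

    runs = {}
    for rid, recs in study.psm_tables.items():
        kept, _ = preprocess.filter_psms(recs, thresholds)
        mat = preprocess.rollup_peptides(kept, study.designs[rid])
        runs[rid] = preprocess.loading_normalize(mat, study.crude_medians[rid])
    bridged = preprocess.bridge_normalize(runs, study.designs)
    log2fc = preprocess.basal_log2fc(bridged)
    if presence is not None:
        log2fc = preprocess.presence_filter(log2fc, presence)
    means = preprocess.replicate_mean(log2fc)
    return log2fc, means
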