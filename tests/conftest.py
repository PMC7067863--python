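"""Shared fixtures: the default synthetic study, run once per session."""

from __future__ import annotations

import warnings

import pytest

from meripseq.pipeline import PipelineConfig, call_peaks, run_differential
from meripseq.synthetic import (
    SimulationConfig,
    simulate_experiment,
    simulate_transcriptome,
)


@pytest.fixture(scope="session")
def default_study():
    """Default study conditions: 100 genes, 50 spiked sites, gamma=8,
    2 conditions x 3 IP/Input pairs at ~30x depth, seed pinned."""
    cfg = SimulationConfig(seed=1)
    txm = simulate_transcriptome(cfg)
    exp = simulate_experiment(cfg, txm)
    return cfg, txm, exp


@pytest.fixture(scope="session")
def called_peaks(default_study):
    """Consensus peaks from the full caller on the default study."""
    _cfg, txm, exp = default_study
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        peaks, sites = call_peaks(
            exp.tracks, exp.samples, txm.genes, PipelineConfig(), txm.genome
        )
    return peaks, sites


@pytest.fixture(scope="session")
def differential_tables(default_study, called_peaks):
    _cfg, txm, exp = default_study
    peaks, _ = called_peaks
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_differential(exp.tracks, exp.samples, txm.genes, peaks,
                                PipelineConfig())
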