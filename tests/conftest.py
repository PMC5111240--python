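"""Shared fixtures: one small simulated clade and its pipeline run.

The clade is noise-free (every transcript detected, none truncated) so that
planted truth and pipeline output can be compared exactly; heavyweight
results are session-scoped and shared across test modules.
"""

from __future__ import annotations

import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make `oracles` importable

from perloss.pipeline import PipelineConfig, PipelineInputs, run_pipeline
from perloss.synthetic_data import SimConfig, simulate_clade


@pytest.fixture(scope="session")
def clade():
    """40 families, 10% planted losses, noise-free transcriptomes."""
    config = SimConfig(
        n_families=40,
        genes_per_contig=10,
        loss_fraction=0.1,
        misannotated_fraction=0.05,
        transcript_detection_prob=1.0,
        truncation_prob=0.0,
        seed=11,
    )
    return simulate_clade(config)


@pytest.fixture(scope="session")
def pipeline_result(clade):
    return run_pipeline(PipelineInputs.from_clade(clade), PipelineConfig())
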