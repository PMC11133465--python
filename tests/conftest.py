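"""Shared fixtures: all test data is generated programmatically."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from csftdna.containers import ReporterSet, SampleCounts, SelectorPanel
from csftdna.simulate import SimulationConfig, simulate_cohort, simulate_panel


def make_counts(records, sample_id="S1", **meta) -> SampleCounts:
    """Build a SampleCounts from (chrom, pos, ref, alt, depth, alt_count) tuples."""
    df = pd.DataFrame(records, columns=["chrom", "pos", "ref", "alt",
                                        "depth", "alt_count"])
    return SampleCounts(sample_id=sample_id, counts=df, **meta)


def make_reporters(variants, patient_id="P1") -> ReporterSet:
    """Build a ReporterSet from (chrom, pos, ref, alt, gene, coding) tuples."""
    df = pd.DataFrame(variants, columns=["chrom", "pos", "ref", "alt",
                                         "gene", "coding"])
    df["sources"] = "test"
    return ReporterSet(patient_id=patient_id, variants=df)


@pytest.fixture(scope="session")
def tiny_panel() -> SelectorPanel:
    """Ten positions, two genes, one non-coding position per gene."""
    rows = []
    for i in range(5):
        rows.append(("chr1", 100 + i, "GENEA", i != 4))
    for i in range(5):
        rows.append(("chr2", 200 + i, "GENEB", i != 4))
    return SelectorPanel(pd.DataFrame(rows, columns=["chrom", "pos", "gene",
                                                     "coding"]))


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return SimulationConfig(n_patients=8, n_controls=8, panel_size=600, seed=42)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    """(panel, samples, clinical, truth) for a small but complete cohort."""
    return simulate_cohort(small_config)


@pytest.fixture(scope="session")
def panel_with_truth():
    """A default-size panel plus its true per-position error map."""
    return simulate_panel(SimulationConfig(seed=11))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
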