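"""Shared fixtures: synthetic cohorts at several scales.

Cohorts are generated in-session (seeded, deterministic); the tiny
on-disk fixture under tests/data/tiny was written by
``triomic.simulate.write_fixture`` with ``GeneratorConfig.scaled(12, 30,
seed=20210925)`` and exercises the file readers.
"""

from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from triomic.io import GenusCountTable
from triomic.simulate import GeneratorConfig, generate

DATA = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def default_cohort():
    """One cohort at the default study design (120 triplets, 200 genera)."""
    return generate(GeneratorConfig(seed=0))


@pytest.fixture(scope="session")
def small_cohort():
    """A faster cohort for tests that only need structure, not power."""
    return generate(GeneratorConfig.scaled(n_patients=40, n_genera=60, seed=1))


@pytest.fixture(scope="session")
def tiny_dir() -> Path:
    return DATA / "tiny"


def make_table(counts: np.ndarray, patients: list[str], types: list[str]) -> GenusCountTable:
    """Hand-build a GenusCountTable from a small dense array."""
    counts = np.asarray(counts)
    g, s = counts.shape
    sample_ids = [f"{p}_{t}" for p, t in zip(patients, types)]
    meta = pd.DataFrame(
        {"patient_id": patients, "sample_type": types},
        index=pd.Index(sample_ids, name="sample_id"),
    )
    df = pd.DataFrame(counts, index=[f"g{i}" for i in range(g)], columns=sample_ids)
    return GenusCountTable(df, meta)
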