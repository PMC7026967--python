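from __future__ import annotations

import numpy as np
import pytest

from otupipe.io import read_reference_fasta
from otupipe.qc import QcParams, screen_reads
from otupipe.simulate import (
    SimConfig,
    default_profiles,
    simulate_counts,
    simulate_reads,
    write_reference_fasta,
)


@pytest.fixture(scope="session")
def profiles():
    return default_profiles()


@pytest.fixture(scope="session")
def reference_path(profiles, tmp_path_factory):
    path = tmp_path_factory.mktemp("ref") / "reference.fasta"
    write_reference_fasta(profiles, path)
    return path


@pytest.fixture(scope="session")
def reference(reference_path):
    return read_reference_fasta(reference_path)


class MiniStudy:
    """A small but complete synthetic study shared across test modules."""

    def __init__(self, profiles, tmp):
        self.profiles = profiles
        self.config = SimConfig(n_samples_per_group=3, reads_per_sample=600, seed=42)
        self.counts, self.truth = simulate_counts(profiles, self.config)
        self.sim = simulate_reads(self.counts, profiles, self.config)
        self.metadata = dict(self.counts.groups)
        self.fastq_dir = tmp / "fastq"
        self.sim.write(self.fastq_dir)
        self.passed = {
            s: screen_reads(reads, QcParams())[0]
            for s, reads in self.sim.reads_by_sample.items()
        }


@pytest.fixture(scope="session")
def mini_study(profiles, tmp_path_factory):
    return MiniStudy(profiles, tmp_path_factory.mktemp("mini"))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
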