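"""Shared fixtures: all test data is generated programmatically."""

from __future__ import annotations

import numpy as np
import pytest

from crprimer import RunConfig, SimulationConfig, run_design, simulate_reference_pair


@pytest.fixture()
def rng():
    # function-scoped so every test sees the same deterministic stream
    return np.random.default_rng(20120224)


@pytest.fixture(scope="session")
def sim_dataset(tmp_path_factory):
    """A small simulated reference pair shared across tests (read-only)."""
    outdir = tmp_path_factory.mktemp("sim")
    cfg = SimulationConfig(seed=7, n_genes=6, n_chromosomes=2)
    return simulate_reference_pair(cfg, outdir)


@pytest.fixture(scope="session")
def sim_design(sim_dataset, tmp_path_factory):
    """A full design run over the shared simulation (read-only)."""
    outdir = tmp_path_factory.mktemp("run")
    p = sim_dataset.paths
    cfg = RunConfig(
        genome_a=p["genome_a"],
        genome_b=p["genome_b"],
        gff_a=p["gff_a"],
        gff_b=p["gff_b"],
        orthologs=p["orthologs"],
        gaf=p["gaf"],
        slim=p["slim"],
        outdir=outdir,
        seed=7,
    )
    return cfg, run_design(cfg)


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])
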