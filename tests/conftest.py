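"""Shared fixtures: a small simulated cohort on disk and its pipeline run."""

import pytest

from raredx.pipeline import run_cohort
from raredx.simulate import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_sim(tmp_path_factory):
    """A 30-family synthetic cohort (default mix rescaled), seed-fixed."""
    outdir = tmp_path_factory.mktemp("sim30")
    cfg = SimulationConfig().with_families(30)
    sim = simulate_cohort(cfg, seed=11, outdir=str(outdir))
    return cfg, sim


@pytest.fixture(scope="session")
def small_run(small_sim):
    cfg, sim = small_sim
    return run_cohort(
        sim.paths["vcf_dir"],
        sim.paths["ped"],
        sim.paths["annotations"],
        sim.paths["phenotypes"],
        sim.paths["ontology"],
        sim.paths["gene_map"],
        cnv_path=sim.paths["cnv"],
        covariates_path=sim.paths["covariates"],
    )


@pytest.fixture(scope="session")
def mini_ontology(tmp_path_factory):
    from raredx.io import read_ontology, write_obo
    from raredx.simulate import build_ontology_terms

    path = tmp_path_factory.mktemp("obo") / "mini.obo"
    write_obo(build_ontology_terms(), str(path))
    return read_ontology(str(path))
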