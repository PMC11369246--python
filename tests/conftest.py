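"""Shared fixtures.

The session-scoped ``study_run`` executes the full default synthetic study
(2 Mb male + 2 Mb female genome, ten planted satellites spanning abundances
0.1-5% and monomer lengths 20-300 bp, 150 bp paired reads at 10x coverage
with 1% base error) once, and the discovery/abundance checks all read from
it.  Smaller fixtures drive the unit tests.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from satellitome import PlantedTruth, RunConfig, read_catalog, run_synthetic

STUDY_SEED = 1


@pytest.fixture(scope="session")
def study_run(tmp_path_factory):
    outdir = tmp_path_factory.mktemp("study")
    config = RunConfig(seed=STUDY_SEED, mf_bias_ratio=1.5)
    manifest = run_synthetic(config, outdir, genome_length=2_000_000, coverage=10.0)
    return {
        "config": config,
        "outdir": outdir,
        "manifest": manifest,
        "summary": manifest["evaluation_summary"],
        "truth": PlantedTruth.from_json(outdir / "truth.json"),
        "evaluation": pd.read_csv(outdir / "evaluation.tsv", sep="\t"),
        "catalog": read_catalog(outdir / "catalog.fasta"),
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
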