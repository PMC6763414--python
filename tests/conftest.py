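"""Shared fixtures: one small synthetic population reused across modules."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from wheatgs import (
    GeneticArchitecture, TrialDesign, compute_grm, simulate_genetic_values,
    simulate_genotypes, simulate_glu_alleles, simulate_line_blues,
    simulate_plot_phenotypes,
)


@pytest.fixture(scope="session")
def small_pop():
    """60 lines from 25 families, 3 chromosomes x 80 markers."""
    geno, families = simulate_genotypes(
        n_families=25, n_lines=60, n_chromosomes=3,
        markers_per_chromosome=80, seed=100)
    glu = simulate_glu_alleles(geno.lines, seed=101, missing_fraction=0.1)
    arch = GeneticArchitecture(n_qtl_background=100)
    gvalues = simulate_genetic_values(geno, glu, arch, seed=102)
    return {"geno": geno, "families": families, "glu": glu,
            "arch": arch, "gvalues": gvalues, "kinship": compute_grm(geno)}


@pytest.fixture(scope="session")
def small_blues(small_pop):
    return simulate_line_blues(small_pop["gvalues"], entry_h2=0.7, seed=103)


@pytest.fixture(scope="session")
def small_plots(small_pop):
    design = TrialDesign.from_architecture(
        small_pop["arch"], n_agronomic_trials=3, n_rheology_trials=2,
        lines_per_agronomic_trial=0.6, rheology_coverage=0.5)
    return simulate_plot_phenotypes(small_pop["gvalues"], design, seed=104)


def rng(seed: int = 0) -> np.random.Generator:
    return np.random.default_rng(seed)
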