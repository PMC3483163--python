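"""Shared fixtures: small hand-built pedigrees and the study-scale structure."""

from __future__ import annotations

import numpy as np
import pytest

from cytoherit.pedigree import Individual, Pedigree, kinship_matrix
from cytoherit.simulate import SimulationConfig, simulate_pedigrees


@pytest.fixture
def trio() -> Pedigree:
    return Pedigree(
        [
            Individual("F", "fam1", sex=1, age=45.0),
            Individual("M", "fam1", sex=2, age=43.0),
            Individual("C", "fam1", father_id="F", mother_id="M", sex=1, age=20.0),
        ]
    )


@pytest.fixture
def sibship() -> Pedigree:
    """Two founders and three full siblings."""
    inds = [
        Individual("F", "fam1", sex=1, age=50.0),
        Individual("M", "fam1", sex=2, age=48.0),
    ]
    for i in range(3):
        inds.append(
            Individual(f"S{i + 1}", "fam1", father_id="F", mother_id="M",
                       sex=1 + i % 2, age=20.0 + i)
        )
    return Pedigree(inds)


@pytest.fixture
def three_gen() -> Pedigree:
    """Grandparents, two sib parents with spouses, and first-cousin children."""
    return Pedigree(
        [
            Individual("GF", "fam1", sex=1),
            Individual("GM", "fam1", sex=2),
            Individual("A", "fam1", father_id="GF", mother_id="GM", sex=1),
            Individual("B", "fam1", father_id="GF", mother_id="GM", sex=2),
            Individual("SA", "fam1", sex=2),
            Individual("SB", "fam1", sex=1),
            Individual("CA", "fam1", father_id="A", mother_id="SA", sex=1),
            Individual("CB", "fam1", father_id="SB", mother_id="B", sex=2),
        ]
    )


@pytest.fixture(scope="session")
def study():
    """The default 17-family study structure (pedigree + assayed subset)."""
    cfg = SimulationConfig(seed=17)
    ped, assayed = simulate_pedigrees(cfg, np.random.default_rng(cfg.seed))
    return ped, assayed


@pytest.fixture(scope="session")
def study_kinship_all(study):
    ped, _ = study
    return kinship_matrix(ped)


@pytest.fixture(scope="session")
def study_kinship_assayed(study):
    ped, assayed = study
    return kinship_matrix(ped, assayed)
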