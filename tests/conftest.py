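import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from mlgblup.pedigree import MISSING, Pedigree
from mlgblup.simdata import SimConfig, TraitDef, simulate_population


def make_pedigree(sire, dam, lines=None, litter=None, genotyped=None,
                  birth_year=None):
    n = len(sire)
    return Pedigree(
        animal_id=np.array([f"a{i}" for i in range(n)], dtype=object),
        sire=np.asarray(sire, dtype=np.int32),
        dam=np.asarray(dam, dtype=np.int32),
        line=(np.asarray(lines, dtype=object) if lines is not None
              else np.array(["L1"] * n, dtype=object)),
        birth_year=(np.asarray(birth_year, dtype=np.int32)
                    if birth_year is not None
                    else np.zeros(n, dtype=np.int32)),
        genotyped=(np.asarray(genotyped, dtype=bool) if genotyped is not None
                   else np.zeros(n, dtype=bool)),
        litter=None if litter is None else np.asarray(litter, dtype=object),
    )


@pytest.fixture
def trio():
    """Sire, dam, offspring (codes 0, 1, 2)."""
    return make_pedigree([MISSING, MISSING, 0], [MISSING, MISSING, 1])


@pytest.fixture(scope="session")
def small_sim():
    """A small three-line population with a crossbred line, shared by tests."""
    cfg = SimConfig(founders_per_line=30, generations=4,
                    sires_per_generation=6, dams_per_generation=12,
                    litter_size=5, n_wgs=600, n_chip=250, n_qtl=40,
                    n_chromosomes=3, crossbred_litters_per_generation=6,
                    crossbred_generations=1, seed=11)
    return simulate_population(cfg)


@pytest.fixture(scope="session")
def small_sim_single_trait():
    """Small purebred-only, single-trait population for evaluation tests."""
    cfg = SimConfig(founders_per_line=30, generations=4,
                    sires_per_generation=6, dams_per_generation=12,
                    litter_size=5, n_wgs=400, n_chip=200, n_qtl=40,
                    n_chromosomes=3, traits=(TraitDef("ADG"),),
                    crossbred_sire_line=None, crossbred_dam_line=None,
                    seed=7)
    return simulate_population(cfg)
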