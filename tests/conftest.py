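"""Shared fixtures: the bundled knowledgebase and a pool of fixture
molecules drawn from the synthetic-cluster truth templates."""

from __future__ import annotations

import numpy as np
import pytest

from bgcforge.knowledgebase import default_knowledgebase
from bgcforge.simulate import (FixtureConfig, build_knowledgebase,
                               sample_cluster_spec)


@pytest.fixture(scope="session")
def kb():
    """The bundled knowledgebase (exercises the YAML loader)."""
    return default_knowledgebase()


@pytest.fixture(scope="session")
def fixture_config():
    return FixtureConfig(seed=7)


@pytest.fixture(scope="session")
def built_kb(fixture_config):
    """Programmatically built KB; should equal the bundled one."""
    return build_knowledgebase(fixture_config)


def _molecule_pool(n: int, seed: int) -> list[str]:
    rng = np.random.default_rng(seed)
    cfg = FixtureConfig(seed=seed)
    families = ["nrps", "pks", "hybrid", "ripp", "glycosylated"]
    out = []
    i = 0
    while len(out) < n:
        fam = families[i % len(families)]
        spec = sample_cluster_spec(rng, fam, f"mol{i}", cfg)
        if spec.product_smiles:
            out.append(spec.product_smiles)
        i += 1
    return out


@pytest.fixture(scope="session")
def fixture_molecules():
    """50 structurally diverse truth-template products (SMILES)."""
    return _molecule_pool(50, seed=21)


@pytest.fixture(scope="session")
def small_molecules():
    """Hand-picked molecules with known descriptor behaviour."""
    return [
        "C",                                  # methane
        "CCO",                                # ethanol
        "NCC(=O)O",                           # glycine
        "NC(C)C(=O)O",                        # alanine
        "c1ccccc1",                           # benzene
        "C1CCCCC1",                           # cyclohexane
        "Oc1ccccc1",                          # phenol
        "CC(=O)N",                            # acetamide
        "OC1OC(CO)C(O)C(O)C1O",               # glucose
        "NC(Cc1ccc(O)cc1)C(=O)O",             # tyrosine
        "NC(Cc1c[nH]c2ccccc12)C(=O)O",        # tryptophan
        "NCC(=O)NC(C)C(=O)NC(CO)C(=O)O",      # Gly-Ala-Ser
    ]
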