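import numpy as np
import pytest

import tmenet
from tmenet.hierarchy import COMPONENT_CATEGORIES, ROLES, CellSpec, HierarchySpec


@pytest.fixture
def toy_spec() -> HierarchySpec:
    """Two cells, one per role, one component each, disjoint genes."""
    return HierarchySpec(
        name="toy",
        cells=(
            CellSpec("cellA", ROLES[0], {"surface": ("g1", "g2")}),
            CellSpec("cellB", ROLES[1], {"secreted": ("g3", "g4")}),
        ),
    )


@pytest.fixture
def shared_gene_spec() -> HierarchySpec:
    """g1 appears in both cells (single node, two memberships)."""
    return HierarchySpec(
        name="shared",
        cells=(
            CellSpec("cellA", ROLES[0], {"surface": ("g1", "g2")}),
            CellSpec("cellB", ROLES[1], {"surface": ("g1", "g3")}),
        ),
    )


@pytest.fixture(scope="session")
def default_spec() -> HierarchySpec:
    return tmenet.default_hierarchy()


def random_spec(rng: np.random.Generator, max_genes: int = 50) -> HierarchySpec:
    """A random valid hierarchy with <= max_genes genes, possibly shared."""
    pool = [f"G{i}" for i in range(max_genes)]
    n_stim = int(rng.integers(1, 4))
    n_supp = int(rng.integers(1, 4))
    cells = []
    for i in range(n_stim + n_supp):
        role = ROLES[0] if i < n_stim else ROLES[1]
        cats = list(rng.choice(COMPONENT_CATEGORIES,
                               size=int(rng.integers(1, 4)), replace=False))
        markers = {}
        for cat in cats:
            k = int(rng.integers(1, 5))
            markers[cat] = tuple(rng.choice(pool, size=k, replace=False))
        cells.append(CellSpec(f"cell{i}", role, markers))
    return HierarchySpec(cells=tuple(cells), name="random")


# ---------------------------------------------------------------------------
# Shared study conditions: one planted stimulatory driver at delta = 4*sigma,
# n = 400 samples, decoy genes present.  Session-scoped because several
# suites (recovery, interpretation, ablation) read the same ensemble.
# ---------------------------------------------------------------------------

DRIVER = "Th1"
N_RECOVERY_RUNS = 20


@pytest.fixture(scope="session")
def strong_cohort(default_spec):
    cfg = tmenet.SimConfig(spec=default_spec, n_samples=400,
                           effect_sizes={DRIVER: 4.0}, noise_sd=1.0,
                           n_decoy_genes=20, seed=11)
    return tmenet.generate(cfg)


@pytest.fixture(scope="session")
def null_cohort(default_spec):
    cfg = tmenet.SimConfig(spec=default_spec, n_samples=400,
                           noise_sd=1.0, n_decoy_genes=20, seed=11)
    return tmenet.generate(cfg)


@pytest.fixture(scope="session")
def strong_ensemble(strong_cohort, default_spec):
    return tmenet.repeat_runs(strong_cohort, default_spec,
                              tmenet.TrainConfig(seed=11),
                              n_runs=N_RECOVERY_RUNS)
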