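import numpy as np
import pytest

from toxmod.association import RankedList
from toxmod.pipeline import PipelineConfig
from toxmod.synthetic_data import PlantedModule, SimulationConfig


@pytest.fixture
def ranked10() -> RankedList:
    """Ten genes g1..g10 with scores 10..1 (already in rank order)."""
    return RankedList(
        np.array([f"g{i}" for i in range(1, 11)], dtype=object),
        np.arange(10, 0, -1, dtype=float),
    )


def make_ranked(n: int, rng: np.random.Generator) -> RankedList:
    scores = np.sort(rng.normal(size=n))[::-1]
    return RankedList(np.array([f"x{i}" for i in range(n)], dtype=object), scores)


@pytest.fixture
def tiny_config(tmp_path) -> PipelineConfig:
    """A minimal two-setting synthetic study that runs in a few seconds."""
    n_pathways, n_chem = 30, 8
    pw = [f"PW{i + 1:02d}" for i in range(n_pathways)]
    ch = [f"chem{i + 1}" for i in range(n_chem)]
    planted = [
        PlantedModule(
            module_id="planted1",
            pathway_ids=frozenset(pw[:6]),
            chemical_ids=frozenset(ch[:4]),
            effect_size=2.0,
            sign_per_pathway={pw[0]: -1},
        )
    ]
    sim = SimulationConfig(
        n_genes={"rat": 300, "human": 300},
        n_pathways=n_pathways,
        pathway_size_range=(15, 20),
        n_chemicals=n_chem,
        settings=("RLV", "PHH"),
        missing_low_fraction=0.0,
        planted_modules=planted,
        rng_seed=11,
    )
    return PipelineConfig(
        outdir=str(tmp_path / "run"),
        seed=11,
        synthetic=sim,
        gsea_n_perm=50,
        gsea_min_overlap=10,
        isa_thr_row_grid=(1.0, 1.5, 2.0),
        isa_thr_col_grid=(1.0, 1.5, 2.0),
        isa_n_seeds=30,
    )
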