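"""Synthetic toxicogenomic datasets with planted pathway-chemical modules.

The generator emulates the design of a large single-dose toxicogenomics
screen run in three experimental settings:

* ``PHH`` / ``PRH`` (primary human / rat hepatocytes): 3 dose levels x
  {2, 8, 24} hr x 2 replicates per chemical, plus vehicle controls at
  every time point;
* ``RLV`` (rat liver in vivo): 3 dose levels x {3, 6, 9, 24} hr x 3
  replicates per chemical, plus controls.

A configurable fraction of chemicals lacks the low-dose arm (a known
irregularity of the human-hepatocyte screen). The two species share one
pathway namespace but have disjoint gene universes, so cross-species
comparisons are only possible at the pathway level — exactly the premise
of the downstream analysis.

Expression follows the linear dose-time model the association stage
assumes: for gene i under chemical j,

    G_i = b0_i + b1_ij * D + b2_i * T + b3_ij * D * T + eps,
    eps ~ Normal(0, sigma^2) i.i.d.,

with dose coded ordinally (control/low/middle/high -> 0/1/2/3) and time
in hours. ``b1_ij`` is nonzero only for genes in pathways of a *planted
module* whose chemical set contains j; this plants coherent blocks in
the pathway x chemical enrichment matrix which the biclustering stage
should recover. Ground truth is exported so recovery can be scored.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .data_model import DOSE_VALUES, PathwayCollection, validate_design

__all__ = [
    "SettingDesign",
    "SETTING_DESIGNS",
    "SETTING_SPECIES",
    "PlantedModule",
    "SimulationConfig",
    "derive_rng",
    "generate_design",
    "generate_pathway_space",
    "simulate_expression",
    "generate_dataset",
    "write_truth_json",
    "read_truth_json",
]


def derive_rng(root_seed: int, *keys: str | int) -> np.random.Generator:
    """Deterministic per-stage random stream.

    Child streams are derived from the root seed plus a path of string or
    integer keys (stage name, setting, chemical, ...), so the stream a
    stage sees does not depend on the order in which other stages run.
    """
    ints = tuple(
        k if isinstance(k, int) else zlib.crc32(str(k).encode("utf-8")) for k in keys
    )
    ss = np.random.SeedSequence(entropy=int(root_seed), spawn_key=ints)
    return np.random.default_rng(ss)


@dataclass(frozen=True)
class SettingDesign:
    """Per-setting factorial layout: dose levels x times x replicates."""

    dose_levels: tuple[str, ...] = ("low", "middle", "high")
    times_hr: tuple[float, ...] = (2.0, 8.0, 24.0)
    n_replicates: int = 2


#: The three emulated experimental designs.
SETTING_DESIGNS: dict[str, SettingDesign] = {
    "PHH": SettingDesign(times_hr=(2.0, 8.0, 24.0), n_replicates=2),
    "PRH": SettingDesign(times_hr=(2.0, 8.0, 24.0), n_replicates=2),
    "RLV": SettingDesign(times_hr=(3.0, 6.0, 9.0, 24.0), n_replicates=3),
}

#: Which species' gene universe each setting measures.
SETTING_SPECIES: dict[str, str] = {"RLV": "rat", "PRH": "rat", "PHH": "human"}


@dataclass(frozen=True)
class PlantedModule:
    """Ground-truth module: a pathway set x chemical set with a dose effect.

    ``effect_size`` is the magnitude of the dose coefficient b1 injected
    into every member gene, in units of the noise SD when sigma = 1.
    ``sign_per_pathway`` lets a module mix up- and down-regulated pathways.
    """

    module_id: str
    pathway_ids: frozenset[str]
    chemical_ids: frozenset[str]
    effect_size: float
    sign_per_pathway: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.pathway_ids or not self.chemical_ids:
            raise ValueError(f"module {self.module_id}: empty pathway or chemical set")
        if self.effect_size < 0:
            raise ValueError(f"module {self.module_id}: effect_size must be >= 0")
        # canonical form: an explicit sign for every member pathway
        full = {p: self.sign_per_pathway.get(p, 1) for p in sorted(self.pathway_ids)}
        object.__setattr__(self, "sign_per_pathway", full)

    def sign(self, pathway_id: str) -> int:
        return self.sign_per_pathway.get(pathway_id, 1)


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic screen.

    Defaults mirror the emulated full-scale screen: 115 chemicals common
    to all three settings, gene universes of 14,462 (rat) and 20,590
    (human) genes, 419 shared pathways of 15-500 genes, and a low-dose
    arm missing for ~60% of the human-hepatocyte chemicals. Tests and
    the bundled demo scale these down explicitly.
    """

    n_genes: dict[str, int] = field(default_factory=lambda: {"rat": 14462, "human": 20590})
    n_pathways: int = 419
    pathway_size_range: tuple[int, int] = (15, 500)
    n_chemicals: int = 115
    settings: tuple[str, ...] = ("RLV", "PRH", "PHH")
    setting_designs: dict[str, SettingDesign] = field(
        default_factory=lambda: dict(SETTING_DESIGNS)
    )
    missing_low_fraction: float = 0.6
    missing_low_settings: tuple[str, ...] = ("PHH",)
    noise_sd: float = 1.0
    beta0_mean: float = 7.0
    beta0_sd: float = 1.0
    beta2_sd: float = 0.1
    beta3_sd: float = 0.0
    planted_modules: list[PlantedModule] = field(default_factory=list)
    #: Draw the gene sets of planted-module pathways mutually disjoint, so
    #: the planted truth is identifiable: genes shared between pathways of
    #: different planted modules would couple the modules' enrichment
    #: profiles and blur the ground truth that recovery is scored against.
    #: Background pathways still overlap freely, as real collections do.
    disjoint_planted_genes: bool = False
    rng_seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.pathway_size_range
        if not (1 <= lo <= hi):
            raise ValueError(f"invalid pathway_size_range {self.pathway_size_range}")
        if not 0.0 <= self.missing_low_fraction <= 1.0:
            raise ValueError("missing_low_fraction must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for s in self.settings:
            if s not in self.setting_designs:
                raise ValueError(f"no design layout for setting {s!r}")

    @property
    def chemical_ids(self) -> list[str]:
        width = len(str(max(self.n_chemicals, 1)))
        return [f"chem{i + 1:0{width}d}" for i in range(self.n_chemicals)]

    @property
    def pathway_id_list(self) -> list[str]:
        width = len(str(max(self.n_pathways, 1)))
        return [f"PW{i + 1:0{width}d}" for i in range(self.n_pathways)]

    def gene_ids(self, species: str) -> list[str]:
        n = self.n_genes[species]
        width = len(str(max(n, 1)))
        return [f"{species}_g{i + 1:0{width}d}" for i in range(n)]

    def missing_low_chemicals(self, setting: str) -> set[str]:
        """Chemicals whose low-dose arm is absent in the given setting."""
        if setting not in self.missing_low_settings or self.missing_low_fraction == 0:
            return set()
        chems = self.chemical_ids
        n_missing = int(round(self.missing_low_fraction * len(chems)))
        rng = derive_rng(self.rng_seed, "missing_low", setting)
        chosen = rng.choice(len(chems), size=n_missing, replace=False)
        return {chems[i] for i in sorted(chosen)}


def generate_design(config: SimulationConfig, setting: str) -> pd.DataFrame:
    """Full-factorial design table for one setting.

    Each chemical gets dose levels x times x replicates treated rows plus
    controls at every time x replicate; low-dose rows are dropped for the
    chemicals selected by ``missing_low_fraction``.
    """
    layout = config.setting_designs[setting]
    missing_low = config.missing_low_chemicals(setting)
    rows: list[dict] = []
    for chem in config.chemical_ids:
        levels = ("control",) + tuple(
            d for d in layout.dose_levels if not (d == "low" and chem in missing_low)
        )
        for dose in levels:
            for t in layout.times_hr:
                for rep in range(1, layout.n_replicates + 1):
                    rows.append(
                        {
                            "sample_id": f"{setting}_{chem}_{dose}_{t:g}h_r{rep}",
                            "chemical": chem,
                            "dose_level": dose,
                            "dose_value": DOSE_VALUES[dose],
                            "time_hr": float(t),
                            "replicate": rep,
                            "setting": setting,
                        }
                    )
    return validate_design(pd.DataFrame(rows))


def generate_pathway_space(
    config: SimulationConfig, species: Sequence[str] = ("rat", "human")
) -> tuple[PathwayCollection, ...]:
    """One pathway collection per species, sharing pathway ids.

    Set sizes are drawn uniformly within ``pathway_size_range`` (the same
    size for a pathway in every species); per-species memberships are
    sampled independently from disjoint species gene universes.
    """
    lo, hi = config.pathway_size_range
    for sp in species:
        if config.n_genes[sp] < hi:
            raise ValueError(
                f"species {sp!r} universe ({config.n_genes[sp]} genes) cannot fill "
                f"sets of up to {hi} genes"
            )
    size_rng = derive_rng(config.rng_seed, "pathway_sizes")
    sizes = size_rng.integers(lo, hi + 1, size=config.n_pathways)
    planted_pathways: set[str] = set()
    if config.disjoint_planted_genes:
        for module in config.planted_modules:
            planted_pathways |= module.pathway_ids
        need = sum(
            int(s)
            for pid, s in zip(config.pathway_id_list, sizes)
            if pid in planted_pathways
        )
        for sp in species:
            if need > config.n_genes[sp]:
                raise ValueError(
                    f"species {sp!r}: disjoint planted pathways need {need} genes, "
                    f"universe has {config.n_genes[sp]}"
                )
    colls = []
    for sp in species:
        rng = derive_rng(config.rng_seed, "pathway_space", sp)
        universe = np.array(config.gene_ids(sp))
        sets = {}
        reserved: set[str] = set()
        for pid, size in zip(config.pathway_id_list, sizes):
            if pid in planted_pathways:
                pool = np.array([g for g in universe if g not in reserved])
                members = rng.choice(pool, size=int(size), replace=False)
                reserved.update(members.tolist())
            else:
                members = rng.choice(universe, size=int(size), replace=False)
            sets[pid] = frozenset(members.tolist())
        colls.append(PathwayCollection(sets=sets))
    return tuple(colls)


def _beta1_matrix(
    gene_ids: list[str],
    chemical_ids: list[str],
    pathways: PathwayCollection,
    planted: Iterable[PlantedModule],
) -> np.ndarray:
    """Dose-effect coefficients b1 (genes x chemicals) implied by planted truth.

    A gene belonging to several planted pathways accumulates their signed
    effects additively.
    """
    gene_index = {g: i for i, g in enumerate(gene_ids)}
    chem_index = {c: j for j, c in enumerate(chemical_ids)}
    beta1 = np.zeros((len(gene_ids), len(chemical_ids)))
    for module in planted:
        cols = [chem_index[c] for c in module.chemical_ids if c in chem_index]
        if not cols:
            continue
        for pid in module.pathway_ids:
            if pid not in pathways:
                continue
            sign = module.sign(pid)
            rows = [gene_index[g] for g in pathways[pid] if g in gene_index]
            beta1[np.ix_(rows, cols)] += sign * module.effect_size
    return beta1


def simulate_expression(
    design: pd.DataFrame,
    pathways: PathwayCollection,
    planted: Iterable[PlantedModule],
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Simulate a genes x samples log-expression matrix for one setting.

    The design table fixes each sample's dose code D and time T; gene
    baselines b0 and time trends b2 are drawn once per gene; planted
    modules set b1 per (gene, chemical); Gaussian noise with SD
    ``config.noise_sd`` is added to every value.
    """
    setting = design["setting"].iloc[0]
    species = SETTING_SPECIES.get(setting, "rat")
    gene_ids = config.gene_ids(species)
    if rng is None:
        rng = derive_rng(config.rng_seed, "expression", setting)
    n_genes, n_samples = len(gene_ids), len(design)
    beta0 = config.beta0_mean + config.beta0_sd * rng.standard_normal(n_genes)
    beta2 = config.beta2_sd * rng.standard_normal(n_genes)
    chem_order = list(dict.fromkeys(design["chemical"]))
    beta1 = _beta1_matrix(gene_ids, chem_order, pathways, planted)
    beta3 = (
        config.beta3_sd * rng.standard_normal((n_genes, len(chem_order)))
        if config.beta3_sd > 0
        else np.zeros((n_genes, len(chem_order)))
    )
    chem_col = np.array([chem_order.index(c) for c in design["chemical"]])
    dose = design["dose_value"].to_numpy(dtype=float)
    time = design["time_hr"].to_numpy(dtype=float)
    values = (
        beta0[:, None]
        + beta1[:, chem_col] * dose[None, :]
        + beta2[:, None] * time[None, :]
        + beta3[:, chem_col] * (dose * time)[None, :]
    )
    if config.noise_sd > 0:
        values = values + config.noise_sd * rng.standard_normal((n_genes, n_samples))
    return pd.DataFrame(values, index=gene_ids, columns=design["sample_id"].to_numpy())


def generate_dataset(
    config: SimulationConfig,
) -> dict:
    """Generate the full synthetic study.

    Returns a dict with per-setting ``design`` and ``expression`` tables,
    per-species pathway collections, and the planted truth.
    """
    species = sorted({SETTING_SPECIES[s] for s in config.settings})
    colls = generate_pathway_space(config, species=species)
    collections = dict(zip(species, colls))
    out = {"pathways": collections, "truth": list(config.planted_modules), "settings": {}}
    for setting in config.settings:
        design = generate_design(config, setting)
        expr = simulate_expression(
            design,
            collections[SETTING_SPECIES[setting]],
            config.planted_modules,
            config,
        )
        out["settings"][setting] = {"design": design, "expression": expr}
    return out


def write_truth_json(planted: Iterable[PlantedModule], path: str | Path) -> None:
    payload = [
        {
            "module_id": m.module_id,
            "pathway_ids": sorted(m.pathway_ids),
            "chemical_ids": sorted(m.chemical_ids),
            "effect_size": m.effect_size,
            "sign_per_pathway": {p: m.sign(p) for p in sorted(m.pathway_ids)},
        }
        for m in planted
    ]
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def read_truth_json(path: str | Path) -> list[PlantedModule]:
    payload = json.loads(Path(path).read_text())
    return [
        PlantedModule(
            module_id=m["module_id"],
            pathway_ids=frozenset(m["pathway_ids"]),
            chemical_ids=frozenset(m["chemical_ids"]),
            effect_size=float(m["effect_size"]),
            sign_per_pathway={p: int(s) for p, s in m["sign_per_pathway"].items()},
        )
        for m in payload
    ]
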