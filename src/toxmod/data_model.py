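"""Core containers and I/O for the toxicogenomic module pipeline.

Three kinds of objects flow through the analysis:

* expression matrices — genes (rows) x samples (columns) of normalized
  log-intensities, tied to a sample-design table describing chemical,
  dose level, exposure time, replicate and experimental setting;
* pathway collections — named gene sets in the Broad GMT dialect, one
  collection per species, sharing pathway identifiers so enrichment
  profiles are comparable across species;
* probe-to-gene maps used to collapse probe-level matrices to one row
  per gene (most-variant probe wins).

Expression values are assumed to be already normalized and on a log
scale; nothing here re-normalizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "DOSE_VALUES",
    "SETTINGS",
    "PathwayCollection",
    "read_gmt",
    "write_gmt",
    "filter_gene_sets",
    "common_pathways",
    "collapse_probes",
    "validate_design",
    "validate_expression",
    "read_design_tsv",
    "write_design_tsv",
    "read_expression_tsv",
    "write_expression_tsv",
]

#: Ordinal numeric coding of dose levels. Dose magnitudes in the emulated
#: design vary per chemical (the high dose is the maximally tolerated one),
#: so an ordinal coding is the minimal choice preserving dose monotonicity;
#: it must match between the generator and the association model.
DOSE_VALUES: dict[str, float] = {"control": 0.0, "low": 1.0, "middle": 2.0, "high": 3.0}

#: Experimental settings: rat liver in vivo, primary rat hepatocytes,
#: primary human hepatocytes.
SETTINGS = ("RLV", "PRH", "PHH")

DESIGN_COLUMNS = [
    "sample_id",
    "chemical",
    "dose_level",
    "dose_value",
    "time_hr",
    "replicate",
    "setting",
]


class GmtParseError(ValueError):
    """Raised when a GMT file line cannot be parsed."""


@dataclass
class PathwayCollection:
    """An ordered collection of named gene sets.

    Parameters
    ----------
    sets
        Mapping from pathway id to a frozen set of gene ids.  Insertion
        order is meaningful and preserved through I/O.
    descriptions
        Optional mapping from pathway id to the free-text description
        column of the GMT format (preserved but unused by the analysis).
    """

    sets: dict[str, frozenset[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for pid in self.sets:
            self.descriptions.setdefault(pid, "")

    def __len__(self) -> int:
        return len(self.sets)

    def __contains__(self, pathway_id: str) -> bool:
        return pathway_id in self.sets

    def __getitem__(self, pathway_id: str) -> frozenset[str]:
        return self.sets[pathway_id]

    @property
    def pathway_ids(self) -> list[str]:
        return list(self.sets)

    def sizes(self) -> pd.Series:
        return pd.Series({p: len(s) for p, s in self.sets.items()}, dtype=int)

    def subset(self, pathway_ids: Iterable[str]) -> "PathwayCollection":
        keep = [p for p in self.sets if p in set(pathway_ids)]
        return PathwayCollection(
            sets={p: self.sets[p] for p in keep},
            descriptions={p: self.descriptions.get(p, "") for p in keep},
        )


def read_gmt(path: str | Path) -> PathwayCollection:
    """Read a Broad-style GMT file (tab-separated: name, description, genes...).

    Duplicate gene tokens within a line are collapsed to a single member.

    Raises
    ------
    GmtParseError
        If a non-empty line has fewer than three tab-separated fields, or
        if a pathway name occurs twice.
    """
    path = Path(path)
    sets: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    with path.open("r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GmtParseError(
                    f"{path}:{lineno}: expected at least 3 tab-separated fields "
                    f"(name, description, >=1 gene), got {len(fields)}"
                )
            name, description = fields[0], fields[1]
            genes = [g for g in fields[2:] if g != ""]
            if not genes:
                raise GmtParseError(f"{path}:{lineno}: gene set {name!r} has no gene tokens")
            if name in sets:
                raise GmtParseError(f"{path}:{lineno}: duplicate pathway name {name!r}")
            sets[name] = frozenset(genes)
            descriptions[name] = description
    return PathwayCollection(sets=sets, descriptions=descriptions)


def write_gmt(coll: PathwayCollection, path: str | Path) -> None:
    """Write a collection as GMT. Genes are written sorted for stable output."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for pid, genes in coll.sets.items():
            desc = coll.descriptions.get(pid, "")
            fh.write("\t".join([pid, desc, *sorted(genes)]) + "\n")


def filter_gene_sets(
    coll: PathwayCollection, min_size: int = 15, max_size: int = 500
) -> PathwayCollection:
    """Keep gene sets with min_size <= |set| <= max_size (bounds inclusive)."""
    if min_size < 1:
        raise ValueError(f"min_size must be >= 1, got {min_size}")
    if max_size < min_size:
        raise ValueError(f"max_size ({max_size}) < min_size ({min_size})")
    keep = [p for p, s in coll.sets.items() if min_size <= len(s) <= max_size]
    return coll.subset(keep)


def common_pathways(
    a: PathwayCollection, b: PathwayCollection
) -> tuple[PathwayCollection, PathwayCollection]:
    """Restrict both collections to their shared pathway ids.

    Gene memberships stay species-specific; only the pathway namespace is
    intersected. Each returned collection keeps its own original order.
    """
    shared = set(a.sets) & set(b.sets)
    return a.subset(shared), b.subset(shared)


def collapse_probes(matrix: pd.DataFrame, probe_map: Mapping[str, str]) -> pd.DataFrame:
    """Collapse a probe-level matrix to one row per gene.

    For genes measured by several probes the probe with the largest
    unbiased sample variance across all samples is kept verbatim (its
    values are not averaged); ties go to the lexicographically smallest
    probe id.  Probes absent from ``probe_map`` are dropped.

    Parameters
    ----------
    matrix
        Probe-level expression, probes as the index, samples as columns.
    probe_map
        Many-to-one mapping probe_id -> gene_id; unmapped probes must
        simply be absent from the map.

    Returns
    -------
    Gene-level matrix indexed by gene id, sorted by gene id.
    """
    mapped = [p for p in matrix.index if p in probe_map]
    if not mapped:
        raise ValueError("no probe of the matrix is present in the probe-gene map")
    sub = matrix.loc[mapped]
    variances = sub.var(axis=1, ddof=1)
    chooser = pd.DataFrame(
        {
            "gene": [probe_map[p] for p in sub.index],
            "var": variances.to_numpy(),
            "probe": sub.index,
        }
    )
    # max variance wins; ties -> lexicographically smallest probe id
    chooser = chooser.sort_values(["gene", "var", "probe"], ascending=[True, False, True])
    winners = chooser.drop_duplicates("gene", keep="first")
    out = sub.loc[winners["probe"]]
    out.index = winners["gene"].to_numpy()
    out = out.sort_index()
    out.index.name = "gene_id"
    return out


def validate_design(design: pd.DataFrame) -> pd.DataFrame:
    """Validate a sample-design table and return it unchanged.

    Checks: required columns; unique sample ids; dose_value == 0 exactly
    for control rows; every treated (chemical, time) stratum has at least
    one control at the same time.
    """
    missing = [c for c in DESIGN_COLUMNS if c not in design.columns]
    if missing:
        raise ValueError(f"design table missing columns: {missing}")
    if design["sample_id"].duplicated().any():
        dup = design.loc[design["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValueError(f"duplicated sample_id in design: {dup!r}")
    is_control = design["dose_level"] == "control"
    zero_dose = design["dose_value"] == 0
    if (is_control != zero_dose).any():
        raise ValueError("dose_value must be 0 exactly for control rows")
    treated = design.loc[~is_control, ["chemical", "time_hr"]].drop_duplicates()
    controls = design.loc[is_control, ["chemical", "time_hr"]].drop_duplicates()
    have = set(map(tuple, controls.to_numpy()))
    for chem, t in map(tuple, treated.to_numpy()):
        if (chem, t) not in have:
            raise ValueError(f"no control sample for chemical {chem!r} at time {t} hr")
    return design


def validate_expression(expr: pd.DataFrame, design: pd.DataFrame | None = None) -> pd.DataFrame:
    """Validate a gene x sample expression matrix (optionally against a design)."""
    if expr.index.duplicated().any():
        raise ValueError("duplicated gene ids in expression matrix")
    values = expr.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        raise ValueError("expression matrix contains non-finite values")
    if design is not None and set(expr.columns) != set(design["sample_id"]):
        raise ValueError("expression columns do not match the design's sample ids")
    return expr


def write_design_tsv(design: pd.DataFrame, path: str | Path) -> None:
    design[DESIGN_COLUMNS].to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_design_tsv(path: str | Path) -> pd.DataFrame:
    design = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "chemical": str})
    return validate_design(design)


def write_expression_tsv(expr: pd.DataFrame, path: str | Path) -> None:
    expr.to_csv(path, sep="\t", index_label="gene_id", float_format="%.10g")


def read_expression_tsv(path: str | Path) -> pd.DataFrame:
    expr = pd.read_csv(path, sep="\t", index_col="gene_id")
    return validate_expression(expr)
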