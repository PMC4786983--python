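"""Cross-dataset module conservation and over-representation tests.

Two modules from different datasets (e.g. rat liver in vivo vs human
hepatocytes) are *conserved* when their pathway supports overlap more
than chance allows under a one-sided (upper-tail) hypergeometric test
and each is the other's most significant partner — the reciprocal
best-hit rule. Three-way conservation anchors on the in-vivo dataset
(RLV): a triple is reported when one RLV module is a reciprocal best
hit of a module in each in-vitro dataset.

The same hypergeometric machinery serves two follow-up questions: is a
module's chemical support enriched for a labeled chemical class (e.g.
known hepatocarcinogens), and does the union of a module's leading-edge
genes overlap an external gene list more than expected?

Conservation is judged on pathway overlap only; chemical overlap is
reported but not required, since the chemicals driving a module need
not coincide across systems.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy import stats

from .gsea import EnrichmentResult
from .isa import Bicluster, ModuleSet

__all__ = [
    "ModuleMatch",
    "ConservedTriple",
    "hypergeom_p",
    "reciprocal_best_hits",
    "conserved_across_three",
    "chemical_class_enrichment",
    "leading_edge_union",
    "gene_list_overlap",
    "matches_to_tsv",
    "triples_to_json",
]


def hypergeom_p(k: int, K_a: int, K_b: int, N: int) -> float:
    """Upper-tail hypergeometric p-value P[X >= k].

    X counts the overlap of a uniformly random size-``K_b`` draw from a
    universe of ``N`` items of which ``K_a`` are marked.
    """
    if not (0 <= K_a <= N and 0 <= K_b <= N):
        raise ValueError(f"need 0 <= K_a, K_b <= N; got K_a={K_a}, K_b={K_b}, N={N}")
    if not (0 <= k <= min(K_a, K_b)):
        raise ValueError(f"need 0 <= k <= min(K_a, K_b); got k={k}")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K_a, K_b))


@dataclass(frozen=True)
class ModuleMatch:
    """A cross-dataset module pair scored by pathway overlap."""

    module_a: str
    module_b: str
    dataset_a: str
    dataset_b: str
    k: int
    K_a: int
    K_b: int
    N: int
    p: float
    reciprocal: bool


def _best_hit(
    module: Bicluster, others: ModuleSet, N: int
) -> tuple[Bicluster, int, float] | None:
    """Most significant partner: minimal p, ties -> larger k, then smaller id."""
    best = None
    for cand in others:
        k = len(module.pathway_ids & cand.pathway_ids)
        p = hypergeom_p(k, len(module.pathway_ids), len(cand.pathway_ids), N)
        key = (p, -k, cand.module_id)
        if best is None or key < best[0]:
            best = (key, cand, k, p)
    if best is None:
        return None
    return best[1], best[2], best[3]


def reciprocal_best_hits(
    a: ModuleSet,
    b: ModuleSet,
    N: int,
    alpha: float = 0.001,
    dataset_a: str = "a",
    dataset_b: str = "b",
) -> list[ModuleMatch]:
    """Reciprocal best-hit module matches between two datasets.

    For every module of ``a`` the best hit in ``b`` is the partner with
    minimal hypergeometric p over pathway overlap (universe size ``N``);
    a match is reported iff the two modules are mutual best hits and
    p < ``alpha``. Empty module sets yield an empty list.
    """
    matches = []
    for mod_a in a:
        hit = _best_hit(mod_a, b, N)
        if hit is None:
            continue
        mod_b, k, p = hit
        back = _best_hit(mod_b, a, N)
        if back is None or back[0].module_id != mod_a.module_id:
            continue
        if p < alpha:
            matches.append(
                ModuleMatch(
                    module_a=mod_a.module_id,
                    module_b=mod_b.module_id,
                    dataset_a=dataset_a,
                    dataset_b=dataset_b,
                    k=k,
                    K_a=len(mod_a.pathway_ids),
                    K_b=len(mod_b.pathway_ids),
                    N=N,
                    p=p,
                    reciprocal=True,
                )
            )
    return matches


@dataclass(frozen=True)
class ConservedTriple:
    """One module conserved across RLV, PRH and PHH (RLV-anchored)."""

    rlv_module: str
    prh_module: str
    phh_module: str
    p_rlv_prh: float
    p_rlv_phh: float
    shared_pathways: frozenset[str]


def conserved_across_three(
    rlv: ModuleSet,
    prh: ModuleSet,
    phh: ModuleSet,
    N: int,
    alpha: float = 0.001,
) -> list[ConservedTriple]:
    """Modules conserved across all three settings.

    Anchored on the in-vivo reference: an RLV module forms a triple when
    it has a reciprocal best hit in PRH *and* in PHH (each at the given
    alpha). The shared pathway core is the three-way intersection.
    """
    m_prh = {m.module_a: m for m in reciprocal_best_hits(rlv, prh, N, alpha, "RLV", "PRH")}
    m_phh = {m.module_a: m for m in reciprocal_best_hits(rlv, phh, N, alpha, "RLV", "PHH")}
    triples = []
    for rlv_mod in rlv:
        mid = rlv_mod.module_id
        if mid in m_prh and mid in m_phh:
            prh_mod = prh[m_prh[mid].module_b]
            phh_mod = phh[m_phh[mid].module_b]
            triples.append(
                ConservedTriple(
                    rlv_module=mid,
                    prh_module=prh_mod.module_id,
                    phh_module=phh_mod.module_id,
                    p_rlv_prh=m_prh[mid].p,
                    p_rlv_phh=m_phh[mid].p,
                    shared_pathways=frozenset(
                        rlv_mod.pathway_ids & prh_mod.pathway_ids & phh_mod.pathway_ids
                    ),
                )
            )
    return triples


def chemical_class_enrichment(
    module: Bicluster,
    class_chemicals: Iterable[str],
    universe_chemicals: Iterable[str],
    alpha: float = 0.05,
) -> tuple[int, float, bool]:
    """Is a module's chemical support enriched for a chemical class?

    Upper-tail hypergeometric over the shared chemical universe. Returns
    (overlap count, p, significant-at-alpha).
    """
    universe = set(universe_chemicals)
    if not universe:
        raise ValueError("empty chemical universe")
    cls = set(class_chemicals)
    mod = set(module.chemical_ids)
    if not cls <= universe or not mod <= universe:
        raise ValueError("class and module chemicals must lie within the universe")
    k = len(mod & cls)
    p = hypergeom_p(k, len(mod), len(cls), len(universe))
    return k, p, p < alpha


def leading_edge_union(
    module: Bicluster,
    results: Mapping[tuple[str, str], EnrichmentResult],
) -> frozenset[str]:
    """Union of leading-edge genes over a module's pathway x chemical cells.

    ``results`` maps (pathway_id, chemical_id) to enrichment results;
    every cell of the module must be present.
    """
    if not module.row_ids or not module.col_ids:
        raise ValueError("empty module")
    missing = [
        (p, c)
        for p in module.row_ids
        for c in module.col_ids
        if (p, c) not in results
    ]
    if missing:
        raise ValueError(f"missing enrichment results for cells: {missing[:5]}")
    genes: set[str] = set()
    for p in module.row_ids:
        for c in module.col_ids:
            genes |= set(results[(p, c)].leading_edge)
    return frozenset(genes)


def gene_list_overlap(
    list_a: Iterable[str], list_b: Iterable[str], universe: Iterable[str]
) -> tuple[int, float]:
    """Upper-tail hypergeometric overlap of two gene lists in a universe."""
    uni = set(universe)
    a, b = set(list_a), set(list_b)
    if not a <= uni or not b <= uni:
        raise ValueError("both gene lists must be subsets of the universe")
    k = len(a & b)
    return k, hypergeom_p(k, len(a), len(b), len(uni))


def matches_to_tsv(matches: Sequence[ModuleMatch], path: str | Path) -> None:
    pd.DataFrame([m.__dict__ for m in matches]).to_csv(
        path, sep="\t", index=False, float_format="%.6g"
    )


def triples_to_json(triples: Sequence[ConservedTriple], path: str | Path) -> None:
    payload = [
        {
            "rlv_module": t.rlv_module,
            "prh_module": t.prh_module,
            "phh_module": t.phh_module,
            "p_rlv_prh": t.p_rlv_prh,
            "p_rlv_phh": t.p_rlv_phh,
            "shared_pathways": sorted(t.shared_pathways),
        }
        for t in triples
    ]
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
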