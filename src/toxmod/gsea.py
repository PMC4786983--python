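"""Preranked gene set enrichment, implemented from first principles.

Given a ranked gene list (here: genes ordered by the signed significance
of their dose association with one chemical) and a gene set, the
enrichment score (ES) is the maximal signed deviation of a weighted
running sum walking down the list: each gene-set hit at position i adds
|s_i|^w / sum_hits |s|^w, each miss subtracts 1/(N - N_hits). With
weight w = 1 this is the classic "weighted" statistic. The running sum
always ends at 0, so ES lies in [-1, 1].

Significance uses a gene-permutation null suited to preranked input:
random gene sets of identical size drawn from the ranked universe. The
normalized enrichment score (NES) divides the ES by the mean |ES| of the
same-sign null values, making scores comparable across set sizes; the
nominal p is the add-one-smoothed same-sign tail frequency.

`PrerankedGSEA(...).fit()` scores a whole pathway collection against one
ranked list; `build_enrichment_matrix` assembles per-chemical results
into the pathway x chemical NES matrix that downstream biclustering
consumes (cells that could not be scored are masked and imputed as 0,
i.e. "no enrichment").
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .association import RankedList
from .data_model import PathwayCollection

__all__ = [
    "EnrichmentResult",
    "EnrichmentMatrix",
    "GSEAResults",
    "PrerankedGSEA",
    "enrichment_score",
    "null_distribution",
    "normalize_and_p",
    "run_gsea",
    "build_enrichment_matrix",
]


@dataclass(frozen=True)
class EnrichmentResult:
    """Enrichment of one pathway in one chemical's ranked list."""

    pathway_id: str
    chemical_id: str
    es: float
    nes: float
    p_nominal: float
    n_overlap: int
    leading_edge: frozenset[str]
    masked: bool = False


#: The positive peak and negative trough of a running sum can tie exactly
#: (up to float noise); deviations closer than this are treated as tied and
#: resolved by the earlier list position.
_TIE_TOL = 1e-9


def _hit_mask(ranked: RankedList, gene_set: Iterable[str]) -> np.ndarray:
    members = set(gene_set)
    return np.fromiter((g in members for g in ranked.gene_ids), bool, len(ranked))


def enrichment_score(
    ranked: RankedList, gene_set: Iterable[str], weight: float = 1.0
) -> tuple[float, np.ndarray, frozenset[str]]:
    """Weighted running-sum enrichment score of a gene set in a ranked list.

    Returns ``(es, running_sum, leading_edge)`` where ``running_sum`` has
    one value per list position (after processing that position) and the
    leading edge contains the hit genes at ranks up to the peak (ES > 0)
    or from the trough onward (ES < 0).

    On a tie in |deviation| the earliest position wins.
    """
    hits = _hit_mask(ranked, gene_set)
    n = len(ranked)
    n_hits = int(hits.sum())
    if n_hits == 0:
        raise ValueError("gene set has no overlap with the ranked universe")
    if n_hits >= n:
        raise ValueError("gene set covers the whole ranked universe")
    weights = np.abs(ranked.scores) ** weight
    hit_w = np.where(hits, weights, 0.0)
    total = hit_w.sum()
    if total > 0:
        incr = hit_w / total
    else:
        # all hit scores are exactly 0: fall back to equal hit increments
        incr = hits / n_hits
    incr = incr - (~hits) / (n - n_hits)
    running = np.cumsum(incr)
    peak = int(np.argmax(np.where(running > 0, running, -np.inf)))
    trough = int(np.argmax(np.where(running < 0, -running, -np.inf)))
    pos_dev = running[peak] if running[peak] > 0 else 0.0
    neg_dev = running[trough] if running[trough] < 0 else 0.0
    if pos_dev == 0.0 and neg_dev == 0.0:
        es, leading = 0.0, frozenset()
    elif pos_dev + neg_dev > _TIE_TOL or (
        abs(pos_dev + neg_dev) <= _TIE_TOL and peak <= trough
    ):
        es = float(pos_dev)
        leading = frozenset(ranked.gene_ids[: peak + 1][hits[: peak + 1]].tolist())
    else:
        es = float(neg_dev)
        leading = frozenset(ranked.gene_ids[trough:][hits[trough:]].tolist())
    return es, running, leading


def _es_from_positions(
    positions: np.ndarray, weights: np.ndarray, n: int
) -> np.ndarray:
    """Vectorized ES for many same-size gene sets given as position arrays.

    ``positions`` is (n_sets, k) of 0-based list positions (unsorted ok);
    ``weights`` is |score|^w per list position. The running sum only needs
    to be evaluated right after each hit (positive-peak candidates) and
    right before each hit (negative-trough candidates).
    """
    n_sets, k = positions.shape
    pos = np.sort(positions, axis=1)
    w = weights[pos]
    totals = w.sum(axis=1, keepdims=True)
    cum_hit = np.where(
        totals > 0,
        np.cumsum(w, axis=1) / np.where(totals > 0, totals, 1.0),
        (np.arange(1, k + 1) / k)[None, :],
    )
    miss_den = n - k
    miss_before = (pos - np.arange(k)[None, :]) / miss_den  # misses before hit m
    dev_after = cum_hit - miss_before
    prev_hit = np.concatenate([np.zeros((n_sets, 1)), cum_hit[:, :-1]], axis=1)
    dev_before = prev_hit - miss_before
    pos_best = dev_after.max(axis=1)
    neg_best = dev_before.min(axis=1)
    # position (0-based step index) at which each extreme is attained
    arg_pos = dev_after.argmax(axis=1)
    arg_neg = dev_before.argmin(axis=1)
    step_pos = pos[np.arange(n_sets), arg_pos]
    step_neg = pos[np.arange(n_sets), arg_neg] - 1
    pos_best = np.maximum(pos_best, 0.0)
    neg_best = np.minimum(neg_best, 0.0)
    diff = pos_best + neg_best
    take_pos = (diff > _TIE_TOL) | ((np.abs(diff) <= _TIE_TOL) & (step_pos <= step_neg))
    return np.where(take_pos, pos_best, neg_best)


def null_distribution(
    ranked: RankedList,
    set_size: int,
    n_perm: int,
    rng: np.random.Generator | int,
    weight: float = 1.0,
) -> np.ndarray:
    """ES null sample from uniformly drawn size-matched random gene sets."""
    n = len(ranked)
    if not 1 <= set_size < n:
        raise ValueError(f"set_size must lie in [1, {n - 1}], got {set_size}")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    weights = np.abs(ranked.scores) ** weight
    keys = rng.random((n_perm, n))
    positions = np.argpartition(keys, set_size - 1, axis=1)[:, :set_size]
    return _es_from_positions(positions, weights, n)


def normalize_and_p(es: float, null_sample: np.ndarray) -> tuple[float, float]:
    """NES and nominal p from a same-sign permutation null.

    nes = es / mean(|same-sign null|); p = add-one-smoothed fraction of
    same-sign null values at least as extreme. es = 0 gives (0, 1). When
    no usable same-sign null value exists the result is flagged as NaN
    (callers mask it; it is not an error).
    """
    null_sample = np.asarray(null_sample, dtype=float)
    if null_sample.size == 0:
        raise ValueError("empty null sample")
    if es == 0:
        return 0.0, 1.0
    same = null_sample[null_sample > 0] if es > 0 else null_sample[null_sample < 0]
    if same.size == 0 or np.mean(np.abs(same)) == 0:
        return float("nan"), float("nan")
    nes = es / np.mean(np.abs(same))
    p = (1.0 + np.sum(np.abs(same) >= abs(es))) / (1.0 + same.size)
    return float(nes), float(p)


class PrerankedGSEA:
    """Preranked GSEA of one ranked list against a pathway collection.

    Parameters
    ----------
    ranked
        The chemical-specific ranked gene list.
    collection
        Pathway collection, already size-filtered to the shared namespace.
    weight
        Exponent on |score| in the running sum (1 = weighted statistic).
    n_perm
        Permutations (random size-matched sets) per distinct overlap size.
    min_overlap
        Pathways overlapping the universe in fewer genes are masked, not
        scored; aligned with the collection size filter's lower bound.
    seed
        Seed (or Generator) for the permutation null.
    """

    def __init__(
        self,
        ranked: RankedList,
        collection: PathwayCollection,
        weight: float = 1.0,
        n_perm: int = 1000,
        min_overlap: int = 15,
        seed: int | np.random.Generator = 0,
    ) -> None:
        if len(collection) == 0:
            raise ValueError("empty pathway collection")
        self.ranked = ranked
        self.collection = collection
        self.weight = weight
        self.n_perm = n_perm
        self.min_overlap = min_overlap
        self._rng = (
            seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        )

    def fit(self) -> "GSEAResults":
        universe = set(self.ranked.gene_ids.tolist())
        overlaps = {
            pid: frozenset(genes & universe)
            for pid, genes in ((p, set(s)) for p, s in self.collection.sets.items())
        }
        sizes_needed = sorted(
            {len(o) for o in overlaps.values() if len(o) >= self.min_overlap}
        )
        nulls = {
            k: null_distribution(self.ranked, k, self.n_perm, self._rng, self.weight)
            for k in sizes_needed
            if k < len(self.ranked)
        }
        results = []
        for pid in self.collection.pathway_ids:
            ov = overlaps[pid]
            if len(ov) < self.min_overlap or len(ov) >= len(self.ranked):
                results.append(
                    EnrichmentResult(
                        pathway_id=pid,
                        chemical_id=self.ranked.chemical_id,
                        es=float("nan"),
                        nes=float("nan"),
                        p_nominal=float("nan"),
                        n_overlap=len(ov),
                        leading_edge=frozenset(),
                        masked=True,
                    )
                )
                continue
            es, _, leading = enrichment_score(self.ranked, ov, self.weight)
            nes, p = normalize_and_p(es, nulls[len(ov)])
            results.append(
                EnrichmentResult(
                    pathway_id=pid,
                    chemical_id=self.ranked.chemical_id,
                    es=es,
                    nes=nes,
                    p_nominal=p,
                    n_overlap=len(ov),
                    leading_edge=leading,
                    masked=bool(np.isnan(nes)),
                )
            )
        return GSEAResults(self, results)


class GSEAResults:
    """Per-pathway enrichment results for one ranked list."""

    def __init__(self, model: PrerankedGSEA, results: list[EnrichmentResult]) -> None:
        self.model = model
        self.results = results
        self.chemical_id = model.ranked.chemical_id

    def __iter__(self):
        return iter(self.results)

    def __getitem__(self, pathway_id: str) -> EnrichmentResult:
        for r in self.results:
            if r.pathway_id == pathway_id:
                return r
        raise KeyError(pathway_id)

    @property
    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "pathway_id": [r.pathway_id for r in self.results],
                "chemical_id": [r.chemical_id for r in self.results],
                "es": [r.es for r in self.results],
                "nes": [r.nes for r in self.results],
                "p_nominal": [r.p_nominal for r in self.results],
                "n_overlap": [r.n_overlap for r in self.results],
                "masked": [r.masked for r in self.results],
                "leading_edge": [";".join(sorted(r.leading_edge)) for r in self.results],
            }
        )

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.10g")

    def summary(self, top: int = 10) -> str:
        t = self.table.sort_values("nes", ascending=False, key=lambda s: s.abs())
        cols = ["pathway_id", "es", "nes", "p_nominal", "n_overlap"]
        return (
            f"Preranked GSEA | chemical: {self.chemical_id} | "
            f"{len(self.results)} pathways, n_perm={self.model.n_perm}\n\n"
            + t[cols].head(top).to_string(index=False, float_format=lambda v: f"{v:.4g}")
        )


def run_gsea(
    ranked: RankedList,
    collection: PathwayCollection,
    n_perm: int = 1000,
    rng_seed: int | np.random.Generator = 0,
    weight: float = 1.0,
    min_overlap: int = 15,
) -> list[EnrichmentResult]:
    """Score every pathway of a collection against one ranked list."""
    model = PrerankedGSEA(
        ranked, collection, weight=weight, n_perm=n_perm, min_overlap=min_overlap, seed=rng_seed
    )
    return model.fit().results


@dataclass
class EnrichmentMatrix:
    """Pathways x chemicals NES matrix plus its mask of unscored cells.

    Masked cells (insufficient overlap or degenerate null) are imputed as
    0 — "no enrichment" — so the biclustering input is complete; the mask
    records which cells were imputed.
    """

    nes: pd.DataFrame
    mask: pd.DataFrame

    @property
    def pathway_ids(self) -> list[str]:
        return list(self.nes.index)

    @property
    def chemical_ids(self) -> list[str]:
        return list(self.nes.columns)

    def to_tsv(self, path: str | Path, mask_path: str | Path | None = None) -> None:
        self.nes.to_csv(path, sep="\t", index_label="pathway_id", float_format="%.10g")
        if mask_path is not None:
            self.mask.astype(int).to_csv(mask_path, sep="\t", index_label="pathway_id")

    @classmethod
    def from_tsv(cls, path: str | Path, mask_path: str | Path | None = None):
        nes = pd.read_csv(path, sep="\t", index_col="pathway_id")
        if mask_path is not None:
            mask = pd.read_csv(mask_path, sep="\t", index_col="pathway_id").astype(bool)
        else:
            mask = pd.DataFrame(False, index=nes.index, columns=nes.columns)
        return cls(nes=nes, mask=mask)


def build_enrichment_matrix(
    results_by_chemical: Mapping[str, Sequence[EnrichmentResult]] | Sequence[Sequence[EnrichmentResult]],
) -> EnrichmentMatrix:
    """Assemble per-chemical enrichment results into one NES matrix.

    Chemical order follows the input order; all chemicals must have been
    scored against the same pathway universe.
    """
    if isinstance(results_by_chemical, Mapping):
        items = list(results_by_chemical.items())
    else:
        items = [(rs[0].chemical_id, rs) for rs in results_by_chemical]
    if not items:
        raise ValueError("no enrichment results supplied")
    pathway_order = [r.pathway_id for r in items[0][1]]
    ref = set(pathway_order)
    nes = {}
    mask = {}
    for chem, rs in items:
        if {r.pathway_id for r in rs} != ref:
            raise ValueError(f"chemical {chem!r} scored against a different pathway universe")
        by_pid = {r.pathway_id: r for r in rs}
        nes[chem] = [
            0.0 if by_pid[p].masked or np.isnan(by_pid[p].nes) else by_pid[p].nes
            for p in pathway_order
        ]
        mask[chem] = [by_pid[p].masked for p in pathway_order]
    nes_df = pd.DataFrame(nes, index=pathway_order)
    mask_df = pd.DataFrame(mask, index=pathway_order)
    return EnrichmentMatrix(nes=nes_df, mask=mask_df)
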