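"""Per-gene dose-time association models and chemical-specific gene ranking.

For one chemical, every gene's expression is regressed on the design

    G = b0 + b1*D + b2*T + b3*D*T + eps

where D is the ordinal dose code (control/low/middle/high -> 0/1/2/3,
vehicle controls included as D = 0) and T the exposure time in hours.
The dose coefficient b1 carries the gene-chemical association; its
two-sided Student t p-value (df = n - 4) and sign define the ranking
score

    score = sign(b1) * (-log10(max(p, 1e-300)))

used to build the preranked gene list consumed by enrichment analysis.

All genes of a chemical share one design matrix, so the fit is a single
vectorized least-squares solve across genes (`DoseTimeAssociation`);
`fit_dose_time_model` is the one-gene entry point with the same
estimates.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "P_FLOOR",
    "AssociationResult",
    "AssociationResults",
    "DoseTimeAssociation",
    "RankedList",
    "fit_dose_time_model",
    "ranking_score",
    "rank_genes",
]

#: p-values are floored here before -log10 so scores stay finite.
P_FLOOR = 1e-300

_COEF_NAMES = ("beta0", "beta1", "beta2", "beta3")


@dataclass(frozen=True)
class AssociationResult:
    """OLS fit of the dose-time model for one (gene, chemical) pair."""

    gene_id: str
    chemical_id: str
    beta0: float
    beta1: float
    beta2: float
    beta3: float
    se_beta1: float
    t_beta1: float
    p_beta1: float

    @property
    def score(self) -> float:
        return ranking_score(self)


def _design_matrix(dose: np.ndarray, time: np.ndarray) -> np.ndarray:
    return np.column_stack([np.ones_like(dose), dose, time, dose * time])


def _check_design(X: np.ndarray) -> None:
    n = X.shape[0]
    if n <= 4:
        raise ValueError(f"need more than 4 samples to fit 4 coefficients, got {n}")
    if n < 6:
        raise ValueError(f"need at least 6 samples for a stable fit, got {n}")
    rank = np.linalg.matrix_rank(X)
    if rank < 4:
        # identify which columns are collinear with the preceding ones
        bad = []
        for j in range(1, 4):
            if np.linalg.matrix_rank(X[:, : j + 1]) == np.linalg.matrix_rank(X[:, :j]):
                bad.append(["intercept", "dose", "time", "dose:time"][j])
        raise ValueError(
            f"rank-deficient design (rank {rank} < 4); collinear columns: {bad}"
        )


def _ols_multi(X: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form OLS for many responses sharing one design matrix.

    Returns (coefficients (4, m), standard errors of beta1 (m,)).
    """
    n = X.shape[0]
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ (X.T @ Y)
    resid = Y - X @ beta
    dof = n - X.shape[1]
    sigma2 = (resid**2).sum(axis=0) / dof
    se1 = np.sqrt(np.maximum(sigma2 * XtX_inv[1, 1], 0.0))
    return beta, se1


class DoseTimeAssociation:
    """Dose-time linear model for all genes of one chemical.

    Parameters
    ----------
    expression
        Genes x samples matrix restricted to this chemical's samples
        (treated rows plus their vehicle controls).
    design
        Design rows for the same samples; must contain ``dose_value``
        and ``time_hr`` and exactly match the expression columns.
    chemical_id
        Label carried into the results (defaults to the design's single
        chemical).
    """

    def __init__(
        self,
        expression: pd.DataFrame,
        design: pd.DataFrame,
        chemical_id: str | None = None,
    ) -> None:
        design = design.set_index("sample_id") if "sample_id" in design.columns else design
        missing = set(expression.columns) - set(design.index)
        if missing:
            raise ValueError(f"design rows missing for samples: {sorted(missing)[:5]}")
        design = design.loc[list(expression.columns)]
        if expression.index.duplicated().any():
            raise ValueError("duplicated gene ids")
        self.expression = expression
        self.design = design
        chems = design["chemical"].unique() if "chemical" in design else ["?"]
        self.chemical_id = chemical_id if chemical_id is not None else str(chems[0])
        self.dose = design["dose_value"].to_numpy(dtype=float)
        self.time = design["time_hr"].to_numpy(dtype=float)
        self.X = _design_matrix(self.dose, self.time)
        _check_design(self.X)

    def fit(self) -> "AssociationResults":
        Y = self.expression.to_numpy(dtype=float).T  # samples x genes
        beta, se1 = _ols_multi(self.X, Y)
        n = self.X.shape[0]
        dof = n - 4
        b1 = beta[1]
        # scale-aware tolerance: residuals this small mean an exact fit
        scale = np.sqrt((Y**2).mean(axis=0))
        tol = 1e-10 * (scale + 1.0)
        zero_se = se1 <= tol
        with np.errstate(divide="ignore", invalid="ignore"):
            t1 = np.where(~zero_se, b1 / np.where(~zero_se, se1, 1.0), 0.0)
        p1 = 2.0 * stats.t.sf(np.abs(t1), dof)
        exact = zero_se & (np.abs(b1) > tol)
        p1 = np.where(exact, P_FLOOR, p1)
        t1 = np.where(exact, np.sign(b1) * np.inf, t1)
        p1 = np.where(zero_se & ~exact, 1.0, p1)
        p1 = np.clip(p1, P_FLOOR, 1.0)
        # constant-gene convention: an exact zero-residual, zero-slope fit
        b1 = np.where(zero_se & ~exact, 0.0, b1)
        table = pd.DataFrame(
            {
                "beta0": beta[0],
                "beta1": b1,
                "beta2": beta[2],
                "beta3": beta[3],
                "se_beta1": se1,
                "t_beta1": t1,
                "p_beta1": p1,
            },
            index=self.expression.index,
        )
        table["score"] = np.sign(table["beta1"]) * (-np.log10(table["p_beta1"]))
        table.loc[zero_se & ~exact, "score"] = 0.0
        return AssociationResults(self, table, dof)


class AssociationResults:
    """Fitted dose-time associations for all genes of one chemical."""

    def __init__(self, model: DoseTimeAssociation, table: pd.DataFrame, dof: int) -> None:
        self.model = model
        self.table = table
        self.dof = dof
        self.chemical_id = model.chemical_id

    def __getitem__(self, gene_id: str) -> AssociationResult:
        row = self.table.loc[gene_id]
        return AssociationResult(
            gene_id=gene_id,
            chemical_id=self.chemical_id,
            beta0=row["beta0"],
            beta1=row["beta1"],
            beta2=row["beta2"],
            beta3=row["beta3"],
            se_beta1=row["se_beta1"],
            t_beta1=row["t_beta1"],
            p_beta1=row["p_beta1"],
        )

    def results_list(self) -> list[AssociationResult]:
        return [self[g] for g in self.table.index]

    def ranked_list(self) -> "RankedList":
        return RankedList.from_scores(self.table["score"], chemical_id=self.chemical_id)

    def summary(self, top: int = 10) -> str:
        t = self.table.sort_values("score", ascending=False)
        lines = [
            f"Dose-time association model | chemical: {self.chemical_id}",
            f"samples: {self.model.X.shape[0]}  genes: {len(t)}  residual df: {self.dof}",
            "",
            t.head(top).to_string(float_format=lambda v: f"{v:.4g}"),
        ]
        return "\n".join(lines)


def fit_dose_time_model(
    expression: pd.Series | np.ndarray,
    design: pd.DataFrame,
    gene_id: str = "gene",
    chemical_id: str | None = None,
) -> AssociationResult:
    """Fit the dose-time model for a single gene (one chemical's samples)."""
    if isinstance(expression, pd.Series):
        values = expression.to_frame().T
        values.index = [gene_id]
        values.columns = expression.index
    else:
        values = pd.DataFrame(
            np.asarray(expression, dtype=float)[None, :],
            index=[gene_id],
            columns=design["sample_id"].to_numpy()
            if "sample_id" in design.columns
            else design.index,
        )
    model = DoseTimeAssociation(values, design, chemical_id=chemical_id)
    return model.fit()[gene_id]


def ranking_score(result: AssociationResult) -> float:
    """Signed significance: sign(b1) * -log10(max(p, floor)).

    A gene with zero dose coefficient and zero residual variance (constant
    expression) scores exactly 0 by convention.
    """
    p = max(result.p_beta1, P_FLOOR)
    if result.se_beta1 == 0 and result.beta1 == 0:
        return 0.0
    return float(np.sign(result.beta1) * (-np.log10(p)))


class RankedList:
    """A chemical-specific gene ranking, strictly ordered.

    Sorted by score descending; ties broken by gene id ascending so the
    order is deterministic. The gene set is a permutation of the input
    universe.
    """

    def __init__(self, gene_ids: np.ndarray, scores: np.ndarray, chemical_id: str = "?"):
        if len(gene_ids) != len(set(gene_ids)):
            raise ValueError("duplicate gene ids in ranked list")
        self.gene_ids = np.asarray(gene_ids, dtype=object)
        self.scores = np.asarray(scores, dtype=float)
        self.chemical_id = chemical_id

    @classmethod
    def from_scores(cls, scores: pd.Series, chemical_id: str = "?") -> "RankedList":
        if scores.index.duplicated().any():
            raise ValueError("duplicate gene ids in scores")
        frame = scores.rename("score").rename_axis("gene").reset_index()
        frame = frame.sort_values(["score", "gene"], ascending=[False, True])
        return cls(
            frame["gene"].to_numpy(), frame["score"].to_numpy(), chemical_id=chemical_id
        )

    def __len__(self) -> int:
        return len(self.gene_ids)

    def position(self, gene_id: str) -> int:
        """0-based rank of a gene."""
        idx = np.nonzero(self.gene_ids == gene_id)[0]
        if len(idx) == 0:
            raise KeyError(gene_id)
        return int(idx[0])

    def to_rnk(self, path: str | Path) -> None:
        """Write the two-column preranked (.rnk) file: gene_id <tab> score."""
        pd.DataFrame({"gene_id": self.gene_ids, "score": self.scores}).to_csv(
            path, sep="\t", index=False, header=False, float_format="%.10g"
        )


def rank_genes(results: list[AssociationResult]) -> RankedList:
    """Rank one chemical's genes by signed significance score."""
    gene_ids = [r.gene_id for r in results]
    if len(gene_ids) != len(set(gene_ids)):
        raise ValueError("duplicate gene_id among association results")
    scores = pd.Series({r.gene_id: r.score for r in results})
    chem = results[0].chemical_id if results else "?"
    return RankedList.from_scores(scores, chemical_id=chem)
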