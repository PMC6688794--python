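"""Model/Results interface over the association tests.

``MultiTraitAssociation`` bundles the aligned trait, genotype and
covariate matrices for one gene or region; ``fit`` runs a chosen test and
returns an :class:`AssociationResults` carrying the statistic, the
permutation p-value, the optimal trait weights (for the score test) and a
``summary()`` table.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import OptimalWeightSolution, optimal_weights
from .data import CovariateMatrix, GenotypeMatrix, PhenotypeMatrix, TestResult
from .inference import (
    PermutationPlan,
    manova_test,
    minp_test,
    residualize,
    tow_cm_test,
)

__all__ = ["MultiTraitAssociation", "AssociationResults"]


class MultiTraitAssociation:
    """Association between K quantitative traits and M variants in a region.

    Parameters
    ----------
    phenotypes, genotypes, covariates
        Aligned sample-by-column matrices (containers, arrays or
        DataFrames); rows must correspond to the same samples in the
        same order.  Use :meth:`from_dataframes` to align by sample ID.
    gene_id
        Optional label carried into results.
    """

    def __init__(self, phenotypes, genotypes, covariates=None, gene_id: str = ""):
        self.phenotypes = (
            phenotypes if isinstance(phenotypes, PhenotypeMatrix)
            else PhenotypeMatrix(np.asarray(phenotypes, dtype=float))
        )
        self.genotypes = (
            genotypes if isinstance(genotypes, GenotypeMatrix)
            else GenotypeMatrix(np.asarray(genotypes, dtype=float))
        )
        self.covariates = None
        if covariates is not None:
            self.covariates = (
                covariates if isinstance(covariates, CovariateMatrix)
                else CovariateMatrix(np.asarray(covariates, dtype=float))
            )
        lengths = {self.phenotypes.n, self.genotypes.n}
        if self.covariates is not None:
            lengths.add(self.covariates.n)
        if len(lengths) != 1:
            raise ValueError("phenotypes, genotypes and covariates disagree on sample count")
        self.gene_id = gene_id

    @classmethod
    def from_dataframes(
        cls, phenotypes: pd.DataFrame, genotypes: pd.DataFrame,
        covariates: pd.DataFrame | None = None, gene_id: str = "",
    ) -> "MultiTraitAssociation":
        """Align all tables on their shared sample index (intersection)."""
        frames = [phenotypes, genotypes] + ([covariates] if covariates is not None else [])
        common = frames[0].index
        for f in frames[1:]:
            common = common.intersection(f.index)
        if len(common) == 0:
            raise ValueError("no samples shared across the input tables")
        common = common.sort_values()  # canonical order, independent of row order
        return cls(
            PhenotypeMatrix.from_dataframe(phenotypes.loc[common]),
            GenotypeMatrix.from_dataframe(genotypes.loc[common]),
            CovariateMatrix.from_dataframe(covariates.loc[common])
            if covariates is not None else None,
            gene_id=gene_id,
        )

    def fit(
        self, method: str = "tow_cm", plan: PermutationPlan | None = None,
        ridge_policy: str = "auto",
    ) -> "AssociationResults":
        """Run one test; ``method`` is ``tow_cm``, ``manova`` or ``minp``."""
        if method == "tow_cm":
            result = tow_cm_test(
                self.phenotypes, self.genotypes, self.covariates,
                plan, ridge_policy=ridge_policy, gene_id=self.gene_id,
            )
            Y_res = residualize(self.phenotypes, self.covariates)
            X_res = residualize(self.genotypes, self.covariates)
            solution = optimal_weights(Y_res, X_res, ridge_policy=ridge_policy)
        elif method == "manova":
            result = manova_test(
                self.phenotypes, self.genotypes, self.covariates, gene_id=self.gene_id
            )
            solution = None
        elif method == "minp":
            result = minp_test(
                self.phenotypes, self.genotypes, self.covariates,
                plan, gene_id=self.gene_id,
            )
            solution = None
        else:
            raise ValueError(f"unknown method {method!r}")
        return AssociationResults(self, result, solution)


class AssociationResults:
    """Fitted association test: statistic, p-value, weights, diagnostics."""

    def __init__(
        self, model: MultiTraitAssociation, result: TestResult,
        solution: OptimalWeightSolution | None,
    ):
        self.model = model
        self.result = result
        self.solution = solution

    @property
    def method(self) -> str:
        return self.result.method

    @property
    def statistic(self) -> float:
        return self.result.statistic

    @property
    def p_value(self) -> float:
        return self.result.p_value

    @property
    def n_permutations_used(self) -> int:
        return self.result.n_permutations_used

    @property
    def trait_weights(self) -> pd.Series | None:
        """Optimal trait weights w° (score test only)."""
        if self.solution is None:
            return None
        return pd.Series(
            self.solution.w_opt, index=self.model.phenotypes.trait_names, name="weight"
        )

    @property
    def per_trait_p(self) -> pd.Series | None:
        if self.result.per_trait_p is None:
            return None
        return pd.Series(
            self.result.per_trait_p, index=self.model.phenotypes.trait_names,
            name="p_value",
        )

    def summary(self) -> str:
        m = self.model
        lines = [
            "Multi-trait gene-based association test",
            "=" * 47,
            f"method:          {self.method}",
            f"gene:            {m.gene_id or '-'}",
            f"samples:         {m.phenotypes.n}",
            f"traits (K):      {m.phenotypes.K}",
            f"variants tested: {self.result.M_tested or m.genotypes.M}",
            f"covariates:      {0 if m.covariates is None else m.covariates.p}",
            f"statistic:       {self.statistic:.6g}",
            f"p-value:         {self.p_value:.4g}",
        ]
        if self.n_permutations_used:
            lines.append(f"permutations:    {self.n_permutations_used}")
        w = self.trait_weights
        if w is not None:
            lines.append("optimal trait weights:")
            for name, val in w.items():
                lines.append(f"  {name:<14s} {val:+.4f}")
            if self.solution.ridge_applied:
                lines.append(f"ridge applied:   lambda0 = {self.solution.lambda0:.3g}")
        pk = self.per_trait_p
        if pk is not None:
            lines.append("per-trait permutation p-values:")
            for name, val in pk.items():
                lines.append(f"  {name:<14s} {val:.4g}")
        return "\n".join(lines)

    def __repr__(self) -> str:
        return (
            f"<AssociationResults {self.method} statistic={self.statistic:.4g} "
            f"p={self.p_value:.4g}>"
        )
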