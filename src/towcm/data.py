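"""In-memory containers for multi-trait gene-based association testing.

The test operates on three aligned sample-by-column matrices: a trait
(phenotype) matrix ``Y`` (n x K), an additively coded genotype matrix
``X`` (n x M), and an optional covariate matrix ``Z`` (n x p).  These
thin dataclasses validate shapes and basic invariants once, so the
numerical core can assume clean input.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PhenotypeMatrix",
    "GenotypeMatrix",
    "CovariateMatrix",
    "TestResult",
]


def _as_2d_float(values, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    if arr.ndim != 2:
        raise ValueError(f"{name} must be 2-dimensional, got shape {arr.shape}")
    if not np.isfinite(arr).all():
        raise ValueError(f"{name} contains non-finite values; resolve missingness upstream")
    return arr


@dataclass
class PhenotypeMatrix:
    """n x K matrix of quantitative trait values, one row per sample."""

    values: np.ndarray
    trait_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = _as_2d_float(self.values, "phenotype matrix")
        n, K = self.values.shape
        if n < 2:
            raise ValueError("need at least two samples")
        if not self.trait_names:
            self.trait_names = [f"trait{k + 1}" for k in range(K)]
        if len(self.trait_names) != K:
            raise ValueError("trait_names length does not match column count")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def K(self) -> int:
        return self.values.shape[1]

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "PhenotypeMatrix":
        return cls(df.to_numpy(dtype=float), trait_names=[str(c) for c in df.columns])


@dataclass
class GenotypeMatrix:
    """n x M matrix of additive genotype scores (ALT-allele counts).

    Raw entries are in {0, 1, 2}; after covariate residualization the
    entries are real.  ``maf`` is the folded allele frequency
    (alt count / 2n, reflected to <= 0.5) computed from the raw scores.
    """

    values: np.ndarray
    variant_ids: list[str] = field(default_factory=list)
    maf: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = _as_2d_float(self.values, "genotype matrix")
        n, M = self.values.shape
        if M < 1:
            raise ValueError("need at least one variant")
        if not self.variant_ids:
            self.variant_ids = [f"v{m + 1}" for m in range(M)]
        if len(self.variant_ids) != M:
            raise ValueError("variant_ids length does not match column count")
        if self.maf is None:
            freq = self.values.mean(axis=0) / 2.0
            self.maf = np.minimum(freq, 1.0 - freq)
        else:
            self.maf = np.asarray(self.maf, dtype=float)
            if self.maf.shape != (M,):
                raise ValueError("maf length does not match variant count")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def M(self) -> int:
        return self.values.shape[1]

    def monomorphic_mask(self) -> np.ndarray:
        """Boolean mask of variants with zero variance in the sample."""
        return self.values.std(axis=0) == 0.0

    def drop_monomorphic(self) -> tuple["GenotypeMatrix", list[str]]:
        """Return a copy without monomorphic variants plus the dropped IDs."""
        mask = self.monomorphic_mask()
        if not mask.any():
            return self, []
        keep = ~mask
        if not keep.any():
            raise ValueError("all variants are monomorphic")
        dropped = [v for v, m in zip(self.variant_ids, mask) if m]
        return (
            GenotypeMatrix(
                self.values[:, keep],
                variant_ids=[v for v, k in zip(self.variant_ids, keep) if k],
                maf=self.maf[keep],
            ),
            dropped,
        )

    def filter_maf(self, lo: float = 0.0, hi: float = 0.5) -> "GenotypeMatrix":
        keep = (self.maf > lo) & (self.maf <= hi)
        if not keep.any():
            raise ValueError(f"no variants with MAF in ({lo}, {hi}]")
        return GenotypeMatrix(
            self.values[:, keep],
            variant_ids=[v for v, k in zip(self.variant_ids, keep) if k],
            maf=self.maf[keep],
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "GenotypeMatrix":
        return cls(df.to_numpy(dtype=float), variant_ids=[str(c) for c in df.columns])


@dataclass
class CovariateMatrix:
    """n x p covariates; the intercept is added internally, never a column."""

    values: np.ndarray
    names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = _as_2d_float(self.values, "covariate matrix")
        n, p = self.values.shape
        if not self.names:
            self.names = [f"z{j + 1}" for j in range(p)]
        if len(self.names) != p:
            raise ValueError("names length does not match column count")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "CovariateMatrix":
        return cls(df.to_numpy(dtype=float), names=[str(c) for c in df.columns])


@dataclass
class TestResult:
    """Outcome of one association test on one gene/region."""

    __test__ = False  # not a pytest test class

    method: str
    statistic: float
    p_value: float
    n_permutations_used: int = 0
    per_trait_p: np.ndarray | None = None
    gene_id: str = ""
    M_tested: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.p_value <= 1.0):
            raise ValueError(f"p-value {self.p_value} outside (0, 1]")
        if (self.per_trait_p is not None) != (self.method == "minp"):
            raise ValueError("per_trait_p is populated exactly for the minP method")

    def as_dict(self) -> dict:
        d = {
            "gene": self.gene_id,
            "method": self.method,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "n_perms": self.n_permutations_used,
            "M_tested": self.M_tested,
        }
        if self.per_trait_p is not None:
            d["per_trait_p"] = ";".join(f"{p:.6g}" for p in self.per_trait_p)
        return d
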