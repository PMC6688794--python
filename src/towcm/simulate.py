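"""Synthetic-data engine for calibration and power studies.

The generator emulates a gene-sized region carrying a mix of common
(MAF > 0.05) and rare (MAF < 0.05) variants, plus K correlated
quantitative traits driven by two covariates, a genetic contribution, and
compound-symmetry correlated normal errors:

    y_k = 0.5 z1 + 0.5 z2 + eta_k + eps_k,
    eta_k = beta_ck x_c + sum_j beta_kj x_j   (associated traits only)

with z1 ~ N(0,1), z2 ~ Bernoulli(0.5), eps rows ~ N(0, Sigma),
Sigma_kl = s_k s_l |rho| for random signs s.  One common variant and a
fraction of the rare variants are causal; the total heritability h is
split across the associated traits by normalized Uniform(0,1) draws, and
effect sizes are set so the rare-causal : common-causal heritability
ratio equals R:

    beta_ck   = sqrt( h_k / (var(x_c) (1 - h_k) (1 + R)) )
    |beta_kj| = sqrt( h_k R / (var(x_j) (1 - h_k) n_c (1 + R)) )

Heritability here is relative to genetic-plus-error variance (the
covariate contribution is excluded from the denominator).  Experiment
runners reproduce the type-I-error and power study designs at
configurable replication.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .data import CovariateMatrix, GenotypeMatrix, PhenotypeMatrix
from .inference import (
    PermutationPlan,
    joint_permutation_test,
    manova_test,
    minp_test,
    tow_cm_test,
)

__all__ = [
    "HaplotypePool",
    "TraitSimConfig",
    "EffectAssignment",
    "sample_maf_spectrum",
    "generate_genotypes",
    "split_heritability",
    "assign_effect_sizes",
    "build_correlation",
    "draw_effects",
    "simulate_traits",
    "simulate_dataset",
    "type1_experiment",
    "power_experiment",
    "plot_power",
]

RARE_MAF_CUTOFF = 0.05
#: rare-variant frequency spectrum: Beta(0.5, 8) truncated to (0.001, 0.05),
#: strongly skewed toward very low frequencies as in exome data
RARE_BETA = (0.5, 8.0)
RARE_BOUNDS = (0.001, 0.05)


@dataclass
class HaplotypePool:
    """Explicit haplotype pool: H binary haplotypes with sampling weights.

    Used when a concrete haplotype structure (e.g. strong LD) is wanted;
    the default generation path samples locus-wise instead, which is the
    H -> infinity limit with independent loci.
    """

    haplotypes: np.ndarray
    frequencies: np.ndarray

    def __post_init__(self) -> None:
        self.haplotypes = np.asarray(self.haplotypes)
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        if self.haplotypes.ndim != 2 or not np.isin(self.haplotypes, (0, 1)).all():
            raise ValueError("haplotypes must be a binary H x M matrix")
        if self.frequencies.shape != (self.haplotypes.shape[0],):
            raise ValueError("one frequency per haplotype required")
        if (self.frequencies < 0).any() or abs(self.frequencies.sum() - 1.0) > 1e-12:
            raise ValueError("frequencies must be nonnegative and sum to 1")

    @property
    def mafs(self) -> np.ndarray:
        freq = self.frequencies @ self.haplotypes
        return np.minimum(freq, 1.0 - freq)

    def sample_genotypes(self, n: int, rng: np.random.Generator) -> np.ndarray:
        idx = rng.choice(len(self.frequencies), size=(n, 2), p=self.frequencies)
        return (self.haplotypes[idx[:, 0]] + self.haplotypes[idx[:, 1]]).astype(float)


def sample_maf_spectrum(M_common: int, M_rare: int, rng: np.random.Generator) -> np.ndarray:
    """Draw target MAFs: common uniform on (0.05, 0.5), rare truncated-Beta.

    Returns the rare-then-common vector under a recorded random shuffle;
    rare and common entries remain identifiable by the 0.05 cutoff.
    """
    if M_common < 0 or M_rare < 0:
        raise ValueError("variant counts must be nonnegative")
    a, b = RARE_BETA
    lo, hi = stats.beta.cdf(RARE_BOUNDS, a, b)
    rare = stats.beta.ppf(rng.uniform(lo, hi, size=M_rare), a, b)
    common = rng.uniform(RARE_MAF_CUTOFF, 0.5, size=M_common)
    maf = np.concatenate([rare, common])
    perm = rng.permutation(maf.size)
    return maf[perm]


def generate_genotypes(
    pool_spec, n: int, rng: np.random.Generator, ld: float = 0.0
) -> GenotypeMatrix:
    """Draw two haplotypes per individual and sum to additive scores.

    ``pool_spec`` is either an explicit :class:`HaplotypePool` or a
    vector of per-locus MAFs.  For a MAF vector the default is
    independent loci; ``ld`` > 0 switches to a first-order Markov
    haplotype model with adjacent-locus allele correlation ~ ``ld``.
    """
    if n < 1:
        raise ValueError("n must be positive")
    if isinstance(pool_spec, HaplotypePool):
        X = pool_spec.sample_genotypes(n, rng)
        ids = [f"v{m + 1}" for m in range(X.shape[1])]
        return GenotypeMatrix(X, variant_ids=ids)
    maf = np.asarray(pool_spec, dtype=float)
    M = maf.size
    if ld == 0.0:
        X = rng.binomial(2, maf[None, :], size=(n, M)).astype(float)
    else:
        hap = np.empty((2 * n, M), dtype=np.int8)
        hap[:, 0] = rng.random(2 * n) < maf[0]
        for m in range(1, M):
            sd_prev = np.sqrt(max(maf[m - 1] * (1 - maf[m - 1]), 1e-12))
            sd_cur = np.sqrt(maf[m] * (1 - maf[m]))
            p = maf[m] + ld * (hap[:, m - 1] - maf[m - 1]) * sd_cur / sd_prev
            hap[:, m] = rng.random(2 * n) < np.clip(p, 0.0, 1.0)
        X = (hap[0::2] + hap[1::2]).astype(float)
    ids = [f"v{m + 1}" for m in range(M)]
    return GenotypeMatrix(X, variant_ids=ids)


def split_heritability(
    h: float, K_assoc: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Split total heritability h over associated traits.

    Draws t_k ~ Uniform(0,1) and sets h_k = h * t_k / sum(t); the shares
    sum to h exactly and are exchangeable across traits.
    """
    if not (0 <= h < 1):
        raise ValueError("h must lie in [0, 1)")
    if K_assoc < 1:
        raise ValueError("need at least one associated trait")
    t = rng.uniform(size=K_assoc)
    return t, h * t / t.sum()


def assign_effect_sizes(
    h_k: float,
    R: float,
    n_c: int,
    var_xc: float,
    var_rare,
    eq8_variance: str = "per_variant",
) -> tuple[float, np.ndarray]:
    """Effect sizes placing heritability h_k with rare:common ratio R.

    ``eq8_variance`` selects the denominator of the rare-variant effect:
    ``per_variant`` uses each rare variant's own genotype variance (the
    ratio of total rare to common heritability is then exactly R);
    ``common`` uses the common variant's variance for every rare effect.
    """
    if h_k >= 1:
        raise ValueError("per-trait heritability must be below 1")
    var_rare = np.asarray(var_rare, dtype=float)
    if h_k <= 0:
        return 0.0, np.zeros(n_c)
    if var_xc <= 0:
        raise ValueError("common-variant variance must be positive")
    beta_c = np.sqrt(h_k / (var_xc * (1 - h_k) * (1 + R)))
    if n_c == 0 or R == 0:
        return float(beta_c), np.zeros(n_c)
    denom_var = var_rare if eq8_variance == "per_variant" else np.full(n_c, var_xc)
    if eq8_variance not in ("per_variant", "common"):
        raise ValueError(f"unknown eq8_variance {eq8_variance!r}")
    beta_rare = np.sqrt(h_k * R / (denom_var * (1 - h_k) * n_c * (1 + R)))
    return float(beta_c), beta_rare


def build_correlation(K: int, rho_mag: float, rng: np.random.Generator) -> np.ndarray:
    """Compound-symmetry trait correlation with random column signs.

    Sigma_kl = s_k s_l |rho| (diagonal 1) for signs s drawn from {-1,+1};
    congruent to the all-positive compound-symmetry matrix, hence
    positive definite for any sign pattern whenever |rho| < 1.
    """
    if not (0 <= rho_mag < 1):
        raise ValueError("correlation magnitude must lie in [0, 1)")
    s = rng.choice([-1.0, 1.0], size=K)
    sigma = rho_mag * np.outer(s, s)
    np.fill_diagonal(sigma, 1.0)
    return sigma


@dataclass
class TraitSimConfig:
    """Full parameterization of one simulation condition."""

    n: int = 1000
    K: int = 4
    rho_mag: float = 0.5
    h: float = 0.0
    R: float = 0.5            # rare:common heritability ratio (0.5 -> 2:1 common:rare)
    n_assoc: int = 4
    rare_causal_fraction: float = 0.2
    risk_fraction: float = 1.0
    M_common: int = 8
    M_rare: int = 40
    ld: float = 0.0
    eq8_variance: str = "per_variant"
    freeze_t: bool = False    # draw trait heritability shares once, not per replicate
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("rho_mag", "rare_causal_fraction", "risk_fraction"):
            v = getattr(self, name)
            if not (0 <= v <= 1) or (name == "rho_mag" and v >= 1):
                raise ValueError(f"{name}={v} out of range")
        if not (0 <= self.h < 1):
            raise ValueError("h must lie in [0, 1)")
        if not (1 <= self.n_assoc <= self.K):
            raise ValueError("n_assoc must lie in 1..K")


@dataclass
class EffectAssignment:
    """Causal-variant choice and per-trait effect sizes for one replicate."""

    common_index: int
    rare_indices: np.ndarray
    beta_common: np.ndarray          # K (zero for null traits)
    beta_rare_abs: np.ndarray        # K x n_c magnitudes
    signs: np.ndarray                # n_c + 1 signs; [0] is the common variant
    per_trait_h: np.ndarray          # K
    t: np.ndarray                    # uniform draws behind the split
    eta: np.ndarray | None = None    # n x K genetic contribution, filled on use


def draw_effects(
    X: GenotypeMatrix, cfg: TraitSimConfig, rng: np.random.Generator,
    t_fixed: np.ndarray | None = None,
) -> EffectAssignment:
    """Pick causal variants and assign per-trait effect sizes."""
    maf = X.maf
    common_pool = np.nonzero(maf > RARE_MAF_CUTOFF)[0]
    rare_pool = np.nonzero((maf > 0) & (maf < RARE_MAF_CUTOFF))[0]
    if common_pool.size == 0:
        raise ValueError("no common variant available to be causal")
    common_index = int(rng.choice(common_pool))
    n_c = int(round(cfg.rare_causal_fraction * rare_pool.size))
    rare_indices = np.sort(rng.choice(rare_pool, size=n_c, replace=False))

    if t_fixed is not None:
        t = np.asarray(t_fixed, dtype=float)
        h_k_assoc = cfg.h * t / t.sum()
    else:
        t, h_k_assoc = split_heritability(cfg.h, cfg.n_assoc, rng)
    per_trait_h = np.zeros(cfg.K)
    per_trait_h[: cfg.n_assoc] = h_k_assoc

    var_xc = float(X.values[:, common_index].var())
    var_rare = X.values[:, rare_indices].var(axis=0)
    beta_common = np.zeros(cfg.K)
    beta_rare_abs = np.zeros((cfg.K, n_c))
    for k in range(cfg.n_assoc):
        bc, br = assign_effect_sizes(
            per_trait_h[k], cfg.R, n_c, var_xc, var_rare, cfg.eq8_variance
        )
        beta_common[k] = bc
        beta_rare_abs[k] = br

    n_causal = n_c + 1
    n_risk = int(round(cfg.risk_fraction * n_causal))
    signs = np.concatenate([np.ones(n_risk), -np.ones(n_causal - n_risk)])
    rng.shuffle(signs)
    return EffectAssignment(
        common_index=common_index, rare_indices=rare_indices,
        beta_common=beta_common, beta_rare_abs=beta_rare_abs, signs=signs,
        per_trait_h=per_trait_h, t=t,
    )


def simulate_traits(
    X: GenotypeMatrix, cfg: TraitSimConfig,
    effects: EffectAssignment | None, rng: np.random.Generator,
) -> tuple[PhenotypeMatrix, CovariateMatrix]:
    """Trait model y_k = 0.5 z1 + 0.5 z2 + eta_k + eps_k."""
    n, K = X.n, cfg.K
    z1 = rng.standard_normal(n)
    z2 = rng.binomial(1, 0.5, size=n).astype(float)
    sigma = build_correlation(K, cfg.rho_mag, rng)
    eps = rng.standard_normal((n, K)) @ np.linalg.cholesky(sigma).T

    eta = np.zeros((n, K))
    if effects is not None:
        xc = X.values[:, effects.common_index]
        xr = X.values[:, effects.rare_indices]
        rare_signed = effects.beta_rare_abs * effects.signs[None, 1:]
        eta = (
            np.outer(xc, effects.signs[0] * effects.beta_common)
            + xr @ rare_signed.T
        )
        effects.eta = eta
    Y = 0.5 * z1[:, None] + 0.5 * z2[:, None] + eta + eps
    return (
        PhenotypeMatrix(Y),
        CovariateMatrix(np.column_stack([z1, z2]), names=["z1", "z2"]),
    )


def simulate_dataset(
    cfg: TraitSimConfig, rng: np.random.Generator | None = None,
    t_fixed: np.ndarray | None = None,
):
    """One full replicate: genotypes, traits, covariates, effect metadata."""
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    maf = sample_maf_spectrum(cfg.M_common, cfg.M_rare, rng)
    X = generate_genotypes(maf, cfg.n, rng, ld=cfg.ld)
    effects = None
    if cfg.h > 0:
        effects = draw_effects(X, cfg, rng, t_fixed=t_fixed)
    Y, Z = simulate_traits(X, cfg, effects, rng)
    return Y, X, Z, effects


# ---------------------------------------------------------------------------
# experiment runners


def _replicate_pvalues(
    cfg: TraitSimConfig, n_reps: int, plan: PermutationPlan,
    methods: tuple[str, ...],
) -> pd.DataFrame:
    """p-values per method over replicates, each with a spawned child seed."""
    ss = np.random.SeedSequence(cfg.seed)
    children = ss.spawn(n_reps)
    t_fixed = None
    if cfg.freeze_t and cfg.h > 0:
        t_fixed = np.random.default_rng(ss.spawn(1)[0]).uniform(size=cfg.n_assoc)
    rows = []
    for rep, child in enumerate(children):
        rng = np.random.default_rng(child)
        Y, X, Z, _ = simulate_dataset(cfg, rng=rng, t_fixed=t_fixed)
        perm_seed = int(rng.integers(2**31 - 1))
        rep_plan = replace(plan, seed=perm_seed)
        row = {"rep": rep}
        if "tow_cm" in methods and "minp" in methods:
            tow, minp = joint_permutation_test(Y, X, Z, rep_plan)
            row["tow_cm"], row["minp"] = tow.p_value, minp.p_value
        elif "tow_cm" in methods:
            row["tow_cm"] = tow_cm_test(Y, X, Z, rep_plan).p_value
        elif "minp" in methods:
            row["minp"] = minp_test(Y, X, Z, rep_plan).p_value
        if "manova" in methods:
            row["manova"] = manova_test(Y, X, Z).p_value
        rows.append(row)
    return pd.DataFrame(rows)


def _rate_ci(k: int, n: int) -> tuple[float, float, float]:
    """Rejection rate with normal-approximation binomial 95% CI."""
    p = k / n
    half = 1.96 * np.sqrt(p * (1 - p) / n)
    return p, max(p - half, 0.0), min(p + half, 1.0)


def type1_experiment(
    cfg: TraitSimConfig, n_reps: int, plan: PermutationPlan,
    alphas: tuple[float, ...] = (0.05, 0.01, 0.001),
    methods: tuple[str, ...] = ("tow_cm", "minp", "manova"),
) -> pd.DataFrame:
    """Estimated type-I error per method and level under the null (eta = 0).

    Cells whose level is at or below 1/n_reps are flagged
    ``underpowered`` (the replicate count cannot resolve them).
    """
    if n_reps < 100:
        raise ValueError("need at least 100 replicates")
    null_cfg = replace(cfg, h=0.0)
    pvals = _replicate_pvalues(null_cfg, n_reps, plan, methods)
    rows = []
    for method in methods:
        for alpha in alphas:
            k = int((pvals[method] <= alpha).sum())
            est, lo, hi = _rate_ci(k, n_reps)
            rows.append({
                "method": method, "n": cfg.n, "rho": cfg.rho_mag, "alpha": alpha,
                "estimate": est, "ci_lo": lo, "ci_hi": hi,
                "n_reps": n_reps, "seed": cfg.seed,
                "underpowered": alpha <= 1.0 / n_reps,
            })
    return pd.DataFrame(rows)


def power_experiment(
    cfg: TraitSimConfig, h_grid, n_reps: int, plan: PermutationPlan,
    alpha: float = 0.05,
    methods: tuple[str, ...] = ("tow_cm", "minp", "manova"),
) -> pd.DataFrame:
    """Power versus total heritability for each method at level alpha."""
    h_grid = list(h_grid)
    if any(b <= a for a, b in zip(h_grid, h_grid[1:])):
        raise ValueError("h grid must be strictly increasing")
    rows = []
    for i, h in enumerate(h_grid):
        cfg_h = replace(cfg, h=h, seed=cfg.seed + 7919 * i)
        pvals = _replicate_pvalues(cfg_h, n_reps, plan, methods)
        for method in methods:
            k = int((pvals[method] <= alpha).sum())
            est, lo, hi = _rate_ci(k, n_reps)
            rows.append({
                "method": method, "n": cfg.n, "rho": cfg.rho_mag, "h": h,
                "n_assoc": cfg.n_assoc, "risk_fraction": cfg.risk_fraction,
                "alpha": alpha, "estimate": est, "ci_lo": lo, "ci_hi": hi,
                "n_reps": n_reps, "seed": cfg_h.seed,
            })
    return pd.DataFrame(rows)


def plot_power(table: pd.DataFrame, path=None):
    """Power versus heritability, one line per method (matplotlib).

    ``table`` is the output of :func:`power_experiment`; returns the
    matplotlib Figure (and saves it when ``path`` is given).
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for method, sub in table.groupby("method"):
        sub = sub.sort_values("h")
        ax.errorbar(
            sub["h"], sub["estimate"],
            yerr=[sub["estimate"] - sub["ci_lo"], sub["ci_hi"] - sub["estimate"]],
            marker="o", capsize=3, label=method,
        )
    rho = table["rho"].iloc[0]
    ax.set_xlabel("total heritability h")
    ax.set_ylabel(f"power at level {table['alpha'].iloc[0]:g}")
    ax.set_title(f"|rho| = {rho:g}, {int(table['n_assoc'].iloc[0])} associated traits")
    ax.set_ylim(0, 1)
    ax.legend()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
    return fig
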