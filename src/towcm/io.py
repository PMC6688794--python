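"""File I/O: VCF and delimited tables, gene regions, the per-gene scan.

Coordinates are 0-based half-open internally; VCF positions are 1-based
as the format requires.  Samples are always matched across files by ID,
never by row order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .data import CovariateMatrix, GenotypeMatrix, PhenotypeMatrix
from .inference import PermutationPlan, manova_test, minp_test, tow_cm_test

logger = logging.getLogger("towcm")

__all__ = [
    "GeneRegionSet",
    "AnalysisConfig",
    "read_table",
    "align_samples",
    "read_genotypes_vcf",
    "write_vcf",
    "run_gene_scan",
]


@dataclass
class GeneRegionSet:
    """Gene definitions: intervals (chrom, start, end) or explicit variant IDs."""

    entries: list[tuple[str, object]] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [g for g, _ in self.entries]
        if len(set(ids)) != len(ids):
            raise ValueError("gene ids must be unique")

    @classmethod
    def from_bed(cls, path) -> "GeneRegionSet":
        """BED: chrom, start, end, name — half-open 0-based as in the format."""
        entries = []
        for i, line in enumerate(Path(path).read_text().splitlines()):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed BED line {i + 1}: {line!r}")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            name = parts[3] if len(parts) > 3 else f"{chrom}:{start}-{end}"
            entries.append((name, (chrom, start, end)))
        return cls(entries)

    @classmethod
    def from_mapping(cls, mapping: dict[str, list[str]]) -> "GeneRegionSet":
        return cls([(g, list(v)) for g, v in mapping.items()])


@dataclass
class AnalysisConfig:
    """Knobs of a per-gene scan."""

    methods: tuple[str, ...] = ("tow_cm",)
    plan: PermutationPlan = field(default_factory=PermutationPlan)
    ridge_policy: str = "auto"
    maf_lo: float = 0.0
    maf_hi: float = 0.5
    missing_policy: str = "mean"   # or "drop" (drop variants >5% missing)
    max_missing: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.methods:
            raise ValueError("at least one method required")
        if not (0 <= self.maf_lo < self.maf_hi <= 0.5):
            raise ValueError("MAF bounds must satisfy 0 <= lo < hi <= 0.5")

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        plan_kw = raw.pop("plan", {})
        plan = PermutationPlan(**plan_kw) if plan_kw else PermutationPlan()
        return cls(plan=plan, **{k: tuple(v) if k == "methods" else v for k, v in raw.items()})


def read_table(path, kind: str = "phenotype") -> pd.DataFrame:
    """Delimited table with a header row; first column is the sample ID.

    Rows with any missing value are dropped (with a log message), since
    the tests require complete phenotype/covariate data.
    """
    df = pd.read_csv(path, sep=None, engine="python", index_col=0)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample IDs in {path}: {dups[:5]}")
    before = len(df)
    df = df.dropna()
    if len(df) < before:
        logger.info("%s: dropped %d rows with missing %s values", path, before - len(df), kind)
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise ValueError(f"non-numeric cells in {path}: {exc}") from exc
    return df


def align_samples(*frames: pd.DataFrame) -> list[pd.DataFrame]:
    """Restrict all tables to their shared sample IDs, preserving one order."""
    common = frames[0].index
    for f in frames[1:]:
        common = common.intersection(f.index)
    if len(common) == 0:
        raise ValueError("no samples shared across the input tables")
    common = common.sort_values()  # canonical order: results invariant to file row order
    logger.info("sample alignment: %d shared IDs", len(common))
    return [f.loc[common] for f in frames]


def read_genotypes_vcf(
    path,
    region: tuple[str, int, int] | None = None,
    sample_subset: list[str] | None = None,
    missing_policy: str = "mean",
    max_missing: float = 0.05,
) -> tuple[GenotypeMatrix, list[str]]:
    """Additive dosages from the GT field of biallelic VCF records.

    ``region`` is (chrom, start, end), half-open 0-based; records are
    filtered in Python so plain uncompressed VCFs need no index.
    Multi-allelic records are skipped with a warning.  Missing genotypes
    are mean-imputed per variant (``mean``) or the variant is dropped
    when its missingness exceeds ``max_missing`` (``drop``).
    Returns the matrix and the sample IDs in matrix row order.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), samples=sample_subset, gts012=True)
    samples = list(vcf.samples)
    if sample_subset is not None:
        missing = set(sample_subset) - set(samples)
        if missing:
            raise ValueError(f"samples absent from VCF: {sorted(missing)[:5]}")
    cols, ids = [], []
    for var in vcf:
        if region is not None:
            chrom, start, end = region
            if var.CHROM != chrom or not (start <= var.POS - 1 < end):
                continue
        if len(var.ALT) != 1:
            logger.warning("skipping multi-allelic record %s:%d", var.CHROM, var.POS)
            continue
        # with gts012: 0/1/2 = ALT count, 3 = missing
        g = np.asarray(var.gt_types, dtype=float)
        g[g == 3] = np.nan
        miss = np.isnan(g)
        if miss.any():
            if missing_policy == "drop" and miss.mean() > max_missing:
                continue
            if miss.all():
                continue
            g[miss] = np.nanmean(g)
        cols.append(g)
        ids.append(var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}")
    if not cols:
        raise ValueError(f"no usable biallelic variants in {path}"
                         + (f" region {region}" if region else ""))
    return GenotypeMatrix(np.column_stack(cols), variant_ids=ids), samples


def write_vcf(path, X: GenotypeMatrix, samples: list[str],
              chrom: str = "1", positions: list[int] | None = None) -> None:
    """Write hard-call genotypes as a minimal plain-text VCF 4.2.

    Fractional (imputed/residualized) dosages are not representable in
    GT; values are rounded to the nearest of {0, 1, 2}.
    """
    positions = positions or list(range(1, X.M + 1))
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for m in range(X.M):
            calls = [gt_map[int(round(min(max(v, 0), 2)))] for v in X.values[:, m]]
            fh.write(f"{chrom}\t{positions[m]}\t{X.variant_ids[m]}\tA\tG\t.\tPASS\t.\tGT\t"
                     + "\t".join(calls) + "\n")


def run_gene_scan(
    config: AnalysisConfig,
    vcf_path,
    phenotypes: pd.DataFrame,
    covariates: pd.DataFrame | None,
    regions: GeneRegionSet,
) -> pd.DataFrame:
    """Run the configured tests gene by gene; one row per (gene, method).

    Per-gene failures are logged and reported as status=failed/skipped
    rows rather than aborting the scan.
    """
    rows = []
    for gene_id, spec in regions.entries:
        chrom = spec[0] if isinstance(spec, tuple) else "."
        try:
            if isinstance(spec, tuple):
                X_all, samples = read_genotypes_vcf(
                    vcf_path, region=spec,
                    missing_policy=config.missing_policy,
                    max_missing=config.max_missing,
                )
            else:
                X_all, samples = read_genotypes_vcf(
                    vcf_path, missing_policy=config.missing_policy,
                    max_missing=config.max_missing,
                )
                keep = [j for j, v in enumerate(X_all.variant_ids) if v in set(spec)]
                if not keep:
                    raise ValueError("none of the listed variant IDs found")
                X_all = GenotypeMatrix(
                    X_all.values[:, keep],
                    variant_ids=[X_all.variant_ids[j] for j in keep],
                )
            geno_df = pd.DataFrame(X_all.values, index=samples, columns=X_all.variant_ids)
            frames = [phenotypes, geno_df] + ([covariates] if covariates is not None else [])
            aligned = align_samples(*frames)
            Y = PhenotypeMatrix.from_dataframe(aligned[0])
            X = GenotypeMatrix.from_dataframe(aligned[1])
            Z = CovariateMatrix.from_dataframe(aligned[2]) if covariates is not None else None
            M_total = X.M
            X, dropped_mono = X.drop_monomorphic()
            if dropped_mono:
                logger.info("%s: dropped %d monomorphic variants", gene_id, len(dropped_mono))
            X = X.filter_maf(config.maf_lo, config.maf_hi)
        except Exception as exc:  # noqa: BLE001 - per-gene isolation is the contract
            logger.error("gene %s failed during extraction: %s", gene_id, exc)
            rows.append({
                "gene": gene_id, "chrom": chrom, "M_total": 0, "M_tested": 0,
                "method": "-", "statistic": np.nan, "p_value": np.nan,
                "n_perms": 0, "seed": config.seed, "status": "skipped",
            })
            continue
        for method in config.methods:
            try:
                if method == "tow_cm":
                    res = tow_cm_test(Y, X, Z, config.plan,
                                      ridge_policy=config.ridge_policy, gene_id=gene_id)
                elif method == "minp":
                    res = minp_test(Y, X, Z, config.plan, gene_id=gene_id)
                elif method == "manova":
                    res = manova_test(Y, X, Z, gene_id=gene_id)
                else:
                    raise ValueError(f"unknown method {method!r}")
                rows.append({
                    "gene": gene_id, "chrom": chrom, "M_total": M_total,
                    "M_tested": res.M_tested or X.M, "method": method,
                    "statistic": res.statistic, "p_value": res.p_value,
                    "n_perms": res.n_permutations_used, "seed": config.plan.seed,
                    "status": "ok",
                })
            except Exception as exc:  # noqa: BLE001
                logger.error("gene %s method %s failed: %s", gene_id, method, exc)
                rows.append({
                    "gene": gene_id, "chrom": chrom, "M_total": M_total,
                    "M_tested": 0, "method": method, "statistic": np.nan,
                    "p_value": np.nan, "n_perms": 0, "seed": config.plan.seed,
                    "status": "failed",
                })
    return pd.DataFrame(rows)
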