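"""Allelic imbalance over germline heterozygous SNPs.

A trustworthy heterozygous-SNP list is the crux: a homozygous or
artifactual SNP smuggled into the list looks exactly like mono-allelic
expression. Candidates therefore must show >= 10x normal-DNA coverage, a
40-60% variant allele fraction, and > 1% population frequency. The
tumor-DNA-more-abundant allele is designated the "major" allele (an
arbitrary label wherever the tumor DNA is balanced — flagged as such).

Downstream: per-spot major-allele fractions versus coverage expose
mono-allelic expression (X-inactivation, immunoglobulin allelic
exclusion); pooling reads across all SNPs of a chromosome arm reveals
regional skew (loss of heterozygosity or copy gain) too subtle to call at
single SNPs; coverage-spike and homology heuristics flag likely mapping
artifacts without auto-removing anything.
"""

from __future__ import annotations

from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd
from scipy.stats import beta

__all__ = [
    "SNP_COLUMNS",
    "read_snp_table",
    "filter_het_snps",
    "assign_major_allele",
    "spot_allele_fractions",
    "detect_monoallelic",
    "region_allele_skew",
    "RegionSkew",
    "binomial_ci",
    "flag_mapping_artifacts",
]

SNP_COLUMNS = [
    "chrom",
    "pos",
    "ref",
    "alt",
    "normal_depth",
    "normal_vaf",
    "pop_freq",
    "tumor_ref_count",
    "tumor_alt_count",
]


def read_snp_table(path) -> pd.DataFrame:
    """Read the candidate heterozygous-SNP TSV (columns SNP_COLUMNS)."""
    df = pd.read_csv(path, sep="\t")
    df.columns = [c.strip().lower() for c in df.columns]
    missing = [c for c in SNP_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return df


def filter_het_snps(
    candidates: pd.DataFrame,
    min_normal_depth: int = 10,
    vaf_range: tuple[float, float] = (0.40, 0.60),
    min_pop_freq: float = 0.01,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Keep candidates passing all three heterozygosity criteria.

    Returns (passing, failures); failures carry a ``fail_reasons``
    column. A missing or null ``pop_freq`` is an error, never a silent
    pass — the population-frequency check is the guard against private
    artifacts.
    """
    if "pop_freq" not in candidates.columns:
        raise ValueError("candidate table lacks a pop_freq column")
    if candidates["pop_freq"].isna().any():
        bad = candidates.index[candidates["pop_freq"].isna()].tolist()
        raise ValueError(f"pop_freq missing for candidate rows {bad[:5]}")
    lo, hi = vaf_range
    reasons = []
    for r in candidates.itertuples():
        why = []
        if r.normal_depth < min_normal_depth:
            why.append("coverage")
        if not (lo <= r.normal_vaf <= hi):
            why.append("vaf_window")
        if not (r.pop_freq > min_pop_freq):
            why.append("pop_freq")
        reasons.append(",".join(why))
    reasons = pd.Series(reasons, index=candidates.index)
    passing = candidates[reasons == ""].copy()
    failures = candidates[reasons != ""].copy()
    failures["fail_reasons"] = reasons[reasons != ""]
    return passing, failures


def assign_major_allele(snps: pd.DataFrame) -> pd.DataFrame:
    """Designate each SNP's major allele from the tumor DNA counts.

    major = allele with the higher tumor read count; an exact tie takes
    ref and is flagged ``arbitrary`` (the label then just records which
    allele was sampled more often); zero coverage on both alleles leaves
    the major allele undefined and flags ``undefined``.
    """
    out = snps.copy()
    ref_n = out["tumor_ref_count"].astype(int)
    alt_n = out["tumor_alt_count"].astype(int)
    major = np.where(alt_n > ref_n, "alt", "ref")
    flag = np.where(
        (ref_n == 0) & (alt_n == 0),
        "undefined",
        np.where(ref_n == alt_n, "arbitrary", ""),
    )
    out["major_allele"] = np.where(flag == "undefined", None, major)
    out["major_allele_flag"] = flag
    return out


def spot_allele_fractions(
    table: pd.DataFrame, snps: pd.DataFrame
) -> pd.DataFrame:
    """Per (SNP, spot) major/minor allele fractions.

    ``table`` is an allele count table over the SNP sites. Coverage is
    ref + alt reads; "other" (neither-allele) reads are excluded from the
    denominator and reported separately. Only covered pairs are returned;
    at each of them major_fraction + minor_fraction == 1.
    """
    key = ["chrom", "pos"]
    ann = snps.set_index(key)[["major_allele"]]
    merged = table.merge(
        ann, left_on=key, right_index=True, how="inner"
    )
    merged = merged[merged["major_allele"].notna()]
    cov = merged["ref_count"] + merged["alt_count"]
    merged = merged[cov > 0].copy()
    cov = merged["ref_count"] + merged["alt_count"]
    major_reads = np.where(
        merged["major_allele"] == "alt", merged["alt_count"], merged["ref_count"]
    )
    merged["coverage"] = cov.astype(int)
    merged["major_fraction"] = major_reads / cov
    merged["minor_fraction"] = 1.0 - merged["major_fraction"]
    cols = key + [
        "ref", "alt", "barcode", "coverage", "major_fraction",
        "minor_fraction", "other_count",
    ]
    return merged[cols].reset_index(drop=True)


def detect_monoallelic(
    fractions: pd.DataFrame,
    min_coverage: int = 25,
    min_fraction: float = 0.90,
    allele_side: str = "minor",
) -> pd.DataFrame:
    """Flag (SNP, spot) pairs expressing essentially one allele.

    Both thresholds are strict: coverage > min_coverage and the selected
    allele's fraction > min_fraction.
    """
    if allele_side not in ("major", "minor"):
        raise ValueError("allele_side must be 'major' or 'minor'")
    frac = fractions[f"{allele_side}_fraction"]
    mask = (fractions["coverage"] > min_coverage) & (frac > min_fraction)
    return fractions[mask].reset_index(drop=True)


class RegionSkew(NamedTuple):
    major_fraction: float
    n_major_reads: int
    n_total_reads: int
    ci95: tuple[float, float]
    n_snps: int


def binomial_ci(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Exact (Clopper-Pearson) binomial confidence interval."""
    if n <= 0:
        raise ValueError("n must be positive")
    alpha = 1.0 - level
    low = 0.0 if k == 0 else float(beta.ppf(alpha / 2.0, k, n - k + 1))
    high = 1.0 if k == n else float(beta.ppf(1.0 - alpha / 2.0, k + 1, n - k))
    return (low, high)


def region_allele_skew(
    fractions: pd.DataFrame,
    snps: pd.DataFrame,
    region: "str | tuple[str, int, int]",
    spot_set: Iterable[str] | None = None,
) -> RegionSkew:
    """Pooled major-allele fraction over all SNPs of a genomic region.

    ``region`` is an arm name (requires an ``arm`` column in ``snps``) or
    a (chrom, start, end) interval (1-based inclusive). Reads are pooled
    across every covered SNP and spot (optionally restricted to
    ``spot_set``), integrating skews individually too subtle to call.
    """
    if isinstance(region, str):
        if "arm" not in snps.columns:
            raise ValueError("arm-named region requires an 'arm' column in snps")
        keep = snps[snps["arm"].astype(str) == region]
    else:
        chrom, start, end = region
        keep = snps[
            (snps["chrom"].astype(str) == str(chrom))
            & (snps["pos"] >= int(start))
            & (snps["pos"] <= int(end))
        ]
    key = ["chrom", "pos"]
    sub = fractions.merge(keep[key].drop_duplicates(), on=key, how="inner")
    if spot_set is not None:
        sub = sub[sub["barcode"].isin(set(spot_set))]
    total = int(sub["coverage"].sum())
    if total == 0:
        raise ValueError(f"no covered SNP in region {region!r}")
    n_major = int(round((sub["coverage"] * sub["major_fraction"]).sum()))
    frac = n_major / total
    return RegionSkew(frac, n_major, total, binomial_ci(n_major, total), len(keep))


def flag_mapping_artifacts(
    coverage_profile: pd.DataFrame,
    homology_genes: Iterable[str] = (),
    ratio_threshold: float = 50.0,
) -> pd.DataFrame:
    """Warn about SNPs whose coverage pattern suggests misaligned reads.

    ``coverage_profile`` has one row per SNP with columns ``chrom``,
    ``pos``, ``gene``, ``site_coverage``, ``end_coverage`` (read depth at
    the transcript's 3' terminus). Warnings, never removal:

    * ``coverage_spike`` — site coverage strictly exceeds
      ``ratio_threshold`` times the 3'-end coverage of the same gene; in
      3'-capture data the SNP site cannot legitimately dwarf the poly-A
      end, so a spike marks reads borrowed from homologous loci.
    * ``homology_cluster`` — the gene belongs to a user-supplied
      homologous gene family (e.g. the S100 cluster).
    """
    homology = set(homology_genes)
    rows = []
    for r in coverage_profile.itertuples():
        reasons = []
        if r.end_coverage > 0 and r.site_coverage > ratio_threshold * r.end_coverage:
            reasons.append("coverage_spike")
        if r.gene in homology:
            reasons.append("homology_cluster")
        if reasons:
            rows.append(
                {
                    "chrom": r.chrom,
                    "pos": r.pos,
                    "gene": r.gene,
                    "warnings": ",".join(reasons),
                }
            )
    return pd.DataFrame(rows, columns=["chrom", "pos", "gene", "warnings"])
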