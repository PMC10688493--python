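"""Spot classification by somatic-mutation evidence.

A spot with at least one mutant read is considered to harbor tumor cells;
spots with only reference reads are graded by how many reference reads
they have, because most somatic mutations are heterozygous and a tumor
cell can legitimately yield wild-type reads. Five or more reference reads
with no mutant read marks a spot unlikely to contain tumor cells.

Also builds the mutation x spot tiling matrix and the co-occurrence
summary used to reason about clonality: mutations sharing spots are
linked and likely arose in the same clone.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd

from .io import SpotLayout, VariantSite

__all__ = [
    "CATEGORIES",
    "classify_spot",
    "classify_all",
    "detection_summary",
    "DetectionSummary",
    "MutationSpotMatrix",
    "mutation_spot_matrix",
    "linkage_summary",
    "LinkageSummary",
]

# ordered from strongest tumor evidence to none
CATEGORIES = (
    "mutant_ge2",
    "mutant_1",
    "ref_5plus",
    "ref_4",
    "ref_3",
    "ref_2",
    "ref_1",
    "no_coverage",
)

CELL_STATES = ("mutant", "ref_only", "no_coverage")


def classify_spot(mut_reads: int, ref_reads: int) -> str:
    """Classify one spot from its summed mutant/reference read counts."""
    if mut_reads < 0 or ref_reads < 0:
        raise ValueError("read counts must be non-negative")
    if mut_reads >= 2:
        return "mutant_ge2"
    if mut_reads == 1:
        return "mutant_1"
    if ref_reads >= 5:
        return "ref_5plus"
    if ref_reads >= 1:
        return f"ref_{ref_reads}"
    return "no_coverage"


def classify_all(table: pd.DataFrame, layout: SpotLayout) -> pd.DataFrame:
    """One classification per layout spot (zero-coverage spots included).

    ``table`` is an allele count table restricted to somatic sites; counts
    are summed across sites per spot before classification.
    """
    sums = (
        table.groupby("barcode")[["alt_count", "ref_count"]].sum()
        if len(table)
        else pd.DataFrame(columns=["alt_count", "ref_count"])
    )
    mut = sums["alt_count"].reindex(layout.barcodes, fill_value=0).astype(int)
    ref = sums["ref_count"].reindex(layout.barcodes, fill_value=0).astype(int)
    category = [classify_spot(m, r) for m, r in zip(mut, ref)]
    return pd.DataFrame(
        {"mut_reads": mut, "ref_reads": ref, "category": category},
        index=layout.barcodes,
    )


class DetectionSummary(NamedTuple):
    n_total: int
    n_detected: int
    percent: float


def detection_summary(
    sites: Iterable[VariantSite],
    table: pd.DataFrame,
    mode: str = "any_read",
) -> DetectionSummary:
    """Fraction of DNA-called mutations detected in the spatial data.

    ``mode='any_read'`` counts a mutation as detected when any spot has a
    read over the site (either allele); ``mode='mutant_read'`` requires a
    mutant read. Percent is reported to one decimal on the 0-100 scale.
    """
    sites = list(sites)
    n_total = len(sites)
    if n_total == 0:
        raise ValueError("empty site list")
    if mode not in ("any_read", "mutant_read"):
        raise ValueError(f"unknown detection mode {mode!r}")
    detected = set()
    if len(table):
        covered = table.copy()
        if mode == "any_read":
            covered = covered[(covered["ref_count"] + covered["alt_count"]) > 0]
        else:
            covered = covered[covered["alt_count"] > 0]
        detected = set(zip(covered["chrom"].astype(str), covered["pos"].astype(int)))
    n_detected = sum(1 for s in sites if (s.chrom, s.pos) in detected)
    percent = round(100.0 * n_detected / n_total, 1)
    return DetectionSummary(n_total, n_detected, percent)


@dataclass
class MutationSpotMatrix:
    """Mutation x spot tiling: per-cell state plus the underlying counts.

    Rows and columns are ordered by descending mutant evidence (number of
    mutant cells in the row/column), ties broken by genomic position and
    barcode respectively.
    """

    states: pd.DataFrame  # str cells, values in CELL_STATES
    alt_counts: pd.DataFrame
    ref_counts: pd.DataFrame

    @property
    def row_mutant_marginals(self) -> pd.Series:
        return (self.states == "mutant").sum(axis=1)

    @property
    def col_mutant_marginals(self) -> pd.Series:
        return (self.states == "mutant").sum(axis=0)


def mutation_spot_matrix(
    table: pd.DataFrame, layout: SpotLayout
) -> MutationSpotMatrix:
    """Build the tiling matrix over all somatic sites in ``table`` and all
    layout spots."""
    if len(table):
        key = (
            table["chrom"].astype(str)
            + ":" + table["pos"].astype(str)
            + ":" + table["ref"].astype(str)
            + ">" + table["alt"].astype(str)
        )
        tagged = table.assign(_site=key)
        alt = tagged.pivot_table(
            index="_site", columns="barcode", values="alt_count", aggfunc="sum"
        )
        ref = tagged.pivot_table(
            index="_site", columns="barcode", values="ref_count", aggfunc="sum"
        )
        site_order = (
            tagged[["_site", "chrom", "pos"]]
            .drop_duplicates("_site")
            .sort_values(["chrom", "pos"], kind="stable")["_site"]
        )
    else:
        alt = ref = pd.DataFrame()
        site_order = pd.Series(dtype=str)
    alt = alt.reindex(index=site_order, columns=layout.barcodes).fillna(0).astype(int)
    ref = ref.reindex(index=site_order, columns=layout.barcodes).fillna(0).astype(int)
    states = pd.DataFrame(
        np.where(alt > 0, "mutant", np.where(ref > 0, "ref_only", "no_coverage")),
        index=alt.index,
        columns=alt.columns,
    )
    # order by mutant evidence, descending; stable ties on position/barcode
    row_key = (states == "mutant").sum(axis=1)
    col_key = (states == "mutant").sum(axis=0)
    rows = row_key.sort_values(ascending=False, kind="stable").index
    cols = col_key.sort_values(ascending=False, kind="stable").index
    return MutationSpotMatrix(
        states.loc[rows, cols], alt.loc[rows, cols], ref.loc[rows, cols]
    )


class LinkageSummary(NamedTuple):
    n_spots_with_ge2_mutations: int
    n_mutations_in_ge2_spots: int
    co_occurring_pairs: list[tuple[str, str]]


def linkage_summary(matrix: MutationSpotMatrix) -> LinkageSummary:
    """Co-occurrence structure over mutant cells only.

    Two mutations co-occur when at least one spot carries mutant reads
    for both; such mutations are linked and consistent with a single
    clone.
    """
    mutant = matrix.states == "mutant"
    per_spot = mutant.sum(axis=0)
    per_mut = mutant.sum(axis=1)
    pairs: set[tuple[str, str]] = set()
    for barcode in per_spot.index[per_spot >= 2]:
        carried = sorted(mutant.index[mutant[barcode]])
        for i, a in enumerate(carried):
            for b in carried[i + 1:]:
                pairs.add((a, b))
    return LinkageSummary(
        int((per_spot >= 2).sum()),
        int((per_mut >= 2).sum()),
        sorted(pairs),
    )
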