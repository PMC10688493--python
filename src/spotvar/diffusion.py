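"""Background-signal quantification for mRNA diffusion on a Visium array.

During hybridization some mRNA diffuses away from the tissue, so spots not
covered by tissue still capture trace reads. To judge whether mutant reads
seen in histologically benign tissue could be diffusion artifacts, spots
are grouped into non-tissue, benign-tissue, and tumor-tissue regions and
the density of mutant spots per mm^2 is compared between groups with exact
Poisson confidence intervals. A density in benign tissue well above the
off-tissue background argues against diffusion as the source.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .io import SpotLayout

__all__ = [
    "REGIONS",
    "RegionSummary",
    "assign_regions",
    "spot_area_mm2",
    "region_summary",
    "poisson_ci",
    "density_fold",
]

REGIONS = ("non_tissue", "benign_tissue", "tumor_tissue")

MUTANT_CATEGORIES = ("mutant_1", "mutant_ge2")


@dataclass(frozen=True)
class RegionSummary:
    """Per-region read totals and mutant-spot density with a 95% CI."""

    region: str
    n_spots: int
    total_reads: int
    median_reads_per_spot: float
    n_mutant_spots: int
    area_mm2: float
    mutant_spot_density: float
    ci95: tuple[float, float]


def assign_regions(
    layout: SpotLayout, region_map: Mapping[str, str] | None = None
) -> pd.Series:
    """Partition layout spots into the three region labels.

    Defaults: spots with ``in_tissue == 0`` are ``non_tissue``, in-tissue
    spots are ``benign_tissue``; ``region_map`` (barcode -> region)
    overrides, typically supplying the tumor mask.
    """
    regions = pd.Series(
        np.where(layout.in_tissue, "benign_tissue", "non_tissue"),
        index=layout.barcodes,
        name="region",
    )
    if region_map:
        for barcode, label in region_map.items():
            if label not in REGIONS:
                raise ValueError(
                    f"unknown region label {label!r} (expected one of {REGIONS})"
                )
            if barcode not in layout:
                raise ValueError(f"region map barcode {barcode!r} not in layout")
            regions.loc[barcode] = label
    return regions


def spot_area_mm2(
    area_model: str = "hex_cell",
    pitch_um: float = 100.0,
    spot_diameter_um: float = 55.0,
) -> float:
    """Tissue area attributed to one spot, in mm^2.

    ``hex_cell`` uses the hexagonal lattice unit cell at the array pitch
    (sqrt(3)/2 * pitch^2 ~= 0.00866 mm^2 at 100 um), i.e. the area of
    array the spot tiles; ``spot_disc`` uses the capture disc itself
    (pi * r^2 ~= 0.00238 mm^2 at 55 um diameter).
    """
    if area_model == "hex_cell":
        pitch_mm = pitch_um / 1000.0
        return math.sqrt(3.0) / 2.0 * pitch_mm**2
    if area_model == "spot_disc":
        r_mm = spot_diameter_um / 2000.0
        return math.pi * r_mm**2
    raise ValueError(f"unknown area model {area_model!r}")


def poisson_ci(k: int, exposure: float, level: float = 0.95) -> tuple[float, float]:
    """Exact (Garwood) confidence interval for a Poisson rate.

    ``low = qchisq(alpha/2, 2k) / 2 / exposure`` (0 when k = 0) and
    ``high = qchisq(1 - alpha/2, 2k + 2) / 2 / exposure``.
    """
    if exposure <= 0:
        raise ValueError("exposure must be positive")
    if k < 0 or k != int(k):
        raise ValueError("k must be a non-negative integer")
    k = int(k)
    alpha = 1.0 - level
    low = 0.0 if k == 0 else chi2.ppf(alpha / 2.0, 2 * k) / 2.0 / exposure
    high = chi2.ppf(1.0 - alpha / 2.0, 2 * k + 2) / 2.0 / exposure
    return (float(low), float(high))


def region_summary(
    regions: pd.Series,
    umi_matrix: pd.DataFrame,
    classifications: pd.DataFrame,
    area_model: str = "hex_cell",
    pitch_um: float = 100.0,
    spot_diameter_um: float = 55.0,
    level: float = 0.95,
) -> list[RegionSummary]:
    """Summarize each non-empty region: reads, mutant spots, density + CI.

    ``regions`` is the :func:`assign_regions` partition; reads per spot
    come from the UMI matrix column sums (spots absent from the matrix
    count zero reads); mutant spots are those classified ``mutant_1`` or
    ``mutant_ge2``.
    """
    per_area = spot_area_mm2(area_model, pitch_um, spot_diameter_um)
    reads = umi_matrix.sum(axis=0).reindex(regions.index, fill_value=0)
    is_mutant = (
        classifications["category"].isin(MUTANT_CATEGORIES)
        .reindex(regions.index, fill_value=False)
    )
    out = []
    for region in REGIONS:
        mask = regions == region
        n = int(mask.sum())
        if n == 0:
            continue
        area = n * per_area
        if area <= 0:
            raise ValueError(f"region {region} has zero area")
        k = int(is_mutant[mask].sum())
        density = k / area
        out.append(
            RegionSummary(
                region=region,
                n_spots=n,
                total_reads=int(reads[mask].sum()),
                median_reads_per_spot=float(reads[mask].median()),
                n_mutant_spots=k,
                area_mm2=area,
                mutant_spot_density=density,
                ci95=poisson_ci(k, area, level),
            )
        )
    return out


def summary_table(summaries: list[RegionSummary]) -> pd.DataFrame:
    rows = []
    for s in summaries:
        rows.append(
            {
                "region": s.region,
                "n_spots": s.n_spots,
                "total_reads": s.total_reads,
                "median_reads_per_spot": s.median_reads_per_spot,
                "n_mutant_spots": s.n_mutant_spots,
                "area_mm2": s.area_mm2,
                "mutant_spot_density": s.mutant_spot_density,
                "ci95_low": s.ci95[0],
                "ci95_high": s.ci95[1],
            }
        )
    return pd.DataFrame(rows)


def density_fold(
    numer: "RegionSummary | float", denom: "RegionSummary | float"
) -> tuple[float, int]:
    """Ratio of mutant-spot densities, plus its nearest-integer rounding.

    Accepts :class:`RegionSummary` objects or raw densities.
    """
    a = numer.mutant_spot_density if isinstance(numer, RegionSummary) else float(numer)
    b = denom.mutant_spot_density if isinstance(denom, RegionSummary) else float(denom)
    if b <= 0:
        raise ValueError(
            "denominator density is zero; report the two densities separately "
            "instead of a fold change"
        )
    fold = a / b
    return fold, int(round(fold))
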