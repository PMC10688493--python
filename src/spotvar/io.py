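"""Readers and writers for the standard Visium-adjacent file formats.

Covers spot layout tables (both the headerless v1 and headered v2
``tissue_positions`` dialects emitted by Space Ranger), gene x spot UMI
matrices (MatrixMarket triplet directories and dense CSV), per-barcode
cluster tables, variant site lists, per-arm DNA copy-number profiles
(plain TSV or CNVkit-style ``.cns`` segments), gene annotations with
chromosome-arm assignments, and Loupe-browser category CSVs.

Conventions
-----------
* Variant positions are 1-based (VCF-style) in every user-facing table;
  interval arithmetic internal to the package is half-open 0-based.
* Barcodes are preserved verbatim, including any ``-1`` style suffix, so
  category exports re-import into Loupe bit-exactly.
* All writers emit deterministically sorted rows.
"""

from __future__ import annotations

import csv
import gzip
import io as _io
import os
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

__all__ = [
    "SpotLayout",
    "VariantSite",
    "SOMATIC",
    "GERMLINE_SNP",
    "read_spot_layout",
    "write_spot_layout",
    "read_umi_matrix",
    "write_umi_matrix_mtx",
    "write_umi_matrix_csv",
    "read_clusters",
    "write_loupe_categories",
    "read_loupe_categories",
    "read_variant_sites",
    "write_variant_sites",
    "read_gene_annotation",
    "write_gene_annotation",
    "read_arm_profile",
    "write_arm_profile",
    "arm_profile_from_cns",
    "validate_arm_profile",
]

SOMATIC = "somatic"
GERMLINE_SNP = "germline_snp"

_BASES = frozenset("ACGT")

# the 6 lattice neighbours of a Visium spot in (array_row, array_col) offsets
HEX_NEIGHBOR_OFFSETS = ((0, 2), (0, -2), (1, 1), (1, -1), (-1, 1), (-1, -1))


@dataclass(frozen=True)
class VariantSite:
    """A single-nucleotide variant site, 1-based.

    ``kind`` distinguishes somatic mutations (tumor-private) from germline
    heterozygous SNPs; the two feed different downstream analyses.
    """

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    kind: str = SOMATIC

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        for name in ("ref_allele", "alt_allele"):
            base = getattr(self, name)
            if len(base) != 1 or base.upper() not in _BASES:
                raise ValueError(f"{name} must be a single base, got {base!r}")
        if self.ref_allele.upper() == self.alt_allele.upper():
            raise ValueError(
                f"ref and alt must differ at {self.chrom}:{self.pos}"
            )
        if self.kind not in (SOMATIC, GERMLINE_SNP):
            raise ValueError(f"unknown site kind {self.kind!r}")

    @property
    def label(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref_allele}>{self.alt_allele}"


class SpotLayout:
    """Spot barcodes with their array (hex-lattice) and pixel coordinates.

    Wraps a DataFrame indexed by barcode with columns ``in_tissue``,
    ``array_row``, ``array_col``, ``pixel_row``, ``pixel_col`` and an
    optional nullable ``cluster``.
    """

    REQUIRED = ("in_tissue", "array_row", "array_col", "pixel_row", "pixel_col")

    def __init__(self, df: pd.DataFrame):
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate barcodes in layout: {dups}")
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise ValueError(f"layout missing columns: {missing}")
        df = df.copy()
        df["in_tissue"] = df["in_tissue"].astype(bool)
        df["array_row"] = df["array_row"].astype(int)
        df["array_col"] = df["array_col"].astype(int)
        if (df["array_row"] < 0).any() or (df["array_col"] < 0).any():
            raise ValueError("array coordinates must be non-negative")
        if "cluster" not in df.columns:
            df["cluster"] = pd.array([pd.NA] * len(df), dtype="Int64")
        else:
            df["cluster"] = df["cluster"].astype("Int64")
        self.df = df
        self._coord_to_barcode = {
            (r, c): b
            for b, r, c in zip(df.index, df["array_row"], df["array_col"])
        }

    def __len__(self) -> int:
        return len(self.df)

    def __contains__(self, barcode: str) -> bool:
        return barcode in self.df.index

    @property
    def barcodes(self) -> pd.Index:
        return self.df.index

    @property
    def in_tissue(self) -> pd.Series:
        return self.df["in_tissue"]

    @property
    def clusters(self) -> pd.Series:
        return self.df["cluster"]

    def neighbors(self, barcode: str) -> list[str]:
        """The (up to 6) lattice neighbours of a spot present in the layout."""
        row = self.df.loc[barcode]
        r, c = int(row["array_row"]), int(row["array_col"])
        out = []
        for dr, dc in HEX_NEIGHBOR_OFFSETS:
            hit = self._coord_to_barcode.get((r + dr, c + dc))
            if hit is not None:
                out.append(hit)
        return out

    def with_clusters(self, clusters: Mapping[str, int] | pd.Series) -> "SpotLayout":
        """Return a copy with per-barcode cluster labels attached."""
        ser = pd.Series(clusters)
        unknown = ser.index.difference(self.df.index)
        if len(unknown):
            raise ValueError(f"cluster barcodes not in layout: {list(unknown[:5])}")
        df = self.df.copy()
        df["cluster"] = pd.array([pd.NA] * len(df), dtype="Int64")
        df.loc[ser.index, "cluster"] = ser.astype(int).values
        return SpotLayout(df)


_LAYOUT_COLS = ("barcode",) + SpotLayout.REQUIRED


def _opener(path):
    path = os.fspath(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_spot_layout(path) -> SpotLayout:
    """Parse a tissue-positions table (headerless v1 or headered v2).

    Six comma-separated columns: barcode, in_tissue, array_row, array_col,
    pixel_row, pixel_col. The header row is auto-detected.
    """
    rows = []
    with _opener(path) as fh:
        reader = csv.reader(fh)
        for lineno, rec in enumerate(reader, start=1):
            if not rec or (len(rec) == 1 and not rec[0].strip()):
                continue
            if lineno == 1 and rec[0].strip().lower() == "barcode":
                continue  # headered (v2) dialect
            if len(rec) != 6:
                raise ValueError(
                    f"{path}: line {lineno}: expected 6 columns, got {len(rec)}"
                )
            barcode = rec[0].strip()
            try:
                in_tissue = int(rec[1])
                if in_tissue not in (0, 1):
                    raise ValueError
                vals = (
                    in_tissue,
                    int(rec[2]),
                    int(rec[3]),
                    float(rec[4]),
                    float(rec[5]),
                )
            except ValueError:
                raise ValueError(f"{path}: line {lineno}: malformed row {rec!r}")
            rows.append((barcode,) + vals)
    df = pd.DataFrame(rows, columns=_LAYOUT_COLS).set_index("barcode")
    return SpotLayout(df)


def write_spot_layout(layout: SpotLayout, path, header: bool = True) -> None:
    df = layout.df.reset_index()[list(_LAYOUT_COLS)].copy()
    df["in_tissue"] = df["in_tissue"].astype(int)
    df.to_csv(path, index=False, header=header)


# ---------------------------------------------------------------------------
# UMI matrices
# ---------------------------------------------------------------------------


def _read_lines(path) -> list[str]:
    with _opener(path) as fh:
        return [ln.rstrip("\n") for ln in fh if ln.strip()]


def _find_one(directory: Path, stems: Sequence[str]) -> Path:
    for stem in stems:
        for suffix in ("", ".gz"):
            cand = directory / (stem + suffix)
            if cand.exists():
                return cand
    raise FileNotFoundError(f"none of {stems} found in {directory}")


def read_umi_matrix(path) -> pd.DataFrame:
    """Read a gene x spot UMI count matrix.

    Accepts either a MatrixMarket triplet directory (``matrix.mtx`` plus
    ``features.tsv``/``genes.tsv`` and ``barcodes.tsv``, optionally
    gzipped) or a dense CSV with gene ids in the first column and one
    column per barcode. Returns an int64 DataFrame (genes x spots).
    """
    path = Path(path)
    if path.is_dir():
        mtx = _find_one(path, ("matrix.mtx",))
        feats = _find_one(path, ("features.tsv", "genes.tsv"))
        bcs = _find_one(path, ("barcodes.tsv",))
        mat = scipy.io.mmread(os.fspath(mtx))
        genes = [ln.split("\t")[0] for ln in _read_lines(feats)]
        barcodes = _read_lines(bcs)
        if mat.shape != (len(genes), len(barcodes)):
            raise ValueError(
                f"matrix shape {mat.shape} does not match "
                f"{len(genes)} genes x {len(barcodes)} barcodes"
            )
        dense = np.asarray(mat.todense() if scipy.sparse.issparse(mat) else mat)
        df = pd.DataFrame(dense, index=genes, columns=barcodes)
    else:
        df = pd.read_csv(path, index_col=0)
    arr = df.to_numpy()
    if (arr < 0).any():
        raise ValueError("UMI matrix contains negative entries")
    if not np.allclose(arr, np.round(arr)):
        raise ValueError("UMI matrix contains non-integer entries")
    if df.index.has_duplicates:
        raise ValueError("duplicate gene ids in UMI matrix")
    if df.columns.has_duplicates:
        raise ValueError("duplicate barcodes in UMI matrix")
    return df.astype(np.int64)


def write_umi_matrix_mtx(matrix: pd.DataFrame, directory) -> None:
    """Write a genes x spots matrix as a MatrixMarket triplet directory."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    coo = scipy.sparse.coo_matrix(matrix.to_numpy(dtype=np.int64))
    scipy.io.mmwrite(os.fspath(directory / "matrix.mtx"), coo, field="integer")
    (directory / "features.tsv").write_text(
        "".join(f"{g}\n" for g in matrix.index)
    )
    (directory / "barcodes.tsv").write_text(
        "".join(f"{b}\n" for b in matrix.columns)
    )


def write_umi_matrix_csv(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path)


def read_clusters(path) -> pd.Series:
    """Read a barcode -> cluster table (CSV, header ``Barcode,Cluster``)."""
    df = pd.read_csv(path)
    df.columns = [c.strip().lower() for c in df.columns]
    if not {"barcode", "cluster"} <= set(df.columns):
        raise ValueError(f"{path}: expected Barcode,Cluster columns")
    ser = df.set_index("barcode")["cluster"].astype(int)
    if ser.index.has_duplicates:
        raise ValueError(f"{path}: duplicate barcodes")
    if (ser < 1).any():
        raise ValueError(f"{path}: cluster labels must be >= 1")
    return ser


# ---------------------------------------------------------------------------
# Loupe category exports
# ---------------------------------------------------------------------------


def write_loupe_categories(
    assignments: Mapping[str, str], path, layout: SpotLayout | None = None
) -> None:
    """Write a Loupe-importable ``Barcode,Category`` CSV, barcode-sorted.

    When a layout is supplied every assigned barcode must exist in it.
    """
    if layout is not None:
        unknown = sorted(b for b in assignments if b not in layout)
        if unknown:
            raise ValueError(f"barcodes not in layout: {unknown}")
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["Barcode", "Category"])
        for barcode in sorted(assignments):
            writer.writerow([barcode, str(assignments[barcode])])


def read_loupe_categories(path) -> dict[str, str]:
    df = pd.read_csv(path)
    if list(df.columns[:2]) != ["Barcode", "Category"]:
        raise ValueError(f"{path}: expected 'Barcode,Category' header")
    return dict(zip(df["Barcode"].astype(str), df["Category"].astype(str)))


# ---------------------------------------------------------------------------
# Variant site lists
# ---------------------------------------------------------------------------

_SITE_COLS = ("chrom", "pos", "ref", "alt")


def read_variant_sites(path, kind: str = SOMATIC) -> list[VariantSite]:
    """Read a tab-delimited site list with columns chrom, pos, ref, alt.

    Extra columns (DNA depths etc.) are ignored here; the allelic-imbalance
    module reads them through :func:`pandas.read_csv` directly.
    """
    df = pd.read_csv(path, sep="\t")
    df.columns = [c.strip().lower() for c in df.columns]
    missing = [c for c in _SITE_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    sites = [
        VariantSite(str(r.chrom), int(r.pos), str(r.ref), str(r.alt), kind)
        for r in df.itertuples()
    ]
    return sites


def write_variant_sites(sites: Iterable[VariantSite], path) -> None:
    rows = sorted(
        ((s.chrom, s.pos, s.ref_allele, s.alt_allele) for s in sites),
        key=lambda t: (t[0], t[1]),
    )
    pd.DataFrame(rows, columns=_SITE_COLS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Gene annotation and per-arm DNA copy-number profiles
# ---------------------------------------------------------------------------

ARM_DIRECTIONS = ("gain", "loss", "neutral")


def read_gene_annotation(path, default_prior: float = 0.5) -> pd.DataFrame:
    """Read a gene annotation TSV: gene_id, chrom, arm, start, end
    [, prior_weight].

    ``prior_weight`` in [0, 1] carries an externally derived
    expression-vs-copy-number correlation prior; absent values default to
    ``default_prior``.
    """
    df = pd.read_csv(path, sep="\t")
    df.columns = [c.strip().lower() for c in df.columns]
    required = ["gene_id", "chrom", "arm", "start", "end"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    if df["gene_id"].duplicated().any():
        raise ValueError(f"{path}: duplicate gene ids")
    if "prior_weight" not in df.columns:
        df["prior_weight"] = default_prior
    df["prior_weight"] = df["prior_weight"].fillna(default_prior).astype(float)
    if ((df["prior_weight"] < 0) | (df["prior_weight"] > 1)).any():
        raise ValueError(f"{path}: prior_weight outside [0, 1]")
    bad = df[~df.apply(lambda r: str(r["arm"]).startswith(str(r["chrom"]).removeprefix("chr")), axis=1)]
    if len(bad):
        raise ValueError(
            f"{path}: arm inconsistent with chrom for genes {bad['gene_id'].tolist()[:5]}"
        )
    return df.set_index("gene_id")


def write_gene_annotation(ann: pd.DataFrame, path) -> None:
    ann.reset_index().to_csv(path, sep="\t", index=False)


def validate_arm_profile(profile: Mapping[str, str], arms: Iterable[str] | None = None) -> dict[str, str]:
    prof = {str(a): str(d) for a, d in profile.items()}
    bad = {a: d for a, d in prof.items() if d not in ARM_DIRECTIONS}
    if bad:
        raise ValueError(f"invalid arm directions: {bad}")
    if arms is not None:
        known = set(arms)
        unknown = sorted(set(prof) - known)
        if unknown:
            raise ValueError(f"profile arms not in annotation: {unknown}")
    if all(d == "neutral" for d in prof.values()):
        raise ValueError("DNA profile has no non-neutral arm; nothing to score")
    return prof


def read_arm_profile(path, arms: Iterable[str] | None = None) -> dict[str, str]:
    """Read an arm -> direction TSV (directions gain/loss/neutral)."""
    df = pd.read_csv(path, sep="\t")
    df.columns = [c.strip().lower() for c in df.columns]
    if not {"arm", "direction"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns arm, direction")
    if df["arm"].duplicated().any():
        raise ValueError(f"{path}: duplicate arms")
    return validate_arm_profile(
        dict(zip(df["arm"].astype(str), df["direction"].astype(str))), arms
    )


def write_arm_profile(profile: Mapping[str, str], path) -> None:
    pd.DataFrame(
        sorted(profile.items()), columns=["arm", "direction"]
    ).to_csv(path, sep="\t", index=False)


def arm_profile_from_cns(
    path, gene_annotation: pd.DataFrame, threshold: float = 0.1
) -> dict[str, str]:
    """Reduce a CNVkit-style ``.cns`` segment table to per-arm calls.

    Arm intervals are taken as the span of annotated genes on each arm.
    Each arm's log2 value is the overlap-length-weighted mean of the
    segments intersecting it; arms above ``+threshold`` are gains, below
    ``-threshold`` losses, otherwise neutral.
    """
    seg = pd.read_csv(path, sep="\t")
    seg.columns = [c.strip().lower() for c in seg.columns]
    required = {"chromosome", "start", "end", "log2"}
    if not required <= set(seg.columns):
        raise ValueError(f"{path}: expected columns {sorted(required)}")
    arm_spans = (
        gene_annotation.groupby("arm")
        .agg(chrom=("chrom", "first"), start=("start", "min"), end=("end", "max"))
    )
    profile: dict[str, str] = {}
    for arm, span in arm_spans.iterrows():
        hits = seg[seg["chromosome"].astype(str) == str(span["chrom"])]
        weights, values = [], []
        for r in hits.itertuples():
            ov = min(int(r.end), int(span["end"])) - max(int(r.start), int(span["start"]) - 1)
            if ov > 0:
                weights.append(ov)
                values.append(float(r.log2))
        if not weights:
            profile[arm] = "neutral"
            continue
        mean_log2 = float(np.average(values, weights=weights))
        if mean_log2 > threshold:
            profile[arm] = "gain"
        elif mean_log2 < -threshold:
            profile[arm] = "loss"
        else:
            profile[arm] = "neutral"
    return profile
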