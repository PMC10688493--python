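"""Seeded synthetic Visium-style fixtures.

Generates every input the pipeline consumes — hex-lattice spot layouts,
negative-binomial UMI matrices with planted arm-level copy-number shifts
(and, optionally, a co-regulated lineage-gene block that is *not* a CNA),
per-site read counts with configurable allele fractions, candidate
heterozygous-SNP tables, and miniature barcode-tagged BAMs over a toy
reference — so every analysis is testable without downloading anything.

The defaults emulate the two coverage regimes of real fresh-frozen
Visium cSCC data (~15,000 and ~1300 UMIs per spot; the default sits at
5000, the rescue-pool operating point), heterozygous somatic mutations
(VAF 0.5 in tumor spots, 0 elsewhere), and faint off-tissue background
from mRNA diffusion.

Everything is deterministic under a fixed seed, and each generator
returns a truth record sufficient to score recovery without re-deriving
simulation internals.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

from .io import GERMLINE_SNP, SOMATIC, SpotLayout, VariantSite

__all__ = [
    "ArmSpec",
    "CoregBlock",
    "SimSite",
    "SimulationConfig",
    "make_layout",
    "tumor_mask",
    "simulate_umi_matrix",
    "default_somatic_sites",
    "default_snp_sites",
    "simulate_site_reads",
    "simulate_snp_records",
    "write_fixture_bam",
    "generate_bundle",
    "SimulationBundle",
]


@dataclass(frozen=True)
class ArmSpec:
    """One chromosome arm: gene count and the log2 shift planted in tumor
    spots (0 = copy-neutral)."""

    name: str
    n_genes: int = 40
    tumor_shift: float = 0.0


@dataclass(frozen=True)
class CoregBlock:
    """A co-regulated (lineage-specific, non-CNA) gene block.

    ``n_genes`` extra genes on ``arm`` are expressed ``2**shift``-fold
    higher in a subset of non-tumor spots, mimicking e.g. a keratin
    cluster — a confounder for expression-based CNV callers. Their
    annotation prior is set low, as reference cohorts show their
    expression does not track copy number.
    """

    arm: str
    n_genes: int = 30
    shift: float = 1.5
    spot_fraction: float = 0.3
    prior_weight: float = 0.1


@dataclass(frozen=True)
class SimSite:
    """A variant site with per-spot-type allele fractions.

    ``rate`` is the mean read depth per in-tissue spot. The alt-read
    fraction is ``vaf_tumor`` in tumor spots, ``vaf_normal`` in other
    tissue spots, and ``vaf_tumor`` in non-tissue spots (background reads
    diffuse out of the tumor); ``vaf_by_cluster`` overrides by layout
    cluster, which lets tests emulate clone-specific haplotypes
    (X-inactivation mosaics).
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    kind: str = SOMATIC
    rate: float = 1.0
    vaf_tumor: float = 0.5
    vaf_normal: float = 0.0
    vaf_by_cluster: tuple[tuple[int, float], ...] | None = None
    other_rate: float = 0.0

    def to_variant(self) -> VariantSite:
        return VariantSite(self.chrom, self.pos, self.ref, self.alt, self.kind)


_DEFAULT_ARMS = (
    ArmSpec("1p", 40, 0.0),
    ArmSpec("1q", 40, 0.0),
    ArmSpec("3p", 40, -0.3),
    ArmSpec("3q", 40, +0.3),
    ArmSpec("5q", 40, 0.0),
    ArmSpec("8q", 40, +0.3),
    ArmSpec("10q", 40, -0.3),
    ArmSpec("13q", 40, 0.0),
)


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs for one synthetic bundle; see module docstring for defaults'
    rationale."""

    seed: int = 0
    n_rows: int = 12
    n_cols: int = 12
    tumor_fraction: float = 0.5
    arms: tuple[ArmSpec, ...] = _DEFAULT_ARMS
    mean_umis_per_spot: float = 5000.0
    nb_dispersion: float = 0.1
    n_somatic_sites: int = 12
    somatic_site_rate: float = 1.0
    somatic_tumor_vaf: float = 0.5
    n_snp_sites: int = 8
    snp_site_rate: float = 2.0
    snp_tumor_major_fraction: float = 0.75
    background_read_rate: float = 0.02
    coreg_block: CoregBlock | None = None


def _barcode(i: int) -> str:
    """Deterministic 16-mer barcode for spot index i, '-1' suffixed."""
    bases = "ACGT"
    digits = []
    for _ in range(16):
        digits.append(bases[i % 4])
        i //= 4
    return "".join(reversed(digits)) + "-1"


def make_layout(cfg: SimulationConfig) -> SpotLayout:
    """Hex lattice with the Visium row-parity convention.

    Row r holds columns ``r % 2, r % 2 + 2, ...`` so every interior spot
    has exactly 6 lattice neighbours. The outermost ring is annotated as
    non-tissue (for lattices at least 3x3).
    """
    if cfg.n_rows < 1 or cfg.n_cols < 1:
        raise ValueError("lattice dimensions must be >= 1")
    rows = []
    idx = 0
    border_ok = cfg.n_rows >= 3 and cfg.n_cols >= 3
    for r in range(cfg.n_rows):
        for j in range(cfg.n_cols):
            c = 2 * j + (r % 2)
            on_border = border_ok and (
                r in (0, cfg.n_rows - 1) or j in (0, cfg.n_cols - 1)
            )
            rows.append(
                {
                    "barcode": _barcode(idx),
                    "in_tissue": 0 if on_border else 1,
                    "array_row": r,
                    "array_col": c,
                    "pixel_row": 100.0 + 70.0 * r,
                    "pixel_col": 100.0 + 35.0 * c,
                }
            )
            idx += 1
    df = pd.DataFrame(rows).set_index("barcode")
    return SpotLayout(df)


def tumor_mask(cfg: SimulationConfig, layout: SpotLayout) -> set[str]:
    """Deterministic contiguous tumor region: the left portion of the
    in-tissue lattice, sized to ``tumor_fraction``."""
    tissue = layout.df[layout.in_tissue]
    if len(tissue) == 0 or cfg.tumor_fraction <= 0:
        return set()
    cut = np.quantile(tissue["array_col"], cfg.tumor_fraction)
    return set(tissue.index[tissue["array_col"] <= cut])


def _assign_clusters(
    layout: SpotLayout, tumor: set[str]
) -> SpotLayout:
    """Cluster 1 = tumor spots, cluster 2 = other tissue spots."""
    tissue = layout.df.index[layout.in_tissue]
    clusters = {b: (1 if b in tumor else 2) for b in tissue}
    return layout.with_clusters(clusters)


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    if dispersion <= 1e-9:
        return rng.poisson(mu)
    n = 1.0 / dispersion
    p = n / (n + mu)
    return rng.negative_binomial(n, p)


def simulate_umi_matrix(
    cfg: SimulationConfig,
    layout: SpotLayout,
    tumor: set[str] | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Negative-binomial gene x spot counts with planted arm shifts.

    Returns (matrix, gene_annotation, truth). Tumor spots draw genes on
    shifted arms with mean scaled by ``2**shift``; non-tissue spots
    receive ``background_read_rate`` of a tissue spot's depth. The
    optional co-regulated block upregulates its genes in a subset of
    non-tumor spots. Truth records the tumor mask, per-arm shifts, and
    block spots.
    """
    rng = rng or np.random.default_rng(cfg.seed)
    if tumor is None:
        tumor = tumor_mask(cfg, layout)

    gene_rows = []
    pos_cursor: dict[str, int] = {}
    for arm in cfg.arms:
        chrom = arm.name[:-1]
        for i in range(arm.n_genes):
            start = pos_cursor.get(arm.name, 1_000)
            gene_rows.append(
                {
                    "gene_id": f"{arm.name}_g{i:03d}",
                    "chrom": chrom,
                    "arm": arm.name,
                    "start": start,
                    "end": start + 2_000,
                    "prior_weight": 0.5,
                }
            )
            pos_cursor[arm.name] = start + 10_000
    block_genes: list[str] = []
    if cfg.coreg_block is not None:
        blk = cfg.coreg_block
        chrom = blk.arm[:-1]
        for i in range(blk.n_genes):
            start = pos_cursor.get(blk.arm, 1_000)
            gid = f"{blk.arm}_blk{i:03d}"
            gene_rows.append(
                {
                    "gene_id": gid,
                    "chrom": chrom,
                    "arm": blk.arm,
                    "start": start,
                    "end": start + 2_000,
                    "prior_weight": blk.prior_weight,
                }
            )
            pos_cursor[blk.arm] = start + 10_000
            block_genes.append(gid)
    ann = pd.DataFrame(gene_rows).set_index("gene_id")

    genes = ann.index
    n_genes = len(genes)
    # relative gene abundances: lognormal, normalized
    abundance = rng.lognormal(mean=0.0, sigma=1.0, size=n_genes)
    abundance /= abundance.sum()
    shift_by_arm = {a.name: a.tumor_shift for a in cfg.arms}
    gene_shift = np.array([shift_by_arm.get(a, 0.0) for a in ann["arm"]])

    barcodes = layout.barcodes
    tissue = layout.in_tissue.to_numpy()
    is_tumor = np.array([b in tumor for b in barcodes])

    non_tumor_tissue = [b for b, t, tu in zip(barcodes, tissue, is_tumor) if t and not tu]
    block_spots: set[str] = set()
    if cfg.coreg_block is not None and non_tumor_tissue:
        k = max(1, int(round(cfg.coreg_block.spot_fraction * len(non_tumor_tissue))))
        block_spots = set(non_tumor_tissue[:k])  # deterministic contiguous pick
    is_block_gene = np.array([g in set(block_genes) for g in genes])

    mat = np.zeros((n_genes, len(barcodes)), dtype=np.int64)
    for j, b in enumerate(barcodes):
        depth = cfg.mean_umis_per_spot * (1.0 if tissue[j] else cfg.background_read_rate)
        log2_fold = gene_shift * (1.0 if is_tumor[j] else 0.0)
        if b in block_spots and cfg.coreg_block is not None:
            log2_fold = log2_fold + is_block_gene * cfg.coreg_block.shift
        mu = depth * abundance * np.exp2(log2_fold)
        mat[:, j] = _nb_draw(rng, mu, cfg.nb_dispersion)
    matrix = pd.DataFrame(mat, index=genes, columns=barcodes)
    truth = {
        "tumor_spots": set(tumor),
        "arm_shifts": shift_by_arm,
        "block_spots": block_spots,
        "block_genes": list(block_genes),
    }
    return matrix, ann, truth


def default_somatic_sites(cfg: SimulationConfig) -> list[SimSite]:
    """Somatic SNVs on the toy contig, heterozygous in tumor spots."""
    bases = "ACGT"
    sites = []
    for i in range(cfg.n_somatic_sites):
        ref = bases[i % 4]
        alt = bases[(i + 1) % 4]
        sites.append(
            SimSite(
                chrom="sim1",
                pos=300 * (i + 1),
                ref=ref,
                alt=alt,
                kind=SOMATIC,
                rate=cfg.somatic_site_rate,
                vaf_tumor=cfg.somatic_tumor_vaf,
                vaf_normal=0.0,
            )
        )
    return sites


def default_snp_sites(cfg: SimulationConfig) -> list[SimSite]:
    """Germline heterozygous SNPs; tumor spots skewed toward the major
    (alt) allele, normal spots balanced."""
    bases = "ACGT"
    sites = []
    for i in range(cfg.n_snp_sites):
        ref = bases[(i + 2) % 4]
        alt = bases[(i + 3) % 4]
        sites.append(
            SimSite(
                chrom="sim2",
                pos=300 * (i + 1),
                ref=ref,
                alt=alt,
                kind=GERMLINE_SNP,
                rate=cfg.snp_site_rate,
                vaf_tumor=cfg.snp_tumor_major_fraction,
                vaf_normal=0.5,
            )
        )
    return sites


def simulate_site_reads(
    sites: Sequence[SimSite],
    layout: SpotLayout,
    tumor: set[str],
    background_read_rate: float = 0.02,
    rng: np.random.Generator | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Per (site, spot) truth counts.

    Depth ~ Poisson(rate) in tissue spots and Poisson(rate x background)
    off tissue; alt reads ~ Binomial(depth, vaf for the spot's type);
    ``other`` reads ~ Binomial(depth, other_rate) represent sequencing
    error. Zero-coverage pairs are omitted (absence = zero).
    """
    rng = rng or np.random.default_rng(seed)
    clusters = layout.clusters
    records = []
    for site in sites:
        vaf_override = dict(site.vaf_by_cluster or ())
        for b in layout.barcodes:
            tissue = bool(layout.in_tissue[b])
            depth = rng.poisson(site.rate * (1.0 if tissue else background_read_rate))
            if depth == 0:
                continue
            cl = clusters[b]
            if not pd.isna(cl) and int(cl) in vaf_override:
                vaf = vaf_override[int(cl)]
            elif b in tumor or not tissue:
                vaf = site.vaf_tumor
            else:
                vaf = site.vaf_normal
            n_other = rng.binomial(depth, site.other_rate) if site.other_rate else 0
            n_alt = rng.binomial(depth - n_other, vaf)
            n_ref = depth - n_other - n_alt
            records.append(
                (site.chrom, site.pos, site.ref, site.alt, b, n_ref, n_alt, n_other)
            )
    df = pd.DataFrame(
        records,
        columns=["chrom", "pos", "ref", "alt", "barcode",
                 "ref_count", "alt_count", "other_count"],
    )
    return df.sort_values(["chrom", "pos", "barcode"], kind="stable").reset_index(
        drop=True
    )


def simulate_snp_records(
    sites: Sequence[SimSite],
    rng: np.random.Generator | None = None,
    seed: int = 0,
    normal_depth: int = 50,
    pop_freq: float = 0.2,
    tumor_depth: int = 60,
) -> pd.DataFrame:
    """Candidate heterozygous-SNP table matching the germline sites.

    Tumor DNA counts are drawn at each site's tumor allele ratio, so the
    major-allele designation recovers the planted haplotype skew.
    """
    rng = rng or np.random.default_rng(seed + 17)
    rows = []
    for s in sites:
        n_alt = int(rng.binomial(tumor_depth, s.vaf_tumor))
        rows.append(
            {
                "chrom": s.chrom,
                "pos": s.pos,
                "ref": s.ref,
                "alt": s.alt,
                "normal_depth": normal_depth,
                "normal_vaf": float(np.clip(rng.normal(0.5, 0.02), 0.42, 0.58)),
                "pop_freq": pop_freq,
                "tumor_ref_count": tumor_depth - n_alt,
                "tumor_alt_count": n_alt,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Miniature tagged BAM over a toy reference
# ---------------------------------------------------------------------------

_OTHER_BASE = {frozenset("AC"): "G", frozenset("AG"): "C", frozenset("AT"): "C",
               frozenset("CG"): "A", frozenset("CT"): "A", frozenset("GT"): "A"}

READ_LENGTH = 60


def _toy_reference(
    sites: Sequence[SimSite], seed: int
) -> dict[str, str]:
    """Deterministic random contigs carrying the ref allele at each site."""
    rng = np.random.default_rng(seed + 101)
    contigs: dict[str, list[str]] = {}
    for chrom in sorted({s.chrom for s in sites}):
        length = max(s.pos for s in sites if s.chrom == chrom) + 2 * READ_LENGTH
        contigs[chrom] = list("".join(rng.choice(list("ACGT"), size=length)))
    for s in sites:
        contigs[s.chrom][s.pos - 1] = s.ref
    return {c: "".join(seq) for c, seq in contigs.items()}


def _make_read(
    header: pysam.AlignmentHeader,
    name: str,
    chrom: str,
    start0: int,
    seq: str,
    barcode: str,
    nm: int,
    umi: str,
    reverse: bool = False,
    mapq: int = 60,
    base_qual: int = 37,
    site_qpos: int | None = None,
    site_qual: int | None = None,
) -> pysam.AlignedSegment:
    read = pysam.AlignedSegment(header)
    read.query_name = name
    read.query_sequence = seq
    read.flag = 16 if reverse else 0
    read.reference_id = header.get_tid(chrom)
    read.reference_start = start0
    read.mapping_quality = mapq
    read.cigartuples = [(0, len(seq))]
    quals = [base_qual] * len(seq)
    if site_qpos is not None and site_qual is not None:
        quals[site_qpos] = site_qual
    read.query_qualities = pysam.qualitystring_to_array(
        "".join(chr(q + 33) for q in quals)
    )
    read.set_tag("CB", barcode)
    read.set_tag("UB", umi)
    read.set_tag("NM", nm)
    return read


def write_fixture_bam(
    table: pd.DataFrame,
    sites: Sequence[SimSite],
    out_dir,
    seed: int = 0,
    artifact_reads: Sequence[tuple[int, str, str]] = (),
) -> tuple[Path, Path]:
    """Emit an indexed, coordinate-sorted tagged BAM realizing ``table``.

    Every (site, spot) count row becomes that many 60 bp forward-strand
    reads carrying the spot barcode (CB), a unique UMI (UB), the correct
    NM edit distance, and base quality 37 — so counting the BAM with the
    default read filters reproduces ``table`` exactly.

    ``artifact_reads`` — (site index, barcode, kind) with kind in
    {orientation, base_quality, mismatch_fraction, mapping_quality} —
    plants alt-supporting reads that each violate exactly one default (or
    configurable) filter; they are absent from ``table`` by construction.

    Returns (bam path, reference FASTA path). The toy reference is
    generated from the seed and written alongside the BAM.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    contigs = _toy_reference(sites, seed)
    fasta = out_dir / "reference.fa"
    with open(fasta, "w") as fh:
        for chrom, seq in contigs.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i:i + 70] + "\n")
    pysam.faidx(os.fspath(fasta))

    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [{"SN": c, "LN": len(s)} for c, s in contigs.items()],
        }
    )
    site_list = list(sites)
    offsets = (5, 12, 19, 26, 33, 40, 47)
    serial = 0

    def reads_for(site: SimSite, barcode: str, base: str, n: int, **kw):
        nonlocal serial
        out = []
        ref_seq = contigs[site.chrom]
        pos0 = site.pos - 1
        for _ in range(n):
            off = offsets[serial % len(offsets)]
            start0 = max(0, min(pos0 - off, len(ref_seq) - READ_LENGTH))
            seq = list(ref_seq[start0:start0 + READ_LENGTH])
            qpos = pos0 - start0
            seq[qpos] = base
            nm = 0 if base == site.ref else 1
            out.append(
                _make_read(
                    header,
                    f"r{serial:07d}",
                    site.chrom,
                    start0,
                    "".join(seq),
                    barcode,
                    nm,
                    umi=f"U{serial:07d}",
                    site_qpos=qpos,
                    **kw,
                )
            )
            serial += 1
        return out

    all_reads: list[pysam.AlignedSegment] = []
    by_site = {(s.chrom, s.pos): s for s in site_list}
    for r in table.itertuples():
        site = by_site[(r.chrom, r.pos)]
        other = _OTHER_BASE[frozenset((site.ref, site.alt))]
        all_reads += reads_for(site, r.barcode, site.ref, int(r.ref_count))
        all_reads += reads_for(site, r.barcode, site.alt, int(r.alt_count))
        all_reads += reads_for(site, r.barcode, other, int(r.other_count))

    for site_idx, barcode, kind in artifact_reads:
        site = site_list[site_idx]
        kw: dict = {}
        if kind == "orientation":
            kw["reverse"] = True
        elif kind == "base_quality":
            kw["site_qual"] = 5
        elif kind == "mapping_quality":
            kw["mapq"] = 0
        elif kind != "mismatch_fraction":
            raise ValueError(f"unknown artifact kind {kind!r}")
        reads = reads_for(site, barcode, site.alt, 1, **kw)
        if kind == "mismatch_fraction":
            reads[0].set_tag("NM", 20)  # claims 1/3 of the read mismatched
        all_reads += reads

    unsorted = out_dir / "reads.unsorted.bam"
    with pysam.AlignmentFile(os.fspath(unsorted), "wb", header=header) as bam:
        for read in all_reads:
            bam.write(read)
    bam_path = out_dir / "reads.bam"
    pysam.sort("-o", os.fspath(bam_path), os.fspath(unsorted))
    unsorted.unlink()
    pysam.index(os.fspath(bam_path))
    return bam_path, fasta


@dataclass
class SimulationBundle:
    """Everything one seeded simulation produced, plus the truth."""

    config: SimulationConfig
    layout: SpotLayout
    tumor_spots: set[str]
    umi_matrix: pd.DataFrame
    gene_annotation: pd.DataFrame
    somatic_sites: list[SimSite]
    somatic_counts: pd.DataFrame
    snp_sites: list[SimSite]
    snp_counts: pd.DataFrame
    snp_records: pd.DataFrame
    truth: dict

    @property
    def somatic_variants(self) -> list[VariantSite]:
        return [s.to_variant() for s in self.somatic_sites]

    @property
    def snp_variants(self) -> list[VariantSite]:
        return [s.to_variant() for s in self.snp_sites]

    @property
    def dna_profile(self) -> dict[str, str]:
        """The planted per-arm DNA profile implied by the truth record."""
        out = {}
        for arm, shift in self.truth["arm_shifts"].items():
            out[arm] = "gain" if shift > 0 else ("loss" if shift < 0 else "neutral")
        return out


def generate_bundle(cfg: SimulationConfig) -> SimulationBundle:
    """Run the whole generator chain under one seed."""
    rng = np.random.default_rng(cfg.seed)
    layout = make_layout(cfg)
    tumor = tumor_mask(cfg, layout)
    layout = _assign_clusters(layout, tumor)
    matrix, ann, truth = simulate_umi_matrix(cfg, layout, tumor, rng)
    somatic = default_somatic_sites(cfg)
    snps = default_snp_sites(cfg)
    somatic_counts = simulate_site_reads(
        somatic, layout, tumor, cfg.background_read_rate, rng
    )
    snp_counts = simulate_site_reads(
        snps, layout, tumor, cfg.background_read_rate, rng
    )
    snp_records = simulate_snp_records(snps, rng)
    return SimulationBundle(
        config=cfg,
        layout=layout,
        tumor_spots=tumor,
        umi_matrix=matrix,
        gene_annotation=ann,
        somatic_sites=somatic,
        somatic_counts=somatic_counts,
        snp_sites=snps,
        snp_counts=snp_counts,
        snp_records=snp_records,
        truth=truth,
    )
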