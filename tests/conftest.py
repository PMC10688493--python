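"""Shared fixtures: hand-sized layouts, count tables, and tiny tagged BAMs
built read-by-read so alignment-level filters can be exercised precisely."""

from __future__ import annotations

import pandas as pd
import pysam
import pytest

from spotvar import simulate
from spotvar.io import SpotLayout


def make_layout(coords, in_tissue=None, clusters=None) -> SpotLayout:
    """Layout from [(barcode, array_row, array_col), ...]."""
    rows = []
    for i, (barcode, r, c) in enumerate(coords):
        rows.append(
            {
                "barcode": barcode,
                "in_tissue": 1 if in_tissue is None else int(in_tissue[i]),
                "array_row": r,
                "array_col": c,
                "pixel_row": 10.0 * r,
                "pixel_col": 10.0 * c,
            }
        )
    layout = SpotLayout(pd.DataFrame(rows).set_index("barcode"))
    if clusters is not None:
        layout = layout.with_clusters(clusters)
    return layout


@pytest.fixture
def three_spot_layout() -> SpotLayout:
    return make_layout([("B1", 0, 0), ("B2", 0, 2), ("B3", 1, 1)])


@pytest.fixture(scope="session")
def small_bundle() -> simulate.SimulationBundle:
    return simulate.generate_bundle(
        simulate.SimulationConfig(seed=3, n_rows=8, n_cols=8)
    )


class BamBuilder:
    """Assemble a small coordinate-sorted, indexed, barcode-tagged BAM."""

    def __init__(self, tmp_path, contigs=None):
        self.tmp_path = tmp_path
        self.contigs = contigs or {"chrT": 2000}
        self.header = pysam.AlignmentHeader.from_dict(
            {
                "HD": {"VN": "1.6"},
                "SQ": [{"SN": c, "LN": n} for c, n in self.contigs.items()],
            }
        )
        self.reads: list[pysam.AlignedSegment] = []
        self._n = 0

    def add_read(
        self,
        chrom="chrT",
        start0=80,
        seq="A" * 40,
        barcode="B1",
        qual=30,
        site_qpos=None,
        site_qual=None,
        mapq=60,
        reverse=False,
        nm=0,
        paired=False,
        proper_pair=True,
        tags=(),
    ):
        read = pysam.AlignedSegment(self.header)
        read.query_name = f"t{self._n:05d}"
        self._n += 1
        read.query_sequence = seq
        flag = 16 if reverse else 0
        if paired:
            flag |= 1 | (2 if proper_pair else 0) | 64
        read.flag = flag
        read.reference_id = self.header.get_tid(chrom)
        read.reference_start = start0
        read.mapping_quality = mapq
        read.cigartuples = [(0, len(seq))]
        quals = [qual] * len(seq)
        if site_qpos is not None and site_qual is not None:
            quals[site_qpos] = site_qual
        read.query_qualities = quals
        read.set_tag("CB", barcode)
        read.set_tag("NM", nm)
        for tag, value in tags:
            read.set_tag(tag, value)
        self.reads.append(read)
        return read

    def write(self, name="test.bam"):
        unsorted = self.tmp_path / ("unsorted_" + name)
        with pysam.AlignmentFile(str(unsorted), "wb", header=self.header) as bam:
            for read in self.reads:
                bam.write(read)
        path = self.tmp_path / name
        pysam.sort("-o", str(path), str(unsorted))
        unsorted.unlink()
        pysam.index(str(path))
        return path


@pytest.fixture
def bam_builder(tmp_path):
    return lambda **kw: BamBuilder(tmp_path, **kw)
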