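"""Shared fixtures: small hand-built panels and chromatin contexts."""

import pytest

from gwsalvage.io import (
    ChromatinContext,
    Contact,
    Fragment,
    GenomicInterval,
    GwasWave,
    LdPanel,
    SnpRecord,
)


@pytest.fixture
def toy_panel() -> LdPanel:
    """A: tight pair with B, loose with C; D isolated via E at 0.3."""
    return LdPanel(
        [
            ("A", "B", 0.9),
            ("A", "C", 0.5),
            ("B", "C", 0.5),
            ("D", "E", 0.3),
        ]
    )


def make_context(
    cell_type: str = "adipocyte",
    peaks=(),
    fragments=(),
    contacts=(),
) -> ChromatinContext:
    frs = {1: {f.fragment_id: f for f in fragments}}
    return ChromatinContext(cell_type, peaks, frs, contacts)


@pytest.fixture
def promoter_context() -> ChromatinContext:
    """One bait (gene G, open), one open other end holding a SNP at pos 1501,
    one closed other end, plus a second bait for bait-to-bait rows."""
    bait = Fragment(GenomicInterval("chr1", 0, 1000), "B1", True, ("G",))
    bait2 = Fragment(GenomicInterval("chr1", 3000, 4000), "B2", True, ("H",))
    oe_open = Fragment(GenomicInterval("chr1", 1000, 2000), "F1")
    oe_closed = Fragment(GenomicInterval("chr1", 2000, 3000), "F2")
    return make_context(
        peaks=[
            GenomicInterval("chr1", 100, 200),  # opens bait B1
            GenomicInterval("chr1", 1400, 1600),  # opens SNPs in F1
        ],
        fragments=[bait, bait2, oe_open, oe_closed],
        contacts=[
            Contact("B1", "F1", 6.0, 1),
            Contact("B1", "F2", 6.0, 1),
            Contact("B1", "B2", 6.0, 1),  # bait-to-bait
        ],
    )


def snp(rsid: str, pos: int, p: float = 1e-5, chrom: str = "chr1") -> SnpRecord:
    return SnpRecord(rsid=rsid, chrom=chrom, pos=pos, pvalue=p)


def wave(label: str, records, sample_size: int = 100_000) -> GwasWave:
    return GwasWave(label, sample_size, records)
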