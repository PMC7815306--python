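"""The variant-to-gene mapping constraint."""

import random

import pytest

from gwsalvage.chromatin import (
    ConstraintEngine,
    ConstraintResult,
    constrain_pool,
    is_open,
    map_variant_to_genes,
    negative_control_set,
)
from gwsalvage.io import (
    ChromatinContext,
    Contact,
    Fragment,
    GenomicInterval,
    SnpRecord,
)
from conftest import make_context, snp


class TestIsOpen:
    def test_one_bp_overlap_is_open(self):
        peaks = [GenomicInterval("chr1", 100, 200)]
        assert is_open(GenomicInterval("chr1", 199, 250), peaks)

    def test_half_open_adjacency_is_closed(self):
        peaks = [GenomicInterval("chr1", 100, 200)]
        assert not is_open(GenomicInterval("chr1", 200, 250), peaks)

    def test_snp_point_containment(self):
        peaks = [GenomicInterval("chr1", 100, 200)]
        assert is_open(("chr1", 150), peaks)  # 1-based pos 150 -> point 149
        assert is_open(("chr1", 200), peaks)  # point 199, last base of peak
        assert not is_open(("chr1", 201), peaks)
        assert not is_open(("chr2", 150), peaks)


class TestMapVariantToGenes:
    def test_open_snp_contacting_open_promoter_passes(self, promoter_context):
        res = map_variant_to_genes(snp("rs1", 1501), promoter_context, mhc=None)
        assert res.passed and res.contacted_genes == {"G"}

    def test_snp_in_baited_fragment_fails_in_promoter(self, promoter_context):
        res = map_variant_to_genes(snp("rs1", 150), promoter_context, mhc=None)
        assert not res.passed and res.failure_reason == "in-promoter"

    def test_bait_to_bait_only_contact_is_no_contact(self):
        bait1 = Fragment(GenomicInterval("chr1", 0, 1000), "B1", True, ("G",))
        bait2 = Fragment(GenomicInterval("chr1", 2000, 3000), "B2", True, ("H",))
        oe = Fragment(GenomicInterval("chr1", 1000, 2000), "F1")
        ctx = make_context(
            peaks=[GenomicInterval("chr1", 0, 3000)],
            fragments=[bait1, bait2, oe],
            contacts=[Contact("B1", "B2", 6.0, 1)],
        )
        res = map_variant_to_genes(snp("rs1", 1500), ctx, mhc=None)
        assert not res.passed and res.failure_reason == "no-contact"

    def test_closed_snp_fails_not_open(self, promoter_context):
        res = map_variant_to_genes(snp("rs1", 2500), promoter_context, mhc=None)
        assert res.failure_reason == "not-open"

    def test_closed_promoter_fails_promoter_closed(self):
        bait = Fragment(GenomicInterval("chr1", 0, 1000), "B1", True, ("G",))
        oe = Fragment(GenomicInterval("chr1", 1000, 2000), "F1")
        ctx = make_context(
            peaks=[GenomicInterval("chr1", 1400, 1600)],  # SNP open, bait closed
            fragments=[bait, oe],
            contacts=[Contact("B1", "F1", 6.0, 1)],
        )
        res = map_variant_to_genes(snp("rs1", 1501), ctx, mhc=None)
        assert res.failure_reason == "promoter-closed"

    def test_mhc_exclusion(self, promoter_context):
        mhc = GenomicInterval("chr1", 1000, 2000)
        res = map_variant_to_genes(snp("rs1", 1501), promoter_context, mhc=mhc)
        assert res.failure_reason == "in-MHC"

    def test_chromosome_absent_from_fragment_map(self, promoter_context, caplog):
        ctx = promoter_context
        ctx.peaks.append(GenomicInterval("chrZ", 0, 100))
        with caplog.at_level("WARNING"):
            res = map_variant_to_genes(snp("rs1", 50, chrom="chrZ"), ctx, mhc=None)
        assert res.failure_reason == "no-contact"
        assert "chrZ" in caplog.text

    def test_min_contact_score_filters(self, promoter_context):
        res = map_variant_to_genes(
            snp("rs1", 1501), promoter_context, mhc=None, min_contact_score=10.0
        )
        assert res.failure_reason == "no-contact"

    def test_result_invariants_enforced(self):
        with pytest.raises(ValueError):
            ConstraintResult("rs1", "ct", passed=True)  # passed without genes
        with pytest.raises(ValueError):
            ConstraintResult("rs1", "ct", passed=False, failure_reason="bogus")


class TestResolutionUnion:
    def test_pass_via_four_fragment_resolution_alone(self):
        """A SNP whose only qualifying contact is in the 4-fragment map passes."""
        bait1 = Fragment(GenomicInterval("chr1", 0, 1000), "B1", True, ("G",))
        oe1 = Fragment(GenomicInterval("chr1", 1000, 2000), "F1")
        # 4-fragment map: coarser grouped intervals, its own id space
        bait4 = Fragment(GenomicInterval("chr1", 0, 4000), "Q1", True, ("G",))
        oe4 = Fragment(GenomicInterval("chr1", 4000, 8000), "Q2")
        ctx = ChromatinContext(
            "ct",
            peaks=[GenomicInterval("chr1", 0, 100), GenomicInterval("chr1", 4500, 4600)],
            fragments={1: {"B1": bait1, "F1": oe1}, 4: {"Q1": bait4, "Q2": oe4}},
            contacts=[Contact("Q1", "Q2", 7.0, 4)],  # only a long-range contact
        )
        res = map_variant_to_genes(snp("rs1", 4551), ctx, mhc=None)
        assert res.passed and res.contacted_genes == {"G"}


def brute_force_constraint(record, ctx, mhc):
    """Independent oracle: literal scan over peaks, fragments and contacts."""
    point0 = record.pos - 1
    if mhc is not None and mhc.contains_point(record.chrom, point0):
        return False
    if not any(p.contains_point(record.chrom, point0) for p in ctx.peaks):
        return False
    finest = min(ctx.fragments)
    for fr in ctx.fragments[finest].values():
        if fr.is_bait and fr.interval.contains_point(record.chrom, point0):
            return False
    for c in ctx.contacts:
        frs = ctx.fragments[c.resolution]
        oe, bait = frs[c.other_fragment_id], frs[c.bait_fragment_id]
        if oe.is_bait:
            continue
        if not oe.interval.contains_point(record.chrom, point0):
            continue
        if any(p.overlaps(bait.interval) for p in ctx.peaks):
            return True
    return False


def random_context(rng, n_frags=12):
    frags = {}
    genes = iter(f"G{i}" for i in range(n_frags))
    for i in range(n_frags):
        bait = rng.random() < 0.3
        frags[f"F{i}"] = Fragment(
            GenomicInterval("chr1", i * 100, (i + 1) * 100),
            f"F{i}",
            bait,
            (next(genes),) if bait else (),
        )
    baits = [f for f in frags.values() if f.is_bait]
    contacts = []
    if baits:
        for _ in range(8):
            b = rng.choice(baits)
            o = rng.choice(list(frags.values()))
            if o.fragment_id != b.fragment_id:
                contacts.append(Contact(b.fragment_id, o.fragment_id, 6.0, 1))
    peaks = [
        GenomicInterval("chr1", s, s + rng.randint(10, 120))
        for s in rng.sample(range(0, n_frags * 100 - 130, 10), 6)
    ]
    return ChromatinContext("ct", peaks, {1: frags}, contacts)


@pytest.mark.parametrize("seed", range(8))
def test_engine_agrees_with_brute_force_scan(seed):
    rng = random.Random(seed)
    ctx = random_context(rng)
    mhc = GenomicInterval("chr1", 150, 250) if seed % 2 else None
    records = [snp(f"rs{p}", p) for p in range(1, 1200, 13)]
    engine = ConstraintEngine(ctx, mhc=mhc)
    for rec in records:
        assert engine.evaluate(rec).passed == brute_force_constraint(rec, ctx, mhc), rec


class TestNegativeControl:
    def test_complement_partition(self, promoter_context):
        pool = [snp("rs_pass", 1501), snp("rs_fail", 2500), snp("rs_prom", 150)]
        results = constrain_pool(pool, promoter_context, mhc=None)
        passing = {r for r, cr in results.items() if cr.passed}
        negative = negative_control_set(pool, promoter_context, mhc=None)
        assert passing == {"rs_pass"}
        assert negative == {"rs_fail", "rs_prom"}
        assert passing | negative == {s.rsid for s in pool}
        assert not passing & negative

    def test_empty_pool(self, promoter_context):
        assert negative_control_set([], promoter_context, mhc=None) == set()

    def test_all_passing_pool(self, promoter_context):
        pool = [snp("rs1", 1501), snp("rs2", 1502)]
        assert negative_control_set(pool, promoter_context, mhc=None) == set()


def test_adding_peaks_is_monotone(promoter_context):
    """Opening more chromatin can only convert failures into passes."""
    pool = [snp(f"rs{p}", p) for p in range(1, 3000, 97)]
    before = constrain_pool(pool, promoter_context, mhc=None)
    wider = ChromatinContext(
        promoter_context.cell_type,
        promoter_context.peaks + [GenomicInterval("chr1", 0, 3000)],
        promoter_context.fragments,
        promoter_context.contacts,
    )
    after = constrain_pool(pool, wider, mhc=None)
    for rsid in before:
        if before[rsid].passed:
            assert after[rsid].passed
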