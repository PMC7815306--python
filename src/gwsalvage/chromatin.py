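"""The variant-to-gene mapping filter.

A sub-threshold SNP survives the chromatin constraint in a given cell type iff

* it does not fall within the MHC region,
* its position overlaps an open-chromatin (ATAC-seq) peak — a region is open
  if it has at least 1 bp of overlap with a peak,
* it does not itself reside in a baited (promoter) fragment, and
* it falls in the non-bait other-end fragment of at least one significant
  promoter interaction (at 1- or 4-fragment resolution) whose bait fragment
  also overlaps an open peak — i.e. both points of contact are open.

Bait-to-bait interactions (both ends baited) are never used: they connect two
promoters and cannot tie a non-coding variant to a target gene.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

from intervaltree import IntervalTree

from .io import ChromatinContext, GenomicInterval, MHC_HG19, SnpRecord

logger = logging.getLogger(__name__)

FAILURE_REASONS = ("in-MHC", "not-open", "in-promoter", "no-contact", "promoter-closed")


@dataclass(frozen=True, slots=True)
class ConstraintResult:
    """Outcome of the constraint for one SNP in one cell type."""

    rsid: str
    cell_type: str
    passed: bool
    contacted_genes: frozenset[str] = frozenset()
    failure_reason: str | None = None

    def __post_init__(self) -> None:
        if self.passed != bool(self.contacted_genes):
            raise ValueError("passed iff contacted_genes is non-empty")
        if not self.passed and self.failure_reason not in FAILURE_REASONS:
            raise ValueError(f"invalid failure_reason {self.failure_reason!r}")
        if self.passed and self.failure_reason is not None:
            raise ValueError("passed results carry no failure_reason")


def is_open(
    query: GenomicInterval | tuple[str, int], peaks: Iterable[GenomicInterval]
) -> bool:
    """Whether a region or SNP overlaps any peak by at least 1 bp.

    ``query`` is either a half-open 0-based interval or a ``(chrom, pos)``
    tuple with a 1-based SNP position.
    """
    if isinstance(query, tuple):
        chrom, pos = query
        return any(p.contains_point(chrom, pos - 1) for p in peaks)
    return any(p.overlaps(query) for p in peaks)


class ConstraintEngine:
    """Indexed evaluator of the chromatin constraint for one cell type.

    Builds interval indexes over peaks and fragment maps once, then evaluates
    SNPs in O(log n) lookups. ``min_contact_score`` optionally re-filters
    contacts (CHiCAGO output is normally already thresholded upstream).
    """

    def __init__(
        self,
        ctx: ChromatinContext,
        mhc: GenomicInterval | None = MHC_HG19,
        min_contact_score: float | None = None,
    ):
        self.ctx = ctx
        self.mhc = mhc
        self._peak_trees: dict[str, IntervalTree] = {}
        for p in ctx.peaks:
            self._peak_trees.setdefault(p.chrom, IntervalTree()).addi(p.start, p.end)
        # fragment interval index per resolution
        self._frag_trees: dict[int, dict[str, IntervalTree]] = {}
        for res, frs in ctx.fragments.items():
            trees: dict[str, IntervalTree] = {}
            for fr in frs.values():
                iv = fr.interval
                trees.setdefault(iv.chrom, IntervalTree()).addi(
                    iv.start, iv.end, fr.fragment_id
                )
            self._frag_trees[res] = trees
        # contacts grouped by (resolution, other-end fragment), bait-to-bait dropped
        self._contacts_by_oe: dict[tuple[int, str], list] = {}
        for c in ctx.contacts:
            if min_contact_score is not None and c.score < min_contact_score:
                continue
            frs = ctx.fragments[c.resolution]
            if frs[c.other_fragment_id].is_bait:
                continue  # bait-to-bait
            self._contacts_by_oe.setdefault(
                (c.resolution, c.other_fragment_id), []
            ).append(c)
        self._bait_open_cache: dict[tuple[int, str], bool] = {}
        self._warned_chroms: set[str] = set()

    def _point_open(self, chrom: str, point0: int) -> bool:
        tree = self._peak_trees.get(chrom)
        return bool(tree and tree[point0])

    def _interval_open(self, iv: GenomicInterval) -> bool:
        tree = self._peak_trees.get(iv.chrom)
        return bool(tree and tree.overlap(iv.start, iv.end))

    def _bait_open(self, resolution: int, bait_id: str) -> bool:
        key = (resolution, bait_id)
        if key not in self._bait_open_cache:
            fr = self.ctx.fragments[resolution][bait_id]
            self._bait_open_cache[key] = self._interval_open(fr.interval)
        return self._bait_open_cache[key]

    def _fragments_at(self, resolution: int, chrom: str, point0: int) -> list[str]:
        trees = self._frag_trees.get(resolution, {})
        tree = trees.get(chrom)
        if tree is None:
            return []
        return [hit.data for hit in tree[point0]]

    def evaluate(self, snp: SnpRecord) -> ConstraintResult:
        """Apply the full constraint to one SNP."""
        point0 = snp.pos - 1

        def fail(reason: str) -> ConstraintResult:
            return ConstraintResult(
                rsid=snp.rsid,
                cell_type=self.ctx.cell_type,
                passed=False,
                failure_reason=reason,
            )

        if self.mhc is not None and self.mhc.contains_point(snp.chrom, point0):
            return fail("in-MHC")
        if not self._point_open(snp.chrom, point0):
            return fail("not-open")

        # promoter residence is judged on the finest fragment map available
        finest = min(self._frag_trees) if self._frag_trees else None
        if finest is not None:
            frs = self.ctx.fragments[finest]
            if any(
                frs[fid].is_bait
                for fid in self._fragments_at(finest, snp.chrom, point0)
            ):
                return fail("in-promoter")

        if all(
            snp.chrom not in trees for trees in self._frag_trees.values()
        ) and self._frag_trees:
            if snp.chrom not in self._warned_chroms:
                self._warned_chroms.add(snp.chrom)
                logger.warning(
                    "%s: chromosome %s absent from the fragment map",
                    self.ctx.cell_type,
                    snp.chrom,
                )
            return fail("no-contact")

        genes: set[str] = set()
        saw_contact = False
        for res in self._frag_trees:
            for fid in self._fragments_at(res, snp.chrom, point0):
                if self.ctx.fragments[res][fid].is_bait:
                    continue
                for c in self._contacts_by_oe.get((res, fid), ()):
                    saw_contact = True
                    if self._bait_open(res, c.bait_fragment_id):
                        genes.update(self.ctx.fragments[res][c.bait_fragment_id].genes)
        if genes:
            return ConstraintResult(
                rsid=snp.rsid,
                cell_type=self.ctx.cell_type,
                passed=True,
                contacted_genes=frozenset(genes),
            )
        return fail("promoter-closed" if saw_contact else "no-contact")


def map_variant_to_genes(
    snp: SnpRecord,
    ctx: ChromatinContext,
    mhc: GenomicInterval | None = MHC_HG19,
    min_contact_score: float | None = None,
) -> ConstraintResult:
    """One-shot constraint evaluation (builds a throwaway index; use
    :class:`ConstraintEngine` for pools)."""
    return ConstraintEngine(ctx, mhc=mhc, min_contact_score=min_contact_score).evaluate(snp)


def constrain_pool(
    snps: Iterable[SnpRecord],
    ctx: ChromatinContext,
    mhc: GenomicInterval | None = MHC_HG19,
    min_contact_score: float | None = None,
) -> dict[str, ConstraintResult]:
    """Evaluate the constraint for a pool of SNPs in one cell type."""
    engine = ConstraintEngine(ctx, mhc=mhc, min_contact_score=min_contact_score)
    return {snp.rsid: engine.evaluate(snp) for snp in snps}


def negative_control_set(
    suggestive_pool: Iterable[SnpRecord],
    ctx: ChromatinContext,
    mhc: GenomicInterval | None = MHC_HG19,
    min_contact_score: float | None = None,
) -> set[str]:
    """The exact complement of the passing set within the pool: SNPs that are
    closed, promoter-residing, contact-free, or MHC-resident."""
    results = constrain_pool(suggestive_pool, ctx, mhc=mhc, min_contact_score=min_contact_score)
    return {rsid for rsid, res in results.items() if not res.passed}
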