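"""Retrospective evaluation: suggestive binning, future-wave classification of
loci, and confusion-matrix construction.

The suggestive stratum of a GWAS release is split into nested p-value bins
``5e-8 <= p < upper`` with upper in {5e-7, 5e-6, 5e-5, 5e-4}; each successive
bin contains the SNPs of every narrower bin. A salvaged locus is a true
positive when it is in tight LD (r² > 0.8) with a SNP that is genome-wide
significant in a future, larger release.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .io import GWS_P, GwasWave, LdPanel
from .ld import Locus

R2_TIGHT = 0.8


@dataclass(frozen=True, slots=True)
class SuggestiveBin:
    """Half-open p-value stratum ``lower <= p < upper``."""

    label: str
    upper: float
    lower: float = GWS_P

    def __post_init__(self) -> None:
        if not (0.0 < self.lower < self.upper <= 1.0):
            raise ValueError(f"invalid bin bounds [{self.lower}, {self.upper})")

    def contains(self, p: float) -> bool:
        return self.lower <= p < self.upper


#: The standard nested bins, narrowest first.
STANDARD_BINS: tuple[SuggestiveBin, ...] = (
    SuggestiveBin("5e-7", 5e-7),
    SuggestiveBin("5e-6", 5e-6),
    SuggestiveBin("5e-5", 5e-5),
    SuggestiveBin("5e-4", 5e-4),
)


@dataclass(frozen=True, slots=True)
class ConfusionCounts:
    """Locus-level confusion counts for one (bin, cell type) evaluation."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def predicted_positive(self) -> int:
        return self.tp + self.fp


def bin_suggestive(wave: GwasWave, sbin: SuggestiveBin) -> set[str]:
    """rsids of the wave whose p-value falls in the suggestive bin."""
    return {r for r, rec in wave.records.items() if sbin.contains(rec.pvalue)}


def classify_future(
    loci: Sequence[Locus],
    future: GwasWave,
    panel: LdPanel,
    r2_tight: float = R2_TIGHT,
    gws_p: float = GWS_P,
) -> dict[Locus, bool]:
    """Label each locus true when any member is, or is in tight LD
    (r² > ``r2_tight``) with, a SNP genome-wide significant in ``future``."""
    future_gws = future.gws_snps(gws_p)
    out: dict[Locus, bool] = {}
    for locus in loci:
        hit = False
        for m in locus.members:
            if m in future_gws or any(
                g in future_gws and r2 > r2_tight
                for g, r2 in panel.partners(m).items()
            ):
                hit = True
                break
        out[locus] = hit
    return out


def _matches(
    constrained: Locus, unconstrained: Locus, panel: LdPanel | None, r2_tight: float
) -> bool:
    if constrained.members & unconstrained.members:
        return True
    if panel is not None:
        for a in constrained.members:
            for b, r2 in panel.partners(a).items():
                if r2 > r2_tight and b in unconstrained.members:
                    return True
    return False


def build_confusion(
    constrained_labels: Mapping[Locus, bool],
    unconstrained_labels: Mapping[Locus, bool],
    panel: LdPanel | None = None,
    r2_tight: float = R2_TIGHT,
) -> ConfusionCounts:
    """Confusion counts over the unconstrained independent loci of a bin.

    Every unconstrained locus is one classification unit. A locus is
    predicted positive when at least one constrained locus matches it, by
    shared membership or (when a panel is given) tight-LD membership; its
    truth is its own future-GWS label. A constrained locus matching no
    unconstrained locus violates the construction (constrained survivors are
    a subset of the unconstrained pool) and raises ``ValueError``.
    """
    unmatched = dict.fromkeys(unconstrained_labels, False)
    for c in constrained_labels:
        hits = [u for u in unconstrained_labels if _matches(c, u, panel, r2_tight)]
        if not hits:
            raise ValueError(
                f"constrained locus {sorted(c.members)} has no unconstrained counterpart"
            )
        for u in hits:
            unmatched[u] = True
    tp = fp = fn = tn = 0
    for u, label in unconstrained_labels.items():
        predicted = unmatched[u]
        if predicted and label:
            tp += 1
        elif predicted:
            fp += 1
        elif label:
            fn += 1
        else:
            tn += 1
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)
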