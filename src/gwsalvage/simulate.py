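"""Synthetic LD panels, multi-wave GWAS summary statistics, and chromatin
contexts with the statistical structure the salvage analysis assumes.

The generative model is deliberately transparent rather than genetically
detailed:

* **LD** is block-diagonal: SNPs come in haplotype blocks; within-block pairs
  draw their r² from a configurable range, between-block r² is zero (a few
  cross-block pairs can be injected so the GWS-LD exclusion step has
  non-trivial work).
* **Association** uses the large-sample z-statistic approximation: a causal
  block's SNPs receive a noncentrality proportional to the block effect times
  the square root of the sample size, attenuated by each SNP's r² to the
  block's causal SNP; null SNPs are standard normal. Later waves reuse the
  per-SNP effects with fresh noise, so true signals strengthen with sample
  size and cross the genome-wide threshold as cohorts grow.
* **Chromatin** wiring is drawn per block and cell type: with probability
  ``enrichment x base rate`` (capped at 1) for causal blocks and the base
  rate for null blocks, the block's SNPs are placed in open other-end
  fragments contacting an open, baited gene promoter. SNPs in tight LD are
  physically clustered, so sharing the block's chromatin outcome mirrors the
  correlated accessibility of a regulatory neighbourhood.

All randomness flows from ``SimulationConfig.seed`` through named substreams,
so every artefact is reproducible from the single seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.stats import norm

from .io import (
    ChromatinContext,
    Contact,
    Fragment,
    GenomicInterval,
    GwasWave,
    LdPanel,
    SnpRecord,
    write_contacts,
    write_ld_table,
    write_peaks,
    write_summary_stats,
)

logger = logging.getLogger(__name__)

_STREAM_LD = 1
_STREAM_EFFECTS = 2
_STREAM_GWAS = 3
_STREAM_CHROMATIN = 4


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic retrospective experiment.

    Defaults emulate the 2010 -> 2018 BMI setting: two waves whose sample
    sizes grow ~2.7-fold, a block effect scale placing causal signals around
    the suggestive stratum in wave 1 (expected |z| ~ 4.2 at n = 249,796), and
    chromatin wiring 10x enriched at causal blocks over a 3% background.
    """

    n_blocks: int = 2000
    snps_per_block: int = 25
    within_block_r2_range: tuple[float, float] = (0.5, 0.95)
    n_causal_blocks: int = 80
    wave_sample_sizes: tuple[int, ...] = (249_796, 681_275)
    #: per-SNP association scale; wave noncentrality = scale * sqrt(n).
    causal_effect_scale: float = 4.2 / np.sqrt(249_796)
    #: relative (0.8-1.2) block-to-block effect heterogeneity half-width.
    effect_jitter: float = 0.2
    chromatin_enrichment: float = 10.0
    #: base probability that a null block is chromatin-wired, per cell type.
    peak_density: float = 0.03
    fragment_length: int = 1000
    cell_types: tuple[str, ...] = ("adipocyte", "hypothalamic_neuron")
    n_cross_block_pairs: int = 0
    cross_block_r2_range: tuple[float, float] = (0.1, 0.35)
    chrom: str = "chrS"
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_blocks, self.snps_per_block, self.fragment_length) < 1:
            raise ValueError("counts must be >= 1")
        if not (0 <= self.n_causal_blocks <= self.n_blocks):
            raise ValueError("n_causal_blocks must be within [0, n_blocks]")
        if self.chromatin_enrichment < 0:
            raise ValueError("chromatin_enrichment must be >= 0")
        lo, hi = self.within_block_r2_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError("within_block_r2_range must be within [0, 1]")
        if len(self.wave_sample_sizes) < 2 or any(
            b <= a for a, b in zip(self.wave_sample_sizes, self.wave_sample_sizes[1:])
        ):
            raise ValueError("wave_sample_sizes must be increasing, length >= 2")

    # -- block/SNP bookkeeping ------------------------------------------------

    @property
    def n_snps(self) -> int:
        return self.n_blocks * self.snps_per_block

    def rsid(self, block: int, i: int) -> str:
        return f"rs{block * self.snps_per_block + i + 1}"

    def block_of(self, rsid: str) -> int:
        return (int(rsid[2:]) - 1) // self.snps_per_block

    def block_snps(self, block: int) -> list[str]:
        return [self.rsid(block, i) for i in range(self.snps_per_block)]

    def causal_blocks(self) -> set[int]:
        return set(range(self.n_causal_blocks))

    def snp_position(self, block: int, i: int) -> int:
        """1-based position: each SNP sits mid-fragment, one fragment per SNP,
        after the block's bait fragment; one spacer fragment between blocks."""
        stride = self.snps_per_block + 2
        frag_index = block * stride + 1 + i
        return frag_index * self.fragment_length + self.fragment_length // 2 + 1

    def _rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence([self.seed, stream]))


def simulate_ld_panel(cfg: SimulationConfig) -> LdPanel:
    """Block-diagonal LD panel: all within-block pairs drawn from the
    configured r² range; optional cross-block pairs below the clustering
    threshold."""
    rng = cfg._rng(_STREAM_LD)
    lo, hi = cfg.within_block_r2_range
    panel = LdPanel()
    m = cfg.snps_per_block
    n_pairs = m * (m - 1) // 2
    for b in range(cfg.n_blocks):
        snps = cfg.block_snps(b)
        draws = rng.uniform(lo, hi, size=n_pairs)
        k = 0
        for i in range(m):
            for j in range(i + 1, m):
                panel.add_pair(snps[i], snps[j], float(draws[k]))
                k += 1
    for _ in range(cfg.n_cross_block_pairs):
        b1, b2 = rng.choice(cfg.n_blocks, size=2, replace=False)
        i1, i2 = rng.integers(0, m, size=2)
        panel.add_pair(
            cfg.rsid(int(b1), int(i1)),
            cfg.rsid(int(b2), int(i2)),
            float(rng.uniform(*cfg.cross_block_r2_range)),
        )
    return panel


def _per_snp_effects(cfg: SimulationConfig, panel: LdPanel) -> np.ndarray:
    """Per-SNP association scale: block effect attenuated by the SNP's r² to
    the block's causal SNP (the block's first SNP)."""
    rng = cfg._rng(_STREAM_EFFECTS)
    effects = np.zeros(cfg.n_snps)
    for b in cfg.causal_blocks():
        u = rng.uniform(1.0 - cfg.effect_jitter, 1.0 + cfg.effect_jitter)
        block_effect = cfg.causal_effect_scale * u
        causal = cfg.rsid(b, 0)
        for i, snp in enumerate(cfg.block_snps(b)):
            r2 = 1.0 if snp == causal else panel.r2(causal, snp)
            effects[b * cfg.snps_per_block + i] = block_effect * r2
    return effects


def simulate_two_wave_gwas(cfg: SimulationConfig, panel: LdPanel) -> list[GwasWave]:
    """Summary statistics for each configured wave.

    z_j(n) ~ Normal(effect_j * sqrt(n), 1) with a fresh noise draw per wave;
    p is the two-sided normal tail. With ``causal_effect_scale = 0`` the
    p-values are uniform on (0, 1).
    """
    effects = _per_snp_effects(cfg, panel)
    rng = cfg._rng(_STREAM_GWAS)
    positions = np.array(
        [
            cfg.snp_position(b, i)
            for b in range(cfg.n_blocks)
            for i in range(cfg.snps_per_block)
        ]
    )
    rsids = [
        cfg.rsid(b, i)
        for b in range(cfg.n_blocks)
        for i in range(cfg.snps_per_block)
    ]
    waves = []
    for w, n in enumerate(cfg.wave_sample_sizes):
        z = effects * np.sqrt(n) + rng.standard_normal(cfg.n_snps)
        p = np.minimum(2.0 * norm.sf(np.abs(z)), 1.0)
        p = np.maximum(p, np.finfo(float).tiny)
        records = (
            SnpRecord(rsid=rsids[j], chrom=cfg.chrom, pos=int(positions[j]), pvalue=float(p[j]))
            for j in range(cfg.n_snps)
        )
        waves.append(GwasWave(label=f"wave{w + 1}", sample_size=n, records=records))
    return waves


def simulate_chromatin(
    cfg: SimulationConfig,
    causal_blocks: set[int] | None = None,
    cell_type: str | None = None,
    panel: LdPanel | None = None,  # noqa: ARG001 - accepted for API symmetry
) -> ChromatinContext:
    """One cell type's chromatin context.

    Fragments tile the synthetic chromosome, one baited promoter fragment per
    block (gene ``GENE<block>``) followed by one fragment per SNP and a
    spacer. A wired block gets peaks over its bait and SNP positions plus a
    significant bait/other-end contact per SNP fragment; unwired blocks may
    receive decoy features (an open SNP without a contact, or a contact whose
    promoter is closed) so every failure mode of the constraint occurs.
    """
    if causal_blocks is None:
        causal_blocks = cfg.causal_blocks()
    if cell_type is None:
        cell_type = cfg.cell_types[0]
    ct_index = cfg.cell_types.index(cell_type) if cell_type in cfg.cell_types else 99
    rng = cfg._rng(_STREAM_CHROMATIN + 100 * ct_index)

    p_wired_causal = min(1.0, cfg.chromatin_enrichment * cfg.peak_density)
    if cfg.chromatin_enrichment * cfg.peak_density > 1.0:
        logger.warning(
            "enrichment x base rate exceeds 1; wiring probability capped at 1"
        )

    L = cfg.fragment_length
    stride = cfg.snps_per_block + 2
    peaks: list[GenomicInterval] = []
    fragments: dict[str, Fragment] = {}
    contacts: list[Contact] = []
    for b in range(cfg.n_blocks):
        base = b * stride
        bait_id = f"F{base}"
        bait_iv = GenomicInterval(cfg.chrom, base * L, (base + 1) * L)
        fragments[bait_id] = Fragment(
            interval=bait_iv, fragment_id=bait_id, is_bait=True, genes=(f"GENE{b}",)
        )
        snp_frag_ids = []
        for i in range(cfg.snps_per_block):
            fid = f"F{base + 1 + i}"
            fragments[fid] = Fragment(
                interval=GenomicInterval(
                    cfg.chrom, (base + 1 + i) * L, (base + 2 + i) * L
                ),
                fragment_id=fid,
            )
            snp_frag_ids.append(fid)
        spacer_id = f"F{base + 1 + cfg.snps_per_block}"
        fragments[spacer_id] = Fragment(
            interval=GenomicInterval(
                cfg.chrom,
                (base + 1 + cfg.snps_per_block) * L,
                (base + 2 + cfg.snps_per_block) * L,
            ),
            fragment_id=spacer_id,
        )

        p_wired = p_wired_causal if b in causal_blocks else cfg.peak_density
        wired = rng.random() < p_wired
        decoy = rng.random()
        if wired:
            peaks.append(bait_iv)
            for i, fid in enumerate(snp_frag_ids):
                pos0 = cfg.snp_position(b, i) - 1
                peaks.append(GenomicInterval(cfg.chrom, pos0 - 50, pos0 + 50))
                contacts.append(
                    Contact(
                        bait_fragment_id=bait_id,
                        other_fragment_id=fid,
                        score=float(rng.uniform(5.0, 15.0)),
                        resolution=1,
                    )
                )
        elif decoy < 0.15:
            # open SNPs, no promoter contact
            for i in range(cfg.snps_per_block):
                pos0 = cfg.snp_position(b, i) - 1
                peaks.append(GenomicInterval(cfg.chrom, pos0 - 50, pos0 + 50))
        elif decoy < 0.25:
            # open SNPs contacting a closed promoter
            for i, fid in enumerate(snp_frag_ids):
                pos0 = cfg.snp_position(b, i) - 1
                peaks.append(GenomicInterval(cfg.chrom, pos0 - 50, pos0 + 50))
                contacts.append(
                    Contact(
                        bait_fragment_id=bait_id,
                        other_fragment_id=fid,
                        score=float(rng.uniform(5.0, 15.0)),
                        resolution=1,
                    )
                )
    return ChromatinContext(
        cell_type=cell_type,
        peaks=peaks,
        fragments={1: fragments},
        contacts=contacts,
    )


def simulate_study(
    cfg: SimulationConfig,
) -> tuple[LdPanel, list[GwasWave], list[ChromatinContext]]:
    """Full study bundle: LD panel, GWAS waves, one context per cell type."""
    panel = simulate_ld_panel(cfg)
    waves = simulate_two_wave_gwas(cfg, panel)
    contexts = [
        simulate_chromatin(cfg, cfg.causal_blocks(), ct) for ct in cfg.cell_types
    ]
    return panel, waves, contexts


def write_study(cfg: SimulationConfig, outdir: str | Path) -> dict[str, Path]:
    """Simulate and write every input in the file dialects the readers consume.

    Returns the mapping of logical names to paths (summary stats per wave, LD
    table, and per-cell-type peaks/baitmap/rmap/ibed)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    panel, waves, contexts = simulate_study(cfg)
    paths: dict[str, Path] = {}
    for wave in waves:
        p = outdir / f"gwas_{wave.label}.tsv"
        write_summary_stats(wave, p)
        paths[f"gwas_{wave.label}"] = p
    paths["ld"] = outdir / "ld.tsv"
    write_ld_table(panel, paths["ld"])
    for ctx in contexts:
        ct = ctx.cell_type
        paths[f"peaks_{ct}"] = outdir / f"{ct}.peaks.bed"
        write_peaks(ctx.peaks, paths[f"peaks_{ct}"])
        paths[f"baitmap_{ct}"] = outdir / f"{ct}.baitmap"
        paths[f"rmap_{ct}"] = outdir / f"{ct}.rmap"
        paths[f"ibed_{ct}"] = outdir / f"{ct}.ibed"
        write_contacts(
            ctx.fragments[1],
            ctx.contacts,
            paths[f"baitmap_{ct}"],
            paths[f"rmap_{ct}"],
            paths[f"ibed_{ct}"],
        )
    return paths
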