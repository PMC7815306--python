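"""The synthetic-data generator: LD structure, association scaling, chromatin
wiring, determinism, and the file round trip."""

import numpy as np
import pytest
from scipy import stats as sps

from gwsalvage.chromatin import constrain_pool
from gwsalvage.io import read_contacts, read_ld_table, read_peaks, read_summary_stats
from gwsalvage.simulate import (
    SimulationConfig,
    simulate_chromatin,
    simulate_ld_panel,
    simulate_study,
    simulate_two_wave_gwas,
    write_study,
)


def small_cfg(**kw):
    base = dict(
        n_blocks=20,
        snps_per_block=3,
        n_causal_blocks=4,
        wave_sample_sizes=(100_000, 400_000),
        seed=0,
    )
    base.update(kw)
    return SimulationConfig(**base)


class TestLdPanel:
    def test_block_pair_combinatorics(self):
        cfg = small_cfg(n_blocks=2, snps_per_block=3, n_causal_blocks=0)
        panel = simulate_ld_panel(cfg)
        assert len(panel) == 6  # 2 blocks x C(3,2)
        b0, b1 = cfg.block_snps(0), cfg.block_snps(1)
        assert all(panel.r2(a, b) == 0.0 for a in b0 for b in b1)

    def test_tight_range_makes_every_pair_a_proxy(self):
        cfg = small_cfg(within_block_r2_range=(0.85, 0.9))
        panel = simulate_ld_panel(cfg)
        for a, b, r2 in panel.iter_pairs():
            assert r2 > 0.8

    def test_cross_block_pairs_injected(self):
        cfg = small_cfg(n_cross_block_pairs=5)
        panel = simulate_ld_panel(cfg)
        cross = [
            (a, b, r2)
            for a, b, r2 in panel.iter_pairs()
            if cfg.block_of(a) != cfg.block_of(b)
        ]
        assert len(cross) == 5
        assert all(0.1 <= r2 <= 0.35 for _, _, r2 in cross)

    def test_deterministic_given_seed(self):
        a = simulate_ld_panel(small_cfg(seed=3))
        b = simulate_ld_panel(small_cfg(seed=3))
        assert sorted(a.iter_pairs()) == sorted(b.iter_pairs())
        c = simulate_ld_panel(small_cfg(seed=4))
        assert sorted(a.iter_pairs()) != sorted(c.iter_pairs())


class TestGwas:
    def test_null_pvalues_are_uniform(self):
        cfg = SimulationConfig(
            n_blocks=2000, snps_per_block=5, n_causal_blocks=0,
            causal_effect_scale=0.0, wave_sample_sizes=(10_000, 20_000), seed=1,
        )
        panel = simulate_ld_panel(cfg)
        waves = simulate_two_wave_gwas(cfg, panel)
        pvals = np.array([r.pvalue for r in waves[0].records.values()])
        assert sps.kstest(pvals, "uniform").pvalue > 0.01

    def test_future_wave_gws_rate_matches_normal_tail_oracle(self):
        """With noncentrality 6 in wave 1 and a 2.7225x sample growth, wave-2
        noncentrality is 9.9; the GWS crossing rate must match the normal
        tail probability within binomial error."""
        n1 = 100_000
        cfg = SimulationConfig(
            n_blocks=4000, snps_per_block=1, n_causal_blocks=4000,
            causal_effect_scale=6.0 / np.sqrt(n1), effect_jitter=0.0,
            wave_sample_sizes=(n1, int(n1 * 2.7225)), seed=2,
        )
        waves = simulate_two_wave_gwas(cfg, simulate_ld_panel(cfg))
        thr = sps.norm.isf(5e-8 / 2)
        expected = sps.norm.sf(thr - 9.9) + sps.norm.sf(thr + 9.9)
        crossed = np.mean(
            [r.pvalue < 5e-8 for r in waves[1].records.values()]
        )
        se = np.sqrt(expected * (1 - expected) / 4000)
        assert abs(crossed - expected) < 4 * se

    def test_signals_strengthen_with_sample_size(self):
        cfg = small_cfg(seed=5)
        panel = simulate_ld_panel(cfg)
        w1, w2 = simulate_two_wave_gwas(cfg, panel)
        causal = [cfg.rsid(b, 0) for b in cfg.causal_blocks()]
        p1 = np.median([w1.records[r].pvalue for r in causal])
        p2 = np.median([w2.records[r].pvalue for r in causal])
        assert p2 < p1

    def test_deterministic_given_seed(self):
        cfg = small_cfg(seed=6)
        panel = simulate_ld_panel(cfg)
        a = simulate_two_wave_gwas(cfg, panel)
        b = simulate_two_wave_gwas(cfg, panel)
        assert all(x.records == y.records for x, y in zip(a, b))


class TestChromatin:
    @staticmethod
    def pass_rates(cfg, n_probe=None):
        panel = simulate_ld_panel(cfg)
        waves = simulate_two_wave_gwas(cfg, panel)
        ctx = simulate_chromatin(cfg, cfg.causal_blocks(), cfg.cell_types[0])
        results = constrain_pool(waves[0].records.values(), ctx, mhc=None)
        causal_ids = {
            r for b in cfg.causal_blocks() for r in cfg.block_snps(b)
        }
        causal = np.mean([results[r].passed for r in causal_ids])
        null = np.mean([results[r].passed for r in results if r not in causal_ids])
        return causal, null

    def test_enrichment_raises_causal_pass_rate(self):
        cfg = SimulationConfig(
            n_blocks=1200, snps_per_block=2, n_causal_blocks=600,
            chromatin_enrichment=10.0, peak_density=0.05, seed=7,
        )
        causal, null = self.pass_rates(cfg)
        assert causal == pytest.approx(0.5, abs=0.07)
        assert null == pytest.approx(0.05, abs=0.03)

    def test_no_enrichment_equalises_pass_rates(self):
        cfg = SimulationConfig(
            n_blocks=1200, snps_per_block=2, n_causal_blocks=600,
            chromatin_enrichment=1.0, peak_density=0.2, seed=8,
        )
        causal, null = self.pass_rates(cfg)
        # two-proportion z-test: no detectable difference
        n = 600 * 2
        pooled = (causal + null) / 2
        z = (causal - null) / np.sqrt(2 * pooled * (1 - pooled) / n)
        assert abs(z) < 3

    def test_wiring_probability_capped_with_warning(self, caplog):
        cfg = small_cfg(chromatin_enrichment=100.0, peak_density=0.5)
        with caplog.at_level("WARNING"):
            simulate_chromatin(cfg, cfg.causal_blocks(), cfg.cell_types[0])
        assert "capped" in caplog.text

    def test_deterministic_given_seed(self):
        cfg = small_cfg(seed=9)
        a = simulate_chromatin(cfg, cfg.causal_blocks(), "adipocyte")
        b = simulate_chromatin(cfg, cfg.causal_blocks(), "adipocyte")
        assert a.peaks == b.peaks and a.contacts == b.contacts

    def test_cell_types_draw_independent_wirings(self):
        cfg = small_cfg(seed=10, n_blocks=50, n_causal_blocks=25)
        a = simulate_chromatin(cfg, cfg.causal_blocks(), cfg.cell_types[0])
        b = simulate_chromatin(cfg, cfg.causal_blocks(), cfg.cell_types[1])
        assert a.contacts != b.contacts


class TestWriteStudy:
    def test_files_round_trip_through_the_readers(self, tmp_path):
        cfg = small_cfg(seed=11)
        paths = write_study(cfg, tmp_path)
        panel, waves, ctxs = simulate_study(cfg)

        back_panel = read_ld_table(paths["ld"])
        assert sorted(back_panel.iter_pairs()) == sorted(
            (a, b, float(f"{r2:.6g}")) for a, b, r2 in panel.iter_pairs()
        )
        back_wave = read_summary_stats(
            paths["gwas_wave1"], waves[0].label, waves[0].sample_size
        )
        assert set(back_wave.records) == set(waves[0].records)
        ct = cfg.cell_types[0]
        assert read_peaks(paths[f"peaks_{ct}"]) == sorted(
            ctxs[0].peaks, key=lambda p: (p.chrom, p.start, p.end)
        )
        frs, contacts = read_contacts(
            paths[f"baitmap_{ct}"], paths[f"rmap_{ct}"], paths[f"ibed_{ct}"], 1
        )
        assert frs == ctxs[0].fragments[1]
        assert len(contacts) == len(ctxs[0].contacts)
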