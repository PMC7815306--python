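"""End-to-end salvage analysis as a model/results pair.

:class:`SalvageAnalysis` is built from in-memory inputs (GWAS waves, an LD
panel, per-cell-type chromatin contexts); :meth:`SalvageAnalysis.fit` executes
proxy expansion -> GWS-LD exclusion -> chromatin constraint -> locus
clustering -> retrospective classification and returns a
:class:`SalvageResults` carrying locus tables, stage counts, confusion
matrices, metrics, Fisher p-values, beta-binomial posteriors and empirical
percentiles, with a ``summary()`` table and TSV writers.

The combined cell-type analysis ("either cell type") takes the union of the
per-cell-type surviving SNPs and re-clusters them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import chromatin, ld, retrospective as retro, stats
from .io import (
    ChromatinContext,
    GenomicInterval,
    GWS_P,
    GwasWave,
    LdPanel,
    MHC_HG19,
    read_contacts,
    read_ld_table,
    read_peaks,
    read_summary_stats,
)

logger = logging.getLogger(__name__)

COMBINED = "combined"
SET_CONSTRAINED = "constrained"
SET_UNCONSTRAINED = "unconstrained"
SET_NEGATIVE = "negative-control"


class PipelineError(RuntimeError):
    """Raised when a pipeline stage fails; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass(frozen=True)
class Thresholds:
    """Every tunable threshold of the pipeline in one place."""

    r2_proxy: float = ld.R2_PROXY
    r2_exclude: float = ld.R2_EXCLUDE
    r2_cluster: float = ld.R2_CLUSTER
    r2_tight: float = retro.R2_TIGHT
    gws_p: float = GWS_P

    def __post_init__(self) -> None:
        for name in ("r2_proxy", "r2_exclude", "r2_cluster", "r2_tight"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not (0.0 < self.gws_p < 1.0):
            raise ValueError(f"gws_p must be in (0, 1), got {self.gws_p}")
        if self.r2_cluster > self.r2_proxy:
            logger.warning(
                "r2_cluster (%g) exceeds r2_proxy (%g): legal but unusual",
                self.r2_cluster,
                self.r2_proxy,
            )


@dataclass
class SalvageBinResult:
    """Salvage-stage output for one suggestive bin."""

    bin: retro.SuggestiveBin
    step_counts: dict[str, int]
    survivors: set[str]
    constraint_results: dict[str, dict[str, chromatin.ConstraintResult]]
    constrained_snps: dict[str, set[str]]  # cell type (incl. combined) -> rsids
    negative_snps: dict[str, set[str]]
    loci: dict[tuple[str, str], list[ld.Locus]]  # (cell type, set name) -> loci


@dataclass(frozen=True)
class EvaluationRow:
    """One (bin, cell type, set) evaluation: counts, metrics and tests."""

    bin: str
    cell_type: str
    set_name: str
    counts: retro.ConfusionCounts
    metrics: stats.MetricSet
    n_loci: int
    fisher_p: float | None = None
    posterior: float | None = None
    empirical_percentile: float | None = None


class SalvageResults:
    """Fitted results: locus tables, stage counts, and per-set evaluations."""

    def __init__(
        self,
        model: "SalvageAnalysis",
        salvage: dict[str, SalvageBinResult],
        rows: list[EvaluationRow],
        seed: int,
    ):
        self.model = model
        self.salvage = salvage
        self.rows = rows
        self.seed = seed

    def to_frame(self) -> pd.DataFrame:
        recs = []
        for r in self.rows:
            recs.append(
                {
                    "bin": r.bin,
                    "cell_type": r.cell_type,
                    "set": r.set_name,
                    "n_loci": r.n_loci,
                    "tp": r.counts.tp,
                    "fp": r.counts.fp,
                    "fn": r.counts.fn,
                    "tn": r.counts.tn,
                    "ppv": r.metrics.ppv,
                    "sensitivity": r.metrics.sensitivity,
                    "specificity": r.metrics.specificity,
                    "fnr": r.metrics.fnr,
                    "fpr": r.metrics.fpr,
                    "fisher_p": r.fisher_p,
                    "posterior": r.posterior,
                    "empirical_percentile": r.empirical_percentile,
                }
            )
        return pd.DataFrame.from_records(recs)

    def step_counts_frame(self) -> pd.DataFrame:
        recs = []
        for label, res in self.salvage.items():
            row = {"bin": label}
            row.update(res.step_counts)
            recs.append(row)
        return pd.DataFrame.from_records(recs)

    def loci_frame(self) -> pd.DataFrame:
        recs = []
        for label, res in self.salvage.items():
            for (ct, set_name), loci in res.loci.items():
                for i, locus in enumerate(loci):
                    recs.append(
                        {
                            "bin": label,
                            "cell_type": ct,
                            "set": set_name,
                            "locus_id": f"{label}:{ct}:{set_name}:{i}",
                            "representative": locus.representative,
                            "members": ";".join(sorted(locus.members)),
                            "n_members": len(locus.members),
                            "n_extended": len(locus.extended_members),
                            "genes": ";".join(sorted(locus.contacted_genes)),
                        }
                    )
        return pd.DataFrame.from_records(recs)

    def constraint_frame(self) -> pd.DataFrame:
        recs = []
        for label, res in self.salvage.items():
            for ct, results in res.constraint_results.items():
                for rsid, cr in sorted(results.items()):
                    recs.append(
                        {
                            "bin": label,
                            "cell_type": ct,
                            "rsid": rsid,
                            "passed": cr.passed,
                            "failure_reason": cr.failure_reason or "",
                            "genes": ";".join(sorted(cr.contacted_genes)),
                        }
                    )
        return pd.DataFrame.from_records(recs)

    def summary(self) -> str:
        df = self.to_frame()
        lines = [
            "Chromatin-constrained salvage of sub-threshold GWAS signals",
            "=" * 64,
            f"waves: {self.model.base_wave.label} (n={self.model.base_wave.sample_size:,})"
            f" -> {self.model.future_wave.label} (n={self.model.future_wave.sample_size:,})",
            f"seed: {self.seed}",
            "",
        ]
        with pd.option_context("display.width", 120, "display.max_columns", 20):
            for label in df["bin"].unique():
                sub = df[df["bin"] == label]
                lines.append(f"-- suggestive bin p < {label} --")
                cols = [
                    "cell_type", "set", "n_loci", "tp", "fp", "fn", "tn",
                    "ppv", "specificity", "sensitivity", "fisher_p", "posterior",
                ]
                lines.append(
                    sub[cols].to_string(index=False, float_format=lambda v: f"{v:.3f}")
                )
                lines.append("")
        return "\n".join(lines)

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "evaluation": outdir / "evaluation.tsv",
            "loci": outdir / "loci.tsv",
            "constraint": outdir / "constraint.tsv",
            "steps": outdir / "steps.log",
        }
        self.to_frame().to_csv(paths["evaluation"], sep="\t", index=False)
        self.loci_frame().to_csv(paths["loci"], sep="\t", index=False)
        self.constraint_frame().to_csv(paths["constraint"], sep="\t", index=False)
        self.step_counts_frame().to_csv(paths["steps"], sep="\t", index=False)
        return paths


class SalvageAnalysis:
    """The chromatin-constrained salvage model over two (or more) GWAS waves.

    Parameters
    ----------
    waves : sequence of GwasWave
        Releases in increasing sample-size order; the first supplies the
        suggestive signals, the last (by default) supplies the future
        genome-wide-significant truth.
    panel : LdPanel
        Pairwise r² lookup.
    contexts : sequence of ChromatinContext
        One per cell type.
    bins : sequence of SuggestiveBin, optional
        Suggestive strata to analyse (defaults to the four nested bins).
    thresholds : Thresholds, optional
    mhc : GenomicInterval or None
        Region excluded outright (defaults to the hg19 extended MHC; pass
        ``None`` when coordinates live on a synthetic genome).
    min_contact_score : float, optional
        Optional re-filter on contact scores.
    """

    def __init__(
        self,
        waves: Sequence[GwasWave],
        panel: LdPanel,
        contexts: Sequence[ChromatinContext],
        bins: Sequence[retro.SuggestiveBin] = retro.STANDARD_BINS,
        thresholds: Thresholds = Thresholds(),
        mhc: GenomicInterval | None = MHC_HG19,
        min_contact_score: float | None = None,
    ):
        if len(waves) < 2:
            raise ValueError("need at least two waves (base and future)")
        self.waves = list(waves)
        self.panel = panel
        self.contexts = list(contexts)
        self.bins = list(bins)
        self.thresholds = thresholds
        self.mhc = mhc
        self.min_contact_score = min_contact_score
        self.base_wave = self.waves[0]
        self.future_wave = self.waves[-1]
        self._engines = {
            ctx.cell_type: chromatin.ConstraintEngine(
                ctx, mhc=mhc, min_contact_score=min_contact_score
            )
            for ctx in self.contexts
        }

    @classmethod
    def from_config(cls, cfg: "RunConfig") -> "SalvageAnalysis":
        """Build the analysis by reading every input file named in ``cfg``."""
        waves = [
            read_summary_stats(w["path"], w["label"], w["sample_size"],
                               columns=w.get("columns"))
            for w in cfg.waves
        ]
        panel = read_ld_table(cfg.ld_path)
        contexts = []
        for ct, spec in cfg.cell_types.items():
            peaks = read_peaks(spec["peaks"])
            fragments: dict[int, dict[str, "object"]] = {}
            contacts = []
            for res_key, res in (("resolution1", 1), ("resolution4", 4)):
                if res_key not in spec:
                    continue
                frs, cts = read_contacts(
                    spec[res_key]["baitmap"],
                    spec[res_key]["rmap"],
                    spec[res_key]["ibed"],
                    resolution=res,
                )
                fragments[res] = frs
                contacts.extend(cts)
            contexts.append(
                ChromatinContext(ct, peaks, fragments, contacts)
            )
        bins = tuple(
            retro.SuggestiveBin(str(u), float(u)) for u in cfg.bin_uppers
        )
        mhc = None
        if cfg.mhc_region:
            chrom, span = cfg.mhc_region.split(":")
            start, end = (int(x.replace(",", "")) for x in span.split("-"))
            mhc = GenomicInterval(chrom, start - 1, end)
        return cls(
            waves, panel, contexts, bins=bins,
            thresholds=cfg.thresholds, mhc=mhc,
            min_contact_score=cfg.min_contact_score,
        )

    # ------------------------------------------------------------------ salvage

    def salvage_bin(self, sbin: retro.SuggestiveBin) -> SalvageBinResult:
        """Run the filtering cascade for one suggestive bin."""
        th = self.thresholds
        wave = self.base_wave
        suggestive = retro.bin_suggestive(wave, sbin)
        with_ld = {s for s in suggestive if self.panel.has_ld(s)}

        expansion = ld.find_proxies(with_ld, self.panel, th.r2_proxy)
        pool = expansion.pool()
        # proxies lacking summary statistics have no testable position
        pool_known = {r for r in pool if r in wave}
        survivors = ld.exclude_gws_ld(
            pool_known, wave.gws_snps(th.gws_p), self.panel, th.r2_exclude
        )

        step_counts = {
            "suggestive": len(suggestive),
            "suggestive_with_ld": len(with_ld),
            "proxies": len(pool_known),
            "after_gws_exclusion": len(survivors),
        }

        records = [wave.records[r] for r in sorted(survivors)]
        constraint_results: dict[str, dict[str, chromatin.ConstraintResult]] = {}
        constrained: dict[str, set[str]] = {}
        negative: dict[str, set[str]] = {}
        for ctx in self.contexts:
            engine = self._engines[ctx.cell_type]
            results = {rec.rsid: engine.evaluate(rec) for rec in records}
            constraint_results[ctx.cell_type] = results
            constrained[ctx.cell_type] = {
                r for r, cr in results.items() if cr.passed
            }
            negative[ctx.cell_type] = survivors - constrained[ctx.cell_type]
            step_counts[f"constrained_{ctx.cell_type}"] = len(
                constrained[ctx.cell_type]
            )
        constrained[COMBINED] = set().union(*constrained.values()) if constrained else set()
        negative[COMBINED] = survivors - constrained[COMBINED]
        step_counts["constrained_combined"] = len(constrained[COMBINED])

        pvals = {r: wave.records[r].pvalue for r in survivors}

        def snp_genes(ct: str, rsid: str) -> frozenset[str]:
            sources = constraint_results if ct == COMBINED else {ct: constraint_results[ct]}
            genes: frozenset[str] = frozenset()
            for res_ in sources.values():
                cr = res_.get(rsid)
                if cr is not None and cr.passed:
                    genes |= cr.contacted_genes
            return genes

        loci: dict[tuple[str, str], list[ld.Locus]] = {}
        unconstrained_loci = ld.cluster_loci(
            survivors, self.panel, th.r2_cluster, pvalues=pvals
        )
        for ct in list(constrained):
            cl = ld.cluster_loci(
                constrained[ct], self.panel, th.r2_cluster, pvalues=pvals
            )
            cl = [
                locus.annotate(
                    bin=sbin.label,
                    cell_types=frozenset([ct]),
                    contacted_genes=frozenset().union(
                        *(snp_genes(ct, m) for m in locus.members), frozenset()
                    ),
                )
                for locus in cl
            ]
            loci[(ct, SET_CONSTRAINED)] = cl
            nl = ld.cluster_loci(
                negative[ct], self.panel, th.r2_cluster, pvalues=pvals
            )
            loci[(ct, SET_NEGATIVE)] = [
                locus.annotate(bin=sbin.label, cell_types=frozenset([ct]))
                for locus in nl
            ]
        loci[(COMBINED, SET_UNCONSTRAINED)] = [
            locus.annotate(bin=sbin.label) for locus in unconstrained_loci
        ]
        step_counts["loci_unconstrained"] = len(unconstrained_loci)
        for ct in constrained:
            step_counts[f"loci_constrained_{ct}"] = len(loci[(ct, SET_CONSTRAINED)])

        return SalvageBinResult(
            bin=sbin,
            step_counts=step_counts,
            survivors=survivors,
            constraint_results=constraint_results,
            constrained_snps=constrained,
            negative_snps=negative,
            loci=loci,
        )

    def salvage(self) -> dict[str, SalvageBinResult]:
        """Run the salvage cascade across every configured bin."""
        out = {}
        for sbin in self.bins:
            try:
                out[sbin.label] = self.salvage_bin(sbin)
            except Exception as exc:  # noqa: BLE001 - annotate with stage
                raise PipelineError(f"salvage[{sbin.label}]", exc) from exc
        return out

    # --------------------------------------------------------------- evaluation

    def fit(
        self,
        seed: int = 0,
        posterior_iterations: int = 100_000,
        empirical_iterations: int = 10_000,
        compute_empirical: bool = True,
    ) -> SalvageResults:
        """Salvage every bin, classify loci against the future wave, and
        assemble the evaluation report."""
        salvage = self.salvage()
        rows: list[EvaluationRow] = []
        ss = np.random.SeedSequence([seed, 0xE5A1])
        stat_seeds = iter(ss.generate_state(4 * len(self.bins) * (len(self.contexts) + 2)))

        for label, res in salvage.items():
            try:
                rows.extend(
                    self._evaluate_bin(
                        res, posterior_iterations, empirical_iterations,
                        compute_empirical, stat_seeds,
                    )
                )
            except Exception as exc:  # noqa: BLE001
                raise PipelineError(f"evaluate[{label}]", exc) from exc
        return SalvageResults(self, salvage, rows, seed)

    def _evaluate_bin(
        self, res, posterior_iterations, empirical_iterations, compute_empirical,
        stat_seeds,
    ) -> list[EvaluationRow]:
        th = self.thresholds
        unconstrained = res.loci[(COMBINED, SET_UNCONSTRAINED)]
        u_labels = retro.classify_future(
            unconstrained, self.future_wave, self.panel, th.r2_tight, th.gws_p
        )
        k2 = sum(u_labels.values())
        n2 = len(u_labels)
        rows = [
            EvaluationRow(
                bin=res.bin.label,
                cell_type=COMBINED,
                set_name=SET_UNCONSTRAINED,
                counts=retro.ConfusionCounts(tp=k2, fp=n2 - k2, fn=0, tn=0),
                metrics=stats.compute_metrics(
                    retro.ConfusionCounts(tp=k2, fp=n2 - k2, fn=0, tn=0)
                ),
                n_loci=n2,
            )
        ]
        label_array = np.array([u_labels[u] for u in unconstrained], dtype=bool)

        for (ct, set_name), loci in res.loci.items():
            if set_name == SET_UNCONSTRAINED:
                continue
            c_labels = retro.classify_future(
                loci, self.future_wave, self.panel, th.r2_tight, th.gws_p
            )
            counts = retro.build_confusion(
                c_labels, u_labels, panel=self.panel, r2_tight=th.r2_tight
            )
            fisher_p = posterior = percentile = None
            if n2 > 0:
                k1, n1 = counts.tp, counts.predicted_positive
                fisher_p = stats.fisher_exact(k1, n1, k2, n2)
                posterior = stats.beta_binomial_posterior(
                    k1, n1, k2, n2,
                    iterations=posterior_iterations,
                    seed=int(next(stat_seeds)) % (2**31),
                ).prob_constrained_better
                if compute_empirical and 0 < n1 <= n2:
                    obs = k1 / n1
                    percentile = stats.empirical_ppv_distribution(
                        label_array, n1, obs,
                        n_iter=empirical_iterations,
                        seed=int(next(stat_seeds)) % (2**31),
                    ).percentile_of_observed
            rows.append(
                EvaluationRow(
                    bin=res.bin.label,
                    cell_type=ct,
                    set_name=set_name,
                    counts=counts,
                    metrics=stats.compute_metrics(counts),
                    n_loci=len(loci),
                    fisher_p=fisher_p,
                    posterior=posterior,
                    empirical_percentile=percentile,
                )
            )
        return rows


# ---------------------------------------------------------------------------
# Declarative configuration for file-based runs (CLI)
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Declarative description of a file-based run.

    ``waves`` is a list of ``{path, label, sample_size[, columns]}`` dicts in
    increasing sample-size order; ``cell_types`` maps a cell-type name to
    ``{peaks, resolution1: {baitmap, rmap, ibed}[, resolution4: {...}]}``.
    ``mhc_region`` is a 1-based ``chrom:start-end`` string or empty to disable.
    """

    waves: list[dict]
    ld_path: str
    cell_types: dict[str, dict]
    bin_uppers: tuple[float, ...] = (5e-7, 5e-6, 5e-5, 5e-4)
    thresholds: Thresholds = field(default_factory=Thresholds)
    mhc_region: str = "chr6:28,477,797-33,448,354"
    min_contact_score: float | None = None
    seed: int = 0
    outdir: str = "salvage_out"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        th = raw.pop("thresholds", {})
        return cls(thresholds=Thresholds(**th), **raw)


def run_salvage(cfg: RunConfig) -> dict[str, Path]:
    """File-in/file-out salvage stage: write locus tables and the stage-count
    log. Partial outputs are removed on failure."""
    outdir = Path(cfg.outdir)
    try:
        analysis = SalvageAnalysis.from_config(cfg)
        results = analysis.salvage()
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("load-inputs", exc) from exc
    try:
        outdir.mkdir(parents=True, exist_ok=True)
        shell = SalvageResults(analysis, results, rows=[], seed=cfg.seed)
        paths = {
            "loci": outdir / "loci.tsv",
            "constraint": outdir / "constraint.tsv",
            "steps": outdir / "steps.log",
        }
        shell.loci_frame().to_csv(paths["loci"], sep="\t", index=False)
        shell.constraint_frame().to_csv(paths["constraint"], sep="\t", index=False)
        shell.step_counts_frame().to_csv(paths["steps"], sep="\t", index=False)
        return paths
    except Exception as exc:  # noqa: BLE001
        for p in outdir.glob("*.tsv"):
            p.unlink(missing_ok=True)
        raise PipelineError("write-salvage", exc) from exc


def run_evaluate(cfg: RunConfig) -> dict[str, Path]:
    """File-in/file-out full evaluation: salvage + retrospective report."""
    try:
        analysis = SalvageAnalysis.from_config(cfg)
        results = analysis.fit(seed=cfg.seed)
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("load-inputs", exc) from exc
    try:
        return results.write(cfg.outdir)
    except Exception as exc:  # noqa: BLE001
        for p in Path(cfg.outdir).glob("*.tsv"):
            p.unlink(missing_ok=True)
        raise PipelineError("write-evaluation", exc) from exc
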