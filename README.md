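# gwsalvage

Chromatin-constrained salvage of sub-threshold GWAS signals, with a
retrospective evaluation framework and a synthetic-data generator.

## The problem

Genome-wide association studies declare a variant significant only below
p < 5×10⁻⁸; each new wave of a GWAS consortium's effort promotes signals that
were merely *suggestive* (5×10⁻⁸ ≤ p < 5×10⁻⁴) in earlier, smaller cohorts.
`gwsalvage` implements an alternative to waiting for larger samples: use
functional genomics — ATAC-seq open chromatin and promoter-focused Capture C
contacts from trait-relevant cell types — as a biological constraint that
picks out the suggestive signals most likely to be real, and map each
surviving variant to the gene promoter(s) it physically touches.

The pipeline, for a chosen suggestive bin of an early GWAS wave:

1. **Proxy expansion** — each suggestive sentinel is expanded to its LD
   proxies (r² > 0.8); sentinels with no LD information are dropped.
2. **GWS-LD exclusion** — candidates in even modest LD (r² > 0.1) with an
   already genome-wide-significant SNP are removed, along with the GWS SNPs
   themselves: the aim is *new* loci.
3. **Chromatin constraint** — a candidate survives in a cell type iff it lies
   in open chromatin (≥1 bp overlap with an ATAC-seq peak), does not itself
   sit in a baited promoter fragment, is outside the MHC, and falls in the
   other end of a significant promoter interaction (1- or 4-DpnII-fragment
   resolution) whose bait promoter is also open. Bait-to-bait interactions
   are ignored. Contacted bait genes become the variant's candidate effector
   genes.
4. **Locus clustering** — survivors are grouped into independent loci as
   connected components of the r² > 0.4 graph, extended once by each
   member's r² > 0.4 panel proxies (a single iteration, not a transitive
   closure).
5. **Retrospective evaluation** — a locus is a true positive when a member
   is, or is in tight LD (r² > 0.8) with, a SNP that is genome-wide
   significant in a later, larger wave. Confusion matrices over the
   unconstrained independent loci of the bin give PPV, sensitivity,
   specificity, FNR and FPR; Fisher's exact test and a flat-prior
   beta-binomial Monte Carlo posterior compare the constrained conversion
   rate k₁/n₁ against the unconstrained rate k₂/n₂, and an empirical
   distribution of PPVs from randomly sampled unconstrained loci locates the
   observed PPV.

Because the original application consumed consortium summary statistics, a
reference LD panel, and cell-type chromatin maps that cannot ship with a
package, `gwsalvage.simulate` generates all three with the structure the
analysis assumes (haplotype-block LD, two GWAS waves whose z-statistics grow
with √n, chromatin wiring enriched at causal blocks), writing the exact file
dialects the readers consume.

## Worked example

```python
import gwsalvage as g

cfg = g.SimulationConfig(seed=7)          # 2,000 LD blocks, 2 waves, 2 cell types
panel, waves, contexts = g.simulate_study(cfg)
analysis = g.SalvageAnalysis(waves, panel, contexts, mhc=None)
results = analysis.fit(seed=7)
df = results.to_frame()
print(df[(df.bin == "5e-4") & (df.cell_type.isin(["combined"]))]
        [["set", "n_loci", "tp", "fp", "ppv", "fisher_p", "posterior"]])
```

prints (seed 7):

```
             set  n_loci  tp  fp      ppv  fisher_p  posterior
   unconstrained      75  49  26 0.653333       NaN        NaN
     constrained      24  23   1 0.958333  0.003070    0.99894
negative-control      51  26  25 0.509804  0.139243    0.05440
```

Read: of 75 independent suggestive loci in the widest bin, 24 survive the
chromatin constraint in either cell type; 23 of those 24 (95.8%) reach
genome-wide significance in the larger second wave, against 49/75 (65.3%)
with no constraint — Fisher p ≈ 0.003, and the posterior probability that
the constrained conversion rate is higher is ≈ 0.999. The negative-control
set (survivors *failing* the constraint) stays near the unconstrained rate.
`results.summary()` prints the same tables for every bin;
`results.step_counts_frame()` shows the cascade's pool sizes
(suggestive → with-LD → proxies → post-exclusion → constrained).

The same run is available from the shell:

```bash
gwsalvage simulate --outdir study/ --seed 7
gwsalvage evaluate --config run.yaml      # paths + thresholds, see RunConfig
gwsalvage report --evaluation out/evaluation.tsv
```

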