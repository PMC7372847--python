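# linepanel

Genomics of trait variation in haplodiploid iso-female line panels.

In haplodiploid insects (e.g. parasitoid wasps) mothers control offspring
sex by fertilising eggs: fertilised diploid eggs become daughters, and
unfertilised haploid eggs become sons.  Under local mate competition,
selection favours female-biased broods, and panels of inbred ("iso-female")
lines — each founded from a single mated female and driven towards
homozygosity by sib-mating — turn the among-line variance in brood sex
ratio into an estimate of its total genetic variance.  `linepanel`
implements the full analysis toolchain for such panels:

- **genotype IO and filtering** — VCF genotype matrices (one sample per
  line), brood-level phenotype tables, line metadata with endosymbiont
  (*Wolbachia*) status flags, and the standard filter chain (exclude
  flagged lines, mask residual heterozygotes, drop fixed / under-called /
  low-MAF SNPs) with an audited per-step log;
- **population genetics** — coverage-standardised window diversity
  (π, Watterson's θ, Tajima's D), pairwise line F_ST (Hudson), complete-
  linkage line clustering, and the F_ST-vs-phenotype structure check;
- **LD decay** — pairwise r², the hyperbolic fit r² = 1/(1 + p·x) with
  half-decay distance 1/p and level crossings (1/v − 1)/p, and per-SNP
  decay landscapes;
- **heritability** — quasi-binomial GLM F-tests for among-line variation
  and broad-sense H² = V_line/(V_line + V_res) by one-way REML;
- **GWAS** — per-SNP binomial (sex ratio) and linear (clutch size) mixed
  models with a line random intercept, and an empirical q-value threshold
  from full-scan permutations of line identity;
- **cross-trait window overlap** — windowed rank-overlap of two traits'
  p-values scored by the exact hypergeometric intersection test against a
  SNP-identity permutation null;
- **variant effects** — a small strand/phase-aware classifier (Sequence
  Ontology terms, amino-acid changes, pN/pS summary);
- **synthetic panels** — a haplodiploid line-panel generator (explicit
  mother–son + full-sib pedigree, hyperbolic founder LD, calibrated
  among-line variance) providing ground truth for every stage.

See `docs/methods.md` for models, defaults and limitations.

## Worked example

Simulate a 34-line panel (8 lines flagged *Wolbachia*-lost, 1 outlier),
apply the GWAS filters, and estimate heritability and LD decay:

```python
import numpy as np
import linepanel as lp
from linepanel.simulate import SimulationConfig, simulate_panel
from linepanel.heritability import among_line_ftest, broad_sense_h2
from linepanel.genotypes import broods_to_frame
from linepanel.ld import pairwise_r2, fit_decay, distance_at_r2

cfg = SimulationConfig(n_lines=34, n_founder_haplotypes=120,
                       n_chromosomes=5, chromosome_length_bp=2_000_000,
                       snps_per_chromosome=400, broods_per_line=38, seed=1)
panel = simulate_panel(cfg)
G, flog = lp.apply_gwas_filters(panel.genotypes, panel.metadata)
print(flog.to_frame().to_string(index=False))

broods = [b for b in panel.broods if b.line_id in set(G.line_ids)]
df = broods_to_frame(broods)
print(among_line_ftest(broods).summary())
print(broad_sense_h2(df["sex_ratio"], df["line_id"], trait="sex_ratio",
                     transform="arcsine-sqrt").summary())

pairs = pairwise_r2(G, max_dist=1_000_000, max_pairs=40_000, seed=1)
fit = fit_decay(pairs)
print(f"half-decay = {fit.half_decay_bp/1000:.1f} kb, "
      f"r2<0.1 at {distance_at_r2(fit, 0.1)/1000:.1f} kb")
```

Output:

```
                step  removed  remaining
      lines_excluded        9         25
het_to_missing_calls     3124       2000
          fixed_snps        0       2000
    min_called_lines        8       1992
             maf_min        0       1992
Binomial GLM (quasi-F): F_24,925 = 5.248, P = 1.21e-14 (dispersion = 1.021)
sex_ratio (arcsine-sqrt): H^2 = 0.098 (V_line = 0.0005502, V_res = 0.005037); LR = 55.377, P = 9.95e-14
half-decay = 36.5 kb, r2<0.1 at 328.9 kb
```

Reading the numbers: the filter log mirrors the canonical chain (9 flagged
lines out, heterozygous calls masked, under-called SNPs dropped); the
quasi-F test shows highly significant among-line variation in sex ratio;
the REML broad-sense heritability recovers the generator's calibration
target (H² ≈ 0.1 on the arcsine-square-root scale); and the hyperbolic LD
fit summarises decay by its half-decay distance.  On a 25-line panel the
fitted half-decay (36.5 kb) exceeds the generating 17.8 kb because the
sampling floor of r² (~1/(n−1)) flattens the tail of the curve — fits on
wider panels recover the generating rate within 10%.

The same stages run from the shell:

```sh
linepanel all --config pipeline.yaml --seed 1 --out results/
```

with subcommands `simulate`, `filter`, `popgen`, `ld`, `h2`, `gwas`,
`overlap`, `effects`, `all`; every stage writes TSV/JSON artifacts plus a
checksummed manifest, and a master seed deterministically derives
per-stage seeds.

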