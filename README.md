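# metabomr

A two-stage genetic screen between a binary disease trait and a panel of
blood metabolites, built entirely on GWAS summary statistics:

1. **Stage one — genetic correlation.** Bivariate LD score regression
   (`metabomr.ldsc`): per-SNP chi-square regressed on LD scores for SNP
   heritability, z-score products for genetic covariance, delete-one-block
   jackknife uncertainty, and a nominal p < 0.05 screen over the panel.
2. **Stage two — Mendelian randomization.** For each screened metabolite,
   instruments are selected (p < 5e-6), LD-clumped (r² < 0.001 over
   10,000 kb), filtered against outcome association (p < 5e-6), a
   confounder blocklist, and palindromic alleles, then harmonized
   (`metabomr.instruments`). Five estimators run on the harmonized set
   (`metabomr.estimators`): random-effects IVW (primary), MR-Egger,
   weighted median, simple mode and weighted mode. A diagnostic battery
   (`metabomr.sensitivity`) computes Cochran's and Rucker's Q, the Egger
   intercept test, MR-PRESSO global / per-SNP outlier / distortion tests,
   and leave-one-out influence. An iterative refinement engine
   (`metabomr.pipeline`) removes PRESSO outliers (or, failing those,
   nominally significant "potential" outliers) while the global test is
   significant, then leave-one-out-influential SNPs, round by round until
   clean; the verdict comes from the final round's random-effects IVW.

Because the real inputs (a UK Biobank disease GWAS and a 486-metabolite
GWAS) are external resources, the package ships a synthetic generator
(`metabomr.synthetic_data`) producing summary statistics, LD scores and
instrument sets with known ground truth: a bivariate polygenic
architecture over equicorrelated LD blocks for LDSC, and instrument sets
with chosen causal effect, pleiotropy regime and planted outliers for MR.

## CLI

```bash
# write a synthetic two-trait study (sumstats, LD scores, LD matrix, truth)
metabomr simulate --out-dir study/ --rg 0.5 --seed 7

# stage one for a single pair
metabomr ldsc-rg --exposure study/exposure.tsv --outcome study/outcome.tsv \
    --ldscores study/ldscores.tsv

# stage two for a single pair, with the refinement loop
metabomr mr --exposure study/exposure.tsv --outcome study/outcome.tsv \
    --ld-matrix study/ld_matrix.tsv --out-dir results/

# the full two-stage screen over a panel
metabomr screen --outcome study/outcome.tsv \
    --exposures met1.tsv --exposures met2.tsv \
    --ldscores study/ldscores.tsv --ld-matrix study/ld_matrix.tsv \
    --out screen.tsv
```

All thresholds live in one YAML config passed via `--config`
(`exposure_p`, `outcome_p`, `clump_r2`, `clump_kb`, `alpha`, `n_boot`,
`n_sim`, `max_rounds`, `seed`, ...). Inputs and outputs are delimited
text; readers accept common GWAS header dialects and LDSC-style LD score
files, and optionally gzip-compressed files.

## Layout

```
src/metabomr/
  sumstats_io.py     # tables, readers/writers, validation
  synthetic_data.py  # GWAS-pair, screen-panel and instrument-set generators
  ldsc.py            # h2 / rg estimation with block jackknife
  instruments.py     # five-step instrument screen + harmonization
  estimators.py      # wald, IVW-RE, Egger, weighted median, modes
  sensitivity.py     # Q statistics, Egger intercept, MR-PRESSO, leave-one-out
  pipeline.py        # refinement engine and panel screen
  cli.py
tests/               # unit + property tests; test_acceptance.py holds the
                     # acceptance criteria at their stated tolerances
scripts/acceptance.py
```
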