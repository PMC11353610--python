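# Methods

## Data model

A **panel** is an ordered list of biallelic SNPs, each with a gene symbol,
rsID and a designated major/minor allele. The packaged default
(`default_panel.json`) is a 13-SNP cytokine/receptor panel covering IL-4,
IL-4R, IL-6, IL-10 (two loci), IL-10RB, IL-13, IL-18, IFNγ, IFNγR2, CD23
and Klotho (two loci). One historical rsID misspelling in circulation for
the IFNγ locus (`rs24030561`) is accepted on input and normalized to
`rs2430561`.

Genotype text is canonicalized **major-allele-first** ("G/C", never
"C/G"), so each heterozygote has exactly one rendering and item equality
in the miner is exact string equality. Calls containing an allele the SNP
does not have, and explicit missing markers (`./.`, empty, `NA`), are
stored as missing; missing calls contribute nothing to allele/genotype
denominators and produce no item in the encoding, which makes support
counts conservative.

## Single-SNP statistics

* **Hardy–Weinberg equilibrium**: Pearson chi-square goodness of fit of
  the three genotype classes against n·p², 2npq, n·q² with (p, q) the
  observed allele frequencies; 1 df (one estimated parameter). Computed
  per group — controls and cases separately — since HWE is only expected
  to hold in the population a group was sampled from. Monomorphic SNPs are
  flagged and reported with p = 1.
* **Fisher exact test**: two-sided, summing hypergeometric probabilities
  of tables no more probable than the observed one (scipy's
  implementation); zero-margin tables return p = 1.
* **Odds ratios**: crude cross-products OR = ad/bc with Woolf
  (log-normal) 95% CIs, exp(ln OR ± 1.96·√(1/a+1/b+1/c+1/d)), no
  continuity correction by default; a Haldane–Anscombe +0.5 correction is
  available by flag for zero cells, which are otherwise reported as 0/∞
  and flagged degenerate. Allelic ORs count two alleles per non-missing
  subject; genotype ORs are one-vs-rest; the dominant model contrasts
  minor-allele carriers against major homozygotes and the recessive model
  contrasts minor homozygotes against the rest.
* No covariate adjustment is performed anywhere (that requires per-subject
  regression modelling, out of scope here), and the primary p-values are
  not multiplicity-corrected; the full report carries a Bonferroni column
  for information only.

Choosing z = 1.96 rather than the exact normal quantile changes the
Woolf bounds only in the fourth significant digit; published CI digits
that were themselves computed from rounded intermediates can differ from
ours by one unit in the last place.

## Encoding and mining

Each subject becomes a transaction: the outcome item
(`Allergic`, Yes/No) plus one (rsID, genotype) item per non-missing call.
Sex and age items are supported (age via half-open bins over configurable
cut points) but **off by default**: mined genotype-cluster vocabularies
in this setting contain no demographic items, and a continuous age cannot
be an item without an arbitrary discretization.

The miner is a from-scratch implementation of the classic levelwise
apriori algorithm: frequent (k−1)-itemsets sharing a (k−2)-prefix are
joined, candidates with any infrequent (k−1)-subset are pruned
(anti-monotonicity), and survivors are counted exactly against every
transaction (no sampling). Rules are generated only for the fixed
single-item consequent (default (`Allergic`, Yes)); antecedent length is
unbounded by default. **Thresholds are inclusive** (support ≥ 0.1,
confidence ≥ 0.9): rule sets in this domain genuinely contain boundary
rules with confidence exactly 0.900, and an exclusive reading would drop
them. Output order is confidence desc, support desc, antecedent
lexicographic — deterministic by construction. The denominator m is the
full cohort, cases plus controls.

`brute_force_rules` re-derives the rule set by expanding every
transaction's power set and counting directly; it shares no code with the
levelwise path and exists purely as an equivalence oracle for tests
(refused above 25 catalog items).

## Rule evaluation

A subject is rule-positive iff the antecedent is a subset of their items;
the outcome item is ignored. The 2×2 of rule-positive/negative ×
case/control gives sensitivity, specificity, PPV and NPV **at the
cohort's own case prevalence** (no re-weighting: with 308/513 cases the
prevalence is 0.60, far above any screening population, so the predictive
values are internal to the study design). On the mining cohort PPV equals
mining confidence and the positive-case fraction equals support,
*exactly* — the same counts appear in both computations; this identity is
asserted for every mined rule in the tests. The cumulative classifier is
the union (positive under any rule), whose sensitivity dominates and
specificity is dominated by every individual rule.

## Synthetic cohorts

The generator emulates the study conditions: 308 cases / 205 controls
typed at the 13-SNP panel, per-group minor-allele frequencies matching
the reported marginal counts (packaged as `study_like.yaml`), plus
planted multi-locus clusters. Controls and case backgrounds are drawn at
HWE — two independent allele draws per genotype — with loci independent
(no linkage disequilibrium: the panel spans many chromosomes, and the
downstream analysis makes no LD assumptions either). Sex and age are
simulated from the reported group demographics (≈54/57% women; age
≈ N(51, 10) / N(50, 12.3) truncated at 18) and take no part in risk.

**Planting.** For a cluster with target confidence c and support s, the
fraction π of cases to overwrite with the pattern and the control "leak"
fraction λ are solved by expected-count inversion, *including* the HWE
background coincidence probability p_bg (the chance an unplanted subject
carries the whole pattern anyway):

    E[n_xy] = π·n_cases + (1−π)·n_cases·p_bg_case = s·m
    E[n_x]  = E[n_xy] + λ·n_ctrl + (1−λ)·n_ctrl·p_bg_ctrl = s·m / c

For patterns of common genotypes the background alone can exceed the
target (negative solution); the simulator then *thins* background
carriers instead — each carrier is independently broken (one pattern SNP
redrawn until it no longer matches) with the probability that makes the
expected surviving count hit the target. Both planting and thinning are
expectation-based, not exact count matching, so realized metrics
fluctuate at sampling scale (for a 2-SNP cluster at m = 513, the
20-replicate mean confidence sits within ±0.04 and support within ±0.02
of target; asserted in the tests). A target of confidence 1.0 thins the
control leak to zero, producing an exception-free rule. Targets requiring
more carriers than a group holds raise an error. Same seed ⇒ byte-identical
cohort.

**Known interactions.** Overlapping clusters (shared SNP/genotype pairs)
are resolved by later-cluster precedence, but planting one cluster raises
the background carrier probability of any cluster sharing its genotypes,
so realized metrics of overlapping clusters drift upward by a few
hundredths relative to targets — visible in the packaged default config,
whose three clusters share the IL-10RB G/G genotype between two of them.
Planting likewise inflates the involved SNPs' marginal case allele
frequencies above the configured background values; the configured
frequencies describe the *background* model, and the marginal
allele-OR check in the tests therefore runs with clusters disabled.

`recovery_benchmark_config` freezes a validation scenario of three
disjoint planted clusters (2, 3 and 4 SNPs; confidence 0.97, support
0.14–0.15): strong enough that Poisson fluctuation of the control leak
rarely drags mined confidence below the 0.9 threshold, so the full
pipeline recovers all three antecedents in ≥95% of seeded replicates
(measured ≈98–99%).

**What passing these simulations does not show:** the generator has no
linkage disequilibrium, population stratification, genotyping error or
covariate-dependent risk, and plants patterns as literal genotype
overwrites; recovery rates on it bound algorithmic correctness, not
performance on real cohorts.

## Problem sizes and numerics

Test-suite and reproduction-script simulations use the study-scale cohort
(m = 513, 13 SNPs) throughout: mining one such cohort at the default
thresholds takes ~0.3 s, so 50-replicate recovery runs finish in well
under a minute. HWE calibration uses 2 000 multinomial replicates at
n = 200, maf = 0.3. Oracle-equivalence tests use ≤ 200 transactions over
≤ 9 features, where exhaustive enumeration is instant. Metric identities
(lift, conviction) are exact rational arithmetic on counts up to float
rounding and are asserted to 1e-12 relative.

## Limitations

* Crude ORs only; covariate-adjusted estimates from the original analyses
  of this design are not reproducible from marginal count tables and are
  deliberately not attempted.
* No redundancy pruning of mined rules: supersets of a strong antecedent
  that still pass the thresholds are all reported.
* In-sample evaluation only (no cross-validation or held-out cohorts),
  matching the rule-as-classifier design this package reproduces.
* Predictive values are prevalence-bound to the cohort composition.
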