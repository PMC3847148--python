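# Methods

## Problem and model

The screen nominates druggable candidate synthetic-lethal partners of
mutant p53 from expression data alone. The premise: many p53 target
genes are transcriptionally *repressed* by wild-type p53, so tumours in
which p53 function is lost show elevated expression of those targets.
Genes that are (a) significantly higher-expressed in samples with a
functional p53 mutation and (b) encode kinases — the readily druggable
slice of the genome — are worth prioritising for RNAi or inhibitor
validation. Expression differences do not by themselves establish
synthetic lethality; the pipeline is a pre-screen, and its output is a
candidate list, not a verified interaction set.

## Mutation functionality classification

The controlled vocabulary for TP53 records is `missense`, `nonsense`,
`frameshift`, `silent`, `synonymous`, `noncoding`, `none`. The first
three are treated as function-abrogating ("functional p53 mutation",
class c1); silent-type changes and wild-type (`none`, or absence from
the table) form class c2. Functionality is defined per mutation, so a
sample with several records is c1 as soon as one of them is functional
("any-functional" rule); this is the only aggregation consistent with
the class being named after the presence of a functional mutation, but
it is a design choice — annotation sources rarely state how compound
mutants were handled. Samples appearing in the table only with non-TP53
records are treated as TP53 wild-type, with a logged warning.

## Per-gene statistics

* **t test.** Two-sided, two-sample; pooled variance by default (the
  classical class-comparison choice), Welch–Satterthwaite by flag. The
  statistic is computed from per-class sums and sums of squares after
  centering the gene's values at their grand mean; centering keeps the
  `ss − sum²/n` subtraction well conditioned, which matters because the
  same sums-based kernel evaluates thousands of label permutations with
  two matrix products. Degenerate inputs: zero standard error with
  equal means gives t = 0, p = 1; with unequal means, p = 0.
* **F test.** One-way ANOVA for more than two classes; with exactly two
  classes F = t² (pooled) and the p-values coincide, which the tests
  assert to 1e-10 across a full simulated dataset.
* **Missing values.** Per-gene complete-case analysis. A gene needs at
  least two non-missing values in each class to be testable; untestable
  genes are logged and excluded from the FDR universe. Genes are grouped
  by missing-value pattern so that all genes sharing a pattern share one
  permutation set.
* **Permutation p.** The proportion of class-label permutations whose
  parametric p is at least as small as the observed one. Comparing on
  the parametric p (not |t|) makes t- and F-tested genes uniform.
  Monte-Carlo mode draws label assignments uniformly with replacement
  and applies add-one smoothing, `p = (1 + k)/(1 + B)`, so a ranking
  p-value of exactly 0 cannot occur; exhaustive mode enumerates every
  distinct c1/c2 assignment once and counts the observed assignment, so
  p > 0 by construction. `auto` (default) switches to exhaustive when
  the assignment space has at most `n_permutations` elements. Ties are
  counted with `p_perm ≤ p_obs + 1e-12`; the absolute guard absorbs
  last-ulp noise without affecting any non-tied comparison. All draws
  come from one seeded generator; identical seeds give bit-identical
  results.
* **FDR.** Benjamini–Hochberg step-up q-values, computed over the
  parametric p-values of all testable genes of a dataset run. The
  default universe is every gene (the kinase filter comes *after*
  testing); `universe=` restricts testing and correction to a gene
  subset such as the kinome, which shrinks the number of tests and
  typically the q-values.

## Candidate selection and consensus

A candidate must pass three filters: selected p ≤ α (default 0.05),
direction up-in-c1, kinase membership (exact, case-sensitive symbol
match; alias resolution is deliberately out of scope). The selection
p-type defaults to the parametric p, with permutation p and q-value
available; the loose 0.05 level is intentional — kinase genes are a
small minority of the genome, and a stringent genome-wide cutoff would
empty the candidate list in small panels. Duplicate gene rows (array
probes) can be kept with `probe_mode="suffix"` (`GENE#1`, `GENE#2`); a
gene is a candidate if any of its probes passes. Consensus counts, per
gene, the datasets in which it was a candidate — a gene untestable in a
dataset simply cannot vote there — and keeps genes with at least
`min_datasets` votes (default 2) alongside the unfiltered union.

## Drug-sensitivity comparison

Sensitivity is a normalized −log(GI50) z-score: lower GI50 means higher
sensitivity, so higher z means higher sensitivity. For each compound
whose annotated targets intersect the candidate set (or all compounds,
by flag), a one-sided pooled t test evaluates the alternative
`mean_c1 > mean_c2` — higher sensitivity in the functional-mutant
lines. One-sided p is the upper tail of the t distribution:
`p2/2` when the statistic favours the alternative, `1 − p2/2`
otherwise, and exactly 0.5 at t = 0. p-values are reported raw: with
few mutant lines the comparison is underpowered, and it serves as a
directional check on the candidates rather than a discovery procedure.
Compound names match after case-folding and whitespace stripping only.

## Synthetic-data generator

The generator emulates the *structure* the analysis assumes, not any
real platform. Per dataset, expression is
`baseline + class_effect + N(0, σ)` with independent Gaussian noise per
gene, a common σ (default 1.0, log-scale units) and per-gene baselines
drawn from U(4, 12) (cosmetic heterogeneity; the t statistic is
location-invariant). Exactly `n_planted` kinase genes (default 10 of a
100-gene kinome in a 1000-gene universe) carry a `+effect_size·σ` shift
(default 1.5) in the functional-mutant class, the same genes in every
dataset of a bundle; datasets share samples and labels but draw noise
independently. Defaults for the class design are 60 samples with 41
functional-mutant, the NCI-60-like shape; mutant samples each receive
one functional TP53 record (80% missense, 10% nonsense, 10% frameshift,
echoing the dominance of missense changes in tumours), and 30% of the
remaining samples receive a silent-type record, exercising the
"non-functional plus wild-type" grouping. The drug matrix is standard
normal z-scores over 30 compounds; 10 "target" compounds map to 1–3
planted genes and get a `+drug_effect` (default 1.0) shift in mutant
lines, the rest map to non-planted kinases. A truth record (planted
genes, target compounds, mutant and silent samples) accompanies every
bundle, and all output is a deterministic function of the seed.

What the generator does *not* emulate: gene–gene correlation (the
univariate tests are insensitive to it pointwise; only the joint
behaviour of the FDR would notice), platform effects, heavy-tailed
noise, real mutation spectra, or missing-value structure beyond
uniformly random dropout. Passing tests therefore demonstrate the
statistical machinery is correct and calibrated under the stated model,
not that real arrays satisfy that model. Callers must supply log-scale
expression; the package never transforms raw values.

## Numerical and design choices

* Missing-value dialect: empty cell, `NA`, `NaN` parse as missing;
  anything else non-numeric is a parse error naming the row and column.
* Result tables are written as TSV with `repr`-precision floats, so a
  write→read→write cycle is byte-identical; per-gene tables sort by
  permutation p (parametric p when the permutation stage was skipped)
  then gene symbol.
* `run_class_comparison(..., scheme=None)` skips the permutation stage;
  the default candidate filter uses the parametric p, so screens that do
  not report permutation p avoid its cost.
* Monte-Carlo permutations sample assignments with replacement; the
  exhaustive mode covers small spaces exactly, and `auto` picks it
  whenever possible, so the with-replacement approximation only operates
  where the assignment space is large.
* The drug-ranking simulation study summarises "target compounds rank
  above non-target compounds" as the fraction of (target, non-target)
  pairs ordered correctly by one-sided p — the pairwise-ranking (AUROC)
  form — because with a 1 SD shift over 41/19 lines the single worst of
  ten target compounds is routinely undercut by the minimum of twenty
  null p-values, making an all-pairs criterion uninformative about the
  method.

## Study sizes used in the checked properties

The test suite and `scripts/acceptance.py` run: 200 small genes
(classes ≤ 5/5) for Monte-Carlo vs exhaustive agreement; one 1000-gene
null bundle at the 41/19 design with 10,000 permutations for type-I
calibration; 1000 random p-vectors against the by-definition BH
step-up; a full default bundle for the F = t² identity; 20 seeds of
3-dataset bundles (10 planted kinases, effect 1.5 σ) for consensus
sensitivity and false-discovery proportion; and 20 replicates of the
default drug design plus shuffled-label nulls. These sizes give binomial
standard errors small enough for 3-SE checks around the nominal levels
while keeping a full run in tens of seconds.

## Known limitations

* No moderated-variance (shrinkage) estimators, covariate adjustment or
  paired designs: the procedure is strictly univariate two-class.
* Gene identifier matching is exact and case-sensitive; cross-platform
  alias resolution must happen upstream.
* No pathway/network enrichment and no dose-response fitting; GI50
  values arrive pre-computed.
* The permutation p's add-one smoothing makes it conservatively biased
  upward by at most `(1 − p)/(B + 1)`, negligible at the default
  B = 10,000 but visible if B is set very small.
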