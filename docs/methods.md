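# Methods

This note documents the models, parameter choices and numerical
conventions behind `cernaforge`, and what the synthetic-data validation
does and does not demonstrate.

## Quantification and differential expression

**Units.** mRNA abundance is FPKM,
`counts / ((lib_size/1e6) * length_kb)`; circRNA abundance is SRPBM,
`junction_reads / (lib_size/1e9)`, i.e. back-splice junction reads per
billion mapped reads. Both are linear in counts and inverse-linear in
depth; they are reporting units only — testing operates on counts.

**TMM normalization** follows the standard trimmed-mean-of-M-values
recipe: the reference sample is the one whose 75th percentile of
count fractions is closest to the mean of those percentiles; per
sample, log2 ratios M and average log intensities A are computed
against the reference over features nonzero in both; the most extreme
30 % of M (each tail) and 5 % of A (each tail) are discarded; the
factor is 2 to the precision-weighted mean of the surviving M values
(weights are inverse delta-method variances); factors are rescaled to
geometric mean 1. The implementation is cross-checked in the test
suite against the Bioconductor reference via `Rscript` at rtol 1e-6.

**Two-group test.** Rather than estimating per-feature negative
binomial dispersions, the test conditions on the per-feature total
count summed within groups: under a Poisson model the test-group sum
given the total is binomial with success probability equal to the
test group's share of the TMM-adjusted effective library size, and the
two-sided exact binomial p-value is used. This is the Poisson limit of
the count-based exact test family; under genuine NB overdispersion raw
p-values are anti-conservative, which matters little here because the
screens also require |log2FC| > 2, a bar that dispersion-level noise
essentially never clears (at dispersion 0.1 and 8 pairs, the log2FC
noise SD is about 0.23). Null calibration is therefore asserted in the
Poisson regime, and recovery (sensitivity >= 0.90, false-call rate
<= 0.05) at the study design of 8 pairs, fold change 6, dispersion 0.1.
The interface reserves room for an NB test; a paired mode conditions
within sample pairs via a continuity-corrected normal approximation to
the sum of per-pair binomials.

**Screens.** log2FC uses depth-normalized group means with a
pseudo-count of 0.5 (the +0.5 guards against zeros; the value is
conventional). Thresholds are strict: a feature at exactly |log2FC| = 2
or p = 0.05 is not called. mRNAs are screened on BH-adjusted p,
circRNAs on raw p; both modes are exposed through `use_adjusted`
because count-based circRNA screens are commonly run unadjusted at
small n, where BH over the much smaller circRNA universe is the only
difference.

## miRNA target scoring

**Alignment.** Local (Smith–Waterman, Gotoh affine) alignment of the
miRNA read 3'→5' against the target read 5'→3'. Scores: Watson–Crick
pair +5, G:U wobble +1, mismatch −3, gap open −9, gap extend −4 (a gap
of length g costs −9 − 4·(g−1)); pair/mismatch contributions at miRNA
positions 2–8 from the 5' end (the seed) are multiplied by 2. A 22-nt
miRNA against its exact reverse complement scores 5·(22−7) + 2·5·7 =
145, which clears the screening threshold of 140; a 21-nt miRNA scores
exactly 140 and does not (the screen is strict), so the generators
default to 22-nt miRNAs, the modal human miRNA length. The DP is
verified against exhaustive enumeration of all monotone pairings on
random short instances. Multiple sites per target are taken as
non-overlapping local maxima, selected greedily by descending score
with leftmost-first tie-breaking for determinism.

**Duplex energy.** Nearest-neighbor stacking over consecutive paired
alignment columns, using the published Watson–Crick RNA stack free
energies at 37 °C (Turner-lab parameters; 10 unique values spanning
−0.93 for AA/UU to −3.42 kcal/mol for GC/CG) plus a duplex-initiation
penalty of +4.09 kcal/mol. Gapped or mismatched columns contribute
nothing and break stacks. Stacks involving a G:U wobble take a single
flat −1.2 kcal/mol term rather than the full wobble table: planted
sites are exact complements (all Watson–Crick), so wobble stacking
precision affects only marginal random alignments that the score
threshold already rejects. Terminal-AU penalties and loop terms are
omitted — this is a duplex screen, not a folding engine; an external
folding tool can be substituted where absolute energies matter. The
site screen is energy < −20 kcal/mol, strict.

## ceRNA network assembly

A (circRNA, mRNA) pair enters the network when (i) at least one miRNA
has a surviving site on both molecules, (ii) the two transcripts have
the same differential direction (the sponge mechanism predicts
co-movement), and (iii) the pair binds its shared miRNAs strongly:
Σ over shared miRNAs of [most-negative site energy on the circRNA +
most-negative site energy on the mRNA] < −90 kcal/mol, strict. The
"sum of per-miRNA best energies across both molecules" reading is one
of several possible conventions for an energy-sum rule; it is the one
that makes a single shared miRNA (≈ 2 × −40 kcal/mol for a perfect
22-nt duplex) insufficient while two shared miRNAs pass comfortably,
and it is configurable. One triple is emitted per (circRNA, shared
miRNA, mRNA); joins are set-based, so output is invariant to input
order, and ties everywhere break lexicographically.

## Hub ranking

Maximal cliques are enumerated by Bron–Kerbosch with pivoting
(`networkx.find_cliques`) and MCC(v) = Σ_{C ∋ v} (|C|−1)! over maximal
cliques C. An isolated node scores 1 (its singleton clique). A planted
6-clique contributes 5! = 120 per member, which dominates anything a
sparse noise graph produces; enumeration is guarded by a configurable
clique budget that raises a resource error on pathological graphs.

## Survival signature

Kaplan–Meier estimation and the two-group log-rank test use lifelines.
The unpenalized Cox fitter is an in-package Newton–Raphson maximizer
of the Breslow partial likelihood (step-halving ascent, Wald CIs;
estimates with |beta| > 15 are flagged as likely monotone-likelihood)
— Breslow because ties are handled simply and, with continuous
simulated times, Breslow and Efron coincide, which the suite exploits
to cross-check against lifelines. The L1-penalized path is delegated
to scikit-survival's glmnet-style coordinate descent; the penalty is
chosen by K-fold (default 5) cross-validated partial-likelihood
deviance. Two selection rules are exposed: `min` (deviance-minimizing,
the default — best for prediction) and `1se` (largest penalty within
one standard error — the standard choice for support recovery, since
the min rule deliberately trades a few false inclusions for fit; in
the recovery simulations the min rule virtually always selects a
superset of the planted genes while the 1-SE rule returns exactly the
planted support in most runs). Genes with zero coefficient are
dropped. The risk score is the linear predictor; patients above the
training-median score are "high risk" (ties to low, so discrete data
split deterministically). Time-dependent AUC is the IPCW
cumulative-case/dynamic-control estimator at fixed horizons; constant
scores return 0.5 by the tie convention, and horizons with no cases,
no controls, or beyond follow-up are reported missing with a warning.

## Enrichment

The weighted-KS running sum increments by |metric|^weight (normalized
by the in-set total) at set members and decrements by 1/(N − N_hit)
elsewhere; ES is the signed maximum deviation, clipped to [−1, 1]
against floating-point drift. The null permutes gene labels (the
ranking here is a precomputed statistic, so sample permutation is not
available); NES divides ES by the mean magnitude of same-sign null
scores, and p = (1 + #{|null ES| ≥ |ES|}) / (1 + n_perm) — the add-one
estimator is never zero, and the magnitude comparison makes p uniform
under a sign-symmetric null. Significance is |NES| > 2 and p < 0.05.

## The synthetic study

The generators emulate the targeted design at desk scale: 1 500 mRNAs
over 8 tumor/normal pairs and 240 circRNAs over 4 pairs (negative
binomial, dispersion 0.1, 10–15 % of features planted at fold change
6 split ~50/50 up/down — fold-change 6 keeps planted features clearly
past the |log2FC| > 2 screen while dispersion keeps per-feature noise
realistic); 10 miRNAs of 22 nt; six planted ceRNA pairs sharing two
miRNAs each (one perfect site per molecule), plus two decoy families
that exercise the filters — a discordant pair with full binding, and a
concordant pair sharing only one miRNA whose duplex energy is drawn
into (−44, −24) kcal/mol so the site passes −20 but the pair cannot
reach −90; a 100-node PPI with a planted 6-clique among 60 noise
edges; and a 136-patient survival cohort with exponential event times,
hazard exp(Σ βx) with β = 1 on three of the clique genes,
standard-normal expression, and Uniform(0, c) censoring with c
root-found to hit the target censoring fraction (30 %). Network
planting targets transcripts whose realized fold change clears the
screen with margin (|log2FC| ≥ 2.3), mirroring how validation
candidates are drawn from the most distinctly expressed transcripts;
without this the recovery contract would hinge on every planted
feature surviving a strict threshold by luck.

**What passing does not show.** Planted binding sites are perfect
complements — real sites are partial, so scanner sensitivity to
seed-plus-supplementary pairing is not measured, only specificity
against random sequence. Expression covariates in the survival cohort
are independent Gaussians; correlated expression would slow LASSO
support recovery. The PPI noise is Erdős–Rényi-like, not degree-heavy
like curated interactomes. The count model has no sample-level batch
structure or length bias. These are deliberate: the suite tests that
each statistic does what its definition says and that the chain is
leak-free and deterministic, not that the thresholds are biologically
optimal.

## Determinism and sizes

Every generator takes one integer seed (NumPy PCG64); the pipeline
derives per-stage child seeds from the config seed by a fixed affine
map mod 2³¹−1, so one seed fixes the whole run and rerunning writes
byte-identical tables. Problem sizes in the default configuration
(above) were chosen so the complete chain, the analysis scripts and
the acceptance computation each finish in well under a minute on a
single core while keeping every statistical check at a scale where its
stated tolerance is meaningful (e.g. 5 000 features for the ±0.01
false-positive-rate band, n = 2 000 for the ±0.15 Cox consistency
check, 50 seeds for the ≥ 80 % support-recovery rate).
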