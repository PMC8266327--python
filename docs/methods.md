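# Methods

This note records the statistical models behind each stage, the defaults and
why they were chosen, what the synthetic generator does and does not
emulate, and the numerical conventions a maintainer would otherwise have to
reverse-engineer.

## Count model and differential expression

Counts are modeled negative-binomial with the edgeR-style parameterization
`var = μ + φμ²` (φ is the squared biological coefficient of variation).
Normalization is reads-per-million only — no TMM or median-of-ratios —
because the downstream locus-level questions depend on ranking and sign,
and RPM is the unit in which all stage outputs are reported.

**Dispersion.** Per-feature φ is a method-of-moments estimate on
within-group residuals around offset-scaled group means, with an n/(n−1)
small-sample correction per group, floored at zero, then shrunk linearly
toward the all-feature median with weight `dispersion_shrink` (default
0.9).  At six samples per group tagwise moment estimates are very noisy, so
heavy moderation toward the common value is the right bias–variance
trade-off; simulation with known φ = 0.05–0.1 shows the common value is
recovered essentially unbiased (±10 %).

**Test.** For each feature the group means are fitted by profile likelihood
(Newton iterations in log-mean, library-size offsets, terms constant in the
mean dropped) and compared by a likelihood-ratio statistic.  The reference
distribution depends on how φ was obtained:

- φ known / supplied: χ²(1).  Null simulations at μ = 500, n = 6/group are
  uniform to KS precision with correct far-tail mass.
- φ estimated from the same data: F(1, d) with d = (n−2)/(1−shrink).  The
  χ² reference is anti-conservative here (≈3.6× the nominal 10⁻³ tail mass
  at shrink 0.3) because it ignores dispersion-estimation error; treating
  the shrinkage weight as prior degrees of freedom restores calibration
  (measured P(any BH false rejection at 0.05) ≈ 0.04 over 300 null
  replicates at the default).

Conventions: an all-zero feature gets (log2fc 0, p 1); a feature zero in
exactly one group keeps its finite LRT p but the infinite fold change is
clamped to ±30.  The fold-change sign is old relative to young.

**Independent filtering.** For every quantile θ in a 0–0.95 grid (step
0.01) BH runs on the features at or above that mean-RPM quantile; the θ
maximizing rejections wins, smallest θ on ties.  This argmax rule is
deterministic and oracle-checkable, but — unlike DESeq2, which smooths the
rejection curve — it is selection-biased under a *global* null: any θ that
happens to clear one rejection wins, so P(at least one false call) through
the full filter is ≈0.26 rather than ≈0.05.  With genuine signal present
the argmax tracks real enrichment and the bias is immaterial; the
FDR-calibration claims in the tests are therefore made at the test+BH
level, and a run on data suspected to be signal-free should be read with
this caveat.  Classification: down/up require FDR < α (default 0.05) and
the matching sign; `min_change` (default 0, i.e. off) additionally requires
|2^log2fc − 1| above a fractional floor; filtered features are `excluded`.

**Sex stratification.** The same NB test re-run within each sex; a feature
is flagged when BH-significant in exactly one sex.  Flags are NA when a sex
is missing from either age group.  Note the flag rate among null features
is bounded by α only on data without strong effects — BH thresholds are
dataset-wide.

## Genomic clusters

The genomic position of a mature miRNA is the first base of its mature
sequence: interval start on `+`, interval end on `−`.  Mature names mapping
to more than one gene are counted once in a "multiple" row of the
chromosome table.  Cluster detection chains *gene* start positions (arms
are collapsed first to avoid double counting): consecutive genes ≤
`max_gap` apart join a chain; maximal chains of ≥ `min_size` genes are
clusters.  Defaults 10 kb / 5 comfortably re-find spans with mean
inter-gene gaps around 2 kb while leaving isolated genes alone; both are
flags.  The reported span is end − start of the chain's bounding positions.

Dominant-strand collapse picks the arm with the greater young-group mean
RPM; an exact tie goes to -5p (arbitrary, fixed, documented).  The gene
inherits the representative arm's class and fold change.  Coordination is
an exact two-sided binomial test of the number of members with negative
log2fc against 0.5, zeros excluded, NA below 5 usable members.  Because RPM
renormalization redistributes the library mass lost to a repressed cluster,
unaffected members sit slightly positive on average; on default synthetic
data the test still returns p < 0.01 in ~84 % of replicates and p ≈ 10⁻⁴ on
the canonical seed.

## Targets, enrichment, organs

**Consensus.** A miRNA–gene pair is kept when ≥ `min_sources` (default 2)
distinct sources predict it; symbols are matched case-insensitively after
trimming because databases disagree on casing.  Arm-level miRNA ids are
queried as-is.  The DIANA-style score threshold is a per-source
`score_min` argument with no default — the conventional miTG scale is
[0, 1] and published thresholds are ambiguous, so nothing is hard-coded.

**Seed sites.** The seed is miRNA nt 2–8.  A site is a reverse-complement
match of nt 2–7 in the UTR, classified by whether nt 8 also pairs (m8, one
base 5′ of the core in UTR coordinates) and whether the base opposite nt 1
is an A (one base 3′): both → 8mer, m8 → 7mer-m8, A1 → 7mer-A1, neither →
6mer.  Each core position is reported once under its strongest class;
positions are 1-based core starts.  No context scoring — counts are
canonical site counts, not TargetScan scores.

**Enrichment.** Two-sided hypergeometric p per term by doubling the smaller
exact tail (capped at 1), BH across tested terms, then the reporting
filters (k ≥ 4, 100·k/K ≥ 5 %, p_adj < 0.01).  "% per term" is interpreted
as coverage of the term (k/K), the more common ClueGO reading.  The default
universe is the union of the supplied gene sets, intersected with the query
before testing; it is an explicit argument because enrichment is sensitive
to it.  Kappa grouping: binary term×gene vectors over the universe,
pairwise Cohen's κ, single pass by ascending adjusted p — each ungrouped
term seeds a group and absorbs every remaining term with κ ≥ 0.4.  This is
a deliberate simplification of ClueGO's iterative merging; group
composition is not claimed to match ClueGO's.

**Organ integration.** Expression is log2 CPM with a 0.5 pseudo-count;
genes under 1 mean CPM are dropped.  The moderated t shrinks per-gene
residual variances toward a prior fitted by moment matching on log s²
(digamma/trigamma equations, trigamma inverted by Newton); d0 → 0 recovers
the ordinary t exactly and d0 → ∞ a common-variance z-test, both covered by
tests.  Precision (voom) weights are omitted: the intersection consumes
binary calls at generous thresholds (raw p < 0.05, linear fold > 1.1, as
printed), which the weighting refinement does not move.  At μ = 200,
φ = 0.05, n = 5/group the power ceiling for *any* two-sample test of a
1.5-fold change at α = 0.05 is ≈0.8 (se(log2fc) ≈ 0.21); CPM
renormalization absorbs a further slice when many genes move together, so
measured recall there is ~0.65 — worth knowing before planning a study at
that size.  Cross-organ ranking reports candidates called up in ≥
⌈⅔·organs⌉ organs (4 of 6), sorted by organ count then symbol.

## qPCR

Comparative CT assumes perfect doubling per cycle: ΔCt = Ct_target −
Ct_reference per sample, ΔΔCt subtracts the reference group's mean ΔCt per
assay×context, rq = 2^−ΔΔCt (so the reference group means 1 by
construction); rq_ref_only = 2^−ΔCt is emitted for heat-map use.  Group
comparison mirrors standard validation practice: two groups — Shapiro–Wilk
per group at 0.05, any failure routes to the exact two-sample rank-sum
test, otherwise median-centered Levene picks pooled vs Welch t; more than
two groups — Levene picks one-way ANOVA (Tukey HSD pairs, studentized
range) vs Welch's ANOVA (Games–Howell pairs).  The diagnostics and their
α = 0.05 cutoffs are choices; only the outcomes ("equal or unequal
variances", "non-normal") were prescribed.  The full decision procedure
mildly inflates type I error through selection; measured ≤ 0.07 at
n = 10/group under a normal null.  Both SD and SEM are reported for group
summaries.

## Synthetic generator

The generator is the study design in miniature, and its defaults are the
study conditions: 6 samples per age group (3 male, 3 female, labels only —
no sex effect is simulated by default), a 50-gene cluster at 2 kb spacing
on one chromosome of three, 300 miRNA genes total, per-gene log-normal
baselines (median 200 counts, σ = 1.2) with a single dominant/minor arm
ratio of 30 (real arm ratios span ~1–500; configurable), NB dispersion
0.05 (BCV ≈ 0.22, typical for inbred-mouse replicates and the value used
throughout the power analyses), library sizes uniform within ±20 % of a
1 M-read target, and 60 % of cluster genes repressed to an old/young ratio
of 0.6.  The ratio field also accepts a (low, high) range sampled per gene
— (0.5, 0.75) reproduces a "25–50 % decline" design.  Organ matrices use
six organs, 2000 genes, n = 5/group, and planted 2-fold aged-up genes (one
gene up in four organs, two decoys in ≤2); two-fold is a realistic effect
for aged-upregulated inflammation genes and keeps the 4-of-6 recovery
reliable given the power ceiling above.  Ct tables are generated as
Ct = base + group shift + N(0, 0.3²) against a constant reference assay,
with shifts 0 / 0.515 / 1.322 cycles (relative expression 1 / 0.70 / 0.40)
for young / old / very old.

What it does not emulate: read-level artifacts (adapter, mapping,
multi-mapping), isomiRs, GC or length biases, correlated dispersions,
batch structure, sex-specific effects (off by default), or real database
noise in target predictions.  Passing the recovery tests therefore shows
the inference chain is correct under its own model assumptions — not that
those assumptions hold for any particular real dataset.

## Determinism and degenerate inputs

Every stochastic stage draws from `numpy` Generators seeded from the single
config seed with fixed per-stage stream offsets; identical configs give
bit-identical outputs, including GFF3/TSV/JSON files (the end-to-end test
asserts byte equality of two runs).  Readers reject rather than coerce:
negative or non-integer counts, orphan mature arms, malformed GMT lines,
Ct values outside (0, 45), and unknown target-table columns are all hard
errors naming the offending record.  Coordinates are 1-based inclusive
everywhere except BED export, the single conversion point.
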