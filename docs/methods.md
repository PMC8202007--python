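# Methods

This note documents the models behind each pipeline stage, the defaults and
why they were chosen, what the synthetic generator does and does not
emulate, and the numerical conventions that matter for reproducibility.

## Design under study

The pipeline targets a pooled composite-library design: for each of six
conditions (two sexes × wild-type liver W, peri-tumor precancerous tissue
P, hepatic tumor T) several animals' RNA is mixed equivalently into one
sequencing library. There are therefore no biological replicates at the
library level; each count table column is a single deep library (tens of
millions of small-RNA reads). All inference choices below follow from that
constraint.

## Normalization

TPM is plain library-size scaling (`x · 1e6 / column total`); columns of
the TPM table sum to 1e6 by construction. TMM factors are computed pairwise
against a reference library (the group whose total count is closest to the
mean total) exactly in the published trimmed-mean-of-M-values form: log
ratios M and average log abundances A over features positive in both
libraries, a double trim keeping features whose average ranks fall inside
the central 40% by M (30% off each tail) and 90% by A (5% off each tail),
and a weighted mean of the surviving M with inverse delta-method variance
weights; the factor is 2 to that mean, and factors are rescaled to
geometric mean 1. The implementation is cross-checked in the test suite
against Bioconductor's edgeR `calcNormFactors` (agreement ≤ 1e-8) and
against an independent loop-based re-implementation (≤ 1e-10). Effective
library size = raw total × factor.

Composition bias is the reason TMM exists here: planting strong one-sided
expression changes (or real tumor biology) inflates the apparent depth of
the affected groups; the trimmed mean removes it as long as a majority of
the mass is not differentially expressed.

## Differential expression without replicates

With one library per condition the NB dispersion φ (var = μ + φμ²) cannot
be estimated, so it is a configuration parameter, default **φ = 0.05** — a
plausible value for pooled composites of an inbred strain, where pooling
averages out most biological variability. This is the standard escape
hatch for unreplicated count designs; q-values are otherwise uncomputable.
The sensitivity of calls to φ can be explored directly through the config.

The test for contrast a/b conditions on the two-group sum s = x_a + x_b.
Under the null of equal relative abundance, the expected split is
proportional to the TMM-effective library sizes (p_a = Ñ_a/(Ñ_a+Ñ_b)):

- φ = 0: the conditional law is exactly Binomial(s, p_a) (Poisson counts).
- φ > 0: the conditional mass is computed by direct summation,
  f(k) ∝ NB(k; μ_a0, φ) · NB(s−k; μ_b0, φ) over k = 0..s with null means
  μ_a0 = s·p_a, μ_b0 = s·(1−p_a), evaluated in log space with a single
  gammaln array reused for both orientations.

Two-sided p-values double the smaller tail, with the observed point
included once in each tail, capped at 1 — the standard exact-test
convention. BH correction runs across all miRNAs within each contrast.
log₂ fold changes use TMM-adjusted abundances with a pseudo-count of 0.5
on both counts to keep zeros finite. The DEMIR gate is q ≤ 0.05 and
|log₂FC| ≥ 1, both boundaries inclusive; a miRNA is a DEMIR overall when
it passes in at least one pairwise contrast. Under null simulations (500
miRNAs, 20 seeds) the empirical type-I error at α = 0.05 stays at or below
nominal; the suite enforces ≤ 0.07.

## QC

Pairwise Pearson R² and a 3-component PCA operate on log₂(TPM+1) — the
transform is unstated in most published workflows; log with pseudo-count 1
is the common choice. Constant columns are flagged, not crashed on.
Saturation curves count distinct detected miRNAs (count ≥ 1) under
binomial thinning; thinning is *nested* (each shallower depth thins the
next deeper draw), which makes the curve monotone by construction rather
than only in expectation.

## Pattern grading

The three within-sex contrasts give each miRNA a signed significance
triple; significant contrasts order their two stages, non-significant ones
equate them. Of the 27 signed triples, 13 are realizable as weak orders of
{W, P, T} (graded 1..3 from the bottom, minimum grade always 1): the
all-equal order is `flat`, nine orders carry the named subtype/category
labels, and three orders (P>T>W, P>W>T, W>T>P) have no named biological
reading and are labelled `other`. The 14 contradictory triples (e.g. T<P,
T>W, P=W) get their own `inconsistent` label instead of a forced grade —
they are possible because the three tests are marginal, and silently
coercing them would fabricate a trajectory.

The recurrence filter keeps miRNAs with ≥ 2 significant contrasts,
counted by default across both sexes' six contrasts (a per-sex mode is a
flag): the joint display of both sexes motivates the pooled reading, and
the cross-sex case (one hit per sex) is deliberately included. Shared
status between sexes requires the same *category* (direction of the tumor
association), not the same subtype — grouping is by direction, and
requiring subtype identity would split e.g. `T>P=W` from `T>W>P` miRNAs
that agree biologically. Venn region counts over the three within-sex
DEMIR sets are emitted per sex, by default before the recurrence filter
(flag `venn_after_filter` for the other order).

## FFL networks

Target edges pass when the pair has total context score < −0.3 in the
first prediction source AND target score > 50 in the second
(pair-level intersection; "present in both sources" is the defining
phrase, and a union mode exists behind a flag). Thresholds are strict
inequalities; −0.3 exactly fails. Pairs whose target is a TF (the TF flag
comes from the differentially expressed mRNA table) are classified as
miRNA-TF rather than duplicated under both relations, keeping the four
relations and the three node classes disjoint in all accounting. Binding
edges require core score = 1.00 (tolerance 1e-9) and matrix score > 0.95;
TF self-edges are dropped by default (flag to allow).

The anti-correlation constraint keeps miRNA repression edges only between
oppositely regulated partners, with each miRNA's direction taken from its
pattern category (positive categories = up at the tumor stage); edges with
missing annotation are dropped and counted, never silently lost. TF edges
are unconstrained. FFL enumeration visits each gene's TF × miRNA regulator
pairs (linear in output size, identical to the O(n³) scan verified in the
tests) and types each triple exclusively: TF→miRNA only = TF-FFL,
miRNA⊣TF only = miRNA-FFL, both = composite-FFL. The summary reports FFL
counts by type, the union-of-FFL edge counts by relation, and node counts
by class.

Sub-networks group the FFLs of one type; node degree is the undirected
count of incident edges within the sub-network (regulation direction is a
biological, not a centrality, property). Hubs are the top ceil(0.25·n)
degrees per node class including all ties at the cutoff — conventional hub
definitions avoid arbitrary exclusion among equals — and the secondary
network is the induced subgraph on the kept nodes.

## Region localization

Membership is by locus midpoint against a 0-based half-open interval, so a
miRNA is never double-assigned (any-overlap is a flag). The default region
is a *placeholder* interval on mouse chr12 standing in for the Dlk1-Dio3
imprinted cluster (12qF1; human 14q32): published analyses name the
cytoband but not coordinates, so the interval is configuration, not fact.
Fractions are printed as one-decimal percentages of placed DEMIRs;
unplaced miRNAs are counted separately and inside + outside + unplaced
always partitions the DEMIR set. The pooled between-sex figure uses the
union of the three contrast DEMIR sets and also reports the
sum-over-contrasts for comparison, since "between the two sexes"
denominators are ambiguous between the two readings. Over-representation
of the region among DEMIRs relative to all placed miRNAs uses the
conditional (Fisher) exact test with a Haldane 0.5 correction of the odds
ratio when a cell is zero.

## Over-representation

Generic hypergeometric ORA replaces any web-service enrichment step:
p = P(X ≥ k) for overlap k between the query and each gene set
(intersected with the universe), BH across tested terms, Log10(P) and
Log10(q) reported alongside count and percent-of-query. The universe is
the supplied background table (e.g. the down-regulated mRNA set), not the
genome — web services default to genome-wide backgrounds, which makes
their p-values incomparable to these; the choice is documented rather than
hidden. Terms with overlap below `min_overlap` (default 3) are skipped.
Term clustering of redundant pathways is out of scope; terms are reported
flat.

## Synthetic data: what it emulates and what it does not

The generator plants a recoverable answer key for every stage. Counts are
one NB draw per miRNA per group (no replicates, like the pooled design)
around lognormal baseline abundances (log-mean 6.5, log-sd 1.5 on a TPM
scale — a heavy-tailed abundance spectrum typical of miRNA libraries);
planted miRNAs scale their absolute means by effect_fold^(grade−1) along
their subtype's W/P/T ordering, and expected counts are *compositional*
(each column renormalized to its library size), so planting induces
exactly the composition bias TMM is meant to remove. Ground-truth DEMIR
labels derive from absolute fold changes at the |log₂| ≥ 1 gate. Default
library sizes (21–31 million) mirror deep pooled small-RNA libraries; the
dispersion default matches the DE stage's φ = 0.05. Recovery benchmarks in
the tests and acceptance script run at 5M-read libraries with effect fold
8 and 200 miRNAs per run — the smallest sizes at which the planted-recovery
claims (sensitivity ≥ 0.90, FDP ≤ 0.10, subtype recovery ≥ 0.95) are
meaningful while keeping the suite quick.

Loci place exactly round(frac_in_region · n) midpoints inside the
configured region and scatter the rest on other chromosomes. Score tables
plant FFLs on disjoint (TF, miRNA, gene) triples with scores strictly
inside the passing ranges; decoys either fail at least one threshold or
are passing edges constructed so that no unplanted triangle can close
(miRNA-only and TF-only target genes), which is what makes planted FFL
recovery exactly 100% rather than approximate. A `decoy_random` flag
produces unstructured noise for stress testing, at the cost of an exact
answer key. Ct tables follow Ct = Ct_ref − log₂(abundance) + N(0, σ) with
a constant reference, so ΔΔCt ratios reproduce TPM ratios up to noise.

What the generator does **not** emulate: sequence-level artifacts (no
FASTQ, no mapping bias), miRNA families and shared seed sequences,
correlated dispersion across related miRNAs, isomiR ambiguity,
batch effects, or realistic pathway topology. Passing recovery tests
therefore demonstrates the pipeline's correctness on its stated model, not
robustness to the full messiness of real libraries.

The `network_accounting_fixture` is a separate deterministic construction:
given per-relation edge counts and per-class node counts it builds an edge
set in which *every* edge and node participates in at least one FFL, by
covering all TF/miRNA link edges with dedicated genes and adding extra
gene edges only along existing link adjacencies. It exists to verify the
summary accounting at published scale (1,182 edges, 326 nodes).

## Numerical conventions

- Exact-test p-values are computed in log space; the conditional mass is
  normalized by its own sum, making the result invariant to the NB
  normalizing constants.
- Floats in JSON outputs are serialized at 6 significant digits; tables
  are TSV with fixed headers; reports are key-sorted for byte-stable
  diffs.
- All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; sub-generators (loci, edges, Ct, pathways)
  use fixed offsets from the config seed, so runs are bit-reproducible.
- Degenerate inputs fail loudly: zero-total libraries, negative
  dispersion, empty ORA universes, undersized regions and unknown labels
  raise `ValueError`; pipeline stages wrap failures in `StageError` with
  the stage name.

## Known limitations

- The fixed common dispersion is an assumption, not an estimate; with a
  single library per group no data-driven alternative exists, and all
  q-values inherit it.
- Fold changes are computed from TMM-adjusted counts with a pseudo-count;
  at very low counts the gate is conservative by design.
- The exact test conditions on estimated null means; it is exact for
  φ = 0 and a conditional approximation for φ > 0 (verified against
  direct summation, but still conditional on the plug-in split).
- Region coordinates, pathway sets and the TF flag are inputs; the
  pipeline validates and accounts for them but cannot detect wrong
  annotation.
- Literature-based filtering of network components (database/PubMed
  curation) is a manual step and out of scope.
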