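# Methods

## The model

A mutational signature σ is a probability vector over the 96
strand-collapsed single-base-substitution classes (central pyrimidine with
its 5′ and 3′ neighbours; purine-centred observations are reverse
complemented, so AGC>ATC is the same event as GCT>GAT). A binding-change
table for one TF experiment assigns a score and a p-value to every
single-nucleotide change at the centre of every 11-mer; positive scores
mean increased binding affinity and the p-value is a strictly decreasing
function of |score|. The 6,291,456 canonical 11-mer changes partition into
the 96 classes, 65,536 changes each.

The signature-weighted score distribution is the mixture
D′_σ = Σ_μ σ_μ · D_μ, where D_μ is the (equal-frequency) distribution of
scores over the changes of class μ. Internally a table is a dense
(96 × 4^{2f}) array pair (f = flank width; 4 at full scale), so D′_σ never
needs to be materialized per change: each change of class μ carries mass
σ_μ / 4^{2f}, and all tail areas are exact dot products between σ and
per-class tail counts. Histograms are presentation only.

Benjamini–Hochberg FDR < 0.1, applied **jointly** to all of a table's
p-values, induces the significance threshold T = min |score| among passing
changes; because p decreases in |score|, the passing set is {|score| ≥ T}.
Tails are therefore computed with an inclusive comparison (score ≥ T,
score ≤ −T), which makes the tail set identical to the BH-passing set —
with a strict comparison the minimal passing change would be lost. Since
p depends only on |score|, one symmetric threshold serves both tails; a
per-sign alternative would require separate BH runs and is not what the
joint construction yields. The gain and loss ratios are

GR = area(D′_Pos) / area(D_Pos), LR = area(D′_Neg) / area(D_Neg),

with the denominators evaluated under the uniform signature (1/96 per
class). The uniform-signature identity GR = LR = 1 holds exactly, and both
ratios are linear in σ, two invariants the test suite asserts.

Tables whose p-values are not monotone in |score| are accepted with a
warning and monotonized per score sign (running minimum along increasing
|score|), preserving the threshold construction. A table in which no
change passes BH has undefined ratios; these propagate as missing values
(never 0 or 1) and are imputed as 1, with a logged count, only inside
clustering.

## Resampling significance

The null hypothesis is that the excess positive-tail mass
area(D′_Pos) − area(D_Pos) is no larger than expected when mutations arise
with equal class frequencies. Each replicate draws class counts from the
uniform multinomial over 96 classes (default n_mutations = 10,000),
renormalizes them to a pseudo-signature, and recomputes the excess; the
reported p-value is the add-one estimator (1 + #{null ≥ observed}) /
(n_reps + 1), default n_reps = 1,000. The negative tail is treated
symmetrically. The observed statistic uses σ itself (not a draw), so the
uniform signature sits at the null's centre with p ≈ 0.5. Seeds are
mandatory in the CLI; the model facade spawns one child seed per
(experiment, signature) pair from the user seed, making results
independent of evaluation order. n_mutations is exposed because the
natural choice in tumor analyses — the observed mutation count — is
dataset-dependent; no single default is privileged.

TFs assayed in multiple experiments are summarized by the standard median
(mean of the middle two for even counts) of GR, LR and the resampling
p-values; a (TF, signature) pair is called gain-of-binding when its
aggregated p_gain < α (default 0.05), loss-of-binding analogously.
Matrices of per-TF GR/LR are clustered on both axes with complete-linkage
agglomerative clustering on Euclidean distance; orderings are
deterministic given input order, and dendrograms are exported as Newick.

## Promoter spectra

Promoter regions span 2000 bp 5′ to 2000 bp 3′ of each annotated TSS
(feature start on +, feature end on −; 4001 reference bases, 0-based
half-open internally, inclusive at both 1-based boundaries). The window is
applied strand-agnostically on the reference because mutation classes are
strand-collapsed anyway. Transcripts sharing a TSS are handled at the
gene level (one region per GTF gene feature); overlapping regions are
retained, and a mutation inside several regions counts once by default
(membership semantics — spectra count mutations, not mutation–region
pairs; a per-region switch exists). Tumors are selected when their
exposure fraction for the target signature is ≥ 0.4 (inclusive), and
mutations are optionally restricted to the signature's major substitution
types — the smallest set of the six types, in descending mass order with
canonical-order tie-breaks, whose cumulative mass strictly exceeds 0.9.
Ref alleles are checked against the genome and mismatches dropped with a
logged count; "chr1" and "1" naming styles are normalized on load.

Spectrum-based and signature-based GR/LR are compared per signature by the
squared Pearson correlation of the pooled paired GR and LR values.

## Entropy analysis

The entropy of a k-mer is the Shannon entropy of its base-composition
frequency vector, in bits by default (the log base is a parameter; the
published analyses this mirrors did not state theirs, so no numeric
agreement with any particular printed median is claimed). ΔH for a change
is H(mutated) − H(reference); it depends only on the composition multiset
and is invariant under position permutation and reverse complement.
AT-richness (> 60% A+T) and GC-richness (< 40%) are evaluated on the
reference k-mer with strict inequalities. The signature-expected ΔH over a
filtered context set weights each eligible change by σ_μ / |eligible
changes of μ| (renormalized over the filter; classes with empty eligible
sets are skipped and logged). It is computed exactly by enumerating flank
*compositions* with multinomial multiplicities — 165 compositions instead
of 65,536 k-mers per class at full scale — and is validated against direct
enumeration at small flank. Per-table medians/MADs over filtered change
sets use the normal-consistent MAD (factor 1.4826). TFs are labelled
AT-PWM (> 60% mean A+T in the PWM) or GC-PWM (< 40%), using the median AT
percent for TFs with several PWMs.

## Enrichment

Over-representation of a TF set in each gene set of a GMT collection is a
one-sided Fisher exact test on (query∩set, query∖set, set∖query, rest of
background), with BH q-values across sets and a q < 0.005 significance
flag. The background defaults to the union of the collection's sets;
analyses of assayed-TF subsets should pass the assayed universe
explicitly, since the proper universe is analysis-specific. Symbols are
matched exactly after upper-casing; no alias resolution.

## Synthetic data

The generator produces every input the pipeline consumes, with the
statistical structure the method assumes rather than biological realism:

* **Toy score tables.** A toy TF is a consensus-derived log-odds motif
  (heterogeneous per-position probabilities, so scores are spread rather
  than atomic). Binding of a k-mer is a softplus-sum occupancy score over
  all motif offsets and both strands: off-motif windows contribute
  essentially nothing, so most central changes score near zero and only
  motif-creating/destroying contexts reach the tails — the shape real
  PBM-derived tables show. A change's score is the binding difference plus
  seeded Gaussian noise (sd 0.25), and its p-value is the two-sided normal
  tail of score/2.5, exactly decreasing in |score|. At these defaults
  about 2% of a reduced-flank table's changes pass BH FDR < 0.1, keeping
  both tails non-degenerate. Reduced flank 2 (256 changes per class,
  24,576 total) is the default test scale; flank 4 reproduces the full
  11-mer geometry.
* **Signatures** from per-type masses, spread within type either uniformly
  or as a mild Dirichlet draw (concentration 15, CV ≈ 0.25, emulating
  smooth broad-spectrum catalog signatures — the package's "flat"
  fixture).
* **Cohorts.** A uniform-random genome with evenly spaced, random-strand
  gene TSSs; mutations drawn class-first from σ and placed uniformly over
  genomic positions whose ±1 bp context realizes the class on either
  strand; exposures record the generating fractions. Because positions
  are context-matched, the promoter-restricted spectrum recovers σ up to
  multinomial noise when promoters tile the genome (the test geometry:
  20 kb, 5 TSSs at 4 kb spacing).

What passing synthetic tests does **not** show: real genomes have biased
composition, clustered mutations and region-dependent mutation rates;
real score tables have experiment-specific noise structure; and real
signature exposures are estimated, not known. The synthetic recovery
results validate the statistic's mechanics and implementation, not its
biological conclusions on any particular dataset.

## Problem sizes and numerical choices

The test suite and acceptance script run at reduced flank (2, or 1 for
brute-force oracle comparisons) with 10⁵-mutation cohorts and ~10³
resampling replicates; these sizes make the full suite run in well under a
minute while leaving every statistical check comfortably powered. Exact
identities (uniform ratios, oracle equivalence) are asserted at 1e-12,
analytic linearity at 1e-9, stochastic checks at conventional levels
(GOF at 0.01, direction plus p < 0.05). Ties in |score| at the BH
threshold are handled by the inclusive tail comparison; ties in type mass
during major-type selection break by canonical type order for determinism.

## Known limitations

* The score tables describe 11-bp windows; TFs with longer recognition
  sequences (many C2H2 zinc fingers) are only partially characterized by
  construction, and the toy generator inherits this.
* The equal-frequency baseline ignores genomic context availability
  (e.g. CpG depletion); GR/LR compare processes, not absolute rates.
* BH is applied jointly across both score signs; if a source table's
  p-values were computed per sign, thresholds would differ slightly.
* Undefined ratios (no significant tail) are reported missing; downstream
  clustering imputes 1, which understates uncertainty for such tables.
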