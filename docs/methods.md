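# Methods

## Problem setting

*Pseudomonas* species differ markedly in their bioactivity, but 16S rRNA
amplicons cannot separate them: many species are less than 1% dissimilar
in 16S. The single-copy housekeeping gene *rpoD* (sigma-70 factor of RNA
polymerase) carries species-level signal, and the PsEG30F/PsEG790R primer
pair brackets a 736 nt fragment of it (length counted including both
primer footprints: 17 nt forward + 703 nt insert + 16 nt reverse). On a
2×300 nt paired-end platform the mates of such an amplicon cannot
overlap — a ~760 nt product leaves a 160 nt uncovered interior gap — so
the usual merge-then-cluster (OTU/ASV) pipelines do not apply. The
package instead classifies each read pair directly against a reference
database of amplicons, in the style of paired RNA-seq annotation.

## In-silico PCR

**Matching model.** A primer site is an anchored, edit-style alignment of
the degenerate primer against the template, with two separately counted
budgets: at most `max_mismatch` substitutions (default 1) and at most
`max_indel` single-base insertions/deletions (default 1). A degenerate
IUPAC code matches a template base iff the base belongs to the code's
set. There is no 3'-terminal anchoring. Two deliberate choices:

* *Template ambiguity codes never match.* An `N` in a template (typically
  a contig gap) counts as a mismatch against every primer code; otherwise
  runs of `N` would act as universal primer sites.
* *Simultaneous mismatch+indel.* The budgets are independent, so an
  alignment using one substitution **and** one indel is within the
  default budget. The semantics are pinned by a brute-force oracle in the
  test suite (exhaustive enumeration over positions × primer expansions ×
  in-budget edit variants); the scanner must agree exactly with it.

**Scanning.** With at most one indel, every anchored alignment is "exact
shift up to a split point, then shift ±1", so per-position minimal
mismatch counts follow from prefix sums of three shifted mismatch
matrices; the scan is fully vectorised for the default budgets and falls
back to explicit search for larger ones. Both strands are scanned
(reverse-strand sites are reported in forward coordinates). Overlapping
same-strand matches at adjacent offsets describe the same physical site
and are deduplicated by lowest edit count, then leftmost position.

**Amplification.** A product joins a forward-primer site to a
reverse-primer site on the opposite strand downstream. Each forward site
pairs with its *nearest* compatible reverse site (PCR's dominant short
product); an all-pairs mode exists for hunting anomalously long products.
Products longer than `max_len` (default 5,000 nt — generous enough to
expose "much longer than expected" pathologies while bounding runaway
scans) are discarded. Both template orientations are handled, and
amplifying the reverse complement of a template yields the same product
lengths with the primer roles exchanged (a tested invariant).

**Benchmarking.** A template counts as amplified iff it yields at least
one product; a primer pair's figure of merit over a collection is the
fraction amplified, the fraction of negative controls amplified, and the
list of products outside the expected length window.

## Reference database

One record per amplified template: the shortest product (ties: first),
with both primer footprints trimmed. Records carry species / group /
subgroup labels (the hierarchical taxonomy used for *Pseudomonas*, e.g.
the P. fluorescens group with subgroups such as P. jessenii). The FASTA
header dialect `>id|species|group|subgroup` (spaces → underscores, `|`
forbidden in fields) is the classifier's contract.

Discriminability is audited by greedy identity clustering: records are
seeded in descending length order (ties broken by id, making the result
deterministic), each joining the first centroid with global-alignment
identity ≥ threshold (default 0.97). Identity is matches / alignment
columns *including gap columns* — the conservative denominator. Species
sharing a cluster are reported as mutually confusable (the
P. putida / P. monteilii situation); everything else is resolvable.
Multiple-sequence alignment and tree building are out of scope — identity
clustering covers the resolvability question the database needs answered.

## Classifier

**Stages.** Exact-prefix barcode demultiplexing (barcodes are short, so
no mismatch tolerance; equal-length unique barcodes required) → 3'
sliding-window quality trim (window 4, mean Phred < 20 cuts; pair
discarded if either mate drops below 100 nt — defaults of the common
trimming-tool family, all overridable) → per-mate alignment → concordance
filter → uniqueness threshold → tabulation.

**Alignment engine.** Internal, not an external mapper. Scoring: match
+2, mismatch −3, gap open −5, gap extend −2 (a gap of length g costs
5 + 2g). Per-mate hits below a floor of 60% of the maximal score (2L) are
dropped. The engine screens each reference with a banded edit-distance
infix search (edlib) under budget k = (2L − floor)/5 — valid because each
unit edit costs at least 5 score units relative to a perfect match — and
then computes exact affine-gap local (Gotoh) scores with a numba-compiled
banded kernel, but only for references within a fixed margin (60, beyond
the Q cap) of the best screening bound. References outside the margin
keep their screening bound: they can neither win the assignment nor pull
the uniqueness score below its cap. Screening is end-to-end on the mate,
which assumes amplicon reads align over (nearly) their whole length;
heavily clipped alignments whose end-to-end distance exceeds k would be
missed. That is the right trade for primer-anchored amplicon reads.

**Concordance and uniqueness.** Mate 1 aligns forward, mate 2 is reverse
complemented first (the fixed amplicon orientation; primers anchor read
orientation, so the reverse-forward case is not searched). A reference is
concordant when both mates hit it and the implied fragment length falls
in 400–1,000 nt (bracketing the 736 nt product). Pairs are ranked by
combined score S; the uniqueness score is Q = c·(S_best − S_second) with
c = 1, capped at 42 (the familiar mapping-quality ceiling). When only one
concordant reference exists, the per-pair score floor stands in for
S_second. A pair is assigned to the best reference's species iff
Q > 10, strictly; exact ties give Q = 0 and stay unassigned. One
published description of this filter says "quality of >10", another
"minimum bit score of 10"; a best-versus-second-best separation score
with threshold 10 is implemented, since the filtering is explicitly
mapping-based. Every stage logs counts, and
assigned + unassigned + discarded = input pairs is asserted end to end.

**Normalisation.** Scaling each sample row to a common depth (default
100,000), preserving composition exactly and allowing fractional values;
a seeded rarefaction (subsampling) mode exists behind a flag for users
who want integer counts.

## Community statistics

* **Observed/expected ratio**: 100·observed/expected per replicate, with
  mean ± SD (ddof = 1) across replicates.
* **Bray-Curtis**: Σ|xᵢ−yᵢ|/Σ(xᵢ+yᵢ) (scipy); symmetric, in [0,1], zero
  iff equal — property-tested.
* **PCoA**: double-centred eigendecomposition. Non-Euclidean matrices
  (negative eigenvalues beyond a relative tolerance of 1e-8) get the
  Cailliez correction — the smallest constant added to off-diagonal
  distances making the configuration embeddable — and the constant is
  recorded in the result.
* **Beta dispersion**: each sample's distance to its group's *spatial
  median* (Weiszfeld iteration, tolerance 1e-10) in PCoA space; the
  group dispersion is the mean distance. The spatial median is the
  conventional default of this analysis; a centroid option exists. Two
  groups are compared with a two-sided Mann-Whitney U test on the
  per-sample distances; singleton groups are rejected.
* **Mann-Whitney U**: exact enumeration of the null distribution when
  n·m ≤ 400, tie-corrected normal approximation otherwise (scipy behind
  the module surface). Calibration is tested: under a seeded null the
  type-I error at α = 0.05 stays within [0.03, 0.07] over 10,000
  replicates.
* **NMDS**: non-metric SMACOF majorization (scikit-learn) from 20 seeded
  random starts; Kruskal stress-1 √(Σ(d−d̂)²/Σd²) is recomputed with
  isotonic regression and the best restart wins. Same seed → identical
  output. Published stress values from the original field data
  (0.1883, 0.1039) require that data and are not reproduced here.
* **Chao1** (bias-corrected): S_obs + F₁(F₁−1)/(2(F₂+1)) via scikit-bio;
  Chao1 ≥ S_obs always, with equality iff F₁(F₁−1) = 0.
* **Rarefaction**: analytic hypergeometric expectation
  E[S(d)] = Σᵢ(1 − C(N−nᵢ,d)/C(N,d)), computed with log-gamma; verified
  against Monte-Carlo subsampling within 3 SE at 10,000 draws.
* **qPCR anchoring**: least-squares CT = slope·log₁₀(CFU) + intercept
  (≥3 points spanning ≥2 log units, slope < 0 required); efficiency
  E = (10^(−1/slope) − 1)·100, with the slope↔efficiency round trip
  tested to 1e-9. Absolute abundance is total CFU/g × relative/100.

## Synthetic data

The generator defines the benchmark conditions: a 166-entry database of
736 nt references evolved from one random ancestor by independent
per-site substitution (rate 1.2× the divergence target; the draw repeats,
still seed-deterministically, until the realised *minimum* pairwise
divergence meets the target — ≥3% by default, ~4% realised; targets above
35% are rejected as unreachable since two independently mutated lineages
saturate near 75% difference). Constant-rate evolution without rate
heterogeneity is intentional: divergence control, not phylogenetic
realism, is the goal.

Reads: mate 1 is the first 300 nt of the amplicon, mate 2 the reverse
complement of the last 300 nt; substitution-only i.i.d. errors at 0.5%
by default (amplicon Illumina error is substitution-dominated, and the
choice keeps score arithmetic hand-checkable); constant Phred 37
qualities with an optional linear 3' decay to exercise the quality
filter; optional barcode prefixes for demultiplexing fixtures. Sample
composition is equimolar, user-specified, or log-normal (σ = 1.5) with
largest-remainder apportionment of read counts; the `mock16` preset
draws 16 members from the full database and emits 1,000 pairs per
species (16,000 pairs) by default.

**What passing benchmarks do and do not show.** The simulator has no PCR
amplification bias, chimeras, primer-efficiency differences between
species, contaminant load, or indel sequencing errors. Perfect mock
recovery here demonstrates that the classification logic is correct under
the stated error model — it does not predict recovery of species that
real primers amplify poorly, and the low concordant-mapping rates seen in
real soil data (driven by PCR artifacts) are not reproducible
synthetically.

## Problem sizes and determinism

The test suite exercises the mock community at 200 pairs per species
(3,200 pairs against 166 references); the acceptance script runs the full
1,000 pairs per species (16,000 pairs), finishing in about two minutes on
one CPU. All stochastic stages take explicit seeds; classification output
is sorted by pair id and therefore independent of read order.

## Known limitations

* The in-silico PCR scanner is tuned for gene/amplicon-scale templates
  (kilobases); whole-genome scans work but hold three m×n mismatch
  matrices in memory per strand.
* Mate orientation is fixed (forward/reverse-complement); amplicons
  cloned in inverted orientation would be reported discordant.
* Barcode matching is exact-only by design; a single sequencing error in
  a barcode discards the pair to the unassigned pool.
* Identity clustering is greedy and order-deterministic, not optimal;
  borderline clusters near the threshold can depend on seeding order,
  which is why the order rule is fixed and documented.
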