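# Methods

## Feature extraction

### SNV (96 classes)

Substitutions are classified by the changed base pair and its immediate
5′/3′ reference context. Purine-reference calls are reverse-complemented
together with their context (the 5′ and 3′ bases swap and complement),
folding the 12 ordered base changes × 16 contexts = 192 raw combinations
two-to-one onto 96 pyrimidine-reference classes. Flanking bases are read
from the reference genome, never from the VCF.

Record acceptance is deliberately conservative and fully accounted:
only single-base REF/ALT alleles are classified (multi-allelic records
are decomposed and each single-base ALT counted independently); by
default only PASS/unfiltered records are used (`--keep-filtered`
overrides); a record whose VCF REF disagrees with the reference base at
that position is skipped (guards against genome-build mix-ups), as are
records at contig edges or with an N flank. Every skipped allele is
tallied by reason, and `accepted + skipped = total` is an invariant the
tests enforce. A contig missing from the reference is a hard error, not
a skip — it almost always means the wrong genome was supplied.

### SV (32 classes)

`SVTYPE` maps DEL→deletion, DUP (incl. `DUP:TANDEM`)→duplication,
INV→inversion, TRA/BND→translocation; unknown types are skipped with a
tally. Event size is `END − POS` for intra-chromosomal events (no +1:
a 10,001→25,001 duplication is 15,000 bp). For translocations the size
is the breakpoint distance — the quantity encodes how far material
moved, not how much — and inter-chromosomal events get infinite size.
Size bins are half-open lower-inclusive decades [10^k, 10^(k+1)) for
k = 2..8. The whole-chromosome bin receives infinite sizes, sizes ≥ 1 Gb,
and intra-chromosomal events spanning at least the contig length
declared in the VCF header (the catalog's large finite bins exceed real
chromosome lengths, so a membership rule had to be chosen; this one is
ours). Events under 100 bp are below the catalog and tallied as skipped.
Breakend mate pairs describe one junction twice; only the record whose
(contig, position) sorts first is counted, the mate is tallied as
`breakend_mate`.

### MSI (18 classes)

A repeat unit of length 1–3 is reduced to its smallest period ("ACAC" →
"AC") and mapped to the lexicographically smallest string among all
cyclic rotations of itself and of its reverse complement. Exhaustive
enumeration of all 84 units of length 1–3 shows this convention yields
exactly 16 classes — A, C, AC, AG, AT, CG, AAC, AAG, AAT, ACC, ACG, ACT,
AGC, AGG, ATC, CCG — which the test suite asserts. Units of declared
length 4–5 are pooled into `unit4`/`unit5` without pattern checking;
the declared length wins even for periodic units like "ACAC" at length 4.
Input is an MSIsensor-style somatic-site table (chromosome, location,
left flank, repeat unit, repeat times, right flank); quantified loci are
the unstable loci the upstream caller reported, not all scanned
microsatellites.

## Merging and group weights

Per sample and group, counts become fractions summing to 1 and are then
scaled by the group weight (default SNV:SV:MSI = 7:2:1, configurable via
a 3-line weights file validated to sum to 1). Capping each group's total
fraction stops one mutation mode from drowning the others — hypermutated
samples may carry 100× more substitutions than structural events, yet
their SNV block still sums to exactly 70%. Consequences tested as
invariants: column stochasticity (1e-9), group-block sums equal to their
weights (1e-9), and scale invariance (multiplying one group's counts by
a constant leaves the merged column unchanged).

A sample with an empty or missing group aborts the merge by default;
under the `zero-fill` policy the group block becomes zeros and the
remaining groups are re-normalized so the column still sums to 1 (NMF
needs column-stochastic input; a deflated column would silently
down-weight the sample instead). SNV-only or SV-only analyses are the
degenerate weight configurations (e.g. 1:0:0), not separate code paths.

## Deciphering

### Factorization

NMF minimizes the Frobenius reconstruction error with the classical
multiplicative updates, which make the objective non-increasing per
iteration (a tested invariant). Initialization is uniform-random from a
seeded generator, so a given seed yields bitwise-identical factors.
Convergence: relative objective change below `tolerance` (default 1e-6)
or `nmf_max_iter` (default 500). After fitting, P's columns are
normalized to sum to 1 and the scale moves into E. The final model is
the best of `n_restarts` (default 5) seeded restarts; signatures are
ordered by descending total exposure and labeled Signature A, B, C, …
scikit-learn's NMF is used in the tests as an independent cross-check
(same planted signatures at cosine ≥ 0.95, comparable error), never as
the implementation.

### Rank selection

For each candidate k, the matrix is perturbed `bootstrap_iterations`
times (default 100): each sample's per-group fraction block is resampled
as a multinomial draw of `bootstrap_events` events (default 1000 — the
merged matrix carries fractions, not original totals, so a nominal
count scale is used) and rescaled to its original block sum, preserving
column stochasticity and group weighting. NMF runs on every replicate;
the pooled replicate signatures are clustered into k consensus clusters
under the constraint that **each replicate contributes exactly one
signature per cluster** (Hungarian matching to consensus centroids,
iterated to a fixed point; a cosine-distance k-medoids pass provides the
initial centroids). Stability is the mean silhouette of that clustering
on cosine distance; mean relative reconstruction error is reported
alongside.

The replicate constraint is what makes the statistic discriminative:
without it, the surplus components fitted at k = k_true + 1 mostly
duplicate real signatures, clusters stay tight, and the silhouette
hardly drops (we measured 0.90 at k = 4 on a planted k = 3 cohort,
versus 0.54 with the constraint). For k = 1, where the silhouette is
undefined, stability is the mean cosine similarity of the pooled
signatures to their medoid.

The suggested k is the **largest k whose stability reaches
`stability_floor`** (default 0.8). This selection rule is this package's
policy; diagnostics for every k are always written so users can override
(`--force-k`). If no k qualifies, the deciphering step demands an
explicit k rather than guessing.

### Exposure refitting

Per-sample exposures against a fixed P are the non-negative
least-squares solution min‖m − P·e‖, e ≥ 0 (active-set NNLS via scipy).
Reports refit rather than reusing E from the factorization so that the
visualization stage works identically with externally supplied
COSMIC/WTSI signature tables. An all-zero profile yields zero exposures
and is flagged. The tests check NNLS against an exhaustive simplex grid
search (resolution 1e-3, closed-form optimal scale per direction) on 2-
and 3-signature problems.

## Reports and metrics

The per-sample report has four pages: exposure pie chart, observed
profile, reconstruction P·e, and residual (observed − reconstruction,
an exact elementwise identity). The pie chart, the cohort
`normalized_weights.txt` and the association calls all derive from the
same refitted exposure vector. `normalized_weights.txt` holds
percentages at 4 decimal places with a largest-remainder correction so
every row sums to exactly 100; a machine-readable per-sample exposure
table accompanies the PDFs since a PDF is not a testable surface.

Association uses a strict `fraction > 0.30` rule — exactly 30% (or the
26% near-miss) is not associated. TMB divides the total substitution
count by 30 (an exome-scale per-Mbp heuristic exposed as a constant;
whole-genome users should override); SVB is the total structural event
count. Both reject fraction-normalized profiles, detected by
non-whole-number entries: burdens are only meaningful on raw counts.

## Synthetic data

The fixtures module generates every input format from seeds: random
ACGT references (optional recorded N injection), SNV VCFs whose variants
are placed at positions realizing requested trinucleotide classes
(optionally on the purine strand to exercise folding), SV VCFs with
SVTYPE/END/CHR2 tags and true breakend mate pairs, MSIsensor-style
tables whose units are random rotations/reverse complements of the
requested class, and planted-signature cohorts (Dirichlet signatures on
sparse supports with pairwise cosine below a bound, Dirichlet exposures,
multinomial event sampling). All fixtures pass through the public file
parsers, are byte-deterministic per seed, and serialize their ground
truth alongside the data.

What the generator does **not** emulate: mapping artifacts, caller-
specific FILTER semantics beyond PASS, clustered rearrangements,
copy-number-dependent SV dialect differences, or realistic genome
composition (uniform base frequencies). Passing tests therefore
demonstrate correctness of classification, weighting, factorization and
accounting — not robustness to the full messiness of real somatic
call sets.

Default cohort scale for demonstrations and tests: 3 signatures,
40–60 samples, 5000 events/sample (echoing exome-scale substitution
counts), bootstrap 15–40 replicates over k = 2..5. These sizes keep a
full run on one CPU in the tens of seconds while leaving the planted
structure recoverable at cosine ≥ 0.95.

## Known limitations

* Clustered vs non-clustered SVs are not distinguished, and the SV
  catalog's largest finite bins are unreachable on real chromosomes
  except through the contig-length rule.
* The bootstrap count scale is nominal when original event totals are
  unavailable; rank-selection stability is comparative across k, not an
  absolute probability.
* The suggested-k rule (stability floor 0.8, maximize k) is a policy,
  not an estimator with guarantees; inspect the diagnostics.
* MSI locus counts are not normalized by the number of scanned
  microsatellites per sample; within-group normalization at merge time
  makes this moot for fractions but not for absolute comparisons
  between samples.
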