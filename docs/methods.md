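# Methods

## Data model and pre-filters

All processing operates on dereplicated datasets: unique nucleotide
sequences with read counts, assumed aligned, indel-free, same strand, and of
one fixed fragment length (default 313 nt, the 3′ "Leray" region of COI).
Canonical order — decreasing count, ties broken by lexicographic sequence —
is applied on input and output everywhere, which makes every algorithm in
the package deterministic without seeds.  The pre-filters are the exact
fragment length and a minimum abundance (`minsize`, default 2, i.e.
singleton removal); both report per-rule removal counts.

Ambiguity codes are rejected rather than masked: the package assumes
quality-filtered input, and a masked base would silently distort distances
and entropies.

## Positional entropy and the Er diagnostic

For every alignment column we take base frequencies across sequences
(optionally weighted by read counts) and compute the Shannon entropy; the
profile (e₁, e₂, e₃) is the mean of column entropies over the columns of
each codon position.  Natural logarithms by default (maximum ln 4 ≈ 1.386);
base-2 is available.  The frame convention is `frame_offset` — the codon
position of the first column, default 3 for the Leray fragment — and codon
positions cycle through any trailing partial codon.

Defaults chosen where genuinely open:

* `weighting="unique"` (each dereplicated sequence counts once): error
  sequences are mostly singletons, so unique weighting is the more sensitive
  noise detector; read weighting is available for composition-style summaries.
* No automatic plateau/knee detection on the Er-vs-α curve: the curve is a
  decision aid, and the choice of α is left to the analyst.  When a retained
  set has no third-position variability at all, Er is undefined and the
  curve reports NaN rather than 0.

The entropy ratio Er = e₂/e₃ falls as denoising removes noise because
uniform errors inflate the (naturally invariant) second positions relatively
more than the (naturally variable) third positions.

## The merge rule and its extensions

The skew test merges daughter *i* into mother *j* iff
count_i / count_j ≤ β(d) = 1/2^(αd+1).  Choices fixed by design:

* Non-strict inequality (≤): the boundary case merges.  Equal-abundance
  pairs can never merge (skew 1 > 0.5 = β(0)), so "strictly more abundant"
  candidacy needs no extra rule, though it is made explicit in the
  two-phase candidate collection.
* Skew always uses original dereplicated counts, never accumulated cluster
  totals.
* The entropy-corrected distance d_corr = Σ d(i)·eᵢ·3/Σeᵢ enters the β
  exponent as a real number, unrounded.  Correction requires the positional
  metric (per-codon-position Hamming); the Levenshtein metric (via edlib) is
  retained for variable-length inputs but cannot track codon positions.

Classic mode scans existing centroids in decreasing abundance and merges
into the first that fits (skew precedence by construction).  Two-phase mode
records every eligible mother per daughter, then selects one by criterion —
minimum skew, minimum d, or minimum skew/β(d) — with deterministic
tie-breaks (larger mother count, then lexicographic mother sequence).
Chains (a chosen mother that is itself a daughter) are resolved by following
links to the terminal motherless sequence, which receives all downstream
reads.  Parents are strictly more abundant than children, so chains cannot
cycle.

Both modes prune candidate mothers by the abundance bound
count_mother ≥ count_daughter/β(d_floor), where d_floor is the smallest
distance two distinct sequences can have (1, or the minimum single-position
entropy weight under correction).  The pruning is a pure optimisation;
equivalence with a literal O(n²) reference implementation is asserted in the
test suite over random instances.

## Clustering

MOTUs are connected components of the graph linking pairs at distance ≤ d
(single linkage; default d = 13 for the 313-nt fragment).  All member
sequences are retained; the representative is the most abundant member.
The d-selection curve reports total MOTUs, MOTUs with ≥ 2 sequences, and
mean intra-/inter-MOTU distances (intra pooled over MOTUs with ≥ 2 members;
inter over representatives only; means reported as absent, not 0, when no
qualifying pairs exist).

Known fidelity gap: the subsequent abundance-based topological refinement
that SWARM applies after its linkage phase is published elsewhere and not
reimplemented, so intra-MOTU distances here run higher than a refined
clustering would produce.  The identity conversion
100·(L − dist)/L is exact and unaffected.

## Pipeline composition

Denoise-then-cluster clusters the retained ESV set.  Cluster-then-denoise
denoises independently within each MOTU; any entropy profile used for
correction is computed once on the whole dataset, because individual MOTUs
rarely contain enough sequences for a stable estimate.  Read totals are
conserved through every stage and order.  Summary ratios (ESVs/MOTU,
reads/MOTU) are rounded to 3 decimals, half-up, matching the conventions of
published summary tables.

## Benchmarks

The coding-plausibility check translates every MOTU member under a set of
genetic codes (default NCBI tables 1, 2, 4, 5, 9, 13, 14 — standard plus
metazoan mitochondrial variants), keeps the code(s) minimising total
internal stops over the MOTU, and flags an ESV as erroneous only if it shows
a stop or a conserved-residue mismatch under *every* selected code (the
lenient reading of "minimal number of wrong amino acids").  One consequence
worth knowing: an in-frame TAA is rescued by the alternative flatworm
mitochondrial code (TAA→Tyr) and is therefore not flagged on its own,
whereas TAG is a stop under all seven defaults.  The five conserved
amino-acid positions are marker- and taxon-specific and must be supplied by
the caller; the simulator emits a matching synthetic configuration, and no
unverifiable residue set is hard-coded.

MOTU classification against an ESV→species assignment table (identity floor
0.97) is: closed (all of one species' assigned ESVs, nothing else), open
(a proper subset, nothing else), hybrid (≥ 2 species, or assigned mixed with
unassigned members), unassigned (no assigned members; excluded from the
closed/open/hybrid denominator).

The match index MI(A,B) = (N_match_A/N_A + N_match_B/N_B)/2 is symmetric and
undefined (an error, not 0) on empty sets; ESVs match by exact sequence,
MOTUs by exact representative sequence.

## The synthetic community generator

One seeded generator (`numpy.random.default_rng`) drives all randomness in a
fixed stream order: centroids → haplotypes → abundances → per-read errors.
What it emulates, with defaults:

| parameter | default | rationale |
|---|---|---|
| n_species | 50 | a moderately complex benthic-style community |
| fragment_length / frame_offset | 313 / 3 | Leray-fragment geometry |
| inter_species_divergence | 30 subs (~10%) | clear barcode gap at d = 13 |
| haplotypes_per_species | mean 5 (shifted Poisson) | a handful of haplotypes per species |
| intra_species_substitutions | mean 2 per haplotype | shallow intra-species divergence |
| codon_position_weights | (0.15, 0.10, 0.75) | modelling choice, not a measured value: intra-species variation placed mostly at third positions |
| species_abundance | lognormal(0, 1) | skewed species abundances |
| within_species_skew | 0.6 dominant, minors lognormal(0, 1.5) | heavy-tailed haplotype frequency spectrum — few common, many rare variants |
| error_rate | 0 (benchmarks use 0.0005/base) | uniform substitution noise at a realistic post-filtering rate |
| n_reads | 40,000 | deep enough that abundant haplotypes clear the 1/β(1) = 64-read bar at α = 5, so skew merging can operate |

Sequences are generated coding-plausible: per-position base compositions are
biased as in real COI (second positions strongly constrained), no codon is a
stop under any default genetic code (TAA, TAG, TGA, AGA, AGG are avoided),
and five conserved amino acids (G/L/P/W/F at codons 20/40/60/80/100) are
fixed via codons that translate identically under all default codes.
Haplotype-level mutations are rejection-sampled to preserve these
constraints; injected sequencing errors are unconstrained — which is exactly
the asymmetry the erroneous-ESV benchmark detects.

With `denoise_safe`, haplotype counts are power-compressed so that
min/max count > β(α_ref, d_min) for the smallest pairwise haplotype
distance d_min: no true pair is merge-eligible, making exact recovery the
correct outcome for any mode.  The compression (and the floor of one read
per haplotype) means the realised read total can differ from `n_reads`;
read conservation between truth counts and the observed dataset always
holds.  An error read that happens to reproduce another true haplotype is
credited to that haplotype, not counted as an error sequence.

What the simulator does **not** emulate: chimeras, indels, quality scores,
strand errors, nuclear mitochondrial pseudogenes, or position-dependent
error profiles.  Passing tests therefore demonstrate correctness of the
algorithms under the stated noise model, not robustness to every artefact
of real sequencing runs.

## Problem sizes and numerical choices

Simulation-based tests run at 10–50 species and 4,000–40,000 reads with 20
fixed replicate seeds; oracle-equivalence tests use random instances of up
to 200 (denoising) / 300 (clustering) sequences against literal pure-Python
references.  These sizes give stable statistics for the properties asserted
while keeping the default test run fast.  Stochastic properties (Er
inflation under noise, the recall advantage of entropy correction) are
asserted as majorities/means over the fixed replicate set rather than
per-replicate, since rare marginal reversals are expected behaviour, not
failures.

Degenerate inputs are contracts, not crashes: empty datasets denoise to
empty results, Er is an error (or NaN in curve output) when e₃ = 0,
mean intra-/inter-MOTU distances are absent when no qualifying pairs exist,
and non-dereplicated input is rejected everywhere with the offending
records named.
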