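# Methods

## Problem setting

A *cis*-regulatory module (CRM) is a DNA segment that binds several
transcription factors (TFs) and drives a spatiotemporal expression
pattern. A classic discovery strategy scans a genome for short windows
containing binding sites (TFBSs) for a defined factor combination, then
filters candidates by cross-species conservation. This package implements
that pipeline at desk scale, together with the evaluation layer used to
ask whether conservation actually separates predictions that worked in
vivo from those that did not, and a mutagenesis-design tool for testing
whether individual sites are required.

## Motif models and scanning

A motif is either a degenerate IUPAC consensus or a 4×L position
frequency matrix (PFM).

- Consensus scoring: score = L − (number of positions violating the
  code); a hit tolerates at most `max_violations` (default 0).
  Ambiguity codes in the *model* match their IUPAC set; ambiguous bases
  in the *data* (N) never match — model and data play asymmetric roles.
- PFM scoring: summed log2 odds of per-column frequencies (pseudocount
  0.5) against a uniform background. PFMs carry no natural threshold, so
  the default is 80% of the maximum attainable score; for real work the
  threshold should be set from the motif's own calibration. No p-value
  calibration is attempted.

Both strands are scanned by scoring the forward model and its reverse
complement at every offset; all coordinates are 0-based half-open on the
plus strand (BED convention). A site matching on both strands over the
same interval (palindrome) is reported once with strand '+', so that
downstream instance counts are per-interval and never double-count.

## Co-occurrence clustering

"All factors within *W* bp of one another" is implemented as
co-membership in a sliding window of width *W* (default 500 bp): a window
qualifies iff every required factor has at least one hit lying entirely
inside it. A hit [s, e) is inside window [x, x+W) iff x ∈ [e−W, s], so
the qualifying window starts are computed exactly by interval arithmetic
(per-factor union of hit intervals, intersected across factors) rather
than by enumeration. Windows sharing at least one base merge into
maximal regions, which are then trimmed to the footprint of their
contained hits; this makes the output deterministic, order-independent,
and idempotent (re-clustering a region's own hits reproduces the
region). An alternative reading — pairwise proximity between sites —
differs on chained clusters; the fixed-window reading was chosen because
it is unambiguous and testable by exhaustive window enumeration.

The "selected subset" filter then requires a minimum instance count per
factor (default 2, except 1 for dTcf).

## Conservation metrics

All metrics are fractions in [0, 1]; a metric that is undefined for a
region is a first-class MISSING value, serialized as `nd` in TSV output.

- **Conserved fraction** ("AVID" column): the fraction of the region's
  reference bases whose alignment column is an identical A/C/G/T match.
  Substitutions, gaps, and unaligned bases all count against; the
  denominator is the full region length. This is the simplest reading of
  "percentage of conserved nucleotides"; whether unaligned bases belong
  in the denominator is genuinely open, and this package includes them.
- **Conserved-block score** ("AVID+DIALIGN" column): the region is
  extended by `extension_bp` (default 700) on each side and the extended
  alignment is decomposed into *conserved ungapped blocks*. External
  aligners each have their own block notion, so the package defines one
  explicitly: maximal gap-free column runs, trimmed to identical-match
  boundaries, kept when ≥ `block_min_len` (6) columns and
  ≥ `block_min_identity` (0.7) identical. The evaluation span is trimmed
  to the first and last blocks that contain a TFBS of the region, and
  the score is (aligned reference bases inside blocks) / (aligned
  reference bases in the span). If no block contains a site the score is
  MISSING. The score is invariant to the extension size whenever the
  flanks contribute no site-bearing blocks.
- **Track mean**: arithmetic mean of a per-base conservation track
  (e.g. phastCons, ingested from bedGraph or fixed-step WIG; scores are
  clamped to [0, 1] with a warning) over the region.
- **Windowed peak score**: the maximum mean of the track over all
  windows [s, s+w) fully inside the region, for w ∈ {100, 200, 500} by
  default — the first window starts at the region's first base, the last
  ends at its final base. A region shorter than w has no defined value
  (MISSING), never a truncated-window value. The associated cutoff
  (default 0.13) is used only for binary classification, never inside
  the score itself; when w equals the region length the peak equals the
  track mean.
- **TFBS presence**: the fraction of the factor universe (size M)
  retaining at least one *conserved* site, hence always a multiple of
  1/M. A site counts as conserved when its columns are gap-free and the
  orthologous subsequence still meets the motif threshold on either
  orientation — deliberately re-matching rather than requiring column
  identity, since substitutions can preserve binding (a degenerate
  position that changes within its IUPAC set keeps the site).
- **TFBS mismatches**: over all site bases that fall within the aligned
  span, the pooled fraction whose column is not an identical match (gap
  columns count as mismatches). Pooling is per-base across all sites of
  the region, not per-site averaging.

The built-in pairwise aligner (global, affine gap costs; defaults match
+1 / mismatch −1 / open −2 / extend −1) is a thin wrapper over
Biopython's dynamic-programming aligner and is intended for simulated or
small sequences; genome-scale alignments are consumed as pairwise MAF.
Ties between equally optimal paths are broken by taking the aligner's
first reported path, which is deterministic for a fixed Biopython
version — determinism, not any particular preference order, is the
property the pipeline relies on.

## Rank-sum statistics

Positive and negative region sets are compared per metric with a
one-sided Wilcoxon rank-sum (Mann–Whitney) test. Missing values are
deleted per metric (pairwise deletion), so sample sizes vary across
columns. The method switches on ties in the pooled column:

- no ties: exact p-value, P(U ≥ U_obs) under the full U null
  distribution computed by the counting recursion
  c(n, m, u) = c(n−1, m, u−m) + c(n, m−1, u);
- ties: normal approximation with mid-ranks, tie-corrected variance
  n₁n₂/12 · [(N+1) − Σ(t³−t)/(N(N−1))], and a 0.5 continuity
  correction.

This switch mirrors the de-facto convention of standard statistical
software at these sample sizes, and is validated in the tests against
SciPy's independent implementation and against brute-force enumeration
over all labelings. The directional alternative is "positives more
conserved": *greater* for the seven similarity metrics and *less* for
the mismatch metric, which is a dissimilarity. Sample means are reported
with sample SDs (n−1 denominator; SD undefined for n = 1). p-values are
written to 4 significant figures. No multiple-testing correction is
applied across the eight columns, matching the original evaluation's
analysis. `relabel_and_recompute` moves one region to the other class
and re-runs every comparison, leaving the input untouched.

The 13-region evaluation matrix shipped in `crmcooc/data/table2.tsv`
(6 positives, 7 negatives; one row missing all alignment-based values,
one row missing the 500-bp peak value because the region is shorter than
the window) is the package's reference input for this layer.

## Knockout design

Substitution sets confined to the target site's footprint are enumerated
exhaustively: by size (1 up to `cap`, default 3), then by position tuple
in lexicographic order, then replacement bases with transversions
preferred. The first set after which rescanning finds no target-motif
match overlapping the footprint on either strand is returned, making
plans deterministic; the search is feasible because motifs are short
(≤ ~14 bp, ≤ C(14,3)·27 candidates). Every plan is verified by rescan,
and collateral effects — sites of any library motif created or destroyed
anywhere in the sequence, matched by (start, end, strand) — are reported
alongside. Binding-energy modeling and phenotype prediction are out of
scope.

## Synthetic data

The generators produce inputs with the statistical structure the
analysis assumes, with a single integer seed threaded everywhere (no
global random state):

- **Background**: i.i.d. bases with a specified GC fraction. Default GC
  0.43, a typical value for the fly genome's euchromatin.
- **Planted clusters**: each cluster window (500 bp, matching the search
  window) receives exact-consensus instances at the configured per-factor
  counts (default: the selected-subset requirement of 2 per factor, 1
  for dTcf), placed without overlap at random offsets; decoy clusters
  omit one non-dTcf factor class entirely. Clusters are spaced ≥ one
  window apart so truth regions map 1:1 onto found regions. Planting
  exact consensi makes recovery deterministic; the placeholder factor
  models are fixed 10-mers chosen so that no motif overlaps itself,
  another motif, or any reverse complement by more than 3 bp (background
  match probability ≈ 2·500/4¹⁰ ≈ 10⁻³ per window). They are
  stand-ins: the real factors' binding models must be supplied by the
  user.
- **Ortholog**: per-base substitutions at `sub_rate` (default 0.1,
  roughly the neutral divergence of moderately distant congeneric
  species), multiplied by `site_bias` (default 0.1) inside planted sites
  to emulate purifying selection; geometric-length (mean 2) indels at
  `indel_rate` (default 0.01) strictly between sites, so the two noise
  channels — site substitution and structural change — stay independent
  and monotonicity tests are clean. The generative alignment is returned
  as ground truth, so alignment error is excluded by construction.
- **Track**: baseline plus disjoint elevated peak intervals, optional
  clamped Gaussian noise.

What the synthetic data does *not* emulate: motif degeneracy in planted
instances (available as an option but off by default), transition /
transversion asymmetry, rate heterogeneity along the sequence,
alignment artifacts, and real binding-site statistics. Passing recovery
tests therefore show the search machinery is correct under its own
model, not that the search would succeed on real genomes — where motif
false positives, not machinery, dominate the error budget.

## Numerical and degenerate-input conventions

- MISSING propagates through report assembly with a logged cause and is
  never silently imputed; classification of a MISSING peak score is
  negative with a warning.
- Zero-length regions, empty sequences for alignment, uncovered track
  regions, and empty samples after missing-value deletion are errors,
  not MISSING.
- p-values are clamped to (0, 1]; a comparison where all values are
  identical reports p = 1.
- A sequence shorter than a motif scans to an empty hit list (not an
  error); a hit wider than the co-occurrence window can never qualify.

## Problem sizes used in the validation suite

The planted-recovery study uses 16 kb genomes with 3 true clusters and 2
decoys over 20 seeds; oracle-equivalence checks use 200 random rank-sum
cases (4–8 per side) and 200 random tracks; the knockout guarantee is
exercised on 100 random motif/sequence pairs. These sizes give exhaustive
or near-exhaustive coverage of the relevant combinatorics while keeping
the whole suite around a few seconds.

## Known limitations

- The instance-count filter and clustering assume deduplicated hits;
  feeding overlapping duplicate hit records inflates counts.
- The conserved-block definition is a package convention; scores are
  comparable within a run but not directly to numbers produced by other
  aligners' block notions.
- The exact rank-sum null is enumerated only when the pooled column is
  tie-free; near-degenerate continuous data that happens to tie switches
  the method (recorded in the result) and can move the p-value at the
  third decimal.
- The built-in aligner is O(len(a)·len(b)) and not suitable for
  megabase inputs.
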