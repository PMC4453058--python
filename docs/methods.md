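# Methods

## The question and the inference design

Mean GC-content differs strongly and persistently between prokaryotic
phyla, which is compatible with purely lineage-level (neutral)
determination. The analysis implemented here targets the environmental
component instead: if some property of a sample's habitat pushes
nucleotide composition up or down, it should push *all* phyla in that
sample in the same direction, so per-phylum mean GC values should be
positively correlated across samples. The screen computes all pairwise
Spearman correlations between phyla and compares the fraction of
significant pairs against the 5% expected by chance at α = 0.05. No
multiple-testing correction is applied — deliberately: the inference is
not "pair (A,B) is correlated" but "the significant fraction exceeds the
chance level", and the chance level is the explicit baseline.

Robustness reruns use (a) sample subsets (a single environment, and all
samples minus that environment), (b) an interquartile outlier filter on
read-level GC, and (c) GC at 4-fold degenerate third codon positions
only, which removes any contribution of amino-acid usage.

## Generative model (synthetic communities)

The generator emulates the state of a survey *after* taxonomic
classification and gene annotation; classification and gene calling
themselves are out of scope, so labels, confidences and coding intervals
are produced directly.

For a sample s in environment e:

* offset_s = gc_offset(e) + Normal(0, offset_sd) — one additive GC shift
  (in GC points) applied identically to every phylum. This is the
  minimal structure that induces cross-phylum correlation; no mechanism
  is modeled, only the shared direction.
* phylum counts ~ Multinomial(reads_per_sample, w), with w the
  environment's normalized abundance weights, optionally re-drawn per
  sample from Dirichlet(c·w) (concentration c). Two environment profiles
  may share one label to model regimes within an environment — the
  Actinobacteria-dominated vs. ordinary gut split is configured exactly
  this way.
* per read of phylum p: target GC g = clip(Normal(mean_gc(p) + offset_s,
  sd_gc(p)), 1, 99)/100. Non-coding reads draw bases i.i.d.: G or C with
  probability g (split evenly), A or T otherwise. Coding reads are
  in-frame runs of codons whose first two bases are drawn uniformly from
  the eight 4-fold boxes and whose third base is G/C with probability g;
  an annotation row (0-based half-open, strand ±, phase 0) is emitted.
  Classification confidence is Uniform[0.8, 1.0] except for a
  `confidence_noise` fraction drawn Uniform[0.5, 0.8), which the 0.80
  screen removes by construction.

Default phylum profiles are the ten dominant phyla with their surveyed
mean GC (Actinobacteria 62.1, Bacteroidetes 46.0, Chlamydiae 40.3,
Crenarchaeota 49.7, Deinococcus-Thermus 64.4, Euryarchaeota 53.7,
Firmicutes 43.1, Proteobacteria 56.4, Spirochaetes 40.6, Tenericutes
32.2). Four SDs are survey values (Spirochaetes 11.8, Tenericutes 8.9,
Chlamydiae 5.5, Deinococcus-Thermus 5.9); the remaining six are not
published and default to 8.0 — a mid-range figure between the narrow and
broad published spreads, treated as a free parameter.

Deliberate simplifications, and what they imply for test evidence: bases
are i.i.d. given the target GC (no motifs, operons, codon-usage bias
beyond GC, or sequencing error), genus labels are uniform draws from
per-phylum pools, and confidences are synthetic. Passing tests therefore
demonstrate that the *pipeline* recovers the modeled structure
(offsets, means, couplings), not that real communities satisfy the
model.

Two consequences of the coding-read construction are worth flagging.
First, a coding read's overall GC is 0.5 + g/3 in expectation (the
4-fold-box prefixes average 75% GC), so whole-read GC is upward-biased
for AT-rich phyla when coding reads are mixed in; the default
`coding_fraction` is therefore 0, and configs that exercise GC4 set it
explicitly. GC4 itself equals g in expectation by construction, which is
the point: it keeps the silent-site oracle exact. Second, because the
target GC is clipped to [1, 99], extreme offsets saturate rather than
producing GC of exactly 0 or 1.

### Matrix-level shortcut

Replicated calibration studies need thousands of collections; base-level
sequence synthesis would dominate their cost without adding information.
`simulate_gc_matrix` draws each cell's mean GC directly from
Normal(mean_gc + offset_s, sd_gc/√n_cell) with n_cell from the same
multinomial — the exact sampling distribution of the read-level
generator's cell means, omitting only the per-base binomial noise
(≈ 0.04 GC points at 150 bp, negligible against sd_gc/√n). The
read-level path is exercised end to end by the signal-recovery study and
the pipeline tests; distributional agreement between the two paths is
itself under test.

## Statistical components

* **Spearman:** ρ is the Pearson correlation of midranks (tie-corrected
  by construction). Two-sided p from the t approximation with n−2 df;
  for n ≤ 9 an exact permutation p over all n! orderings of one rank
  vector. At the n = 9 boundary the two agree within 0.05 (tested). A
  constant vector makes the pair untestable (NaN), excluded from summary
  denominators. Pairwise-complete samples per pair; pairs with fewer
  than 5 complete samples are untestable.
* **Mann–Whitney:** U from midranks, reported as min(U_a, U_b);
  two-sided p by exact enumeration of all C(n_a+n_b, n_a) group
  assignments when both groups have ≤ 8 values (valid under ties),
  otherwise the normal approximation with tie-corrected variance and
  continuity correction. Fully tied pooled data yields p = 1.
* **Hypergeometric:** point mass and upper tail computed in log-gamma
  space. The *point mass* P(X = k) is the quantity reported as the
  headline "hypergeometric P value" of the enrichment table: with
  N = 111, K = n = 24 it reproduces the published gut-panel values
  (k = 5 → 0.220, 9 → 0.026, 10 → 0.008, 11 → 0.002) which the upper
  tail does not. Readers wanting a conventional one-sided test should
  use the upper tail, which is always reported alongside.
* **Enrichment table:** the dominated set is selected once (abundance
  ≥ 0.5 by default; the top-22% rule is available — with the surveyed
  panel both give 24 samples, but they need not coincide in general);
  per phylum, N and the sets are restricted to samples with a
  non-missing GC cell, and K = n. All rankings break ties by sample id
  for determinism.
* **GC and GC4:** GC excludes N from numerator and denominator and
  errors on all-ambiguous input. Matrix cells are plain arithmetic means
  of read GC over a sample × phylum group ("binned" only in that sense);
  cells with fewer than `min_reads = 10` reads are missing — no minimum
  is inherent in the method, but one-read means would feed pure noise
  into the correlations. GC4 pools all extracted third positions in a
  group and reports one GC value, with the pooled site count as n.
* **IQR filter:** quartiles by linear interpolation per phylum, pooled
  across samples. The default "literal" mode keeps [Q1, Q3] inclusive —
  the direct reading of an "interquartile region" filter — and thus
  discards up to half the reads; "tukey" mode keeps [Q1 − 1.5·IQR,
  Q3 + 1.5·IQR], the conventional outlier fence, and is offered because
  the literal band is aggressive. Pools smaller than 4 skip the filter
  with a warning.
* **Screening:** length ≥ 100 and confidence ≥ 0.80, both inclusive
  (the natural reading of "shorter than 100 bp removed" and "80% or
  higher kept"); removals attributed to the first failing filter so
  stage counts reconcile exactly.
* **4-fold extraction:** interval → coding strand (reverse complement
  for "−") → drop `frame_offset` leading bases → complete codons only
  (trailing partials dropped, never padded — padding could fabricate
  silent sites). Only the 4-fold boxes of the 6-fold amino acids
  (CTN/TCN/CGN) contribute; TTR, AGY and AGR never do, enforced by
  enumeration over all 64 codons. Codons with N in the prefix are
  skipped; an N in the third position of a 4-fold codon is carried and
  excluded by the GC computation.

## Replication studies (experiments module)

Problem sizes were chosen to mirror the surveyed design while staying
desk-scale: 10 phyla × 100 samples × 200 reads/sample for the 500-fold
null calibration; one read-level collection of 100 samples × 300 reads ×
150 bp for signal recovery (offset SD 3 GC points); 200 panels of 111
gut samples (24 dominated, +5 GC points) for enrichment recovery. Under
the null the mean significant fraction lands at ~0.05; under coupling
all 45 pairs are significantly positive; in the panels the mean overlap
exceeds its null mean n·K/N = 5.19 and the rank-sum test flags the
dominated group in effectively every replicate.

## Known limitations

* The generator's Normal-GC / additive-offset model is a caricature;
  real per-phylum GC distributions are multimodal mixtures of genera,
  and environmental effects need not be additive or shared equally.
* Observed GC matrices from real surveys can be fed in directly (FASTA +
  label/annotation/sample TSVs), but published table values that depend
  on the original read data are out of reach by design; only the
  analytic hypergeometric values are exactly reproducible.
* The point-mass "hypergeometric P" is reported for compatibility and is
  not a tail probability; treat it descriptively and prefer the upper
  tail for formal testing.
* Genus-set Jaccard treats a single read as presence; with shallow
  samples the sets, and hence the index, are sensitive to depth.
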