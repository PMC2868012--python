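# Methods

This note documents the models and procedures implemented in `chiptile`,
the parameters that matter, the numerical conventions, and what the
synthetic-data fixtures do and do not establish.

## Coordinates and containers

All genomic coordinates are 0-based, half-open internally; GFF3 (1-based
inclusive) and WIG (1-based) are converted at the I/O boundary. A probe
matching the reverse strand over forward interval [s, s+L) is stored with
start s and strand "−", so windowing, peak intervals and profile
alignment live in a single coordinate system. The TSS of a minus-strand
feature is its rightmost base (end − 1), the standard convention.

Intensity matrices carry a `scale_tag` (raw → log2 → percentile →
enrichment) that can only advance through the documented operations; QC
reports the tag alongside every table rather than assuming a scale.

## Probe remapping

Probe sequences are matched exactly (no mismatches) against the genome
with an Aho–Corasick automaton over {A,C,G,T}. Reverse-strand hits are
found by augmenting the pattern set with reverse complements — one
streaming pass, identical results to scanning a reverse-complemented
genome. `N` in the genome resets the automaton to the root, so no match
spans it; probes containing `N` are excluded up front and counted as
"none" (exact matching over an ambiguity code is ill-defined).

Classification: exactly one hit (over both strands) → retained; zero →
"none"; two or more → "multiple". A probe hitting once per strand — in
particular a palindromic probe, whose reverse complement equals itself and
which therefore reports a forward and a reverse hit at the same locus —
counts as "multiple": any ambiguity about the probe's origin disqualifies
it. Probes are identified by id, not sequence; two probes sharing one
sequence receive the same match list and can both be "unique".

The scan is linear: amortized at most two automaton transitions per
genome character (each failure-link follow strictly decreases trie depth).
An instrumented transition counter on the automaton makes this testable.

## Normalization

Within-array rank-percentile: value_i → rank_i / n with average ranks for
ties, computed over the non-NaN entries (NaN re-inserted). The definition
rank/n (rather than (rank−0.5)/n) makes the maximum exactly 1 and the
output invariant under any strictly monotone transform of the input —
which is also why logging before ranking changes nothing downstream of the
ranks; `log2_transform` is still exposed as an explicit pipeline step
because MA values and the bias diagnostics are naturally read on the log
scale.

Enrichment is the per-probe difference of percentiles, experiment minus
reference, averaged when several IP/reference pairs are given. The
reference (mock IP or digested genomic DNA) carries the same
sequence-specific hybridization bias as the experiment but no specific
binding, so the subtraction cancels the bias without modelling it.

The Buck–Lieb median-rank-percentile combines k replicate arrays: each
array is converted to within-array ranks, the per-probe median rank across
arrays is divided by n. With k = 1 it reduces to rank-percentile; it is
invariant to the order of the replicate arrays.

## Bias diagnostics

Probes are grouped by GC count (0..25); each populated group is summarized
by median, quartiles (linear interpolation between order statistics) and
mean. The positional diagnostic is a 4 × 25 matrix: cell (b, p) is the
mean intensity of probes whose base at position p is b. Probes containing
`N` are excluded from both diagnostics entirely (not just the N position),
which keeps the per-position counts equal across positions and makes the
conservation identity — count-weighted column mean equals the global mean
— exact to float precision.

## Peak calling

Per-probe enrichment scores x are standardized. The pipeline default is
robust standardization, z = (x − median)/(MAD·1.4826), because enriched
probes inflate the plain mean and standard deviation; plain
(x − mean)/sd(n−1) is available.

The moving average S_i over the window of 2w+1 probes centred at probe i
has null variance

    Var(S_i) = [m + 2 Σ_{k=1}^{m−1} (m−k) ρ_k] / m²

where m is the actual window size and ρ_k the autocorrelation of the score
sequence at probe-lag k, taken as 0 beyond `max_lag` (default 2w). Windows
shrink at chromosome ends and the variance is recomputed for the shrunken
m, so the track keeps one value per probe. If a wild ρ estimate drives the
variance to ≤ 1/(4m²) it is floored there with a warning.

ρ is the standard sample autocorrelation of z in probe order, pooled
across chromosomes by probe-count weighting; a chromosome contributes its
own estimate only when it holds at least 10·max_lag probes. Because
enrichment itself induces autocorrelation, a one-shot estimate overstates
the null correlation and costs power; the pipeline therefore runs a
two-pass refinement: provisional seed probes (and their w-neighbourhoods)
are masked, ρ is re-estimated on the remaining presumed-unbound probes
(only pairs with both endpoints unmasked contribute, rescaled by the
retained pair fraction), and the track is recomputed. On data without
enrichment the two estimates coincide.

S* = S/√Var is referred to the upper tail of the standard normal — the
test is one-sided because ChIP enrichment is directional; depletion is out
of scope. Benjamini–Hochberg adjustment is applied genome-wide. Probes
with adjusted p ≤ `fdr_q` seed peaks; consecutive seeds merge while the
gap between probe *intervals* (next start − previous start − L) is at most
`max_gap` bp — measuring between intervals, not starts, keeps the rule
unambiguous for variable tiling. Regions with fewer than `min_probes`
probes are discarded; the peak interval is [first start, last start + L).

Defaults: w = 4 (a 9-probe window ≈ 200 bp at 20 bp tiling, matching
typical sonication fragment sizes), fdr_q = 0.05, max_gap = 250 bp,
min_probes = 4. With w = 0 and no correlation the caller reduces exactly
to a per-probe z-test with BH — a useful oracle.

## Profiles and region correlation

A probe belongs to a feature's window when its *start's* strand-signed
offset from the anchor lies in [−upstream, downstream); using the start
rather than the midpoint is a documented simplification that users
comparing across tools should note. Bins without probes are missing;
features whose window leaves the chromosome are truncated, not dropped.
Per-bin quantiles (default levels 0.05…0.95 in steps of 0.05) use linear
interpolation between order statistics over non-missing values. Outlier
rows are those with more than half of their non-missing bins outside the
[0.05, 0.95] band.

Transcript-relative regions are specified as (anchor ± offset) pairs over
{TSS, TTS} in transcription coordinates; a region that degenerates
(non-positive length) for a short gene skips that gene with a count. The
shipped default region set (promoter, TSS, early elongation, elongation,
pre-TTS, post-TTS) is a configuration file, not a constant. Expression is
joined by exact feature-id match; per region, Pearson r over complete
pairs is reported with n (at least 3 pairs required). Gene grouping by
expression percentile (e.g. bottom 20% / top 10%) is provided as a generic
utility.

## Synthetic data

The generator exists so that every pipeline stage can be tested against
known ground truth. One master seed fans out to per-component child seeds
through fixed offsets; the whole dataset regenerates byte-identically.

- Genome: i.i.d. bases with P(G)+P(C) = `gc_fraction` (default 0.4, a
  yeast-like composition).
- Probes: genome substrings every `spacing` bp (default 20 bp, L = 25,
  mimicking dense tiling). A `dup_fraction` get a second copy planted in a
  reserved appendix chromosome (expected "multiple") — the appendix keeps
  the planting from disturbing other probes' uniqueness; a
  `scramble_fraction` are replaced by sequences verified absent from both
  strands (expected "none"). The generator recounts every probe's
  occurrences and raises if the realized class differs from the intention,
  so the truth table is both by construction and verified.
- Intensities: log2 value = baseline + gc_slope·GC + positional effects +
  enrichment (IP arrays only, inside planted blocks) + N(0, noise_sd²);
  raw scale is 2^value. Reference arrays share the sequence biases but no
  enrichment — the premise that a control IP captures unspecific binding.
  Defaults: baseline 8, noise_sd 0.25, 2 IP + 1 reference arrays, 20
  blocks of 300 bp at 8 noise-sd (= 2 log2 units: a four-fold enrichment,
  typical of a clearly bound region).
- Expression: slope·(region occupancy) + N(0, noise_sd²), tied by default
  to mid-transcript occupancy.

The default desk-scale fixture (one 200 kb chromosome, ~10,000 probes)
runs the full pipeline in seconds; the caller-calibration analyses use
20,000 probes and 50 replicate simulations, sizes at which the sampling
bounds quoted in the tests are sharp.

What the generator does **not** emulate: fragment-size smoothing of
enrichment edges (planted blocks are sharp), spatial array artefacts,
saturation, or dye effects of two-color platforms. Tests passing on these
fixtures certify algorithmic correctness — exact recovery, calibration,
invariances — not robustness to every real-data pathology.

## Numerical conventions

Text output is UTF-8 with LF endings and tab separators; floats are
serialized with repr-shortest form. These choices make identical runs
byte-identical, which the test-suite asserts end-to-end. NaN propagates
through normalization and is excluded from downstream statistics with
counts; degenerate inputs (all-NaN vectors, constant score vectors, empty
chromosomes) raise typed validation errors rather than producing silent
output.

## Known limitations

Exact matching only — probes with even one mismatch to the current
assembly are dropped as "none" rather than recovered. The normal-tail
p-values rest on the standardized scores being approximately Gaussian
under the null; heavy-tailed score distributions would need the robust
standardization plus a larger `fdr_q` margin. Region–expression
correlations with few features are noisy (the worked example's n = 80 is
deliberately honest about this). Binary Affymetrix CEL/BPMAP files are not
parsed; tab-delimited equivalents stand in for them.
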