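# Methods

This note documents the models, the synthetic-data generator and the
numerical choices behind `rg4scape`. Everything operates in transcript
coordinates — 0-based, half-open intervals on the sense strand of single
transcripts partitioned into 5′UTR / CDS / 3′UTR. Genome↔transcript
projection, spliced alignment and multi-isoform collapse are out of
scope: synthetic reads are born in transcript space, and real inputs are
expected already projected.

## Motif scanning (`g4scan`)

Putative G4s are regex classes over RNA (T accepted and mapped to U):

- three-tetrad: `G{3,}(N{1,7}G{3,}){3}` — the standard quadparser
  consensus of four runs of ≥ 3 G separated by 1–7 nt loops;
- two-tetrad: `G{2,}(N{1,9}G{2,}){3}`, reported only where the match is
  not contained in a three-tetrad match, so the classes partition the
  hits. There is no single agreed two-tetrad definition; the loop cap
  (default 9) is a parameter because downstream counts depend on it.

Matching is leftmost with greedy tract extension, continuing from each
match end, so every scan is deterministic and spans never overlap.
Alternative registrations of the same G-rich region are deliberately not
enumerated — enrichment statistics need one count per locus. No
thermodynamic scoring (G4Hunter-style), bulged or long-loop subclasses.

Feature annotation of a motif uses its midpoint (half-open rule: a
midpoint exactly at the 5′UTR/CDS boundary is CDS). Anchors for pileups
use the same midpoint, configurable to the motif start.

## Peak calling (`peakcall`)

Read 5′ ends (the crosslink proxy, iCLIP convention) are binned at 30 nt
per transcript; the background is a negative binomial with mean μ and
size r, conditioned on counts ≥ 1 (zero truncation removes unexpressed
bins), fitted jointly across all transcripts of a library — per-transcript
fitting would starve the fit. The per-bin significance is the conditional
upper tail `P(X ≥ k | X ≥ 1)`; bins below a *raw* p cutoff (default
10⁻⁴, no multiplicity correction) merge into peaks across gaps of up to
one insignificant bin.

Numerical choices:

- Maximum likelihood in (log μ, log r) by Nelder–Mead,
  method-of-moments initialisation, function tolerance 1e-8.
- The dispersion is boxed to r ∈ [1e-2, 1e6]. Both bounds are real
  phenomena: under-dispersed (sub-Poisson) samples push r → ∞, and
  heavy-tailed decaying histograms push (μ, r) → 0, where the ZTNB
  degenerates into a logarithmic series with no meaningful background
  mean. Hitting either bound logs a warning.
- `fit_background` refits after excluding bins whose tail probability
  falls below 1e-3 under the provisional fit (two passes by default) —
  the same idea as estimating a peak caller's local background outside
  candidate peaks. Without it, a few hundred planted sites inflate the
  fitted dispersion and roughly double the calling threshold.

Consensus peaks are the per-base regions covered by peaks from at least
`min_replicates` (default 2) replicates — "occurring in" is read as
any-overlap depth, so `min=1` is the merged union and `min=n` the
intersection footprint.

## BG4 differential enrichment (`bg4diff`)

Candidate regions are all bases whose coverage exceeds a CPM threshold in
*any* IP library (BG4 or A9), merged. The default threshold for real
data is the field's 1 CPM rule; the pipeline's synthetic runs use an
automatic threshold of 1.9 × the mean per-base coverage CPM
(= 1.9 × 10⁶ · read_length / workspace_length), because on a compact
workspace every base exceeds 1 CPM — see the generator section.

Reads are counted per region (≥ 1 bp overlap); each region is tested
IP vs input with the NB exact test: counts are linearly scaled to the
geometric-mean library size and rounded, replicate sums on each side are
NB with size n·r, and conditioning on the total gives a two-sided p as
the sum of all conditional outcomes no more likely than the observed one
("minlike", which reduces to the exact binomial test as dispersion → 0
with equal library sizes). The common dispersion is method-of-moments,
pooled across regions and roles, floored at 1e-6. This is a declared
simplification of an edgeR-style TMM + tagwise empirical-Bayes stack;
the exact test is retained as the inferential core. log₂FC uses mean CPM
with pseudocount 0.5; BH FDR across regions.

A structure peak is a region where BG4-vs-input passes log₂FC > 0.8 and
FDR < 0.05 (both strict) and A9-vs-input does *not* pass the same rule —
the formalisation of "not enriched in the negative control".

## Shuffle enrichment (`enrich`)

The null relocates each query interval, length preserved, to a uniform
position inside a transcript drawn with probability ∝ transcript length
among transcripts long enough to hold it; placements never straddle
transcript ends. Statistics: total overlap bp (default) or count of
query intervals touching the annotation. Fold = observed / mean(null);
the 95 % CI is the 2.5/97.5 percentile of null/mean(null); empirical
p = (1 + #{null ≥ obs})/(1 + N) for enrichment, mirrored for depletion,
reported as two one-sided tests (never doubled). Claiming an empirical
FDR floor of f requires N ≥ 1/f permutations — enforced by config
validation. BH is applied across the annotations tested in one panel; a
single feature's raw p at α is exactly calibrated by exchangeability, so
joint statements over a panel should use the panel-corrected value. No
GC or segment-composition conditioning is attempted.

## Positional skew (`positional`)

Pileups sum read 5′ ends at offsets −w..+w (default w = 100 nt) from
motif midpoints, CPM-normalised. The per-site skew
`S = (R₃ − R₅)/(R₃ + R₅)` (offset 0 excluded; sites with fewer than 5
flank reads dropped) is this package's formalisation of qualitative
binding geometry: S > 0 for proteins engaging the structure from its 3′
side, S < 0 from the 5′ side, S ≈ 0 for binding across the G-rich
stretch. Two proteins are compared with a two-sided rank-sum test:
because skew values tie heavily, the small-sample branch (both groups
≤ 20) is an exact tie-aware permutation distribution of the rank sum,
computed by dynamic programming over doubled midranks; larger samples
use the tie-corrected normal approximation.

## Translational efficiency (`te`)

`TE = (CPM_polysome + 0.5)/(CPM_total + 0.5)` per transcript, replicate
and condition; the total-lysate denominator cancels abundance changes.
Differential TE pairs replicates by index, takes per-replicate
Δ = log₂(TE_treated/TE_control), and tests the Δs against zero with a
one-sample t-test (zero-variance rows get p = 1); an unpaired Welch mode
on log₂ TE exists for unbalanced designs. Transcripts whose
total-fraction CPM never reaches 1 in any library are excluded before
testing; BH FDR across the rest.

Gene-set views: (1) a weighted Kolmogorov–Smirnov running sum over the
logFC-TE ranking (weight 1; hit increments ∝ |score|, miss decrements
1/(N−m)), with a *gene-label* permutation null — a sample-permutation
null is not identifiable at three replicates — and NES = ES / mean |null
ES| of matching sign; (2) an upper-tail hypergeometric test of a label
among the FDR-significant transcripts, with an optional Bonferroni factor
for label panels.

## The synthetic-data generator

The generator emulates the statistical structure of a transcriptome-wide
G4 study; its defaults are the conditions under which the recovery tests
run.

- **Transcriptome**: 300 transcripts, 5′UTR 60–160 nt, CDS 300–900 nt,
  3′UTR 150–450 nt, GC 0.45. The first 60 transcripts are "RP-like"
  (ribosomal-protein style): an 8-nt pyrimidine tract at the 5′ end
  followed by a guaranteed three-tetrad 5′UTR G4. Motif planting rates
  per (feature, class) favour the 5′UTR; 60 % of motifs are flagged
  folded. Planted motifs are drawn from the class grammar with G-free
  loops, flanks are sanitised of G over 12 nt so scans recover exact
  spans, and background is resampled until no unplanted three-tetrad
  match lies within 20 nt of a truth span.
- **Abundance**: log-normal with σ = 1 (mean-normalised) — a realistic
  CPM dynamic range. The BG4 experiment uses its own draw with σ = 0.25:
  with σ = 1 both the enriched islands and the abundance-driven
  background scale with transcript abundance, so no fixed CPM candidate
  threshold can separate fragment-scale islands from abundant-transcript
  blankets on a compact workspace (the detection band is only ln E wide
  in log-abundance). On a real transcriptome the 1 CPM rule works
  because mean coverage sits far below 1 CPM; the narrowed spread is the
  desk-scale stand-in for that separation.
- **Protein libraries**: 100 000 reads of 30 nt (fragment sizes are not
  modelled; pileups use 5′ ends, so length only affects coverage).
  Background 5′ ends uniform within transcripts chosen ∝ abundance ×
  length. Each profiled protein binds each motif with probability 0.8;
  per-site extra reads ~ NB(mean = local background per read-length
  window × (enrichment − 1), dispersion 0.01), placed at the motif
  midpoint + round(N(offset_mean, offset_sd)). The three default
  profiles (offset +15 / −15 / 0 nt, sd 8, 10-fold) reproduce 3′-skewed,
  5′-skewed and centred binding geometries. Library sizes are exact:
  background fills to the configured total.
- **uvRIP libraries**: three replicates each of BG4, A9 and input.
  BG4 carries (E − 1)-fold extra reads over folded motifs (E = 4
  default), both antibodies carry the same enrichment over 10 planted
  40-nt "sticky" decoy regions, inputs are pure background. The measured
  IP/input count ratio at folded motif spans is ≈ 4 (the extra mass
  displaces ~14 % of the background, placing the ratio near 3.9).
- **Polysome counts**: NB counts at a nominal depth of 3 × 10⁶ per
  library with dispersion 5e-4. Treated-condition polysome means of
  RP-like transcripts are scaled by 2^(−0.5); total-RNA means never
  change. These are the deep-count, near-technical-noise conditions in
  which a plain one-sample t at n = 3 (df = 2) can detect a 0.5 log₂
  effect at FDR < 0.1 at all — at read-library depth and biological-scale
  dispersion the df-2 p-value floor leaves the significant set empty.
  Library sizes are the nominal depth rather than column sums, so the
  planted effect on ~20 % of the polysome library does not register as a
  compositional shift on unaffected transcripts.
- **Determinism**: every library/replicate draws from an independent RNG
  stream derived from the master seed by fixed CRC-32 hashing of a
  stream label, so outputs are bit-identical under a fixed seed and
  adding a library never perturbs the others.

What the generator does *not* emulate: sequencing error, PCR duplicates
and UMIs, rRNA contamination, fragment-length variation, isoform
structure, GC-dependent coverage bias, and genuinely biological replicate
variability in the polysome counts. Passing recovery tests therefore
demonstrate the correctness and calibration of the statistics under the
declared noise model, not robustness to every artefact of real libraries.

## Pipeline

One YAML config drives simulate → scan → callpeaks → consensus → bg4diff
→ enrich → positional → te → gsea. Config validation aggregates all
rule violations (threshold ranges, `min_replicates ≤ replicates`,
`n_perm ≥ 1/fdr_floor`). Each stage reads inputs from and writes outputs
to the run directory, so stages are individually re-runnable; a manifest
records SHA-256 checksums of every output, `--resume` skips stages whose
outputs verify and re-executes any stage with missing or corrupted files,
and a config change disables resumption. The shipped default run (120
transcripts, 20 000 reads/library, 500 permutations) completes in well
under a minute and is bit-reproducible under a fixed seed.

## Known limitations

- The two-tetrad motif class is definition-sensitive; counts should be
  compared only under a stated loop cap.
- The NB exact test's linear library-size scaling (with rounding) is
  slightly anti-conservative for very small counts compared to
  quantile-based count equalisation.
- The shuffle null conditions on nothing but transcript length; feature
  composition or GC conditioning would tighten enrichment estimates for
  base-composition-correlated annotations.
- Consensus peak support records any-overlap, not reciprocal-overlap
  fractions.
- The paired TE test assumes replicate indices correspond across
  fractions and conditions (a processing-batch pairing).
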