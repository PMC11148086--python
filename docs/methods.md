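# Methods

## Background and scope

Okazaki-fragment sequencing (Ok-seq) reads out the direction of replication
forks: Okazaki fragments synthesized by leftward-moving forks map to the
Watson (plus) strand and those from rightward forks to the Crick (minus)
strand. Per 1-kb bin, the replication-fork directionality is
RFD = (C − W)/(C + W), and a replication origin (initiation zone) appears as
an ascending RFD transition — Crick coverage rising while Watson falls.
`okseq` implements origin calling from this signature, orientation statistics
of origin summits against gene annotations, detection of condition-specific
dormant origins at transcription termination sites (TTSs), and a stochastic
simulator that generates stranded tracks with known ground truth. Read
trimming, alignment, deduplication and RNA-seq quantification are out of
scope: the package starts from stranded bedGraph coverage and a gene table
with FPKM values.

## Origin calling

1. **Binning.** bedGraph values are interpreted as per-bin count densities:
   bin *i* accumulates `value · overlap/bin_size`, which treats per-bp and
   pre-binned exports identically and conserves the implied fragment count.
   The grid is anchored at coordinate 0; 1-kb bins by default.
2. **Smoothing.** Both strand signals are convolved with a Hann window
   `w[n] = 0.5(1 − cos 2πn/(m−1))`, normalized to unit sum, of width 60 kb
   (m = 60 bins) by default. Convolution is zero-padded; the output slice is
   offset by `(m−1)//2`, which keeps the smoothed derivative of a step edge
   peaked exactly at the step junction for both odd and even m. A validity
   mask excludes ⌈m/2⌉ bins at each chromosome end, where zero padding leaks
   into the average; chromosomes shorter than the window are skipped with a
   warning.
3. **Differentiation.** Forward differences `d[i] = s[i+1] − s[i]`, assigned
   to the junction between bins i and i+1. With 60-kb smoothing, a central
   scheme moves results by less than one bin; the forward scheme is the
   simplest consistent choice.
4. **Region calling.** Maximal runs of valid junctions with
   DER(Watson) < 0 and DER(Crick) > 0 become candidate origins. Each
   junction is scored DER-SCORE = −DER(W)·DER(C); the region keeps its
   maximum, with ties broken to the leftmost junction, whose genomic position
   is the summit. `min_region_bins` (default 1: no minimum run length) is
   exposed for users who want to suppress short runs. A relative tolerance of
   1e−9 of the chromosome's largest |derivative| treats float-rounding noise
   as zero so that exactly flat stretches cannot seed one-junction regions;
   it is far below any data-driven derivative.
5. **Efficiency filter.** log10 maximum scores from all chromosomes are
   pooled (so chromosome order cannot matter), median-centered (a monotone
   shift — only the histogram grid is affected, never the ranking),
   histogrammed into 100 bins, and the cutoff is the left edge of the first
   bin, scanning from the left, whose height reaches half the mode height:
   the lower bound of the distribution's full width at half maximum. Calls
   at or above the cutoff pass. With fewer than 50 calls the histogram cannot
   locate a mode reliably and the filter is skipped with a warning (all
   calls pass). A histogram rather than a KDE keeps the estimate
   deterministic with no bandwidth choice; on 10,000 standard-normal scores
   the cutoff lands near −σ√(2 ln 2) ≈ −1.18 and retains ≈ Φ(1.1774) ≈ 88%,
   with a small upward bias of the mode height (max of noisy bins) shifting
   the cutoff slightly right.

Score units are (smoothed counts/bin per bin)²; only relative values are
meaningful, which is why all downstream use is through ranks, the joint
cutoff, or presence/absence.

## Relative-distance statistics

For each query point a between flanking reference points, the relative
distance is min(d_left, d_right)/(d_left + d_right) ∈ [0, 0.5]; under
independence it is uniform. Query points outside the reference span of a
chromosome, or on chromosomes with fewer than two reference points, are
dropped and counted. Histograms use 50 left-closed 0.01-wide bins plus a
51st bin holding the maximal value 0.5 exactly. The implementation matches
`bedtools reldist` bin-for-bin on shared inputs (asserted in the tests).

Conditions are compared with a paired t-test over the k leading bin
proportions (default k = 3: relative distances 0, 0.01, 0.02), paired by bin
index, df = k − 1. Pairing by bin index (rather than by replicate) is the
reading most consistent with comparing two per-condition histograms; a
replicate-paired comparison can be assembled from per-replicate histograms
by the caller. When all k differences are exactly zero the statistic is
undefined and t = 0, p = 1 is returned by convention. Origins enter as
summit points; strand plays no role here (it enters only through gene
context). A display-only fit p(r) = a·e^(−r/λ) + c with a 90% delta-method
band is provided for plots; parameters are bounded to [0,1] (and λ ≤ 1,
since decay lengths beyond the relative-distance range are indistinguishable
from the constant term); if least squares fails a monotone PCHIP spline is
substituted with a warning. The fit is never used for inference. Uniform
random control sites (distinct positions per chromosome, seeded) provide the
independence baseline.

## Gene context

Transcriptional volume is FPKM × gene length — a proxy for the number of
engaged RNA polymerases; genes strictly above the median volume form the
high stratum. Origin summits are assigned to categories with precedence
TSS > TTS > genic > intergenic, using ±1 kb windows around the TSS/TTS
points by default; log2 enrichment compares the observed category fractions
with the genomic footprint of each category computed from the same windows
and chromosome sizes. The full transcript-model category set (UTRs, exons,
introns) would require a GTF and is deliberately collapsed to these four.

A gene is a **candidate** for a new TTS origin when its oriented window
[TTS − 1 kb, TTS + 50 kb] contains at least one treated-sample summit and no
control-sample summit. The bounds are flags, not inferred constants: the
downstream extent mirrors the 50-kb neighbor-proximity threshold. By default
post-filter origin sets are compared (a flag compares pre-filter sets). The
closest treated summit is attached with its signed distance (positive =
downstream). Neighbor classes scan downstream of the candidate's TTS in its
direction of transcription: the first feature of another gene encountered is
its TSS if co-oriented (tandem) or its TTS if opposite (convergent); within
50 kb of the TTS origin that class applies, otherwise the candidate is
isolated. The classification is invariant under mirroring the genome.

## Simulator

Per simulated cell cycle every origin fires independently with its
efficiency; cells with no firing are redrawn, because Okazaki fragments only
come from replicated DNA. Fired origins emit two equal-speed forks, so each
bin is replicated by the nearest fired origin — rightward when that origin
lies left of the bin center, with exact-midpoint ties resolved rightward.
Averaging over cells gives p_right per bin; with all efficiencies 1 the
result equals the closed-form nearest-origin step function for any number of
cells. Reads are sampled per bin as total ~ Poisson(depth) and
Crick ~ Binomial(total, p_right); a noiseless mode returns the expected
counts for closed-form checks. There is no fork stalling, speed noise,
replication timing or mappability model: uniform fork speed keeps the
nearest-fired-origin geometry exact and the oracles closed-form. All
randomness flows from one seed through named substreams (firing, reads,
placement).

**Stress scenario.** The demo gene model is one chromosome of 20 regularly
spaced genes (500-kb spacing, 120-kb length, first start 200 kb); alternate
genes are high-volume (FPKM 20 vs 0.5, equal lengths, so the median volume
splits them exactly). The control condition places one origin at the TSS of
every high-volume gene; the treated condition adds a dormant origin of
efficiency 0.5 downstream of the TTS of a seeded choice of 8 high-volume
genes, at offsets cycling through 5/15/25 kb — the midpoints of the thirds
of the 1–30 kb placement band, so the band is covered evenly rather than
left to sampling chance. Constitutive TSS origins fire deterministically
(efficiency 1.0): they are the fixed reference against which stochastic
dormant firing is measured, and — because this synthetic genome has no
licensed origins between the placed ones, unlike a real genome — always-on
flanks keep passively replicated stretches single-stranded, so the sparse
origin map cannot itself manufacture two-strand shot-noise regions that a
real sample's dense origin population would drown out. High-volume strands
are arranged so every dormant origin falls strictly between two high-volume
TTSs (no dropped points in relative-distance scoring).

What passing tests on this generator do **not** show: calibration of
DER-SCORE against absolute firing efficiency (only rank agreement is
asserted; the score is depth- and geometry-dependent), behavior under
replication timing programs, fork-speed heterogeneity, mappability gaps, or
the broad unimodal score distributions of real genomes with ~10^4 origins.

## Default analysis sizes

The bundled demo and the acceptance script use one ~10-Mb chromosome,
depth 50 reads per 1-kb bin, 500 simulated cells, 10–18 origins, and
10,000-point null draws for the relative-distance checks — sizes at which
every closed-form or brute-force oracle is still exact and the full pipeline
runs in seconds.

## Known limitations

* The FWHM filter assumes a unimodal score distribution; on strongly bimodal
  synthetic inputs the lower half-maximum bound tracks the dominant mode.
* Enrichment values are NaN/−∞ for categories with zero observed or zero
  genomic fraction.
* Loaded origin BED files carry rescaled 0–1000 scores, so absolute
  DER-SCOREs do not round-trip (regions and summits do).
* `bedGraph` inputs with overlapping intervals are summed, not averaged.
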