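# Methods

## Coordinate conventions

All internal coordinates are 0-based, half-open; conversion happens only at
file boundaries (GTF is 1-based inclusive, BED/bedGraph already half-open).
Transcript coordinates run 5′→3′: position 0 of a minus-strand transcript is
its highest genomic position. A *cleavage position* is the transcript
coordinate of the **first tail base** (and its genomic projection). This
makes the body end equal to the cleavage site and the tail start equal to
cleavage + 1 in 1-based output annotation, so the re-annotation rule for the
miRNA analysis is a pure truncation/append: the body keeps the original
transcript id with its last exon shortened, the tail is a single-exon region
with a "B" suffix. Unstranded coverage is accepted and used as-is for both
strands; the algorithm only consumes transcript-projected totals.

## Windowing

Mean coverage in 50-nt windows at 20-nt offsets, introns excised, then
log2(mean + 1). The pseudocount of one read-depth unit keeps zero-coverage
windows finite while being negligible at the ≥20× coverages the pipeline is
intended for. Trailing bases not covered by a full window are dropped so all
observations are identically shaped. A window is labelled 3′-UTR iff its
*start* is at or past the CDS end; the ~2 windows straddling the boundary
are labelled by their start. Windows start at transcript position 0 (the
annotated CDS start when 5′-UTRs are annotated; the synthetic transcripts
have none). Log base 2 is used package-wide; the base only rescales the
Gaussian parameters.

## Normalization

One OLS fit *Y = aX + b* per treatment on all CDS windows genome-wide
(X = control log2, Y = treatment log2) absorbs library-depth and
protocol-scale differences. Windows with zero raw coverage in **both**
tracks are excluded from fitting (they sit at a pseudocount-determined point
and carry no information) but kept in the deviation profiles. Transcripts
with mean CDS coverage below a configurable floor (default 1) are skipped
entirely — the segmentation is meaningless on noise-only profiles. Because
the control is itself a noisy measurement, the OLS slope shows classical
errors-in-variables attenuation (≈0.93 instead of 1 on the synthetic data);
the intercept compensates and the deviations remain centred, so the
downstream segmentation is unaffected. OLS is used as the literal reading of
a linear regression model; robust variants are out of scope.

## Segmentation model

A two-state Gaussian HMM on the deviation sequence with states Body and
Tail, state means μ_B and μ_T, **shared** variance σ², initial Body
probability π_B and a single allowed Body→Tail transition (transition matrix
[[1−τ, τ], [0, 1]]). Tail is absorbing, so the path space is exactly the set
of changepoints k ∈ {0..n}. That collapse is used computationally: the
forward–backward recursions reduce to an exact posterior over k (vectorized
across transcripts), and the Viterbi decoder is validated against
brute-force enumeration of all changepoint paths — the two must agree
exactly, and do on 1,000 random profiles.

Fitting is **global per treatment** across all transcript profiles
(per-transcript emission parameters would be unidentifiable on short
profiles); decoding is per transcript. Numerical choices: all likelihoods in
log space; σ² floored at 1e-6; τ clamped to [1e-6, 1−1e-6]; EM stops at
|ΔLL| < 1e-6 (configurable) or 200 iterations, returning the best fit with a
warning if unconverged. Initialization is deterministic and data-driven:
μ_B = mean deviation over CDS windows, μ_T = mean over the last quartile of
3′-UTR windows (nudged apart in the mode's direction if needed), σ² pooled,
τ = 1/median profile length, π_B = 0.99. Viterbi ties break toward the
smallest k (most proximal cleavage). Decoding spans all windows — CDS
windows anchor the Body state — but k is reported only when it falls in the
3′-UTR; `--mode deplete|enrich` selects the sign expected of μ_T − μ_B
(negative under TEX/CAP-IP-like body enrichment, positive under 3′-PD-like
tail enrichment). Multiple cleavages per transcript are out of scope: only
the first changepoint is modelled.

## Significance

The deviations of the two decoded segments (not raw coverage) are compared
with a two-sided two-sample KS test (asymptotic p); segments need ≥3 windows
each, otherwise the call is untestable. A direction gate (mean tail
deviation below/above mean body deviation per mode) precedes FDR. The FDR
family is **every analysed transcript**: a transcript with no decoded or
testable transition is a non-discovery with p = 1, not a hypothesis removed
from the family — removing it would condition the family on the test
outcome and destroy calibration. Genes take the minimum transcript p;
Benjamini–Hochberg is applied across genes (BH chosen as the field default;
the procedure is only named "FDR" upstream). Default thresholds p < 0.01 and
FDR < 0.01.

Overlapping windows make the KS inputs autocorrelated and the decoded split
is itself chosen to maximize separation, so nominal p-values are
anti-conservative. Measured on a 2,000-transcript null simulation, the
gene-level fraction at q < 0.01 is ≈0.013–0.014 — above the nominal 0.01
but within 2× (the packaged acceptance run documents the exact value).

## Synthetic data

The generator emulates: per-transcript coverage with a planted cleavage
point; a tail:body coverage ratio multiplied by 0.66 under depletion-mode
treatments (TEX/CAP-IP-like; a 34% decrease) and by 1.41 under
enrichment-mode (3′-PD-like; a 41% increase) — the reported average effect
sizes; log-normal multiplicative noise in 20-nt blocks (sd 0.3 in log2
units per track), which induces realistic window-to-window autocorrelation;
proximal/distal 3′-end peaks with Gaussian positional jitter (sd 10 nt);
and negative-binomial region counts (gamma–Poisson, dispersion 0.05, 3+3
replicates) with a 0.6× repression applied only to fragments carrying a
planted 7-mer seed site. Transcript geometry: CDS 600–2400 nt over 1–5
exons, 3′-UTR ≈ log-normal around 900 nt (min 350), cleavage offset from
the stop codon exponential with scale 250 nt (so >60% of sites fall within
500 nt of the stop), a ≥160-nt tail margin, both strands, expression
log-normal around 60× with a 20× floor. All generators are pure functions
of (config, seed); stage-specific child seeds keep outputs byte-identical
across runs.

What the generator does **not** emulate: fragment-end/GC bias (control
coverage is flat in expectation), read-level sampling (noise is block
log-normal, not Poisson-with-depth), isoform mixtures (one transcript per
gene), multiple cleavages per transcript, and real seed-site sequence
context (accidental 7-mer matches are scrubbed so planted truth is exact).
Passing tests therefore demonstrate correctness of the algorithms under the
stated statistical structure, not performance on real libraries.

### A known, quantified limitation

With 50/20 overlapping windows, adjacent observations share ≥60% of their
bases, so *any* base-level noise produces ~0.6–0.7 correlation between
neighbouring windows. At the default noise level this widens the
changepoint decoder's error tails: ~80–84% of planted cleavage points are
localized within ±2 windows (±40 nt) by the full pipeline, versus ~95–98%
for the same decoder on profiles with independent window noise of equal
marginal sd (the segmentation test suite measures both). Localization
within ±100 nt exceeds 90%, which is the scale that matters for matching
cleavage points to 3′-end peaks.

## miRNA body/tail analysis

Seed targets are exact reverse-complement matches of miRNA positions 2–8
(7-mer-m8-style; configurable start/length; no wobble or 3′-supplementary
pairing). Region fold changes use median-of-ratios size factors and
log2((mean_trt + 0.5)/(mean_ctrl + 0.5)); regions below a mean normalized
count of 10 are flagged out of distribution tests. This transparent
computation replaces a shrinkage-based differential-expression fit — the
distribution comparisons depend on fold changes, not shrinkage — and counts
can be exported for any external tool when exact replication is wanted.
When a sizeable fraction of regions is repressed in one direction,
median-of-ratios absorbs part of the shift into the size factors
(≈0.14 log2 units at 27% repressed regions in the synthetic scenario); the
body − tail difference cancels this bias and is the planted-effect
estimator used in tests. Tail-region seed analyses carry a caveat: the tail
is taken to run from cleavage+1 to the annotated transcript end, but tail
boundaries are uncertain when several cleavages occur, so no accuracy claim
is made for tail-site results.

## 3′-end peak analyses

Proximal = smallest transcript coordinate peak, distal = largest;
intermediate peaks are recorded but ignored for ratios. The paired t-test
runs on log-transformed distal/proximal ratios by default (ratio
distributions are right-skewed; a raw-ratio option exists). Peak calling
itself is upstream of this package; peak tables are inputs. The APA
enrichment control draws positions uniformly from randomly chosen 3′-UTRs
with an explicit seed.

## Problem sizes

The packaged test-and-acceptance runs use 500-transcript effect datasets, a
2,000-transcript null, 300 transcripts for the miRNA scenario, 200 for
annotation round trips and 1,000 random profiles for decoder-vs-enumeration
checks — sizes at which every Monte-Carlo assertion has comfortable margin
while the whole suite stays fast.
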