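# tailseg

Detection of post-transcriptional 3′-UTR cleavage points from
treatment-vs-control RNA-seq coverage, with downstream 3′-end-peak and miRNA
body/tail regulation analyses.

## The problem

Mature mRNAs can be cleaved post-transcriptionally at alternative
polyadenylation (APA) sites inside their 3′-UTR, producing two stable,
independent molecules: a capped **body** (the CDS with a shortened 3′-UTR)
and an uncapped **tail** (the 3′-UTR downstream of the cleavage point).
Enrichment protocols that select on the 5′ cap — degrading uncapped RNA
(TEX), immunoprecipitating capped RNA (CAP IP), or pulling down in-vitro
capped, previously uncapped RNA (3′-PD) — shift the tail:body coverage ratio
relative to an untreated control. `tailseg` finds the per-transcript
transition point of that shift and turns it into a re-annotation of the
transcriptome that separates body and tail, which in turn changes how miRNA
knockdown effects should be quantified.

## The model

For each transcript, mean read coverage is computed in overlapping 50-nt
windows at 20-nt offsets along the intron-less transcript (CDS + 3′-UTR) and
log2-transformed. A single genome-wide linear model

&nbsp;&nbsp;&nbsp;&nbsp;*Y = aX + b*

is fitted per treatment on all CDS windows (X = control log coverage,
Y = treatment log coverage), and per-window deviations
*dᵢ = yᵢ − (a·xᵢ + b)* become the observation sequence of a two-state
Gaussian hidden Markov model:

- states **Body** and **Tail** with means μ_B, μ_T and a **shared** variance
  σ²;
- left-to-right transition matrix [[1−τ, τ], [0, 1]] — Tail is absorbing, so
  every state path is Body^k Tail^(n−k) for a single changepoint k.

Parameters are fitted globally per treatment by Baum–Welch (EM) and the
per-transcript changepoint is decoded with the Viterbi algorithm. Each
decoded transition is scored with a two-sample Kolmogorov–Smirnov test
between body- and tail-segment deviations; transcripts collapse to genes by
minimum p, and Benjamini–Hochberg FDR is applied across all analysed genes.
Downstream modules analyse 3′-end-seq proximal/distal peak ratios (paired
t-test on log distal/proximal ratios), cleavage-to-peak distances, APA-site
enrichment around predicted cleavage points, and miRNA 7-mer seed-target
fold-change distributions on the body/tail re-annotation.

A full synthetic-data generator (`tailseg.simulate`) produces transcript
models, sequences, coverage pairs, 3′-end peaks and count matrices with
planted ground truth, so the whole pipeline is testable without sequencing
data.

## Worked example

```
tailseg simulate --n 200 --seed 42 --cleavage-prob 0.6 --out demo
tailseg segment --gtf demo/transcripts.gtf --control demo/control.bedgraph \
    --treatment demo/tex.bedgraph --mode deplete --label tex \
    --out demo/calls.tsv --gene-out demo/genes.tsv --params-out demo/params.json
tailseg mirna --calls demo/calls.tsv --counts demo/counts.tsv \
    --design demo/design.tsv --regions demo/regions.tsv \
    --fasta demo/transcripts.fa --mirna UAUUGCACUUGUCCCGGCCUGU --out demo/mir
tailseg peaks3p --calls demo/calls.tsv --peaks-before demo/peaks_before.tsv \
    --peaks-after demo/peaks_after.tsv --out demo/pk
```

prints

```
112 testable calls, 112 significant, 112 genes
body-with-seed vs tail: KS D=0.804, p=4.23e-15 (n=46)
mean distal/proximal relative change: -33.7% (paired t=-60.19, p=3.06e-88, n=115)
fraction of cleavage points within 100 nt of the proximal peak: 95.5%
```

Reading these numbers: of 200 simulated transcripts (60% carrying a planted
cleavage), 112 get a direction-consistent, testable transition in the
3′-UTR, all significant at p < 0.01 and FDR < 0.01. The fitted HMM
(`demo/params.json`) recovers μ_B ≈ 0 and μ_T ≈ −0.58 — the planted 34%
tail depletion is log2 0.66 ≈ −0.60 on this scale. Transcript bodies that
carry a miRNA seed site drop in expression while their tails do not (KS
p = 4.2e-15), the distal 3′-end peak loses ≈ 34% of its height relative to
the proximal peak after tail depletion, and 95% of predicted cleavage points
fall within 100 nt of the proximal 3′-end peak.

Each call row reports the transition window index k, the cleavage position
in transcript and genomic coordinates (the first tail base), the Viterbi and
no-transition log-likelihoods, the KS statistic with p/q values, and the
mean body/tail deviations.

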