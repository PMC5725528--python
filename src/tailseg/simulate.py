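"""Synthetic transcriptome generator with planted 3'-UTR cleavage points.

Generates every input the downstream analyses consume: transcript models on a
compact synthetic genome, transcript sequences with planted miRNA seed sites,
control/treatment coverage pairs with the tail-coverage shift the enrichment
protocols produce, 3'-end peak tables, and negative-binomial region count
matrices with a body-confined miRNA knockdown effect.

Default effect sizes mirror the reported biology: tail coverage multiplied by
0.66 under capped-body enrichment (TEX / CAP-IP-like depletion of uncapped
tails, a 34% decrease) and by 1.41 under uncapped-tail enrichment
(3'-PD-like, a 41% increase).  Noise is multiplicative log-normal applied in
20-nt blocks, which gives window-scale autocorrelation comparable to what the
50/20 windowing induces on real coverage.

All generators are pure functions of (config.seed, stage): each stage draws
from ``numpy.random.default_rng([seed, stage_code, ...])``, so identical
configs give byte-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import GenomeCoverage, TranscriptModel

TREATMENT_CODES = {"control": 0, "tex": 1, "capip": 2, "pd3": 3}

_BASES = np.array(list("ACGT"))
_COMP = str.maketrans("ACGT", "TGCA")


@dataclass
class SimulationConfig:
    """Knobs of the synthetic transcriptome; defaults are the study conditions.

    ``tail_factors`` multiply tail-region coverage relative to body under each
    treatment; ``noise_sd`` is the log2-scale s.d. of the multiplicative noise
    applied per ``noise_block`` nt; ``repression_factor`` scales the abundance
    of fragments carrying a planted 7-mer seed site in the miRNA-transfection
    experiment.
    """

    n_transcripts: int = 500
    seed: int = 0
    # annotation geometry (nt)
    exon_count_mean: float = 2.5
    cds_len_range: tuple[int, int] = (600, 2400)
    utr3_len_mean: float = 900.0
    utr3_len_sd_log: float = 0.5
    utr3_len_min: int = 350
    utr3_len_max: int = 3000
    intron_len_range: tuple[int, int] = (80, 400)
    intergenic_gap: int = 1000
    transcripts_per_chrom: int = 500
    # cleavage truth
    cleavage_prob: float = 0.5
    cleavage_offset_scale: float = 250.0   # exponential prior from stop codon
    cleavage_offset_min: int = 60
    tail_min_len: int = 160
    # expression and coverage noise
    expr_log_mean: float = float(np.log(60.0))
    expr_log_sd: float = 0.5
    min_expression: float = 20.0
    noise_sd: float = 0.3
    noise_block: int = 20
    depth_factor: float = 1.0
    tail_factors: dict = field(default_factory=lambda: {
        "tex": 0.66, "capip": 0.66, "pd3": 1.41})
    # 3'-end peaks
    peak_jitter_sd: float = 10.0
    peak_height_log_sd: float = 0.05
    proximal_height_scale: float = 0.8
    # region counts (miRNA experiment)
    n_replicates: int = 3
    mean_count_per_kb: float = 200.0
    dispersion: float = 0.05
    repression_factor: float = 0.6
    body_seed_frac: float = 0.4
    tail_seed_frac: float = 0.2
    mirna: str = "UAUUGCACUUGUCCCGGCCUGU"   # hsa-miR-92a-3p

    def __post_init__(self):
        if not 0.0 <= self.cleavage_prob <= 1.0:
            raise ValueError("cleavage_prob must lie in [0, 1]")
        if any(f <= 0 for f in self.tail_factors.values()):
            raise ValueError("tail factors must be > 0")
        if self.repression_factor <= 0:
            raise ValueError("repression factor must be > 0")
        if self.utr3_len_min < self.cleavage_offset_min + self.tail_min_len:
            raise ValueError("utr3_len_min too small for cleavage margins")


@dataclass
class GroundTruth:
    """Planted per-transcript truth: cleavage state/position, expression and
    seed-site placement (transcript coordinates; -1 = no site)."""

    table: pd.DataFrame

    def row(self, transcript_id: str) -> pd.Series:
        return self.table.set_index("transcript_id").loc[transcript_id]

    @property
    def cleaved_ids(self) -> list[str]:
        t = self.table
        return list(t.loc[t["cleaved"], "transcript_id"])


def _seed_site(mirna: str, seed_start: int = 1, seed_len: int = 7) -> str:
    """DNA target site = reverse complement of miRNA seed (positions 2-8)."""
    seed = mirna.upper().replace("U", "T")[seed_start:seed_start + seed_len]
    if len(seed) < seed_len:
        raise ValueError("miRNA too short for a 7-mer seed")
    return seed.translate(_COMP)[::-1]


def _scrub_accidental(seq: np.ndarray, site: str, keep: set[int]) -> None:
    """Mutate chance occurrences of ``site`` outside planted positions."""
    text = "".join(seq)
    for _ in range(3):
        changed = False
        start = text.find(site)
        while start != -1:
            if start not in keep:
                mid = start + len(site) // 2
                cur = seq[mid]
                seq[mid] = _BASES[(np.where(_BASES == cur)[0][0] + 1) % 4]
                changed = True
            start = text.find(site, start + 1)
        if not changed:
            break
        text = "".join(seq)


def simulate_annotation(config: SimulationConfig
                        ) -> tuple[list[TranscriptModel], dict[str, str],
                                   GroundTruth]:
    """Generate transcript models, spliced sequences and planted truth.

    The cleavage-position prior (exponential from the stop codon, scale
    ``cleavage_offset_scale``) places the majority of true cleavage sites
    within 500 nt of the stop codon.
    """
    rng = np.random.default_rng([config.seed, 11])
    site = _seed_site(config.mirna)
    models, seqs, rows = [], {}, []
    cursors: dict[str, int] = {}
    for i in range(config.n_transcripts):
        tid, gid = f"T{i + 1:05d}", f"G{i + 1:05d}"
        chrom = f"chr{i // config.transcripts_per_chrom + 1}"
        strand = "+" if rng.random() < 0.5 else "-"
        cds_len = int(rng.integers(*config.cds_len_range))
        utr3_len = int(np.clip(
            rng.lognormal(math.log(config.utr3_len_mean)
                          - config.utr3_len_sd_log ** 2 / 2,
                          config.utr3_len_sd_log),
            config.utr3_len_min, config.utr3_len_max))
        L = cds_len + utr3_len
        # last exon holds the whole 3'-UTR plus some CDS overhang, so cleavage
        # always falls inside the 3'-most exon
        overhang = int(rng.integers(100, 300))
        n_exons = 1 + int(rng.poisson(max(config.exon_count_mean - 1, 0)))
        head = cds_len - overhang
        if head < (n_exons - 1) * 50:
            n_exons = max(1, head // 50 + 1) if head > 0 else 1
        if n_exons == 1:
            lens = [L]
        else:
            cuts = np.sort(rng.choice(np.arange(50, head - 49),
                                      size=n_exons - 2, replace=False)) \
                if n_exons > 2 else np.array([], dtype=int)
            bounds = np.concatenate([[0], cuts, [head]])
            lens = list(np.diff(bounds)) + [overhang + utr3_len]
            lens = [int(x) for x in lens]
        if strand == "-":
            # transcript order is reverse-genomic: the UTR-holding exon must
            # sit genomically first
            lens = lens[::-1]
        cursor = cursors.get(chrom, 0) + config.intergenic_gap
        exons = []
        for j, ln in enumerate(lens):
            if j > 0:
                cursor += int(rng.integers(*config.intron_len_range))
            exons.append((cursor, cursor + ln))
            cursor += ln
        cursors[chrom] = cursor
        tx = TranscriptModel(tid, gid, chrom, strand, tuple(exons), cds_len)

        cleaved = rng.random() < config.cleavage_prob
        cleavage_tx = -1
        if cleaved:
            off = config.cleavage_offset_min + rng.exponential(
                config.cleavage_offset_scale)
            off = min(off, utr3_len - config.tail_min_len)
            cleavage_tx = cds_len + int(round(off))
        expr = max(config.min_expression,
                   float(rng.lognormal(config.expr_log_mean,
                                       config.expr_log_sd)))

        seq = rng.choice(_BASES, size=L)
        body_end = cleavage_tx if cleaved else cds_len
        body_seed = tail_seed = -1
        planted: set[int] = set()
        if rng.random() < config.body_seed_frac and body_end > 80:
            body_seed = int(rng.integers(30, body_end - 40))
            seq[body_seed:body_seed + len(site)] = list(site)
            planted.add(body_seed)
        if rng.random() < config.tail_seed_frac and L - body_end > 60:
            tail_seed = int(rng.integers(body_end + 20, L - 30))
            seq[tail_seed:tail_seed + len(site)] = list(site)
            planted.add(tail_seed)
        _scrub_accidental(seq, site, planted)

        models.append(tx)
        seqs[tid] = "".join(seq)
        rows.append({"transcript_id": tid, "gene_id": gid, "cleaved": cleaved,
                     "cleavage_tx": cleavage_tx, "expression": expr,
                     "cds_end_tx": cds_len, "length_tx": L,
                     "body_seed_pos": body_seed, "tail_seed_pos": tail_seed})
    truth = GroundTruth(pd.DataFrame(rows))
    return models, seqs, truth


def _add_transcript_coverage(cov: GenomeCoverage, tx: TranscriptModel,
                             values_tx: np.ndarray) -> None:
    vals = values_tx[::-1] if tx.strand == "-" else values_tx
    offset = 0
    for s, e in tx.exons:
        cov.add(tx.chrom, s, vals[offset:offset + (e - s)])
        offset += e - s


def simulate_coverage_pair(models: list[TranscriptModel], truth: GroundTruth,
                           config: SimulationConfig, treatment: str = "tex"
                           ) -> tuple[GenomeCoverage, GenomeCoverage]:
    """Control and treatment per-base coverage tracks.

    Control coverage is flat in expectation along each transcript; the
    treatment track multiplies coverage downstream of the true cleavage point
    by the treatment's tail factor (cleaved transcripts only).  Both tracks
    get independent multiplicative log-normal noise per ``noise_block`` nt.
    """
    if treatment not in config.tail_factors:
        raise ValueError(f"unknown treatment label {treatment!r}; "
                         f"expected one of {sorted(config.tail_factors)}")
    rng = np.random.default_rng([config.seed, 21,
                                 TREATMENT_CODES[treatment]])
    factor = config.tail_factors[treatment]
    control, treated = GenomeCoverage(), GenomeCoverage()
    tt = truth.table.set_index("transcript_id")
    for tx in models:
        row = tt.loc[tx.transcript_id]
        L = tx.length_tx
        expr = float(row["expression"])
        base = np.full(L, expr)
        trt = base * config.depth_factor
        if bool(row["cleaved"]):
            trt = trt.copy()
            trt[int(row["cleavage_tx"]):] *= factor
        nblocks = -(-L // config.noise_block)
        for target, arr in ((control, base), (treated, trt)):
            if config.noise_sd > 0:
                noise = np.exp2(rng.normal(0.0, config.noise_sd, nblocks))
                arr = arr * np.repeat(noise, config.noise_block)[:L]
            _add_transcript_coverage(target, tx, arr)
    return control, treated


def simulate_end_peaks(models: list[TranscriptModel], truth: GroundTruth,
                       config: SimulationConfig, treatment: str = "tex"
                       ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """3'-end peak tables (transcript_id, pos, height) before/after treatment.

    Cleaved transcripts get a proximal peak at the cleavage position and a
    distal peak at the transcript end; after treatment the distal height is
    scaled by the tail factor.  Positions get Gaussian jitter
    (``peak_jitter_sd``); uncleaved transcripts have only a distal peak.
    """
    if treatment not in config.tail_factors:
        raise ValueError(f"unknown treatment label {treatment!r}")
    rng = np.random.default_rng([config.seed, 31,
                                 TREATMENT_CODES[treatment]])
    factor = config.tail_factors[treatment]
    tt = truth.table.set_index("transcript_id")
    before, after = [], []
    for tx in models:
        row = tt.loc[tx.transcript_id]
        L, cds_end = tx.length_tx, tx.cds_end_tx
        expr = float(row["expression"])

        def h():
            return expr * float(np.exp2(rng.normal(0, config.peak_height_log_sd)))

        distal_pos = int(np.clip(round(L - 1 + rng.normal(0, config.peak_jitter_sd)),
                                 cds_end + 1, L - 1))
        dh_before, dh_after = h(), h()
        if bool(row["cleaved"]):
            prox = int(np.clip(round(row["cleavage_tx"]
                                     + rng.normal(0, config.peak_jitter_sd)),
                               cds_end + 1, distal_pos - 1))
            ph_before = expr * config.proximal_height_scale \
                * float(np.exp2(rng.normal(0, config.peak_height_log_sd)))
            ph_after = expr * config.proximal_height_scale \
                * float(np.exp2(rng.normal(0, config.peak_height_log_sd)))
            before.append((tx.transcript_id, prox, ph_before))
            after.append((tx.transcript_id, prox, ph_after))
            after.append((tx.transcript_id, distal_pos, dh_after * factor))
        else:
            after.append((tx.transcript_id, distal_pos, dh_after))
        before.append((tx.transcript_id, distal_pos, dh_before))
    cols = ["transcript_id", "pos", "height"]
    return (pd.DataFrame(before, columns=cols),
            pd.DataFrame(after, columns=cols))


def simulate_region_counts(models: list[TranscriptModel], truth: GroundTruth,
                           config: SimulationConfig, mirna: str | None = None
                           ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Negative-binomial counts for body/tail (cleaved) and whole/CDS/UTR3
    (uncleaved) regions in control vs miRNA-transfected samples.

    The repression factor is applied only to *fragments* whose sequence
    carries a planted seed site: for a cleaved transcript the body and tail
    are independent molecules, so a body site leaves the tail untouched; for
    an uncleaved transcript a site anywhere represses the whole molecule.
    Returns (counts regions x samples, region metadata with seed truth).
    """
    del mirna  # sites were planted at annotation time; flags come from truth
    rng = np.random.default_rng([config.seed, 41])
    tt = truth.table.set_index("transcript_id")
    samples = ([f"ctrl_{r + 1}" for r in range(config.n_replicates)]
               + [f"mir_{r + 1}" for r in range(config.n_replicates)])
    e0 = math.exp(config.expr_log_mean)
    rows, meta = [], []

    def nb(mean: float) -> int:
        if mean <= 0:
            return 0
        if config.dispersion <= 0:
            return int(round(mean))
        lam = rng.gamma(1.0 / config.dispersion, mean * config.dispersion)
        return int(rng.poisson(lam))

    for tx in models:
        row = tt.loc[tx.transcript_id]
        tid = tx.transcript_id
        L, expr = tx.length_tx, float(row["expression"])
        rel = expr / e0
        body_seed = int(row["body_seed_pos"]) >= 0
        tail_seed = int(row["tail_seed_pos"]) >= 0
        rep = config.repression_factor
        if bool(row["cleaved"]):
            c = int(row["cleavage_tx"])
            parts = [
                (tid, "body", c, body_seed, rep if body_seed else 1.0),
                (tid + "B", "tail", L - c, tail_seed, rep if tail_seed else 1.0),
            ]
        else:
            whole_rep = rep if (body_seed or tail_seed) else 1.0
            cds = tx.cds_end_tx
            parts = [
                (tid + "_CDS", "CDS", cds, body_seed, whole_rep),
                (tid + "_UTR3", "UTR3", L - cds, tail_seed, whole_rep),
            ]
        frag_counts = {}
        for rid, role, length, has_seed, factor in parts:
            mean = rel * (length / 1000.0) * config.mean_count_per_kb
            counts = ([nb(mean) for _ in range(config.n_replicates)]
                      + [nb(mean * factor)
                         for _ in range(config.n_replicates)])
            frag_counts[rid] = counts
            rows.append([rid] + counts)
            meta.append({"region_id": rid, "transcript_id": tid, "role": role,
                         "length": length, "has_seed": has_seed})
        whole = np.sum([frag_counts[p[0]] for p in parts], axis=0)
        rows.append([tid + "_whole"] + [int(x) for x in whole])
        meta.append({"region_id": tid + "_whole", "transcript_id": tid,
                     "role": "whole", "length": L,
                     "has_seed": body_seed or tail_seed})
    counts = pd.DataFrame(rows, columns=["region_id"] + samples)
    counts = counts.set_index("region_id")
    design = pd.Series(["control"] * config.n_replicates
                       + ["mirna"] * config.n_replicates, index=samples,
                       name="condition")
    counts.attrs["design"] = design
    return counts, pd.DataFrame(meta)


def write_dataset(outdir, config: SimulationConfig,
                  treatment: str = "tex") -> dict[str, str]:
    """Emit a complete plain-text dataset (GTF, FASTA, bedGraphs, peak/count
    TSVs, ground-truth TSV) into ``outdir``; returns the path map."""
    import os

    from .io import write_fasta, write_transcripts_gtf

    os.makedirs(outdir, exist_ok=True)
    models, seqs, truth = simulate_annotation(config)
    control, treated = simulate_coverage_pair(models, truth, config, treatment)
    pk_before, pk_after = simulate_end_peaks(models, truth, config, treatment)
    counts, regions = simulate_region_counts(models, truth, config)
    design = counts.attrs["design"]

    paths = {name: os.path.join(outdir, fname) for name, fname in [
        ("gtf", "transcripts.gtf"), ("fasta", "transcripts.fa"),
        ("control", "control.bedgraph"),
        ("treatment", f"{treatment}.bedgraph"),
        ("peaks_before", "peaks_before.tsv"),
        ("peaks_after", "peaks_after.tsv"),
        ("counts", "counts.tsv"), ("design", "design.tsv"),
        ("regions", "regions.tsv"), ("truth", "truth.tsv")]}
    write_transcripts_gtf(models, paths["gtf"])
    write_fasta(seqs, paths["fasta"])
    control.to_bedgraph(paths["control"])
    treated.to_bedgraph(paths["treatment"])
    pk_before.to_csv(paths["peaks_before"], sep="\t", index=False,
                     float_format="%.10g")
    pk_after.to_csv(paths["peaks_after"], sep="\t", index=False,
                    float_format="%.10g")
    counts.to_csv(paths["counts"], sep="\t")
    design.to_frame().to_csv(paths["design"], sep="\t")
    regions.to_csv(paths["regions"], sep="\t", index=False)
    truth.table.to_csv(paths["truth"], sep="\t", index=False,
                       float_format="%.10g")
    return paths
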