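"""End-to-end transcriptome segmentation: windowing -> regression -> HMM ->
Viterbi -> KS significance -> gene-level FDR."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .coverage import project_to_transcript, windowed_log_coverage
from .io import CALL_COLUMNS, GenomeCoverage, TranscriptModel
from .normalization import (DeviationProfile, NormalizationModel,
                            compute_deviations, fit_linear_model,
                            pool_cds_windows)
from .segmentation import CleavageHMM
from .significance import bh_fdr, gene_aggregate, ks_segments

logger = logging.getLogger("tailseg")


@dataclass
class SegmentationResult:
    """Everything the segmentation stage produces.

    ``decoded`` has one row per analysed transcript (diagnostics included);
    ``calls`` is the cleavage-call table restricted to transcripts with a
    testable, direction-consistent transition in the 3'-UTR; ``genes`` is the
    gene-level aggregation with BH q-values.
    """

    decoded: pd.DataFrame
    calls: pd.DataFrame
    genes: pd.DataFrame
    normalization: NormalizationModel
    hmm: CleavageHMM
    n_skipped_low_expression: int
    n_skipped_short: int


def segment_transcriptome(transcripts: list[TranscriptModel],
                          control: GenomeCoverage,
                          treatment: GenomeCoverage,
                          mode: str = "deplete",
                          window: int = 50, step: int = 20,
                          pseudocount: float = 1.0,
                          expression_floor: float = 1.0,
                          min_fit_windows: int = 200,
                          p_thresh: float = 0.01, fdr: float = 0.01,
                          min_segment: int = 3,
                          treatment_label: str = "treatment"
                          ) -> SegmentationResult:
    """Detect per-transcript 3'-UTR cleavage points from a coverage pair.

    Transcripts shorter than one window or with mean CDS coverage below
    ``expression_floor`` are skipped.  A call is retained when the decoded
    transition lies in the 3'-UTR, both segments have at least
    ``min_segment`` windows, and the segment means shift in the direction the
    mode implies (tail below body for 'deplete', above for 'enrich').
    """
    ctrl_tracks, trt_tracks, kept = [], [], []
    n_short = n_low = 0
    for tx in transcripts:
        if tx.length_tx < window:
            n_short += 1
            continue
        c = project_to_transcript(control, tx)
        t = project_to_transcript(treatment, tx)
        cds_span = c[: tx.cds_end_tx] if tx.cds_end_tx > 0 else c
        if cds_span.mean() < expression_floor:
            n_low += 1
            continue
        ctrl_tracks.append(windowed_log_coverage(
            c, tx.cds_end_tx, window, step, pseudocount, tx.transcript_id))
        trt_tracks.append(windowed_log_coverage(
            t, tx.cds_end_tx, window, step, pseudocount, tx.transcript_id))
        kept.append(tx)
    if not kept:
        raise ValueError("no transcripts passed the expression/length filters")
    logger.info("segmenting %d transcripts (%d short, %d low expression)",
                len(kept), n_short, n_low)

    x, y, cm, tm = pool_cds_windows(ctrl_tracks, trt_tracks)
    model = fit_linear_model(x, y, min_windows=min_fit_windows,
                             control_means=cm, treatment_means=tm)
    logger.info("normalization: Y = %.4f X + %.4f (n=%d, resid sd %.4f)",
                model.slope, model.intercept, model.n_windows, model.resid_sd)

    profiles: list[DeviationProfile] = [
        compute_deviations(c, t, model)
        for c, t in zip(ctrl_tracks, trt_tracks)]
    hmm = CleavageHMM(mode=mode)
    hmm.fit(profiles)

    rows = []
    for tx, prof in zip(kept, profiles):
        cand = hmm.decode(prof)
        k, n = cand.k, prof.n
        in_utr3 = bool(0 < k < n and prof.is_utr3[k])
        test = ks_segments(prof, k, min_segment) if in_utr3 else None
        body_mean = float(prof.deviations[:k].mean()) if 0 < k else np.nan
        tail_mean = float(prof.deviations[k:].mean()) if k < n else np.nan
        directional = bool(in_utr3 and (
            tail_mean < body_mean if mode == "deplete"
            else tail_mean > body_mean))
        tested = bool(in_utr3 and directional and test is not None
                      and test.testable)
        cleavage_tx = int(prof.starts[k]) if in_utr3 else -1
        rows.append({
            "transcript_id": tx.transcript_id, "gene_id": tx.gene_id,
            "treatment": treatment_label, "k": k, "n_windows": n,
            "cleavage_tx": cleavage_tx,
            "cleavage_genomic": (tx.tx_to_genomic(cleavage_tx)
                                 if in_utr3 else -1),
            "loglik": cand.loglik,
            "loglik_no_transition": cand.loglik_no_transition,
            "ks_D": test.statistic if tested else np.nan,
            "pvalue": test.pvalue if tested else np.nan,
            "body_mean_dev": body_mean, "tail_mean_dev": tail_mean,
            "in_utr3": in_utr3, "directional": directional,
            "tested": tested,
        })
    decoded = pd.DataFrame(rows)

    tested_mask = decoded["tested"].to_numpy(dtype=bool)
    # the hypothesis family is every analysed transcript: a transcript with
    # no decoded/testable transition is a non-discovery (p = 1), not a
    # hypothesis removed from the FDR family
    family_p = decoded["pvalue"].fillna(1.0).to_numpy()
    decoded["qvalue"] = bh_fdr(family_p)
    decoded["significant"] = (tested_mask
                              & (decoded["pvalue"] < p_thresh)
                              & (decoded["qvalue"] < fdr))
    calls = decoded.loc[tested_mask, CALL_COLUMNS + ["significant"]]
    calls = calls.reset_index(drop=True)

    fam = decoded[["transcript_id", "gene_id"]].copy()
    fam["pvalue"] = family_p
    genes = gene_aggregate(fam, p_thresh=p_thresh, fdr=fdr)
    return SegmentationResult(decoded, calls, genes, model, hmm, n_low,
                              n_short)
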