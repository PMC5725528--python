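"""Project genomic coverage into transcript coordinates and window it.

The observation sequence the segmentation model works on is built here: mean
coverage in overlapping windows (default 50 nt in 20 nt offsets) along the
intron-less transcript, log2-transformed with a pseudocount.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io import GenomeCoverage, TranscriptModel

logger = logging.getLogger("tailseg")


@dataclass
class WindowTrack:
    """Windowed log coverage along one transcript.

    ``is_utr3[i]`` is True iff the window *start* lies at or past the CDS end
    (windows straddling the boundary are labelled by their start).
    """

    transcript_id: str
    starts: np.ndarray
    means: np.ndarray
    log2: np.ndarray
    is_utr3: np.ndarray
    window: int
    step: int
    cds_end_tx: int

    @property
    def n(self) -> int:
        return len(self.starts)


def project_to_transcript(cov: GenomeCoverage,
                          tx: TranscriptModel) -> np.ndarray:
    """Per-base coverage along the transcript, 5'->3', introns excised.

    A chromosome absent from the coverage yields all zeros with a warning.
    """
    if tx.chrom not in cov.arrays:
        logger.warning("chromosome %s absent from coverage; %s gets zeros",
                       tx.chrom, tx.transcript_id)
    parts = [cov.get(tx.chrom, s, e) for s, e in tx.exons]
    values = np.concatenate(parts)
    if tx.strand == "-":
        values = values[::-1]
    return values


def windowed_log_coverage(values: np.ndarray, cds_end_tx: int,
                          window: int = 50, step: int = 20,
                          pseudocount: float = 1.0,
                          transcript_id: str = "") -> WindowTrack:
    """Mean coverage in overlapping windows, then log2(mean + pseudocount).

    Window count is floor((L - window)/step) + 1; trailing bases not covered
    by a full window are dropped.
    """
    values = np.asarray(values, dtype=float)
    L = len(values)
    if L < window:
        raise ValueError(
            f"transcript shorter than window ({L} < {window})")
    n = (L - window) // step + 1
    starts = np.arange(n) * step
    csum = np.concatenate([[0.0], np.cumsum(values)])
    means = (csum[starts + window] - csum[starts]) / window
    log2 = np.log2(means + pseudocount)
    is_utr3 = starts >= cds_end_tx
    return WindowTrack(transcript_id, starts, means, log2, is_utr3,
                       window, step, cds_end_tx)


def metagene_profile(tracks: dict[str, np.ndarray],
                     anchors: dict[str, int],
                     flank: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Average relative coverage around per-transcript anchor positions.

    Each transcript's per-base coverage is normalized by its own mean before
    averaging, so the profile is in units of "fraction of the transcript's
    average exonic coverage".  Returns (offsets, mean profile, n contributing);
    offsets with no contributing transcript are NaN in the profile.
    """
    if not anchors:
        raise ValueError("empty anchor set")
    width = 2 * flank + 1
    total = np.zeros(width)
    count = np.zeros(width, dtype=int)
    for tid, anchor in anchors.items():
        values = np.asarray(tracks[tid], dtype=float)
        mean = values.mean()
        if mean <= 0:
            continue
        rel = values / mean
        lo = max(0, anchor - flank)
        hi = min(len(values), anchor + flank + 1)
        if lo >= hi:
            continue
        sl = slice(lo - (anchor - flank), hi - (anchor - flank))
        total[sl] += rel[lo:hi]
        count[sl] += 1
    profile = np.where(count > 0, total / np.maximum(count, 1), np.nan)
    offsets = np.arange(-flank, flank + 1)
    return offsets, profile, count
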