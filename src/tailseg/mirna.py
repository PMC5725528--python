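"""Body/tail re-annotation at cleavage points and miRNA seed-target analysis.

A significant cleavage call splits a transcript into two independent
annotation units: the body (original id, last exon truncated at the cleavage
site) and the tail (id + "B", a single exon from cleavage+1 — in the 1-based
output convention — to the original transcript end).  Region-level expression
changes are computed from count matrices with median-of-ratios size factors,
and transcripts carrying an exact 7-mer seed match (reverse complement of
miRNA positions 2-8) are treated as miRNA targets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import TranscriptModel

_COMP = str.maketrans("ACGTN", "TGCAN")


@dataclass(frozen=True)
class RegionAnnotation:
    region_id: str
    parent: str
    role: str                 # body | tail | whole | CDS | UTR3
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.exons)


def split_annotation(tx: TranscriptModel, cleavage_genomic: int
                     ) -> tuple[RegionAnnotation, RegionAnnotation]:
    """Split a transcript at a cleavage point into body and tail regions.

    ``cleavage_genomic`` is the 0-based genomic coordinate of the *first tail
    base* in transcript orientation (the convention the call tables use).
    The body keeps the original id with its last exon truncated just before
    that base; the tail becomes a single-exon region with the "B" suffix.  In
    1-based GTF output this realises "body end = cleavage site, tail start =
    cleavage site + 1".
    """
    c_tx = tx.genomic_to_tx(cleavage_genomic)  # raises if not exonic
    if c_tx < tx.cds_end_tx:
        raise ValueError(f"{tx.transcript_id}: cleavage inside CDS")
    if c_tx >= tx.length_tx - 0:
        raise ValueError(f"{tx.transcript_id}: empty tail")
    if c_tx == 0:
        raise ValueError(f"{tx.transcript_id}: empty body")
    last = tx.exons[-1] if tx.strand == "+" else tx.exons[0]
    if not (last[0] <= cleavage_genomic < last[1]):
        raise ValueError(
            f"{tx.transcript_id}: cleavage outside the 3'-most exon")
    if tx.strand == "+":
        body_exons = tx.exons[:-1] + ((last[0], cleavage_genomic),)
        tail_exons = ((cleavage_genomic, last[1]),)
    else:
        body_exons = ((cleavage_genomic + 1, last[1]),) + tx.exons[1:]
        tail_exons = ((last[0], cleavage_genomic + 1),)
    body = RegionAnnotation(tx.transcript_id, tx.transcript_id, "body",
                            tx.chrom, tx.strand, body_exons)
    tail = RegionAnnotation(tx.transcript_id + "B", tx.transcript_id, "tail",
                            tx.chrom, tx.strand, tail_exons)
    return body, tail


def region_sequence(region: RegionAnnotation, tx: TranscriptModel,
                    tx_seq: str) -> str:
    """Spliced sequence of a region, read off the parent transcript sequence."""
    coords = []
    for s, e in region.exons:
        coords.extend(tx.genomic_to_tx(g) for g in (s, e - 1))
    t0, t1 = min(coords), max(coords) + 1
    return tx_seq[t0:t1]


def write_regions_gtf(regions: list[RegionAnnotation],
                      path: str) -> None:
    """Write body/tail regions as GTF exon features (1-based inclusive)."""
    with open(path, "w") as fh:
        for reg in regions:
            attrs = (f'gene_id "{reg.parent}"; '
                     f'transcript_id "{reg.region_id}"; '
                     f'region_role "{reg.role}";')
            for s, e in reg.exons:
                fh.write(f"{reg.chrom}\ttailseg\texon\t{s + 1}\t{e}\t.\t"
                         f"{reg.strand}\t.\t{attrs}\n")


def seed_site(mirna: str, seed_start: int = 1, seed_len: int = 7) -> str:
    """DNA target site: reverse complement of the miRNA 7-mer seed (pos 2-8)."""
    m = mirna.upper().replace("U", "T")
    if len(m) < seed_start + seed_len:
        raise ValueError("miRNA too short for the requested seed")
    seed = m[seed_start:seed_start + seed_len]
    return seed.translate(_COMP)[::-1]


def find_seed_sites(region_seq: str, mirna: str, seed_start: int = 1,
                    seed_len: int = 7) -> list[int]:
    """All 0-based positions of exact 7-mer seed matches in a DNA sequence.

    Overlapping occurrences are all returned; ambiguous bases (N) never match.
    """
    site = seed_site(mirna, seed_start, seed_len)
    seq = region_seq.upper().replace("U", "T")
    hits, start = [], seq.find(site)
    while start != -1:
        hits.append(start)
        start = seq.find(site, start + 1)
    return hits


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors (computed on regions with no zeros)."""
    mat = counts.to_numpy(dtype=float)
    if np.any(mat.sum(axis=0) == 0):
        raise ValueError("a sample has all-zero counts")
    positive = np.all(mat > 0, axis=1)
    if positive.sum() == 0:
        raise ValueError("no region has positive counts in every sample")
    logm = np.log(mat[positive])
    log_geo = logm.mean(axis=1, keepdims=True)
    sf = np.exp(np.median(logm - log_geo, axis=0))
    return pd.Series(sf, index=counts.columns, name="size_factor")


def region_fold_changes(counts: pd.DataFrame, design: pd.Series,
                        pseudocount: float = 0.5,
                        count_floor: float = 10.0) -> pd.DataFrame:
    """Per-region log2 fold changes (treatment vs control) from raw counts.

    Counts are normalized by median-of-ratios size factors, averaged per
    condition, and log2FC = log2((mean_trt + c) / (mean_ctrl + c)) with
    pseudocount c.  Regions whose mean normalized count is below
    ``count_floor`` are flagged (``above_floor``) for exclusion from
    distribution tests.
    """
    conditions = design.unique()
    if len(conditions) != 2:
        raise ValueError("design must have exactly two conditions")
    ctrl_cond = "control" if "control" in conditions else conditions[0]
    trt_cond = [c for c in conditions if c != ctrl_cond][0]
    sf = size_factors(counts)
    norm = counts / sf
    ctrl = norm.loc[:, design[design == ctrl_cond].index].mean(axis=1)
    trt = norm.loc[:, design[design == trt_cond].index].mean(axis=1)
    log2fc = np.log2((trt + pseudocount) / (ctrl + pseudocount))
    mean_norm = norm.mean(axis=1)
    return pd.DataFrame({
        "region_id": counts.index,
        "mean_normalized": mean_norm.to_numpy(),
        "mean_control": ctrl.to_numpy(),
        "mean_treatment": trt.to_numpy(),
        "log2fc": log2fc.to_numpy(),
        "above_floor": (mean_norm >= count_floor).to_numpy(),
    }).set_index("region_id")


def compare_fc_distributions(fc_a, fc_b, label_a: str = "a",
                             label_b: str = "b"):
    """Two-sided KS comparison of two log2FC samples, with ECDF tables.

    Returns (ks result, ecdf DataFrame).  Groups smaller than 3 get a
    warning flag in the frame's attrs (the p-value is then unreliable).
    """
    a = np.sort(np.asarray(fc_a, dtype=float))
    b = np.sort(np.asarray(fc_b, dtype=float))
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    ks = stats.ks_2samp(a, b, alternative="two-sided")
    ecdf = pd.concat([
        pd.DataFrame({"group": label_a, "log2fc": a,
                      "ecdf": np.arange(1, len(a) + 1) / len(a)}),
        pd.DataFrame({"group": label_b, "log2fc": b,
                      "ecdf": np.arange(1, len(b) + 1) / len(b)}),
    ], ignore_index=True)
    ecdf.attrs["unreliable"] = len(a) < 3 or len(b) < 3
    return ks, ecdf


def paired_region_difference(records: pd.DataFrame,
                             pairs: list[tuple[str, str]]) -> pd.DataFrame:
    """Per-pair difference log2FC(first) - log2FC(second).

    ``records`` is the output of :func:`region_fold_changes`; incomplete
    pairs are dropped (count in attrs).
    """
    rows, dropped = [], 0
    for first, second in pairs:
        if first not in records.index or second not in records.index:
            dropped += 1
            continue
        rows.append({"first": first, "second": second,
                     "delta_log2fc": float(records.loc[first, "log2fc"]
                                           - records.loc[second, "log2fc"])})
    out = pd.DataFrame(rows, columns=["first", "second", "delta_log2fc"])
    out.attrs["n_dropped"] = dropped
    return out
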