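"""Segment testing and multiple-testing control for decoded cleavage points.

Each decoded transition is scored with a two-sample Kolmogorov-Smirnov test
between the body- and tail-segment deviations; transcript results are
collapsed to genes by the minimum p-value and the gene table is FDR-controlled
with Benjamini-Hochberg.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .normalization import DeviationProfile


@dataclass
class SegmentTest:
    transcript_id: str
    statistic: float      # KS D = sup |ECDF_body - ECDF_tail|
    pvalue: float
    n_body: int
    n_tail: int
    body_mean: float
    tail_mean: float
    testable: bool


def ks_segments(profile, k: int, min_segment: int = 3) -> SegmentTest:
    """Two-sided two-sample KS test between body (d[:k]) and tail (d[k:]).

    A segment smaller than ``min_segment`` windows marks the call untestable
    (NaN statistic/p) rather than producing an unreliable p-value.
    """
    if isinstance(profile, DeviationProfile):
        tid, d = profile.transcript_id, np.asarray(profile.deviations, float)
    else:
        tid, d = "", np.asarray(profile, dtype=float)
    body, tail = d[:k], d[k:]
    if len(body) < min_segment or len(tail) < min_segment:
        return SegmentTest(tid, np.nan, np.nan, len(body), len(tail),
                           float(np.mean(body)) if len(body) else np.nan,
                           float(np.mean(tail)) if len(tail) else np.nan,
                           testable=False)
    res = stats.ks_2samp(body, tail, alternative="two-sided", method="asymp")
    return SegmentTest(tid, float(res.statistic), float(res.pvalue),
                       len(body), len(tail), float(body.mean()),
                       float(tail.mean()), testable=True)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (adjusted p-values)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def gene_aggregate(tests: pd.DataFrame, gene_map: dict[str, str] | None = None,
                   p_thresh: float = 0.01, fdr: float = 0.01) -> pd.DataFrame:
    """Collapse transcript-level tests to one call per gene.

    ``tests`` needs columns transcript_id and pvalue (and gene_id unless
    ``gene_map`` is given).  Gene p-value = minimum transcript p-value; BH FDR
    is applied across genes.  Transcripts without a gene mapping are dropped
    with a count in the table's attrs.
    """
    df = tests.copy()
    if gene_map is not None:
        df["gene_id"] = df["transcript_id"].map(gene_map)
    if "gene_id" not in df.columns:
        raise ValueError("need gene_id column or gene_map")
    n_unmapped = int(df["gene_id"].isna().sum())
    df = df.dropna(subset=["gene_id", "pvalue"])
    rows = []
    for gid, sub in df.groupby("gene_id", sort=True):
        best = sub.loc[sub["pvalue"].idxmin()]
        rows.append({"gene_id": gid, "best_transcript": best["transcript_id"],
                     "pvalue": float(best["pvalue"]),
                     "n_transcripts": len(sub)})
    genes = pd.DataFrame(rows,
                         columns=["gene_id", "best_transcript", "pvalue",
                                  "n_transcripts"])
    if len(genes):
        genes["qvalue"] = bh_fdr(genes["pvalue"].to_numpy())
        genes["significant"] = ((genes["pvalue"] < p_thresh)
                                & (genes["qvalue"] < fdr))
    else:
        genes["qvalue"] = np.array([], dtype=float)
        genes["significant"] = np.array([], dtype=bool)
    genes.attrs["n_unmapped"] = n_unmapped
    return genes


def set_overlap(call_sets: dict[str, set]) -> dict[tuple[str, ...], int]:
    """Exact intersection cardinalities for every pair/triple/... of call sets."""
    out: dict[tuple[str, ...], int] = {}
    names = sorted(call_sets)
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            inter = set.intersection(*(set(call_sets[n]) for n in combo))
            out[combo] = len(inter)
    return out
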