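"""3'-end-seq analyses around predicted cleavage points.

Peak tables carry one row per (transcript, peak) with transcript-coordinate
positions and heights.  A cleaved transcript is expected to show a proximal
peak (3' end of the shortened body) and a distal peak (canonical transcript
end); depleting uncapped tails lowers the distal peak relative to the
proximal one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class RatioChangeResult:
    per_transcript: pd.DataFrame  # r_before, r_after, rel_change, log2_change
    t_statistic: float
    pvalue: float
    mean_rel_change: float
    n: int
    on_log_ratios: bool


def label_proximal_distal(peaks: pd.DataFrame) -> pd.DataFrame:
    """Label the most 5' (proximal) and most 3' (distal) peak per transcript.

    Transcripts with fewer than two peaks are excluded (reason recorded in the
    result's attrs); intermediate peaks are counted but ignored for ratios.
    """
    rows, excluded = [], {}
    for tid, sub in peaks.groupby("transcript_id", sort=True):
        if len(sub) < 2:
            excluded[tid] = "fewer than 2 peaks"
            continue
        prox = sub.loc[sub["pos"].idxmin()]
        dist = sub.loc[sub["pos"].idxmax()]
        rows.append({"transcript_id": tid,
                     "proximal_pos": int(prox["pos"]),
                     "proximal_height": float(prox["height"]),
                     "distal_pos": int(dist["pos"]),
                     "distal_height": float(dist["height"]),
                     "n_intermediate": len(sub) - 2})
    out = pd.DataFrame(rows, columns=["transcript_id", "proximal_pos",
                                      "proximal_height", "distal_pos",
                                      "distal_height", "n_intermediate"])
    out.attrs["excluded"] = excluded
    return out


def ratio_change(before: pd.DataFrame, after: pd.DataFrame,
                 on_log_ratios: bool = True) -> RatioChangeResult:
    """Relative change of the distal/proximal height ratio per transcript.

    The paired t-test is computed on log-transformed ratios by default (ratio
    distributions are right-skewed); set ``on_log_ratios=False`` for the raw
    version.  Transcripts with a zero proximal height are excluded.
    """
    lb = label_proximal_distal(before).set_index("transcript_id")
    la = label_proximal_distal(after).set_index("transcript_id")
    common = lb.index.intersection(la.index)
    rows = []
    for tid in common:
        pb, pa = lb.loc[tid], la.loc[tid]
        if pb["proximal_height"] <= 0 or pa["proximal_height"] <= 0:
            continue
        rb = pb["distal_height"] / pb["proximal_height"]
        ra = pa["distal_height"] / pa["proximal_height"]
        if rb <= 0:
            continue
        rows.append({"transcript_id": tid, "r_before": rb, "r_after": ra,
                     "rel_change": (ra - rb) / rb,
                     "log2_change": np.log2(ra / rb) if ra > 0 else -np.inf})
    df = pd.DataFrame(rows)
    if len(df) < 2:
        raise ValueError("need >= 2 paired transcripts for the t-test")
    x = df["log2_change"].to_numpy() if on_log_ratios \
        else (df["r_after"] - df["r_before"]).to_numpy()
    if np.ptp(x) == 0:
        raise ValueError("degenerate variance: all paired differences equal")
    res = stats.ttest_rel(df["r_after"], df["r_before"]) \
        if not on_log_ratios else stats.ttest_1samp(x, 0.0)
    return RatioChangeResult(df, float(res.statistic), float(res.pvalue),
                             float(df["rel_change"].mean()), len(df),
                             on_log_ratios)


def nearest_peak_distance(calls: pd.DataFrame, peaks: pd.DataFrame,
                          threshold: int = 100
                          ) -> tuple[pd.DataFrame, float]:
    """Distance from each predicted cleavage point to the most proximal peak.

    ``calls`` needs transcript_id and cleavage_tx columns; returns the
    per-transcript distances and the fraction within ``threshold`` nt.
    Transcripts without peaks are excluded.
    """
    prox = peaks.groupby("transcript_id")["pos"].min()
    rows = []
    for row in calls.itertuples(index=False):
        if row.transcript_id not in prox.index:
            continue
        d = abs(int(row.cleavage_tx) - int(prox[row.transcript_id]))
        rows.append({"transcript_id": row.transcript_id, "distance": d})
    df = pd.DataFrame(rows, columns=["transcript_id", "distance"])
    if len(df) == 0:
        return df, float("nan")
    frac = float((df["distance"] <= threshold).mean())
    return df, frac


def apa_enrichment(calls: pd.DataFrame, apa_sites: dict[str, list[int]],
                   utr_bounds: dict[str, tuple[int, int]],
                   window: int = 500, n_random: int | None = None,
                   seed: int = 0):
    """Offsets of the nearest APA site around predicted cleavage points,
    against a random-position control drawn uniformly from random UTRs.

    Returns (observed offsets, control offsets, KS result).
    """
    if not apa_sites or all(len(v) == 0 for v in apa_sites.values()):
        raise ValueError("empty APA site list")
    rng = np.random.default_rng(seed)

    def nearest_offset(tid: str, pos: int) -> float | None:
        sites = apa_sites.get(tid)
        if not sites:
            return None
        off = np.asarray(sites) - pos
        off = off[np.abs(off) <= window]
        if len(off) == 0:
            return None
        return float(off[np.argmin(np.abs(off))])

    observed = []
    for row in calls.itertuples(index=False):
        off = nearest_offset(row.transcript_id, int(row.cleavage_tx))
        if off is not None:
            observed.append(off)
    n_random = n_random if n_random is not None else len(calls)
    tids = sorted(utr_bounds)
    control = []
    for _ in range(n_random):
        tid = tids[rng.integers(len(tids))]
        lo, hi = utr_bounds[tid]
        pos = int(rng.integers(lo, hi))
        off = nearest_offset(tid, pos)
        if off is not None:
            control.append(off)
    observed, control = np.asarray(observed), np.asarray(control)
    if len(observed) == 0 or len(control) == 0:
        raise ValueError("no offsets within the window in one of the samples")
    ks = stats.ks_2samp(observed, control, alternative="two-sided")
    return observed, control, ks
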