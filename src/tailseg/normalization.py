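"""Treatment-vs-control normalization of windowed log coverage.

A single linear model Y = aX + b is fitted per treatment on all CDS-labelled
windows genome-wide, where X is the control log2 window coverage and Y the
treatment's.  Per-transcript deviations from this model are the observation
sequences handed to the segmentation HMM.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator

from .coverage import WindowTrack


@dataclass
class NormalizationModel:
    slope: float
    intercept: float
    n_windows: int
    resid_sd: float

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.slope * np.asarray(x, dtype=float) + self.intercept


@dataclass
class DeviationProfile:
    """Per-window deviations d_i = y_i - (a x_i + b) for one transcript."""

    transcript_id: str
    deviations: np.ndarray
    starts: np.ndarray
    is_utr3: np.ndarray
    cds_end_tx: int

    @property
    def n(self) -> int:
        return len(self.deviations)


class TreatmentNormalizer(BaseEstimator):
    """Ordinary-least-squares Y = aX + b fitted on CDS window log coverage.

    Parameters
    ----------
    min_windows : minimum number of pooled CDS windows required to fit.
    exclude_double_zero : drop windows whose *raw* mean coverage is zero in
        both tracks before fitting; such windows sit at a single point in log
        space determined only by the pseudocount and carry no information
        about the treatment/control relationship.
    """

    def __init__(self, min_windows: int = 200, exclude_double_zero: bool = True):
        self.min_windows = min_windows
        self.exclude_double_zero = exclude_double_zero

    def fit(self, X, y, control_means=None, treatment_means=None):
        """Fit on 1-d arrays of control (X) and treatment (y) log values."""
        x = np.asarray(X, dtype=float).ravel()
        y = np.asarray(y, dtype=float).ravel()
        if x.shape != y.shape:
            raise ValueError("control and treatment windows must be paired")
        if self.exclude_double_zero and control_means is not None:
            cm = np.asarray(control_means, dtype=float).ravel()
            tm = np.asarray(treatment_means, dtype=float).ravel()
            keep = (cm > 0) | (tm > 0)
            x, y = x[keep], y[keep]
        if len(x) < self.min_windows:
            raise ValueError(
                f"only {len(x)} CDS windows available; need >= {self.min_windows}")
        if np.ptp(x) == 0:
            raise ValueError("zero variance in control windows; cannot fit")
        res = stats.linregress(x, y)
        self.slope_ = float(res.slope)
        self.intercept_ = float(res.intercept)
        self.n_windows_ = len(x)
        resid = y - (self.slope_ * x + self.intercept_)
        dof = max(len(x) - 2, 1)
        self.resid_sd_ = float(np.sqrt(np.sum(resid ** 2) / dof))
        return self

    def predict(self, X):
        return self.slope_ * np.asarray(X, dtype=float) + self.intercept_

    @property
    def model_(self) -> NormalizationModel:
        return NormalizationModel(self.slope_, self.intercept_,
                                  self.n_windows_, self.resid_sd_)


def pool_cds_windows(control_tracks: list[WindowTrack],
                     treatment_tracks: list[WindowTrack]):
    """Collect matched CDS-window (log2, raw-mean) values across transcripts."""
    xs, ys, cms, tms = [], [], [], []
    for ctrl, trt in zip(control_tracks, treatment_tracks):
        if ctrl.n != trt.n or not np.array_equal(ctrl.starts, trt.starts):
            raise ValueError(f"{ctrl.transcript_id}: window grids differ")
        cds = ~ctrl.is_utr3
        xs.append(ctrl.log2[cds])
        ys.append(trt.log2[cds])
        cms.append(ctrl.means[cds])
        tms.append(trt.means[cds])
    return (np.concatenate(xs), np.concatenate(ys),
            np.concatenate(cms), np.concatenate(tms))


def fit_linear_model(control_logs, treatment_logs, min_windows: int = 200,
                     control_means=None, treatment_means=None
                     ) -> NormalizationModel:
    """OLS fit of treatment on control log window coverage (CDS windows)."""
    est = TreatmentNormalizer(min_windows=min_windows)
    est.fit(control_logs, treatment_logs, control_means=control_means,
            treatment_means=treatment_means)
    return est.model_


def compute_deviations(control: WindowTrack, treatment: WindowTrack,
                       model: NormalizationModel) -> DeviationProfile:
    """Per-window deviations of the treatment track from the fitted model."""
    if control.n != treatment.n or not np.array_equal(control.starts,
                                                      treatment.starts):
        raise ValueError(
            f"{control.transcript_id}: control/treatment window grid mismatch")
    d = treatment.log2 - model.predict(control.log2)
    return DeviationProfile(control.transcript_id, d, control.starts.copy(),
                            control.is_utr3.copy(), control.cds_end_tx)
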