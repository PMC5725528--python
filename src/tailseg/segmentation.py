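"""Two-state ("Body"/"Tail") Gaussian HMM with a single allowed transition.

The model: observations d_1..d_n (per-window deviations from the
treatment~control regression) are emitted by a left-to-right chain with
transition matrix [[1-tau, tau], [0, 1]] — Tail is absorbing, so every state
path has the form Body^k Tail^(n-k) for some changepoint k in {0..n}.  Both
states emit Gaussians with state-specific means and a *shared* variance.

Parameters are fitted globally across transcripts by Baum-Welch (EM); the
per-transcript changepoint is decoded with the Viterbi algorithm.  Because the
path space is exactly the set of changepoints, the forward-backward recursions
collapse to an exact posterior over k, which is what the E-step computes
(vectorized across transcripts); a brute-force changepoint enumeration is also
exposed as an independent check on the Viterbi decoder.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp
from sklearn.base import BaseEstimator

from .normalization import DeviationProfile

_LOG2PI = np.log(2.0 * np.pi)


@dataclass
class HmmParams:
    mu_body: float
    mu_tail: float
    sigma2: float
    pi_body: float = 0.99
    tau: float = 0.05

    def __post_init__(self):
        if self.sigma2 <= 0:
            raise ValueError("sigma2 must be > 0")
        if not (0.0 <= self.tau <= 1.0 and 0.0 <= self.pi_body <= 1.0):
            raise ValueError("tau and pi_body must lie in [0, 1]")


@dataclass
class CleavageCandidate:
    """Decoded changepoint for one transcript.

    ``k`` is the index of the first Tail window; ``k == n`` means no
    transition was decoded (the all-Body path won).
    """

    transcript_id: str
    k: int
    loglik: float
    loglik_no_transition: float


def _as_array(profile) -> tuple[str, np.ndarray]:
    if isinstance(profile, DeviationProfile):
        return profile.transcript_id, np.asarray(profile.deviations, float)
    return "", np.asarray(profile, dtype=float)


def _log_norm(x: np.ndarray, mu: float, sigma2: float) -> np.ndarray:
    return -0.5 * (_LOG2PI + np.log(sigma2) + (x - mu) ** 2 / sigma2)


def _changepoint_loglik(d: np.ndarray, p: HmmParams) -> np.ndarray:
    """log P(d, path with changepoint k) for k = 0..n.

    k = 0 is the all-Tail path (enters Tail at t=0), k = n the all-Body path.
    """
    n = len(d)
    lpb = _log_norm(d, p.mu_body, p.sigma2)
    lpt = _log_norm(d, p.mu_tail, p.sigma2)
    cb = np.concatenate([[0.0], np.cumsum(lpb)])
    ct = np.concatenate([[0.0], np.cumsum(lpt)])
    st = ct[-1] - ct  # st[k] = sum_{i>=k} lpt
    with np.errstate(divide="ignore"):
        log_pi, log_1mpi = np.log(p.pi_body), np.log1p(-p.pi_body)
        log_tau, log_1mtau = np.log(p.tau), np.log1p(-p.tau)
    k = np.arange(n + 1)
    ll = log_pi + cb + np.maximum(k - 1, 0) * log_1mtau + st + log_tau
    ll[0] = log_1mpi + st[0]
    ll[n] = log_pi + cb[n] + (n - 1) * log_1mtau
    return ll


def brute_force_transition(profile, params: HmmParams) -> CleavageCandidate:
    """Exhaustively score every changepoint path and return the argmax.

    Ties break toward the smallest k (most proximal cleavage).  Serves as the
    exact reference the Viterbi decoder must agree with.
    """
    tid, d = _as_array(profile)
    if len(d) < 2:
        raise ValueError("profile must have at least 2 windows")
    if not np.all(np.isfinite(d)):
        raise ValueError("non-finite observations")
    ll = _changepoint_loglik(d, params)
    k = int(np.argmax(ll))
    return CleavageCandidate(tid, k, float(ll[k]), float(ll[len(d)]))


def viterbi_transition(profile, params: HmmParams) -> CleavageCandidate:
    """Most likely Body^k Tail^(n-k) path via the Viterbi recursion.

    The left-to-right topology forces the decoded path to be a single
    changepoint; ties break toward the smallest k.
    """
    tid, d = _as_array(profile)
    n = len(d)
    if n < 2:
        raise ValueError("profile must have at least 2 windows")
    if not np.all(np.isfinite(d)):
        raise ValueError("non-finite observations")
    p = params
    lpb = _log_norm(d, p.mu_body, p.sigma2)
    lpt = _log_norm(d, p.mu_tail, p.sigma2)
    with np.errstate(divide="ignore"):
        log_pi, log_1mpi = np.log(p.pi_body), np.log1p(-p.pi_body)
        log_tau, log_1mtau = np.log(p.tau), np.log1p(-p.tau)
    delta_b = log_pi + lpb[0]
    delta_t = log_1mpi + lpt[0]
    from_body = np.zeros(n, dtype=bool)
    delta_b_hist = np.empty(n)
    delta_b_hist[0] = delta_b
    for t in range(1, n):
        jump = delta_b + log_tau
        stay = delta_t
        # strict > : on a tie prefer staying in Tail, i.e. the earlier
        # transition, so ties resolve toward the smallest k
        from_body[t] = jump > stay
        delta_t = max(jump, stay) + lpt[t]
        delta_b = delta_b + log_1mtau + lpb[t]
        delta_b_hist[t] = delta_b
    loglik_no_transition = float(delta_b)
    if delta_t >= delta_b:  # tie prefers Tail end (k < n)
        loglik = float(delta_t)
        k = n - 1
        while k > 0 and not from_body[k]:
            k -= 1
    else:
        loglik, k = loglik_no_transition, n
    return CleavageCandidate(tid, k, loglik, loglik_no_transition)


class CleavageHMM(BaseEstimator):
    """Constrained two-state Gaussian HMM fitted by Baum-Welch.

    Fitting is global: one parameter set per treatment, estimated across all
    transcript profiles; decoding is per transcript.

    Parameters
    ----------
    mode : 'deplete' (tail coverage reduced; mu_tail < mu_body expected, as
        under TEX/CAP-IP-like enrichment of capped bodies) or 'enrich'
        (mu_tail > mu_body, 3'-PD-like enrichment of uncapped tails).
    tol : EM stops when the total log-likelihood improves by less than this.
    max_iter : maximum EM iterations.
    sigma2_floor : lower bound on the shared emission variance.
    init : optional :class:`HmmParams` overriding the data-driven start.

    Attributes (after :meth:`fit`)
    ------------------------------
    params_ : fitted :class:`HmmParams`
    loglik_trace_ : total log-likelihood per EM iteration
    converged_ : whether |dLL| < tol was reached
    mode_consistent_ : whether the fitted means respect the mode's sign
    """

    _TAU_BOUNDS = (1e-6, 1.0 - 1e-6)

    def __init__(self, mode: str = "deplete", tol: float = 1e-6,
                 max_iter: int = 200, sigma2_floor: float = 1e-6,
                 init: HmmParams | None = None):
        self.mode = mode
        self.tol = tol
        self.max_iter = max_iter
        self.sigma2_floor = sigma2_floor
        self.init = init

    # -- initialization ----------------------------------------------------
    def _default_init(self, profiles) -> HmmParams:
        body_vals, tail_vals, lengths = [], [], []
        for prof in profiles:
            _, d = _as_array(prof)
            lengths.append(len(d))
            if isinstance(prof, DeviationProfile) and prof.is_utr3.any() \
                    and not prof.is_utr3.all():
                body_vals.append(d[~prof.is_utr3])
                utr = d[prof.is_utr3]
            else:
                split = max(1, int(len(d) * 0.75))
                body_vals.append(d[:split])
                utr = d[split:] if split < len(d) else d[-1:]
            q = max(1, len(utr) // 4)
            tail_vals.append(utr[-q:])
        allv = np.concatenate([_as_array(p)[1] for p in profiles])
        mu_b = float(np.mean(np.concatenate(body_vals)))
        mu_t = float(np.mean(np.concatenate(tail_vals)))
        gap = 0.1
        if self.mode == "deplete" and mu_t >= mu_b:
            mu_t = mu_b - gap
        elif self.mode == "enrich" and mu_t <= mu_b:
            mu_t = mu_b + gap
        sigma2 = max(float(np.var(allv)), self.sigma2_floor)
        tau = 1.0 / max(float(np.median(lengths)), 2.0)
        return HmmParams(mu_b, mu_t, sigma2, pi_body=0.99, tau=tau)

    # -- EM ----------------------------------------------------------------
    def fit(self, X, y=None):
        """Fit on a list of deviation profiles (arrays or DeviationProfile)."""
        profiles = list(X)
        if not profiles:
            raise ValueError("no profiles to fit")
        arrays = [_as_array(p)[1] for p in profiles]
        if any(len(a) < 2 for a in arrays):
            raise ValueError("every profile needs >= 2 windows")
        if any(not np.all(np.isfinite(a)) for a in arrays):
            raise ValueError("non-finite observations")
        if self.mode not in ("deplete", "enrich"):
            raise ValueError(f"unknown mode {self.mode!r}")

        lengths = np.array([len(a) for a in arrays])
        N, T = len(arrays), int(lengths.max())
        D = np.zeros((N, T))
        mask = np.zeros((N, T), dtype=bool)
        for i, a in enumerate(arrays):
            D[i, : len(a)] = a
            mask[i, : len(a)] = True
        if np.ptp(D[mask]) == 0:
            warnings.warn("all observations identical; variance floored")

        p = self.init if self.init is not None else self._default_init(profiles)
        mu_b, mu_t = p.mu_body, p.mu_tail
        sigma2 = max(p.sigma2, self.sigma2_floor)
        pi_b = min(max(p.pi_body, 1e-6), 1 - 1e-6)
        tau = min(max(p.tau, self._TAU_BOUNDS[0]), self._TAU_BOUNDS[1])

        karr = np.arange(T + 1)[None, :]          # candidate changepoints
        valid = karr <= lengths[:, None]          # k in {0..n_i}
        trace = []
        converged = False
        for _ in range(self.max_iter):
            lpb = np.where(mask, _log_norm(D, mu_b, sigma2), 0.0)
            lpt = np.where(mask, _log_norm(D, mu_t, sigma2), 0.0)
            cb = np.concatenate([np.zeros((N, 1)), np.cumsum(lpb, 1)], 1)
            ct = np.concatenate([np.zeros((N, 1)), np.cumsum(lpt, 1)], 1)
            st = ct[:, [-1]] - ct                 # suffix tail sums
            ll_k = (np.log(pi_b) + cb + np.maximum(karr - 1, 0) * np.log1p(-tau)
                    + st + np.log(tau))
            ll_k[:, 0] = np.log1p(-pi_b) + st[:, 0]
            at_n = karr == lengths[:, None]
            ll_k = np.where(at_n, ll_k - np.log(tau), ll_k)
            ll_k = np.where(valid, ll_k, -np.inf)

            seq_ll = logsumexp(ll_k, axis=1)
            total_ll = float(seq_ll.sum())
            trace.append(total_ll)
            if len(trace) > 1 and abs(trace[-1] - trace[-2]) < self.tol:
                converged = True
                break

            w = np.exp(ll_k - seq_ll[:, None])    # posterior over k
            w = np.where(valid, w, 0.0)
            # P(state_t = Body) = P(k > t): complementary cumulative of w
            wc = np.cumsum(w, axis=1)
            gamma_b = np.where(mask, 1.0 - wc[:, :-1], 0.0)
            gamma_t = np.where(mask, wc[:, :-1], 0.0)

            nb, nt = gamma_b.sum(), gamma_t.sum()
            sb, st_sum = (gamma_b * D).sum(), (gamma_t * D).sum()
            mu_b = sb / max(nb, 1e-300)
            mu_t = st_sum / max(nt, 1e-300)
            sq = ((gamma_b * (D - mu_b) ** 2).sum()
                  + (gamma_t * (D - mu_t) ** 2).sum())
            sigma2 = max(sq / max(nb + nt, 1e-300), self.sigma2_floor)
            # expected transition counts out of Body
            e_bb = (w * np.maximum(karr - 1, 0)).sum()
            e_bt = (w[:, 1:].sum() - w[at_n].sum())
            tau = e_bt / max(e_bb + e_bt, 1e-300)
            tau = min(max(tau, self._TAU_BOUNDS[0]), self._TAU_BOUNDS[1])
            pi_b = float(np.mean(1.0 - w[:, 0]))
            pi_b = min(max(pi_b, 1e-6), 1 - 1e-6)

        self.params_ = HmmParams(float(mu_b), float(mu_t), float(sigma2),
                                 float(pi_b), float(tau))
        self.loglik_trace_ = np.asarray(trace)
        self.converged_ = converged
        self.n_iter_ = len(trace)
        if not converged:
            warnings.warn("Baum-Welch did not converge; returning best fit")
        self.mode_consistent_ = (mu_t < mu_b if self.mode == "deplete"
                                 else mu_t > mu_b)
        if not self.mode_consistent_:
            warnings.warn(
                f"fitted means do not separate in {self.mode} direction "
                f"(mu_body={mu_b:.3g}, mu_tail={mu_t:.3g})")
        return self

    # -- decoding ----------------------------------------------------------
    def decode(self, profile) -> CleavageCandidate:
        return viterbi_transition(profile, self.params_)

    def predict(self, X) -> np.ndarray:
        """Viterbi changepoint index per profile (k = n means no transition)."""
        return np.array([self.decode(p).k for p in X], dtype=int)

    def score(self, X, y=None) -> float:
        """Total log-likelihood of the profiles under the fitted parameters."""
        return float(sum(
            logsumexp(_changepoint_loglik(_as_array(p)[1], self.params_))
            for p in X))


def fit_hmm_baum_welch(profiles, init: HmmParams | None = None,
                       tol: float = 1e-6, max_iter: int = 200,
                       mode: str = "deplete"
                       ) -> tuple[HmmParams, np.ndarray]:
    """Functional wrapper: fit the HMM and return (params, loglik trace)."""
    est = CleavageHMM(mode=mode, tol=tol, max_iter=max_iter, init=init)
    est.fit(profiles)
    return est.params_, est.loglik_trace_
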