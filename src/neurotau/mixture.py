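"""Mixture-of-exponentials fits to spike-count autocorrelations.

A neuron's autocorrelation is modelled as a linear mixture of exponential
decays,

    AC(t) = sum_{i=1}^{M} c_i * exp(-t / tau_i),

with M between 1 and 4. Fits are nonlinear least squares in linear AC
space over the lag range ``start_lag .. max_lag`` (log-space fitting is
not possible because AC can be <= 0 at long lags). The model order M* is
chosen by the Bayesian information criterion among converged fits, subject
to every component contributing at least 1% of the total mixing weight
(``c_i >= 0.01 * sum(c)``); otherwise the model with fewer timescales is
preferred even when the BIC favours the larger one. A selected fit passes
quality control when its coefficient of determination exceeds 0.5.

The effective timescale summarises a multi-timescale neuron by the
mixing-coefficient-weighted mean

    tau_eff = sum(c_i tau_i) / sum(c_i),

which matches the area under the mixture autocorrelation to that of a
single exponential with timescale tau_eff.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import least_squares

from .acf import Autocorrelogram, find_fit_start

__all__ = [
    "ExpMixtureResults",
    "ExpMixtureModel",
    "NoConvergedFitError",
    "fit_exp_mixture",
    "select_model",
    "effective_timescale",
    "MIN_COEFF_FRACTION",
    "QC_R2_THRESHOLD",
]

#: Minimum fractional contribution of a component in a selected model.
MIN_COEFF_FRACTION = 0.01
#: R^2 threshold for a fit to pass quality control.
QC_R2_THRESHOLD = 0.5


class NoConvergedFitError(RuntimeError):
    """No candidate model order produced a converged fit."""


@dataclass(frozen=True)
class ExpMixtureResults:
    """Fitted exponential mixture for one unit.

    ``taus`` are ascending, in seconds; ``coeffs`` are the matching
    nonnegative mixing coefficients. ``bic`` uses the least-squares form
    n*ln(RSS/n) + k*ln(n) with k = 2M free parameters over the n fitted
    lags. ``qc_pass`` is only meaningful on a selected model.
    """

    unit_id: object
    M: int
    taus: np.ndarray
    coeffs: np.ndarray
    bic: float
    r_squared: float
    start_lag: int
    rss: float
    n_fitted: int
    converged: bool
    qc_pass: bool = False

    @property
    def tau_eff(self) -> float:
        return effective_timescale(self)

    def predict(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return np.sum(self.coeffs[:, None]
                      * np.exp(-t[None, :] / self.taus[:, None]), axis=0)

    def satisfies_min_coeff(self, fraction: float = MIN_COEFF_FRACTION) -> bool:
        total = float(np.sum(self.coeffs))
        if total <= 0:
            return False
        return bool(np.all(self.coeffs >= fraction * total))

    def summary(self) -> str:
        lines = [
            "Exponential mixture fit",
            "=" * 40,
            f"unit:        {self.unit_id}",
            f"M:           {self.M}",
            f"converged:   {self.converged}",
            f"BIC:         {self.bic:.2f}",
            f"R^2:         {self.r_squared:.4f}",
            f"start lag:   {self.start_lag}",
            f"tau_eff [s]: {self.tau_eff:.4g}" if np.sum(self.coeffs) > 0
            else "tau_eff [s]: undefined",
            f"QC pass:     {self.qc_pass}",
            "-" * 40,
            "  i      tau [s]        c_i",
        ]
        for i, (tau, c) in enumerate(zip(self.taus, self.coeffs), start=1):
            lines.append(f"  {i}   {tau:10.4g}  {c:10.4g}")
        return "\n".join(lines)


def effective_timescale(fit: ExpMixtureResults) -> float:
    """Mixing-coefficient-weighted mean of the fitted timescales."""
    total = float(np.sum(fit.coeffs))
    if total <= 0:
        raise ValueError("effective timescale undefined: sum of coefficients is 0")
    return float(np.dot(fit.coeffs, fit.taus) / total)


class ExpMixtureModel:
    """Exponential-mixture model of one autocorrelogram.

    Parameters
    ----------
    ac : Autocorrelogram to fit.
    start_lag : first fitted lag index; by default the earliest lag at
        which the autocorrelation begins to decay (argmax over the first
        ``search_horizon`` lags).
    duration : recording duration in seconds, used as the upper bound on
        fitted timescales; defaults to ``n_bins * bin_width``.
    n_starts : number of random multi-start initializations per model order.
    seed : seed for the multi-start draws (fits are deterministic given it).
    """

    def __init__(self, ac: Autocorrelogram, start_lag: int | None = None,
                 duration: float | None = None, n_starts: int = 10,
                 search_horizon: int = 20, seed: int = 0):
        self.ac = ac
        self.start_lag = (find_fit_start(ac, search_horizon)
                          if start_lag is None else int(start_lag))
        if self.start_lag < 1:
            raise ValueError("start_lag must be >= 1 (lag 0 is excluded)")
        self.duration = (ac.n_bins * ac.bin_width
                         if duration is None else float(duration))
        self.n_starts = int(n_starts)
        self.seed = int(seed)

    def fit(self, M: int) -> ExpMixtureResults:
        """Fit an M-component mixture by multi-start nonlinear least squares."""
        if not 1 <= M <= 4:
            raise ValueError("M must be in 1..4")
        t = self.ac.lags[self.start_lag:]
        y = self.ac.ac[self.start_lag:]
        n = y.size
        dt = self.ac.bin_width
        tss = float(np.sum((y - y.mean()) ** 2))

        lo = np.concatenate([np.zeros(M), np.full(M, dt)])
        hi = np.concatenate([np.full(M, np.inf), np.full(M, self.duration)])

        def resid(p):
            c, tau = p[:M], p[M:]
            return np.sum(c[:, None] * np.exp(-t[None, :] / tau[:, None]),
                          axis=0) - y

        def jac(p):
            c, tau = p[:M], p[M:]
            e = np.exp(-t[None, :] / tau[:, None])      # (M, n)
            J = np.empty((n, 2 * M))
            J[:, :M] = e.T
            J[:, M:] = (c[:, None] * e * t[None, :] / tau[:, None] ** 2).T
            return J

        rng = np.random.default_rng(self.seed)
        amp = max(float(y[0]), 1e-3)
        best = None
        n_stall = 0
        tau_lo, tau_hi = dt, min(self.ac.max_lag, self.duration)
        for _ in range(self.n_starts):
            log_tau = rng.uniform(np.log(tau_lo), np.log(tau_hi), size=M)
            taus0 = np.sort(np.exp(log_tau))
            coeffs0 = rng.dirichlet(np.ones(M)) * amp
            p0 = np.concatenate([coeffs0, taus0])
            try:
                res = least_squares(resid, p0, jac=jac, bounds=(lo, hi),
                                    method="trf", max_nfev=400)
            except Exception:
                continue
            if not np.all(np.isfinite(res.x)):
                continue
            rss = float(np.sum(res.fun ** 2))
            if best is not None and rss >= best[0] * (1 - 1e-6):
                n_stall += 1
            else:
                n_stall = 0
            if best is None or rss < best[0]:
                best = (rss, res.x, bool(res.success))
            # deterministic early stop: repeated starts no longer improve
            if n_stall >= 2 and best[2]:
                break

        if best is None or tss <= 0:
            nan = np.full(M, np.nan)
            return ExpMixtureResults(
                unit_id=self.ac.unit_id, M=M, taus=nan, coeffs=nan,
                bic=np.inf, r_squared=-np.inf, start_lag=self.start_lag,
                rss=np.inf, n_fitted=n, converged=False)

        rss, p, success = best
        c, tau = p[:M], p[M:]
        order = np.argsort(tau)
        tau, c = tau[order], c[order]
        r2 = 1.0 - rss / tss
        k = 2 * M
        bic = n * np.log(max(rss, 1e-300) / n) + k * np.log(n)
        return ExpMixtureResults(
            unit_id=self.ac.unit_id, M=M, taus=tau, coeffs=c, bic=float(bic),
            r_squared=float(r2), start_lag=self.start_lag, rss=rss,
            n_fitted=n, converged=success)

    def fit_select(self, max_components: int = 4) -> ExpMixtureResults:
        """Fit M = 1..max_components and select the best model."""
        fits = [self.fit(M) for M in range(1, max_components + 1)]
        return select_model(fits)


def fit_exp_mixture(ac: Autocorrelogram, M: int, start_lag: int | None = None,
                    **kwargs) -> ExpMixtureResults:
    """Functional wrapper: fit an M-component mixture to ``ac``."""
    return ExpMixtureModel(ac, start_lag=start_lag, **kwargs).fit(M)


def select_model(fits: list[ExpMixtureResults],
                 min_coeff_fraction: float = MIN_COEFF_FRACTION,
                 qc_threshold: float = QC_R2_THRESHOLD) -> ExpMixtureResults:
    """BIC model selection with the minimum-contribution constraint.

    Among converged fits whose components all contribute at least
    ``min_coeff_fraction`` of the total mixing weight, the fit with the
    lowest BIC wins; BIC ties break toward smaller M (parsimony). A fit
    whose best BIC model violates the contribution rule is thus demoted to
    a smaller admissible model. The returned fit carries
    ``qc_pass = (R^2 > qc_threshold)``.
    """
    admissible = [f for f in fits
                  if f.converged and f.satisfies_min_coeff(min_coeff_fraction)]
    if not admissible:
        raise NoConvergedFitError(
            "no converged fit satisfies the minimum-contribution rule")
    admissible.sort(key=lambda f: (f.bic, f.M))
    chosen = admissible[0]
    return replace(chosen, qc_pass=bool(chosen.r_squared > qc_threshold))
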