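"""Convergence diagnostics and posterior summaries.

ESS uses the autocorrelation-time estimator with the initial-positive-
sequence truncation rule; R-hat is the classic potential scale reduction
factor of Gelman & Rubin (between/within chain variances, no rank
normalisation); HPD intervals are the narrowest contiguous interval holding
the requested mass; the multivariate point estimate is the geometric median
computed on per-dimension standardised samples.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .kinetics import MODEL_SPACE

#: convergence rules applied in report flags
ESS_THRESHOLD = 100.0
RHAT_THRESHOLD = 1.1


def effective_sample_size(series) -> float:
    """n / (1 + 2*sum(rho_k)), with the autocorrelation sum truncated at the
    first non-positive pair (rho_{2t} + rho_{2t+1} <= 0)."""
    x = np.asarray(series, dtype=float)
    n = x.size
    if n < 10:
        raise ValueError("series too short for an ESS estimate (need >= 10)")
    x = x - x.mean()
    var = np.dot(x, x) / n
    if var == 0:
        raise ValueError("ESS undefined for a constant series")
    # FFT autocovariance
    m = 1 << (2 * n - 1).bit_length()
    f = np.fft.rfft(x, m)
    acov = np.fft.irfft(f * np.conjugate(f), m)[:n].real / n
    rho = acov / acov[0]
    s = 0.0
    t = 1
    while t + 1 < n:
        pair = rho[t] + rho[t + 1]
        if pair <= 0:
            break
        s += pair
        t += 2
    return float(n / (1.0 + 2.0 * s))


def r_hat(chains: Sequence[Sequence[float]]) -> float:
    """Classic potential-scale-reduction factor over >= 2 equal-length chains."""
    arrays = [np.asarray(c, dtype=float) for c in chains]
    if len(arrays) < 2:
        raise ValueError("R-hat needs at least two chains")
    n = min(a.size for a in arrays)
    if n < 2:
        raise ValueError("chains too short")
    x = np.stack([a[:n] for a in arrays])
    m = x.shape[0]
    chain_means = x.mean(axis=1)
    chain_vars = x.var(axis=1, ddof=1)
    W = chain_vars.mean()
    B = n * chain_means.var(ddof=1)
    if W == 0:
        return math.inf if B > 0 else 1.0
    var_plus = (n - 1) / n * W + B / n
    return float(math.sqrt(var_plus / W))


def hpd_interval(samples, mass: float = 0.95) -> tuple[float, float]:
    """Narrowest contiguous interval containing ceil(mass*n) sorted samples."""
    x = np.sort(np.asarray(samples, dtype=float))
    n = x.size
    if n < 20:
        raise ValueError("need >= 20 samples for an HPD interval")
    k = int(math.ceil(mass * n))
    if k >= n:
        return float(x[0]), float(x[-1])
    widths = x[k - 1 :] - x[: n - k + 1]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + k - 1])


def geometric_median(
    samples, tol: float = 1e-8, max_iter: int = 1000
) -> np.ndarray:
    """Minimiser of the summed Euclidean distances, by Weiszfeld iterative
    reweighting on per-dimension standardised samples (mixed units), with the
    result mapped back to natural units."""
    x = np.atleast_2d(np.asarray(samples, dtype=float))
    if x.shape[0] == 1:
        return x[0].copy()
    scale = x.std(axis=0, ddof=0)
    scale[scale == 0] = 1.0
    loc = x.mean(axis=0)
    z = (x - loc) / scale
    m = np.median(z, axis=0)
    for _ in range(max_iter):
        d = np.linalg.norm(z - m, axis=1)
        if np.any(d < 1e-12):
            # a data point: it is the minimiser if its Weiszfeld residual
            # vanishes; nudging avoids division by zero
            d = np.maximum(d, 1e-12)
        w = 1.0 / d
        new = (z * w[:, None]).sum(axis=0) / w.sum()
        if np.linalg.norm(new - m) <= tol * (1.0 + np.linalg.norm(m)):
            m = new
            break
        m = new
    return loc + scale * m


@dataclass(frozen=True)
class ParameterSummary:
    ess: Optional[float]
    rhat: Optional[float]
    hpd: tuple[float, float]
    converged: bool


@dataclass(frozen=True)
class SummaryReport:
    """Posterior summary conditional on each model in the credible set."""

    model_probabilities: Mapping[int, float]
    credible_set: tuple[int, ...]
    per_model: Mapping[int, Mapping[str, ParameterSummary]]
    point_estimates: Mapping[int, Mapping[str, float]]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for m, params in self.per_model.items():
            for name, s in params.items():
                rows.append(
                    {
                        "model": m,
                        "posterior_probability": self.model_probabilities[m],
                        "parameter": name,
                        "geometric_median": self.point_estimates[m][name],
                        "hpd_low": s.hpd[0],
                        "hpd_high": s.hpd[1],
                        "ess": s.ess,
                        "rhat": s.rhat,
                        "converged": s.converged,
                    }
                )
        return pd.DataFrame(rows)


def summarize(traces, mass: float = 0.95) -> SummaryReport:
    """Table-style posterior report: per-model probabilities and, for each
    model in the credible set, per-active-parameter ESS, R-hat, HPD interval
    and the joint geometric-median point estimate."""
    from .inference import credible_set as _credible_set
    from .inference import combine_traces, posterior_model_probabilities

    probs = posterior_model_probabilities(traces)
    cset = tuple(_credible_set(traces, mass))
    df = combine_traces(traces)
    per_model: dict[int, dict[str, ParameterSummary]] = {}
    medians: dict[int, dict[str, float]] = {}
    for m in cset:
        sub = df[df["model"] == m]
        active = MODEL_SPACE[m].active_parameters
        gm = geometric_median(sub[list(active)].to_numpy())
        medians[m] = dict(zip(active, map(float, gm)))
        per_model[m] = {}
        for name in active:
            series = sub[name].to_numpy()
            per_chain = [
                g[name].to_numpy() for _, g in sub.groupby("chain") if len(g) >= 2
            ]
            try:
                ess = effective_sample_size(series)
            except ValueError:
                ess = None
            try:
                rh = r_hat(per_chain) if len(per_chain) >= 2 else None
            except ValueError:
                rh = None
            hpd = hpd_interval(series, mass)
            converged = (
                ess is not None
                and ess > ESS_THRESHOLD
                and rh is not None
                and rh < RHAT_THRESHOLD
            )
            per_model[m][name] = ParameterSummary(ess, rh, hpd, converged)
    return SummaryReport(probs, cset, per_model, medians)
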