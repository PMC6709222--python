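"""Bisection psychometrics: cumulative-Gumbel fits, BP / DL / CV, bootstrap CIs.

The psychometric function is a cumulative Gumbel (extreme-value) CDF applied
to the natural log of duration,

    psi(d) = gamma + (1 - gamma - lambda) * G(ln d),
    G(x)   = 1 - exp(-exp((x - alpha) / beta)),

so that with gamma = lambda = 0 the fit is exactly a binomial regression
with a complementary log-log link on ln d.  The log abscissa makes the model
scale-invariant and reflects the log spacing of the stimulus set.  From the
fitted curve we report the bisection point BP = psi^{-1}(0.5), the
difference limen DL = (psi^{-1}(0.75) - psi^{-1}(0.25)) / 2, and the
coefficient of variation CV = DL / BP.  Confidence intervals come from a
parametric bootstrap (resampling binomial counts from the fitted curve,
1999 replicates by default) with bias-corrected percentile endpoints.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import norm

__all__ = [
    "PsychometricFit", "fit_psychometric", "threshold", "bp_dl_cv",
    "bootstrap_ci", "chronometric", "psi",
]


@dataclass
class PsychometricFit:
    alpha: float                  # Gumbel location on ln-duration
    beta: float                   # Gumbel scale on ln-duration
    gamma: float = 0.0            # lower asymptote (guess rate)
    lambda_: float = 0.0          # lapse rate
    bp_ms: float = np.nan
    dl_ms: float = np.nan
    cv: float = np.nan
    ci: dict = field(default_factory=dict)
    n_boot: int = 0
    converged: bool = True


def _gumbel_cdf(x, alpha, beta):
    return 1.0 - np.exp(-np.exp((x - alpha) / beta))


def psi(durations_ms, fit: PsychometricFit):
    """Probability of a "long" response at each duration under the fit."""
    x = np.log(np.asarray(durations_ms, float))
    return fit.gamma + (1.0 - fit.gamma - fit.lambda_) * _gumbel_cdf(x, fit.alpha, fit.beta)


def threshold(fit: PsychometricFit, p: float) -> float:
    """Duration (ms) at which psi equals p; closed-form inversion of the Gumbel.

    p must lie strictly between the asymptotes (gamma, 1 - lambda).
    """
    if not (fit.gamma < p < 1.0 - fit.lambda_):
        raise ValueError(f"p={p} outside reachable range "
                         f"({fit.gamma}, {1.0 - fit.lambda_})")
    p_corr = (p - fit.gamma) / (1.0 - fit.gamma - fit.lambda_)
    with np.errstate(over="ignore"):  # diverging beta -> inf threshold, handled upstream
        return float(np.exp(fit.alpha + fit.beta * np.log(-np.log(1.0 - p_corr))))


def bp_dl_cv(fit: PsychometricFit) -> tuple[float, float, float]:
    """Bisection point, difference limen and coefficient of variation."""
    if not fit.converged or not np.isfinite(fit.beta):
        warnings.warn("bp_dl_cv on unconverged fit: propagating NaN")
        return (np.nan, np.nan, np.nan)
    bp = threshold(fit, 0.5)
    dl = 0.5 * (threshold(fit, 0.75) - threshold(fit, 0.25))
    return (bp, dl, dl / bp)


# ---------------------------------------------------------------------------
# fitting

def _cloglog_irls_batch(x: np.ndarray, k: np.ndarray, n: np.ndarray,
                        max_iter: int = 100, tol: float = 1e-10):
    """Batched ML fit of the binomial cloglog model mu = 1-exp(-exp(b0 + b1 x)).

    ``k`` may be (m,) or (B, m) for B response vectors sharing the design;
    returns (b0, b1, converged) each of shape (B,) (or scalars for 1-D k).
    Newton-Raphson on the 2-parameter log-likelihood, vectorized over B.
    """
    x = np.asarray(x, float)
    k2 = np.atleast_2d(np.asarray(k, float))
    n2 = np.atleast_2d(np.asarray(n, float)) * np.ones_like(k2)
    B, m = k2.shape
    xc = x - x.mean()  # centred abscissa: near-orthogonal parametrization

    def loglik(b0, b1):
        eta = np.clip(b0[:, None] + b1[:, None] * xc, -30.0, 30.0)
        mu = np.clip(-np.expm1(-np.exp(eta)), 1e-12, 1.0 - 1e-12)
        return (k2 * np.log(mu) + (n2 - k2) * np.log1p(-mu)).sum(1)

    # start: least squares on the cloglog of shrunk empirical proportions
    p_emp = np.clip((k2 + 0.5) / (n2 + 1.0), 1e-4, 1 - 1e-4)
    zt = np.log(-np.log(1.0 - p_emp))
    sxx = np.sum(xc**2)
    b1 = zt @ xc / sxx
    b0 = zt.mean(1)
    b1 = np.clip(b1, 0.05, 50.0)
    ll = loglik(b0, b1)
    g0 = g1 = np.zeros(B)
    for _ in range(max_iter):
        eta = np.clip(b0[:, None] + b1[:, None] * xc, -30.0, 30.0)
        ee = np.exp(eta)
        mu = np.clip(-np.expm1(-ee), 1e-12, 1.0 - 1e-12)
        dmu = np.exp(eta - ee)                    # d mu / d eta
        r = (k2 - n2 * mu) * dmu / (mu * (1.0 - mu))      # score weights
        w = n2 * dmu**2 / (mu * (1.0 - mu))               # Fisher weights
        g0 = r.sum(1)
        g1 = (r * xc).sum(1)
        h00 = w.sum(1)
        h01 = (w * xc).sum(1)
        h11 = (w * xc * xc).sum(1)
        det = h00 * h11 - h01**2
        safe = np.abs(det) > 1e-300
        d0 = np.where(safe, (h11 * g0 - h01 * g1) / np.where(safe, det, 1.0), 0.0)
        d1 = np.where(safe, (h00 * g1 - h01 * g0) / np.where(safe, det, 1.0), 0.0)
        # damped step: halve per element until the likelihood does not drop
        scale = np.ones(B)
        for _half in range(12):
            b0n = b0 + scale * d0
            b1n = b1 + scale * d1
            lln = loglik(b0n, b1n)
            bad = ~(lln >= ll - 1e-9)
            if not bad.any():
                break
            scale[bad] *= 0.5
        b0, b1, ll = b0n, b1n, lln
        if np.max(np.abs(np.column_stack([scale * d0, scale * d1]))) < tol:
            break
    grad_norm = np.hypot(g0, g1)
    ok = np.isfinite(b0) & np.isfinite(b1) & (grad_norm < 1e-4 * (1 + n2.sum(1)))
    # slope must be positive and sane for an identifiable threshold
    ok &= (b1 > 1e-3) & (b1 < 1e3)
    b0 = b0 - b1 * x.mean()  # back to the uncentred parametrization
    if np.asarray(k).ndim == 1:
        return float(b0[0]), float(b1[0]), bool(ok[0])
    return b0, b1, ok


def _neg_loglik_lapse(params, x, k, n):
    alpha, beta, gamma, lam = params
    if beta <= 0 or gamma < 0 or lam < 0 or gamma + lam >= 1:
        return 1e12
    mu = gamma + (1 - gamma - lam) * _gumbel_cdf(x, alpha, beta)
    mu = np.clip(mu, 1e-12, 1 - 1e-12)
    return -np.sum(k * np.log(mu) + (n - k) * np.log1p(-mu))


def fit_psychometric(durations_ms, n_long, n_total,
                     lapse_mode: str = "fixed0") -> PsychometricFit:
    """Maximum-likelihood cumulative-Gumbel fit to (duration, #long, #total) data.

    lapse_mode "fixed0" fixes gamma = lambda = 0 (a cloglog binomial
    regression on ln d); "estimate" estimates both asymptotes bounded at
    0.05, via multi-start local optimization over a coarse (alpha, beta)
    grid.  Non-identifiable data (all-short, all-long, or flat) yield
    ``converged=False`` with NaN thresholds rather than raising.
    """
    d = np.asarray(durations_ms, float)
    k = np.asarray(n_long, float)
    n = np.asarray(n_total, float)
    if len(np.unique(d)) < 3:
        raise ValueError("need at least 3 distinct durations")
    if np.any(k > n) or np.any(k < 0):
        raise ValueError("need 0 <= n_long <= n_total elementwise")
    x = np.log(d)

    if lapse_mode == "fixed0":
        b0, b1, ok = _cloglog_irls_batch(x, k, n)
        alpha, beta = (-b0 / b1, 1.0 / b1) if ok else (np.nan, np.nan)
        fit = PsychometricFit(alpha=alpha, beta=beta, converged=ok)
    elif lapse_mode == "estimate":
        b0, b1, ok = _cloglog_irls_batch(x, k, n)
        if ok:
            starts = [(-b0 / b1, 1.0 / b1)]
        else:
            starts = []
        mid = np.median(x)
        starts += [(a, b) for a in (mid - 0.3, mid, mid + 0.3) for b in (0.1, 0.3, 0.6)]
        best, best_f = None, np.inf
        for a0, be0 in starts:
            res = minimize(_neg_loglik_lapse, [a0, be0, 0.01, 0.01], args=(x, k, n),
                           method="Nelder-Mead",
                           options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 4000})
            f = res.fun
            # tie-break: highest likelihood then smallest beta
            if f < best_f - 1e-9 or (abs(f - best_f) <= 1e-9 and best is not None
                                     and res.x[1] < best[1]):
                best, best_f = res.x, f
        a, b, g, l = best
        g, l = min(max(g, 0.0), 0.05), min(max(l, 0.0), 0.05)
        ok = np.isfinite(best_f) and 0 < b < 1e3
        fit = PsychometricFit(alpha=a, beta=b, gamma=g, lambda_=l, converged=bool(ok))
    else:
        raise ValueError(f"unknown lapse_mode {lapse_mode!r}")

    if fit.converged:
        bp, dl, cv = bp_dl_cv(fit)
        if not (d.min() * 0.25 <= bp <= d.max() * 4):
            fit.converged = False
            bp = dl = cv = np.nan
        fit.bp_ms, fit.dl_ms, fit.cv = bp, dl, cv
    return fit


# ---------------------------------------------------------------------------
# bootstrap

def _bc_interval(theta_boot: np.ndarray, theta_hat: float, level: float = 0.95):
    """Bias-corrected percentile interval from bootstrap replicates."""
    tb = theta_boot[np.isfinite(theta_boot)]
    if len(tb) == 0:
        return (np.nan, np.nan)
    prop = np.mean(tb < theta_hat)
    prop = min(max(prop, 1.0 / (len(tb) + 1)), 1 - 1.0 / (len(tb) + 1))
    z0 = norm.ppf(prop)
    zc = norm.ppf(0.5 + level / 2)
    lo = norm.cdf(2 * z0 - zc)
    hi = norm.cdf(2 * z0 + zc)
    return (float(np.quantile(tb, lo)), float(np.quantile(tb, hi)))


def bootstrap_ci(durations_ms, n_long, n_total, n_boot: int = 1999,
                 seed: int = 0, level: float = 0.95) -> PsychometricFit:
    """Point fit plus bias-corrected parametric-bootstrap intervals for BP/DL/CV.

    Binomial counts are resampled from the fitted curve, each replicate is
    refit (batched), and bias-corrected percentile intervals are attached to
    the returned fit.  Deterministic given ``seed``.
    """
    d = np.asarray(durations_ms, float)
    n = np.asarray(n_total, float)
    fit = fit_psychometric(d, n_long, n, lapse_mode="fixed0")
    if not fit.converged:
        warnings.warn("bootstrap_ci: point fit unconverged; no intervals computed")
        return fit
    rng = np.random.default_rng(seed)
    p_hat = psi(d, fit)
    k_boot = rng.binomial(n.astype(np.int64), p_hat, size=(n_boot, len(d)))
    b0, b1, ok = _cloglog_irls_batch(np.log(d), k_boot, n)
    n_bad = int((~ok).sum())
    if n_bad > 0.2 * n_boot:
        warnings.warn(f"bootstrap_ci: {n_bad}/{n_boot} replicates unconverged")
    alpha_b = np.where(ok, -b0 / b1, np.nan)
    beta_b = np.where(ok, 1.0 / b1, np.nan)
    ln2 = np.log(np.log(2.0))
    bp_b = np.exp(alpha_b + beta_b * ln2)
    hi_b = np.exp(alpha_b + beta_b * np.log(-np.log(0.25)))
    lo_b = np.exp(alpha_b + beta_b * np.log(-np.log(0.75)))
    dl_b = 0.5 * (hi_b - lo_b)
    cv_b = dl_b / bp_b
    fit.ci = {
        "bp_ms": _bc_interval(bp_b, fit.bp_ms, level),
        "dl_ms": _bc_interval(dl_b, fit.dl_ms, level),
        "cv": _bc_interval(cv_b, fit.cv, level),
    }
    fit.n_boot = n_boot
    return fit


# ---------------------------------------------------------------------------
# chronometric summary

def chronometric(trials: pd.DataFrame) -> pd.DataFrame:
    """Per-duration mean and SE of reaction time for bisection trials.

    Missing RTs are excluded; the per-cell count of excluded trials is
    reported.  Single-trial cells report SE = NaN; empty cells yield a NaN
    row with a warning.
    """
    df = trials.copy()
    out = []
    for dur, g in df.groupby("duration_ms", sort=True):
        rt = g["rt_ms"].astype(float)
        valid = rt.dropna()
        if len(valid) == 0:
            warnings.warn(f"chronometric: no valid RTs for duration {dur}")
            out.append({"duration_ms": dur, "mean_rt_ms": np.nan, "se_rt_ms": np.nan,
                        "n": 0, "n_missing": len(rt)})
            continue
        se = np.nan if len(valid) < 2 else valid.std(ddof=1) / np.sqrt(len(valid))
        out.append({"duration_ms": dur, "mean_rt_ms": valid.mean(), "se_rt_ms": se,
                    "n": len(valid), "n_missing": int(rt.isna().sum())})
    return pd.DataFrame(out)
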