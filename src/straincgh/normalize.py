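"""Background correction and within-array normalization.

Net spot intensity X = fg - bg is modeled as X = B + S with
B ~ Normal(mu, sigma^2) machine background and S ~ Exponential(mean alpha)
true hybridization signal. The corrected intensity is the posterior mean
E[S | X = x] plus a fixed offset (default 50), which is strictly positive
and strictly increasing in x, so log-ratios are always defined.

The density of the convolution is

    f(x) = (1/alpha) exp((mu - x)/alpha + sigma^2/(2 alpha^2))
           * Phi((x - mu - sigma^2/alpha) / sigma)

and S | X = x is a Normal(x - mu - sigma^2/alpha, sigma^2) truncated to
(0, inf), giving the closed-form posterior mean used here. Everything is
evaluated in the log domain (scipy.special.log_ndtr) so extreme nets
neither overflow nor lose the Mills-ratio tail.

Intensity-dependent dye/spatial bias is then removed per print-tip group by
robust local linear regression (loess) of M on A.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize, minimize_scalar
from scipy.special import log_ndtr
from scipy.stats import median_abs_deviation
from statsmodels.nonparametric.smoothers_lowess import lowess

from ._utils import EstimationError
from .io import ArrayScan

_LOG_SQRT_2PI = 0.5 * math.log(2.0 * math.pi)

DEFAULT_OFFSET = 50.0


@dataclass(frozen=True)
class NormexpParams:
    """Convolution parameters: Normal(mu, sigma^2) background + Exp(mean alpha) signal."""

    mu: float
    sigma: float
    alpha: float

    def __post_init__(self) -> None:
        if not (self.sigma > 0 and self.alpha > 0):
            raise ValueError("sigma and alpha must be > 0")


@dataclass
class MAValues:
    """Per-spot M (log2 ratio), A (mean log2 intensity) and print-tip group."""

    values: pd.DataFrame  # columns M, A, tip_group; index = probe_id

    def __post_init__(self) -> None:
        missing = [c for c in ("M", "A", "tip_group") if c not in self.values.columns]
        if missing:
            raise ValueError(f"MAValues missing columns {missing}")


def normexp_loglik(net: np.ndarray, mu: float, sigma: float, alpha: float) -> float:
    """Total log-likelihood of the normal+exponential convolution."""
    x = np.asarray(net, dtype=float)
    z = (x - mu - sigma**2 / alpha) / sigma
    return float(
        np.sum(-math.log(alpha) + (mu - x) / alpha + sigma**2 / (2 * alpha**2) + log_ndtr(z))
    )


def normexp_fit(net, min_n: int = 50) -> NormexpParams:
    """Maximum-likelihood fit of (mu, sigma, alpha) to net intensities.

    Starts from method-of-moments values (mean/variance/third moment of the
    convolution) and refines by Nelder-Mead on (mu, log sigma, log alpha).
    """
    x = np.asarray(net, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < min_n:
        raise EstimationError(f"need at least {min_n} values to fit normexp, got {x.size}")
    sd = float(np.std(x))
    if sd == 0.0:
        raise EstimationError("all net intensities identical; cannot fit normexp")

    m1 = float(np.mean(x))
    v = sd**2
    m3 = float(np.mean((x - m1) ** 3))
    alpha0 = max((m3 / 2.0) ** (1.0 / 3.0) if m3 > 0 else sd / 2.0, sd / 100.0)
    sigma0 = math.sqrt(max(v - alpha0**2, (sd / 100.0) ** 2))
    mu0 = m1 - alpha0

    def nll(theta):
        mu, log_sigma, log_alpha = theta
        if abs(log_sigma) > 50 or abs(log_alpha) > 50:
            return 1e300
        return -normexp_loglik(x, mu, math.exp(log_sigma), math.exp(log_alpha))

    res = minimize(
        nll,
        x0=np.array([mu0, math.log(sigma0), math.log(alpha0)]),
        method="Nelder-Mead",
        options={"maxiter": 3000, "xatol": 1e-6, "fatol": 1e-8},
    )
    mu, log_sigma, log_alpha = res.x
    return NormexpParams(mu=float(mu), sigma=float(math.exp(log_sigma)),
                         alpha=float(math.exp(log_alpha)))


def normexp_fit_anchored(net, bg, min_n: int = 50) -> NormexpParams:
    """Normexp fit anchored on the measured spot backgrounds.

    The full three-parameter MLE degenerates on bright-dominated arrays
    (a strain carrying nearly every probe): the normal component migrates
    onto the signal bump and the correction then wipes out true signal.
    Net intensity fg - bg has a zero-mean background residual by
    construction, and the scanner's background columns measure the
    background process directly, so here mu is pinned at 0, sigma is the
    robust (MAD) spread of the backgrounds scaled by sqrt(2) for the
    difference of two draws, and only the signal mean alpha is fit by ML.
    """
    x = np.asarray(net, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < min_n:
        raise EstimationError(f"need at least {min_n} values to fit normexp, got {x.size}")
    b = np.asarray(bg, dtype=float)
    sigma = max(math.sqrt(2.0) * median_abs_deviation(b, scale="normal"), 1e-3)
    scale = max(float(np.mean(np.abs(x))), sigma)

    res = minimize_scalar(
        lambda log_alpha: -normexp_loglik(x, 0.0, sigma, math.exp(log_alpha)),
        bounds=(math.log(scale) - 8, math.log(scale) + 8),
        method="bounded",
        options={"xatol": 1e-8},
    )
    return NormexpParams(mu=0.0, sigma=sigma, alpha=float(math.exp(res.x)))


def normexp_posterior_mean(net, params: NormexpParams) -> np.ndarray:
    """E[S | X = net] under the convolution model (vectorized, log-domain)."""
    x = np.asarray(net, dtype=float)
    m = x - params.mu - params.sigma**2 / params.alpha
    z = m / params.sigma
    log_phi = -0.5 * z**2 - _LOG_SQRT_2PI
    # Mills-type ratio phi(z)/Phi(z); log_ndtr keeps the far-left tail exact.
    ratio = np.exp(log_phi - log_ndtr(z))
    return m + params.sigma * ratio


def normexp_correct(net, params: NormexpParams, offset: float = DEFAULT_OFFSET) -> np.ndarray:
    """Background-corrected intensity: posterior-mean signal plus offset."""
    return normexp_posterior_mean(net, params) + offset


def correct_scan(
    scan: ArrayScan, offset: float = DEFAULT_OFFSET, method: str = "anchored"
) -> tuple[ArrayScan, dict[str, NormexpParams]]:
    """Fit normexp to each channel's net intensities (non-flagged spots) and
    add corrected columns ``corr_test`` / ``corr_ref`` to a copy of the scan.

    ``method`` is "anchored" (default; background-anchored fit, robust on
    arrays where nearly every probe hybridizes) or "mle" (full
    three-parameter maximum likelihood).
    """
    good = scan.good()
    if method == "anchored":
        def fit(ch):
            return normexp_fit_anchored(
                good[f"fg_{ch}"].to_numpy() - good[f"bg_{ch}"].to_numpy(),
                good[f"bg_{ch}"].to_numpy(),
            )
    elif method == "mle":
        def fit(ch):
            return normexp_fit(good[f"fg_{ch}"].to_numpy() - good[f"bg_{ch}"].to_numpy())
    else:
        raise ValueError(f"unknown correction method {method!r}")
    params = {"test": fit("test"), "ref": fit("ref")}
    spots = scan.spots.copy()
    spots["corr_test"] = normexp_correct(
        spots["fg_test"].to_numpy() - spots["bg_test"].to_numpy(), params["test"], offset
    )
    spots["corr_ref"] = normexp_correct(
        spots["fg_ref"].to_numpy() - spots["bg_ref"].to_numpy(), params["ref"], offset
    )
    return ArrayScan(strain_id=scan.strain_id, spots=spots), params


def ma_values(scan: ArrayScan) -> MAValues:
    """M/A transform of the corrected channels, non-flagged spots only."""
    if "corr_test" not in scan.spots.columns:
        raise ValueError("scan is not background-corrected; run correct_scan first")
    good = scan.good()
    ct = np.log2(good["corr_test"].to_numpy())
    cr = np.log2(good["corr_ref"].to_numpy())
    df = pd.DataFrame(
        {"M": ct - cr, "A": 0.5 * (ct + cr), "tip_group": good["block"].to_numpy()},
        index=pd.Index(good["probe_id"], name="probe_id"),
    )
    return MAValues(values=df)


def printtip_loess(
    ma: MAValues, span: float = 0.3, iterations: int = 4, min_group: int = 10
) -> MAValues:
    """Center M on A within each print-tip group by robust loess.

    Each tip group's M is replaced by M - c(A) where c is a tricube-weighted
    local linear fit with ``iterations`` robustifying reweights. Groups
    smaller than ``min_group`` fall back to the whole-array fit. A and the
    per-group spot count are preserved exactly.
    """
    df = ma.values
    if df.empty:
        raise EstimationError("no spots to normalize")
    out = df.copy()
    whole_fit = None

    def fit(sub: pd.DataFrame) -> np.ndarray:
        return lowess(
            sub["M"].to_numpy(),
            sub["A"].to_numpy(),
            frac=span,
            it=iterations,
            return_sorted=False,
        )

    for _, idx in df.groupby("tip_group").groups.items():
        sub = df.loc[idx]
        if len(sub) >= min_group:
            trend = fit(sub)
        else:
            if whole_fit is None:
                whole_fit = pd.Series(fit(df), index=df.index)
            trend = whole_fit.loc[idx].to_numpy()
        out.loc[idx, "M"] = sub["M"].to_numpy() - trend
    return MAValues(values=out)
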