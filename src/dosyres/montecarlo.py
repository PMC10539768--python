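"""Monte Carlo verification of the CRLB, noise titration, and SNR_lim fits.

The Monte Carlo route mirrors the analytical one: build an attenuation table
``exp(-eps_i)``, repeatedly add Gaussian noise of standard deviation
``S0/(2 SNR)``, fit each realization to ``alpha exp(-beta eps_i)`` by
nonlinear least squares in the amplitude domain, and measure the ensemble
standard deviation of beta.  With the schedule expressed in exponent units
the true beta is 1, so the diffusion resolution is

    R_D = 1 / sd(beta)

over the replicate ensemble, directly comparable with the CRLB value.

Noise titration takes a single measured (or simulated) decay, adds
successively larger amounts of synthetic Gaussian noise, refits, and
averages ``R_D = beta/sigma_beta`` over many additions per noise level,
mapping out R_D versus SNR.  Fitting the effective-SNR model to such a
titration extracts the ceiling SNR_lim imposed by non-noise error sources.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
from scipy.optimize import curve_fit

from .resolution import (
    FitConvergenceError,
    FShapeParams,
    crlb_resolution,
    effective_snr,
    f_approx,
)
from .sampling import EpsilonSchedule

__all__ = [
    "DecayCurve",
    "ExpFitResult",
    "MCResolution",
    "TitrationResult",
    "SnrLimEstimate",
    "simulate_decay",
    "fit_exponential",
    "mc_resolution",
    "titrate_noise",
    "simulate_titration_from_model",
    "fit_snr_lim",
]

#: Convergence settings for the exponential fits.
_XTOL = 1e-10
_MAX_ITER = 200


@dataclass
class DecayCurve:
    """A single sampled decay: amplitudes S_i at exponents eps_i.

    ``snr`` is the peak signal-to-noise ratio S0/(2 sigma_S); ``sigma_s`` the
    amplitude noise standard deviation.  Either may be omitted, but when both
    are set they must be mutually consistent with ``s0``.
    """

    epsilons: np.ndarray
    amplitudes: np.ndarray
    s0: float = 1.0
    sigma_s: Optional[float] = None
    snr: Optional[float] = None

    def __post_init__(self) -> None:
        self.epsilons = np.asarray(self.epsilons, dtype=float)
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if self.epsilons.shape != self.amplitudes.shape or self.epsilons.ndim != 1:
            raise ValueError("epsilons and amplitudes must be matching 1-D arrays")
        if self.sigma_s is not None and self.sigma_s < 0:
            raise ValueError("sigma_s must be non-negative")
        if self.sigma_s is None and self.snr is not None and math.isfinite(self.snr):
            self.sigma_s = self.s0 / (2.0 * self.snr)
        elif self.snr is None and self.sigma_s is not None and self.sigma_s > 0:
            self.snr = self.s0 / (2.0 * self.sigma_s)
        elif self.snr is not None and self.sigma_s is not None and math.isfinite(self.snr):
            if not math.isclose(self.sigma_s, self.s0 / (2.0 * self.snr), rel_tol=1e-6):
                raise ValueError("snr and sigma_s are inconsistent with s0")


@dataclass(frozen=True)
class ExpFitResult:
    """Two-parameter exponential fit alpha exp(-beta eps) with standard errors."""

    alpha: float
    beta: float
    sigma_alpha: float
    sigma_beta: float
    covariance: np.ndarray
    r_d: float  # beta/sigma_beta, the D/sigma_D analogue


@dataclass(frozen=True)
class MCResolution:
    """Monte Carlo resolution estimate for a sampling scheme."""

    r_d: float  # 1 / ensemble sd(beta)
    r_d_err: float  # bootstrap standard error of r_d
    mean_sigma_beta: float  # mean per-fit standard error, for diagnostics
    n_reps: int
    n_failures: int


@dataclass
class TitrationResult:
    """R_D versus SNR from noise titration of a single decay."""

    snr_levels: np.ndarray
    mean_r_d: np.ndarray
    n_additions: int
    sd_r_d: Optional[np.ndarray] = None  # per-level sd of the per-addition R_D

    def __post_init__(self) -> None:
        self.snr_levels = np.asarray(self.snr_levels, dtype=float)
        self.mean_r_d = np.asarray(self.mean_r_d, dtype=float)
        if self.snr_levels.shape != self.mean_r_d.shape:
            raise ValueError("snr_levels and mean_r_d must match")
        if self.n_additions < 1:
            raise ValueError("n_additions must be >= 1")
        if np.any(self.snr_levels <= 0):
            raise ValueError("snr levels must be positive")


@dataclass(frozen=True)
class SnrLimEstimate:
    value: float
    stderr: float


def _child_rngs(seed: int, n: int) -> list:
    """Deterministic per-replicate substreams: replicate i is identical no
    matter how many replicates are requested in total."""
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def simulate_decay(
    schedule: Union[EpsilonSchedule, Sequence[float]],
    snr: float,
    s0: float = 1.0,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    snr_lim: float = math.inf,
) -> DecayCurve:
    """Simulate one noisy decay ``S_i = s0 exp(-eps_i) + n_i``.

    The noise is Gaussian with standard deviation ``s0/(2 snr)``;
    ``snr = inf`` gives the noiseless table.  A finite ``snr_lim`` adds a
    second, independent Gaussian error of standard deviation
    ``s0/(2 snr_lim)`` emulating non-noise error sources at their
    effective-SNR ceiling.
    """
    eps = schedule.epsilons if isinstance(schedule, EpsilonSchedule) else np.asarray(schedule, float)
    if snr <= 0:
        raise ValueError("snr must be positive (use inf for noiseless)")
    clean = s0 * np.exp(-eps)
    var = 0.0
    if math.isfinite(snr):
        var += (s0 / (2.0 * snr)) ** 2
    if math.isfinite(snr_lim):
        var += (s0 / (2.0 * snr_lim)) ** 2
    if var > 0:
        if rng is None:
            rng = np.random.default_rng(seed)
        amps = clean + rng.normal(0.0, math.sqrt(var), size=eps.size)
    else:
        amps = clean.copy()
    # the curve is labelled with its *noise* SNR; a finite snr_lim is an
    # amplitude imperfection riding on the signal, not part of the noise
    return DecayCurve(
        epsilons=eps,
        amplitudes=amps,
        s0=s0,
        sigma_s=s0 / (2.0 * snr) if math.isfinite(snr) else 0.0,
        snr=snr if math.isfinite(snr) else None,
    )


def _initial_guess(eps: np.ndarray, S: np.ndarray, sigma: Optional[float]) -> tuple:
    """Weighted log-linear start restricted to points clearly above the noise."""
    if sigma is not None and sigma > 0:
        mask = S > 3.0 * sigma
    else:
        mask = S > 0
    if mask.sum() < 3:
        return float(np.max(S)), 1.0
    x, y = eps[mask], S[mask]
    # weights ~ y: relative error of log y is sigma/y
    coef = np.polyfit(x, np.log(y), 1, w=y)
    return float(np.exp(coef[1])), float(-coef[0])


def fit_exponential(curve: DecayCurve) -> ExpFitResult:
    """Nonlinear least squares of S_i = alpha exp(-beta eps_i).

    The fit is done in the amplitude domain (never log-transformed), so
    noisy points that dip negative are handled naturally.  Standard errors
    come from the residual-scaled covariance at the optimum.
    """
    eps, S = curve.epsilons, curve.amplitudes
    if eps.size < 3:
        raise ValueError("need at least 3 points for a two-parameter fit")
    if np.unique(eps).size != eps.size:
        raise ValueError("epsilon values must be distinct")
    p0 = _initial_guess(eps, S, curve.sigma_s)
    model = lambda x, a, b: a * np.exp(-b * x)
    try:
        popt, pcov = curve_fit(model, eps, S, p0=p0, xtol=_XTOL, maxfev=50 * _MAX_ITER)
    except RuntimeError as exc:
        raise FitConvergenceError(f"exponential fit did not converge: {exc}", p0=p0) from exc
    alpha, beta = float(popt[0]), float(popt[1])
    with np.errstate(invalid="ignore"):
        sig = np.sqrt(np.diag(pcov))
    sigma_alpha, sigma_beta = float(sig[0]), float(sig[1])
    if not math.isfinite(sigma_beta):  # zero-residual (noiseless) fit
        sigma_beta = 0.0
        sigma_alpha = 0.0
    r_d = beta / sigma_beta if sigma_beta > 0 else (math.inf if beta > 0 else 0.0)
    if beta <= 0:
        r_d = 0.0
    return ExpFitResult(
        alpha=alpha,
        beta=beta,
        sigma_alpha=sigma_alpha,
        sigma_beta=sigma_beta,
        covariance=np.asarray(pcov),
        r_d=r_d,
    )


def _batch_fit_exponential(
    eps: np.ndarray, S: np.ndarray, sigma: Optional[float]
) -> tuple:
    """Vectorized Gauss-Newton fit of alpha exp(-beta eps) across replicates.

    ``S`` has shape (R, N).  Returns (alpha, beta, sigma_beta, converged)
    arrays of length R.  Matches :func:`fit_exponential` to solver tolerance;
    it exists so that ensemble sizes of 1e4-1e5 replicates stay cheap.
    """
    R, N = S.shape
    # log-linear start per replicate, on points above the noise floor
    thresh = 3.0 * sigma if sigma else 0.0
    mask = S > max(thresh, 0.0)
    enough = mask.sum(axis=1) >= 3
    alpha = np.max(S, axis=1)
    beta = np.ones(R)
    if enough.any():
        w = np.where(mask, np.maximum(S, 1e-300), 0.0)
        logy = np.where(mask, np.log(np.maximum(S, 1e-300)), 0.0)
        w2 = w * w
        sw = w2.sum(axis=1)
        sx = (w2 * eps).sum(axis=1)
        sy = (w2 * logy).sum(axis=1)
        sxx = (w2 * eps**2).sum(axis=1)
        sxy = (w2 * eps * logy).sum(axis=1)
        det = sw * sxx - sx**2
        ok = enough & (det > 0)
        slope = np.where(ok, (sw * sxy - sx * sy) / np.where(det > 0, det, 1.0), -1.0)
        inter = np.where(ok, (sxx * sy - sx * sxy) / np.where(det > 0, det, 1.0), 0.0)
        beta = np.where(ok, -slope, beta)
        alpha = np.where(ok, np.exp(inter), alpha)
    converged = np.zeros(R, dtype=bool)
    ssr = None
    for _ in range(_MAX_ITER):
        E = np.exp(-np.outer(beta, eps))  # (R, N)
        model = alpha[:, None] * E
        r = S - model
        ssr = (r * r).sum(axis=1)
        # Jacobian columns: d/dalpha = E, d/dbeta = -alpha eps E
        J1 = E
        J2 = -alpha[:, None] * eps * E
        a11 = (J1 * J1).sum(axis=1)
        a12 = (J1 * J2).sum(axis=1)
        a22 = (J2 * J2).sum(axis=1)
        g1 = (J1 * r).sum(axis=1)
        g2 = (J2 * r).sum(axis=1)
        det = a11 * a22 - a12 * a12
        det = np.where(det > 1e-300, det, 1e-300)
        da = (a22 * g1 - a12 * g2) / det
        db = (a11 * g2 - a12 * g1) / det
        # step halving where the step would increase SSR
        step = np.ones(R)
        for _half in range(20):
            na = alpha + step * da
            nb = beta + step * db
            nssr = ((S - na[:, None] * np.exp(-np.outer(nb, eps))) ** 2).sum(axis=1)
            worse = nssr > ssr * (1 + 1e-14)
            if not worse.any():
                break
            step = np.where(worse, step * 0.5, step)
        alpha = alpha + step * da
        beta = beta + step * db
        rel = np.abs(step * db) / np.maximum(np.abs(beta), 1e-300)
        rel_a = np.abs(step * da) / np.maximum(np.abs(alpha), 1e-300)
        converged |= (rel < _XTOL) & (rel_a < _XTOL)
        if converged.all():
            break
    # per-fit standard error of beta from the residual-scaled covariance
    E = np.exp(-np.outer(beta, eps))
    r = S - alpha[:, None] * E
    ssr = (r * r).sum(axis=1)
    J2 = -alpha[:, None] * eps * E
    a11 = (E * E).sum(axis=1)
    a12 = (E * J2).sum(axis=1)
    a22 = (J2 * J2).sum(axis=1)
    det = np.maximum(a11 * a22 - a12 * a12, 1e-300)
    s2 = ssr / max(N - 2, 1)
    sigma_beta = np.sqrt(np.maximum(s2 * a11 / det, 0.0))
    return alpha, beta, sigma_beta, converged


def mc_resolution(
    schedule: Union[EpsilonSchedule, Sequence[float]],
    snr: float,
    n_reps: int = 10_000,
    seed: int = 0,
    n_bootstrap: int = 200,
) -> MCResolution:
    """Monte Carlo diffusion resolution: R_D = 1/sd(beta) over replicates.

    The attenuation table ``exp(-eps_i)`` (true alpha = beta = 1) is
    perturbed with fresh Gaussian noise of standard deviation ``1/(2 snr)``
    per replicate and refitted; the ensemble standard deviation of the
    fitted beta gives R_D, with a bootstrap standard error.  The mean
    per-fit sigma_beta is reported alongside as a diagnostic of the
    covariance-based error estimate.
    """
    if n_reps < 100:
        raise ValueError("need n_reps >= 100")
    eps = schedule.epsilons if isinstance(schedule, EpsilonSchedule) else np.asarray(schedule, float)
    sigma = 1.0 / (2.0 * snr)
    clean = np.exp(-eps)
    rngs = _child_rngs(seed, n_reps)
    S = np.vstack([clean + g.normal(0.0, sigma, size=eps.size) for g in rngs])
    alpha, beta, sigma_beta, converged = _batch_fit_exponential(eps, S, sigma)
    n_fail = int((~converged).sum())
    if n_fail > 0.01 * n_reps:
        raise FitConvergenceError(
            f"{n_fail}/{n_reps} replicate fits failed to converge"
        )
    beta_ok = beta[converged]
    sd = float(np.std(beta_ok, ddof=1))
    r_d = 1.0 / sd
    boot_rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(n_reps + 1)[-1])
    idx = boot_rng.integers(0, beta_ok.size, size=(n_bootstrap, beta_ok.size))
    boot = 1.0 / np.std(beta_ok[idx], axis=1, ddof=1)
    return MCResolution(
        r_d=r_d,
        r_d_err=float(np.std(boot, ddof=1)),
        mean_sigma_beta=float(np.mean(sigma_beta[converged])),
        n_reps=n_reps,
        n_failures=n_fail,
    )


def titrate_noise(
    curve: DecayCurve,
    target_snrs: Sequence[float],
    n_additions: int = 100,
    seed: int = 0,
) -> TitrationResult:
    """Add synthetic noise to a measured decay and map R_D versus SNR.

    For each target SNR below the curve's intrinsic SNR, Gaussian noise of
    variance ``s0^2/4 (1/snr_t^2 - 1/snr_0^2)`` is added so the total noise
    matches the target; the curve is refitted and ``R_D = beta/sigma_beta``
    recorded, averaging ``n_additions`` independent additions per level.
    """
    if curve.snr is None:
        raise ValueError("curve must carry its intrinsic snr")
    targets = np.asarray(target_snrs, dtype=float)
    if np.any(targets > curve.snr * (1 + 1e-9)):
        raise ValueError("target snr cannot exceed the intrinsic snr")
    if n_additions < 1:
        raise ValueError("n_additions must be >= 1")
    eps = curve.epsilons
    mean_rd = np.empty(targets.size)
    sd_rd = np.empty(targets.size)
    rngs = _child_rngs(seed, targets.size)
    for j, (t, rng) in enumerate(zip(targets, rngs)):
        var_add = curve.s0**2 / 4.0 * max(1.0 / t**2 - 1.0 / curve.snr**2, 0.0)
        sigma_tot = curve.s0 / (2.0 * t)
        if var_add == 0.0:
            res = fit_exponential(curve)
            mean_rd[j] = res.r_d
            sd_rd[j] = 0.0
            continue
        noise = rng.normal(0.0, math.sqrt(var_add), size=(n_additions, eps.size))
        S = curve.amplitudes[None, :] + noise
        _, beta, sigma_beta, conv = _batch_fit_exponential(eps, S, sigma_tot)
        rd = np.where(sigma_beta > 0, beta / sigma_beta, 0.0)[conv]
        mean_rd[j] = float(np.mean(rd))
        sd_rd[j] = float(np.std(rd, ddof=1)) if rd.size > 1 else 0.0
    return TitrationResult(
        snr_levels=targets, mean_r_d=mean_rd, n_additions=n_additions, sd_r_d=sd_rd
    )


def simulate_titration_from_model(
    snr_levels: Sequence[float],
    snr_lim: float,
    N: int,
    eps_max: float,
    params: FShapeParams,
    n_additions: int = 100,
    seed: int = 0,
    rel_sd: float = 0.28,
) -> TitrationResult:
    """Synthetic titration drawn around the effective-SNR prediction.

    Per-level mean R_D is ``SNR_eff(snr; snr_lim) sqrt(N-1) f(eps_max)``
    with Gaussian scatter ``rel_sd * value / sqrt(n_additions)``; the
    default ``rel_sd`` is the relative spread of a single-addition
    ``beta/sigma_beta`` at the ~10 residual degrees of freedom typical of a
    12-point decay.  Used for parameter-recovery exercises on
    :func:`fit_snr_lim`.
    """
    levels = np.asarray(snr_levels, dtype=float)
    rng = np.random.default_rng(seed)
    truth = np.array(
        [effective_snr(s, snr_lim) * math.sqrt(N - 1) * f_approx(eps_max, params) for s in levels]
    )
    scatter = rel_sd * truth / math.sqrt(n_additions)
    vals = truth + rng.normal(0.0, 1.0, size=levels.size) * scatter
    return TitrationResult(
        snr_levels=levels, mean_r_d=vals, n_additions=n_additions, sd_r_d=scatter
    )


def fit_snr_lim(
    titration: TitrationResult,
    N: int,
    eps_max: float,
    params: FShapeParams,
) -> SnrLimEstimate:
    """Fit the effective-SNR ceiling to a titration curve.

    The model ``R_D(snr) = snr snr_lim/sqrt(snr_lim^2+snr^2) sqrt(N-1)
    f(eps_max)`` has a single free parameter snr_lim; everything else is
    fixed by the experiment design.  A warning is raised when the fitted
    ceiling lies outside the titrated SNR range (knee not bracketed).
    """
    levels = titration.snr_levels
    if levels.size < 4:
        raise ValueError("need at least 4 SNR levels spanning the knee")
    scale = math.sqrt(N - 1) * f_approx(eps_max, params)

    def model(snr, lim):
        return snr * lim / np.sqrt(lim**2 + snr**2) * scale

    p0 = float(np.exp(np.mean(np.log(levels))))
    popt, pcov = curve_fit(model, levels, titration.mean_r_d, p0=[p0], maxfev=20000)
    lim = float(popt[0])
    stderr = float(np.sqrt(pcov[0, 0]))
    if not (levels.min() <= lim <= levels.max()):
        warnings.warn(
            f"fitted snr_lim={lim:.3g} lies outside the titrated SNR range "
            f"[{levels.min():.3g}, {levels.max():.3g}]; the knee is not bracketed "
            "and the estimate may be unstable"
        )
    return SnrLimEstimate(value=lim, stderr=stderr)
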