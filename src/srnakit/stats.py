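"""Bespoke statistics of the sRNA study.

* Fold-change regression with a random re-pairing null: the log2 fold-change
  of each cis-sRNA's target is regressed on the sRNA's own fold-change, and
  the regression F statistic is compared to a null distribution built by
  randomly re-pairing targets with sRNAs (10,000 iterations by default).
  Re-pairing preserves both marginal distributions while destroying the
  association, so under independence the null F follows F(1, n-2) — its
  median for n around 69 is ~0.45.
* A pooled two-proportion Z-test (used for network-membership fractions).
* Electrophoretic size calibration: a gamma GLM with inverse link
  (mean size = 1 / (b0 + b1 * distance)) fitted to ladder standards by
  iteratively reweighted least squares, with delta-method t-intervals for
  predicted sizes; a parametric-bootstrap interval mode is available.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .errors import ValidationError

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class FoldChangePair:
    srna_id: str
    srna_log2fc: float
    target_locus: str
    target_log2fc: float


@dataclass(frozen=True)
class RegressionResult:
    """One-predictor OLS summary; f is +inf when the fit is exact."""

    n: int
    slope: float
    intercept: float
    r2: float
    f: float

    @property
    def df(self) -> tuple[int, int]:
        return (1, self.n - 2)


@dataclass
class BootstrapNull:
    n_iter: int
    values: np.ndarray
    median_f: float
    p_emp: float
    seed: int


@dataclass
class LadderCalibration:
    """Inverse-link gamma GLM: E[size] = 1 / (b0 + b1 * distance)."""

    b0: float
    b1: float
    shape: float
    cov: np.ndarray  # 2x2 covariance of (b0, b1)
    n_standards: int
    distance_range: tuple[float, float]
    deviance_trace: list[float] = field(default_factory=list)


@dataclass(frozen=True)
class SizePrediction:
    estimate: float
    lower: float
    upper: float
    extrapolated: bool

    def contains(self, size: float) -> bool:
        return self.lower <= size <= self.upper


# ---------------------------------------------------------------------------
# Fold-change pairing and regression


def pair_fold_changes(calls, cis_targets: dict[str, str], de_results) -> list[FoldChangePair]:
    """Pair each cis sRNA's fold-change with its target's.

    ``de_results`` maps feature id -> DEResult (or anything with a
    ``log2fc``).  sRNAs lacking either their own or their target's DE record
    are dropped and counted in a log message.
    """
    seen: set[str] = set()
    pairs: list[FoldChangePair] = []
    dropped = 0
    for call in calls:
        if call.mode != "cis":
            continue
        if call.id in seen:
            raise ValidationError(f"duplicate sRNA id {call.id}")
        seen.add(call.id)
        locus = cis_targets.get(call.id)
        de_s = de_results.get(call.id)
        de_t = de_results.get(locus) if locus else None
        if de_s is None or de_t is None:
            dropped += 1
            continue
        if not (np.isfinite(de_s.log2fc) and np.isfinite(de_t.log2fc)):
            dropped += 1
            continue
        pairs.append(FoldChangePair(call.id, de_s.log2fc, locus, de_t.log2fc))
    if dropped:
        log.info("pair_fold_changes: dropped %d cis sRNA(s) lacking fold-changes", dropped)
    return pairs


def _ols_f(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float, float]:
    """(slope, intercept, r2, f) of y ~ x by the normal equations."""
    n = x.size
    xc = x - x.mean()
    yc = y - y.mean()
    sxx = float(xc @ xc)
    sxy = float(xc @ yc)
    syy = float(yc @ yc)
    slope = sxy / sxx
    intercept = float(y.mean() - slope * x.mean())
    if syy == 0:
        return slope, intercept, 0.0, 0.0
    r2 = sxy**2 / (sxx * syy)
    if r2 >= 1.0 - 1e-14:
        return slope, intercept, 1.0, float("inf")
    f = (n - 2) * r2 / (1 - r2)
    return slope, intercept, float(r2), float(f)


def fit_fc_regression(pairs: list[FoldChangePair]) -> RegressionResult:
    """OLS of target fold-change on sRNA fold-change, with the F statistic
    on (1, n-2) degrees of freedom."""
    n = len(pairs)
    if n < 3:
        raise ValidationError(f"need at least 3 pairs, got {n}")
    x = np.array([p.srna_log2fc for p in pairs])
    y = np.array([p.target_log2fc for p in pairs])
    if np.ptp(x) == 0:
        raise ValidationError("zero variance in sRNA fold-changes")
    slope, intercept, r2, f = _ols_f(x, y)
    return RegressionResult(n=n, slope=slope, intercept=intercept, r2=r2, f=f)


def bootstrap_f_null(
    pairs: list[FoldChangePair],
    n_iter: int = 10_000,
    seed: int = 0,
    with_replacement: bool = False,
) -> BootstrapNull:
    """Random re-pairing null for the fold-change regression F statistic.

    Each iteration permutes the target fold-change vector against the fixed
    sRNA vector (pairing without replacement; ``with_replacement=True``
    resamples instead) and records the OLS F.  The empirical exceedance
    probability of the observed F uses +1 smoothing:
    p = (1 + #{null F >= observed F}) / (n_iter + 1).
    """
    n = len(pairs)
    if n < 3:
        raise ValidationError(f"need at least 3 pairs, got {n}")
    x = np.array([p.srna_log2fc for p in pairs])
    y = np.array([p.target_log2fc for p in pairs])
    obs = fit_fc_regression(pairs).f

    rng = np.random.default_rng(seed)
    if with_replacement:
        ymat = y[rng.integers(0, n, size=(n_iter, n))]
    else:
        ymat = rng.permuted(np.broadcast_to(y, (n_iter, n)).copy(), axis=1)
    xc = x - x.mean()
    sxx = float(xc @ xc)
    yc = ymat - ymat.mean(axis=1, keepdims=True)
    syy = np.einsum("ij,ij->i", yc, yc)
    sxy = yc @ xc
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(syy > 0, sxy**2 / (sxx * syy), 0.0)
        fvals = np.where(r2 < 1, (n - 2) * r2 / (1 - r2), np.inf)
    fvals = np.asarray(fvals, dtype=float)
    p_emp = (1 + int(np.sum(fvals >= obs))) / (n_iter + 1)
    return BootstrapNull(
        n_iter=n_iter,
        values=fvals,
        median_f=float(np.median(fvals)),
        p_emp=float(p_emp),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Two-proportion Z-test


def two_proportion_ztest(k1: int, n1: int, k2: int, n2: int) -> tuple[float, float]:
    """Pooled two-sided two-proportion Z-test.

    Returns (z, p); a degenerate pooled proportion (0 or 1) gives (0, 1).
    """
    if not (0 <= k1 <= n1 and 0 <= k2 <= n2) or n1 == 0 or n2 == 0:
        raise ValidationError("need 0 <= k <= n and n > 0 in both groups")
    pool = (k1 + k2) / (n1 + n2)
    if pool in (0.0, 1.0):
        return 0.0, 1.0
    se = np.sqrt(pool * (1 - pool) * (1 / n1 + 1 / n2))
    z = (k1 / n1 - k2 / n2) / se
    p = 2 * sps.norm.sf(abs(z))
    return float(z), float(p)


# ---------------------------------------------------------------------------
# Ladder calibration (gamma GLM, inverse link)


def calibrate_ladder(
    sizes,
    distances,
    max_iter: int = 100,
    tol: float = 1e-10,
) -> LadderCalibration:
    """Fit E[size] = 1/(b0 + b1*distance) with gamma errors by IRLS.

    The inverse link is canonical for the gamma family, so IRLS is Newton's
    method on the log-likelihood; step halving guards positivity of the
    linear predictor and monotone deviance decrease.  The dispersion
    (1/shape) is the Pearson estimate and scales the coefficient covariance
    from the observed information.
    """
    y = np.asarray(sizes, dtype=float)
    d = np.asarray(distances, dtype=float)
    if y.size != d.size or y.size < 3:
        raise ValidationError("need >= 3 (size, distance) standards")
    if (y <= 0).any():
        raise ValidationError("sizes must be positive")
    if np.unique(d).size < 2:
        raise ValidationError("distances must not all coincide")
    X = np.column_stack([np.ones_like(d), d])

    # initialize from OLS on the transformed response 1/y
    beta = np.linalg.lstsq(X, 1.0 / y, rcond=None)[0]
    eta = X @ beta
    if (eta <= 0).any():
        beta = np.array([1.0 / y.mean(), 0.0])
        eta = X @ beta

    def deviance(mu):
        return float(2 * np.sum(-np.log(y / mu) + (y - mu) / mu))

    mu = 1.0 / eta
    dev = deviance(mu)
    trace = [dev]
    converged = False
    for _ in range(max_iter):
        # canonical link: W = mu^2, working response uses d(eta)/d(mu) = -1/mu^2
        w = mu**2
        z = eta + (mu - y) / mu**2
        WX = X * w[:, None]
        beta_new = np.linalg.solve(X.T @ WX, WX.T @ z)
        # step halving to keep eta positive and deviance non-increasing
        step = 1.0
        for _half in range(30):
            cand = beta + step * (beta_new - beta)
            eta_c = X @ cand
            if (eta_c > 0).all():
                dev_c = deviance(1.0 / eta_c)
                if dev_c <= dev + 1e-12:
                    break
            step /= 2
        else:
            raise ValidationError(f"IRLS failed to make progress; last deviance {dev:.6g}")
        beta, eta, mu = cand, eta_c, 1.0 / eta_c
        trace.append(dev_c)
        if abs(dev - dev_c) < tol * (abs(dev_c) + 1.0):
            converged = True
            dev = dev_c
            break
        dev = dev_c
    if not converged:
        raise ValidationError(f"IRLS did not converge in {max_iter} iterations; "
                              f"last deviance {dev:.6g}")

    pearson = float(np.sum(((y - mu) / mu) ** 2))
    dof = max(y.size - 2, 1)
    dispersion = pearson / dof
    info = X.T @ (X * (mu**2)[:, None])
    cov = dispersion * np.linalg.inv(info)
    return LadderCalibration(
        b0=float(beta[0]),
        b1=float(beta[1]),
        shape=float(1.0 / dispersion) if dispersion > 0 else float("inf"),
        cov=cov,
        n_standards=int(y.size),
        distance_range=(float(d.min()), float(d.max())),
        deviance_trace=trace,
    )


def predict_size(
    calibration: LadderCalibration,
    distance: float,
    level: float = 0.95,
    method: str = "delta",
    n_boot: int = 2000,
    seed: int = 0,
) -> SizePrediction:
    """Point estimate and confidence interval for the size at a migration
    distance.

    The default interval is the delta method on the linear predictor
    (t quantile, n-2 df), mapped through the inverse link; ``method=
    "bootstrap"`` instead draws coefficients from their sampling
    distribution.  Distances outside 1.5x the fitted range trigger a warning
    and flag the result as extrapolated.
    """
    lo_d, hi_d = calibration.distance_range
    span = hi_d - lo_d
    margin = 0.25 * span  # guard range total width = 1.5x the fitted span
    extrapolated = not (lo_d - margin <= distance <= hi_d + margin)
    if extrapolated:
        warnings.warn(
            f"distance {distance} outside the calibration guard range "
            f"[{lo_d - margin:.3g}, {hi_d + margin:.3g}]",
            stacklevel=2,
        )
    xv = np.array([1.0, distance])
    eta = float(xv @ np.array([calibration.b0, calibration.b1]))
    if eta <= 0:
        raise ValidationError(f"non-positive linear predictor at distance {distance}")
    est = 1.0 / eta
    dof = max(calibration.n_standards - 2, 1)
    if method == "delta":
        se_eta = float(np.sqrt(xv @ calibration.cov @ xv))
        crit = sps.t.ppf(0.5 + level / 2, dof)
        eta_lo = eta - crit * se_eta
        eta_hi = eta + crit * se_eta
        upper = 1.0 / eta_lo if eta_lo > 0 else float("inf")
        lower = 1.0 / eta_hi
    elif method == "bootstrap":
        rng = np.random.default_rng(seed)
        draws = rng.multivariate_normal(
            [calibration.b0, calibration.b1], calibration.cov, size=n_boot
        )
        etas = draws @ xv
        etas = etas[etas > 0]
        if etas.size < n_boot // 2:
            raise ValidationError("bootstrap interval unstable: predictor sign flips")
        lower, upper = np.quantile(1.0 / etas, [(1 - level) / 2, 0.5 + level / 2])
        lower, upper = float(lower), float(upper)
    else:
        raise ValidationError(f"unknown interval method {method!r}")
    return SizePrediction(estimate=est, lower=float(lower), upper=float(upper),
                          extrapolated=extrapolated)


def size_consistent(
    calibration: LadderCalibration, distance: float, transcriptome_size: float
) -> bool:
    """Whether a transcriptome-derived size falls inside the blot 95% CI."""
    return predict_size(calibration, distance).contains(transcriptome_size)
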