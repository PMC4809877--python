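"""Two-condition differential expression with an exact negative-binomial test.

Counts for annotated genes and putative sRNAs are analyzed together so that
between-sample normalization can assume most features are unchanged.  The
pipeline is:

1. :func:`normalization_factors` — trimmed-mean-of-M-values (TMM) scale
   factors.  The returned factors fold the raw library size and the TMM
   correction into a single per-sample scale, rescaled to geometric mean 1,
   so normalized counts are simply ``y / factor``.
2. :func:`estimate_dispersions` — per-feature method-of-moments negative
   binomial dispersion from within-condition residuals, shrunk toward a
   mean-dispersion trend.
3. :func:`nb_exact_test` — replicates collapsed to per-condition pseudo-sums
   on a common effective library size; conditional on the total, the
   two-sided exact p-value sums the probabilities of all splits as or less
   likely than the observed one under negative-binomial variation.
4. :func:`bh_adjust` — Benjamini–Hochberg FDR.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .errors import ValidationError
from .io_formats import signed_fold

log = logging.getLogger(__name__)

_DISP_FLOOR = 1e-8


@dataclass
class CountMatrix:
    """Integer counts, features x samples, with a condition label per sample."""

    counts: pd.DataFrame  # index: feature ids, columns: sample ids
    conditions: dict[str, str]  # sample id -> condition label

    def __post_init__(self):
        if self.counts.index.has_duplicates:
            raise ValidationError("duplicate feature ids")
        if set(self.counts.columns) != set(self.conditions):
            raise ValidationError("sample ids of counts and conditions disagree")
        arr = self.counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                raise ValidationError("counts must be integers")
            self.counts = self.counts.round().astype(np.int64)
        if (self.counts.to_numpy() < 0).any():
            raise ValidationError("counts must be non-negative")

    @property
    def condition_labels(self) -> list[str]:
        return sorted(set(self.conditions.values()))

    def samples_in(self, condition: str) -> list[str]:
        return [s for s in self.counts.columns if self.conditions[s] == condition]


@dataclass(frozen=True)
class DEResult:
    """Per-feature differential-expression record (condition A over B)."""

    feature: str
    log2fc: float
    p: float
    q: float | None
    mean_expr: float

    @property
    def signed_fold(self) -> float:
        return signed_fold(self.log2fc)


# ---------------------------------------------------------------------------
# TMM normalization


def normalization_factors(
    counts: CountMatrix, trim_m: float = 0.30, trim_a: float = 0.05
) -> pd.Series:
    """Per-sample scale factors: library size x TMM correction, geomean 1.

    For each sample against a reference, log2 count-ratio (M) and mean
    log2 abundance (A) are computed over features expressed in both; the top
    and bottom ``trim_m`` of M and ``trim_a`` of A are trimmed and the
    remaining M values averaged with inverse-asymptotic-variance weights.
    """
    y = counts.counts.to_numpy(dtype=float)
    lib = y.sum(axis=0)
    if (lib == 0).any():
        bad = counts.counts.columns[lib == 0].tolist()
        raise ValidationError(f"all-zero sample(s): {bad}")
    if not ((y > 0).any(axis=1) & (y.sum(axis=1) > 0)).any():
        raise ValidationError("no feature with a nonzero count")

    # reference: sample whose upper-quartile count fraction is most typical
    f75 = np.array([np.quantile(y[:, j] / lib[j], 0.75) for j in range(y.shape[1])])
    ref = int(np.argmin(np.abs(f75 - f75.mean())))

    tmm = np.ones(y.shape[1])
    for j in range(y.shape[1]):
        if j == ref:
            continue
        ok = (y[:, j] > 0) & (y[:, ref] > 0)
        yj, yr = y[ok, j], y[ok, ref]
        m = np.log2((yj / lib[j]) / (yr / lib[ref]))
        a = 0.5 * np.log2((yj / lib[j]) * (yr / lib[ref]))
        w = (lib[j] - yj) / (lib[j] * yj) + (lib[ref] - yr) / (lib[ref] * yr)
        lo_m, hi_m = np.quantile(m, [trim_m, 1 - trim_m])
        lo_a, hi_a = np.quantile(a, [trim_a, 1 - trim_a])
        keep = (m >= lo_m) & (m <= hi_m) & (a >= lo_a) & (a <= hi_a)
        if keep.sum() == 0:
            log.warning("TMM: no features survive trimming for sample %s; "
                        "falling back to median log-ratio", counts.counts.columns[j])
            tmm[j] = 2.0 ** np.median(m)
        else:
            tmm[j] = 2.0 ** (np.sum(w[keep] * m[keep]) / np.sum(w[keep]))

    scale = lib * tmm
    scale = scale / np.exp(np.mean(np.log(scale)))
    return pd.Series(scale, index=counts.counts.columns, name="factor")


# ---------------------------------------------------------------------------
# Dispersion estimation


def estimate_dispersions(
    counts: CountMatrix,
    factors: pd.Series,
    shrinkage: float | None = None,
    prior_df: float = 10.0,
    trend_window: float = 0.1,
) -> pd.Series:
    """Per-feature NB dispersion, method of moments with trend shrinkage.

    The raw estimate pools within-condition moments of normalized counts:
    phi = (s^2 - m) / m^2 (with the small-sample correction to the
    denominator).  Estimates are floored and shrunk toward a rolling-mean
    trend over features ordered by mean expression; degenerate features
    (zero mean) receive the trend value.

    By default the shrinkage weight follows the empirical-Bayes convention
    prior_df / (prior_df + residual_df), so weakly replicated designs lean
    harder on the trend; pass ``shrinkage`` to fix the weight explicitly.
    """
    z = counts.counts.to_numpy(dtype=float) / factors.reindex(counts.counts.columns).to_numpy()
    conds = counts.condition_labels
    col_idx = {s: i for i, s in enumerate(counts.counts.columns)}
    num = np.zeros(z.shape[0])
    den = np.zeros(z.shape[0])
    means = z.mean(axis=1)
    for c in conds:
        cols = [col_idx[s] for s in counts.samples_in(c)]
        if len(cols) < 2:
            continue
        zc = z[:, cols]
        m = zc.mean(axis=1)
        v = zc.var(axis=1, ddof=1)
        w = len(cols) - 1
        # denominator corrects the small-sample bias of m^2: E[m^2] = mu^2 + var/n
        denom = m**2 - v / len(cols)
        with np.errstate(divide="ignore", invalid="ignore"):
            phi_c = np.where((m > 0) & (denom > 0), (v - m) / denom, np.nan)
        ok = np.isfinite(phi_c)
        num[ok] += w * phi_c[ok]
        den[ok] += w
    if not (den > 0).any():
        raise ValidationError("need >=2 replicates in at least one condition")
    if shrinkage is None:
        resid_df = sum(
            max(len(counts.samples_in(c)) - 1, 0) for c in conds
        )
        shrinkage = prior_df / (prior_df + resid_df)
    raw = np.where(den > 0, num / np.maximum(den, 1), np.nan)
    raw = np.where(np.isfinite(raw), np.maximum(raw, _DISP_FLOOR), np.nan)

    # mean-ordered rolling-mean trend
    order = np.argsort(means)
    n = len(raw)
    win = max(20, int(trend_window * n))
    trend = np.empty(n)
    raw_sorted = raw[order]
    fill = np.nanmean(raw) if np.isfinite(raw).any() else _DISP_FLOOR
    for i in range(n):
        lo, hi = max(0, i - win // 2), min(n, i + win // 2 + 1)
        window = raw_sorted[lo:hi]
        window = window[np.isfinite(window)]
        trend[i] = window.mean() if window.size else fill
    trend_full = np.empty(n)
    trend_full[order] = trend

    phi = np.where(
        np.isfinite(raw),
        (1 - shrinkage) * raw + shrinkage * trend_full,
        trend_full,
    )
    phi = np.maximum(phi, _DISP_FLOOR)
    return pd.Series(phi, index=counts.counts.index, name="dispersion")


# ---------------------------------------------------------------------------
# Exact negative-binomial test


def _nb_logpmf(k: np.ndarray, mean: float, size: float) -> np.ndarray:
    """log PMF of NB with given mean and size (= 1/dispersion); Poisson limit
    taken when size is effectively infinite."""
    k = np.asarray(k, dtype=float)
    if not np.isfinite(size) or size > 1e12:
        return k * np.log(mean) - mean - gammaln(k + 1)
    logp = np.log(size / (size + mean))
    logq = np.log(mean / (size + mean))
    return gammaln(k + size) - gammaln(size) - gammaln(k + 1) + size * logp + k * logq


def exact_nb_pvalue(s1: int, s2: int, n1: int, n2: int, phi: float) -> float:
    """Two-sided exact NB p-value for the split (s1, s2) of the total.

    ``s1`` is the pseudo-sum of ``n1`` equal-library replicates with
    per-replicate dispersion ``phi`` (so the sum is NB with size n1/phi);
    likewise ``s2``.  Conditional on the total, the p-value sums the
    probabilities of all splits whose probability does not exceed that of
    the observed split (relative tie tolerance 1e-12).
    """
    total = s1 + s2
    if total == 0:
        return 1.0
    mu = total / (n1 + n2)
    k = np.arange(total + 1)
    if phi <= 0:
        size1 = size2 = np.inf
    else:
        size1, size2 = n1 / phi, n2 / phi
    lp = _nb_logpmf(k, n1 * mu, size1) + _nb_logpmf(k[::-1], n2 * mu, size2)
    lz = logsumexp(lp)
    cond = lp - lz
    obs = cond[s1]
    keep = cond <= obs + 1e-12
    return float(min(1.0, np.exp(logsumexp(cond[keep]))))


def nb_exact_test(
    counts: CountMatrix,
    factors: pd.Series,
    dispersions: pd.Series,
    numerator: str | None = None,
    denominator: str | None = None,
    adjust: bool = True,
    min_mean: float = 0.0,
) -> list[DEResult]:
    """Exact NB test per feature; log2fc is numerator over denominator.

    Replicate counts are rescaled to the geometric-mean effective library
    (``y / factor``, factors having geometric mean 1) and summed per
    condition; the rounded pseudo-sums enter the conditional exact test.
    Features with normalized mean below ``min_mean`` get q = None (reported
    NA), mirroring a low-count reporting floor.
    """
    labels = counts.condition_labels
    if len(labels) != 2:
        raise ValidationError(f"need exactly two conditions, got {labels}")
    if numerator is None:
        numerator, denominator = labels[0], labels[1]
    if {numerator, denominator} != set(labels):
        raise ValidationError("numerator/denominator must be the two condition labels")
    f = factors.reindex(counts.counts.columns).to_numpy()
    if (f <= 0).any() or not np.isfinite(f).all():
        raise ValidationError("factors must be positive and finite")
    z = counts.counts.to_numpy(dtype=float) / f
    cols1 = [counts.counts.columns.get_loc(s) for s in counts.samples_in(numerator)]
    cols2 = [counts.counts.columns.get_loc(s) for s in counts.samples_in(denominator)]
    n1, n2 = len(cols1), len(cols2)
    s1 = np.rint(z[:, cols1].sum(axis=1)).astype(np.int64)
    s2 = np.rint(z[:, cols2].sum(axis=1)).astype(np.int64)
    m1 = z[:, cols1].mean(axis=1)
    m2 = z[:, cols2].mean(axis=1)
    phi = dispersions.reindex(counts.counts.index).to_numpy()
    if not np.isfinite(phi).all():
        raise ValidationError("non-finite dispersion")

    results = []
    for i, feat in enumerate(counts.counts.index):
        if s1[i] + s2[i] == 0:
            p, lfc = 1.0, 0.0
        else:
            p = exact_nb_pvalue(int(s1[i]), int(s2[i]), n1, n2, float(phi[i]))
            lfc = float(np.log2((m1[i] + 0.5) / (m2[i] + 0.5)))
        results.append((feat, lfc, p, float((m1[i] * n1 + m2[i] * n2) / (n1 + n2))))

    pvals = np.array([r[2] for r in results])
    if adjust:
        qvals = bh_adjust(pvals)
    else:
        qvals = np.full(len(results), np.nan)
    out = []
    for (feat, lfc, p, mean_expr), q in zip(results, qvals):
        q_out = None if (adjust and mean_expr < min_mean) else (float(q) if np.isfinite(q) else None)
        out.append(DEResult(feature=feat, log2fc=lfc, p=p, q=q_out, mean_expr=mean_expr))
    return out


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted values; NaN propagates as NaN."""
    p = np.asarray(pvalues, dtype=float)
    q = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    if ((p[ok] < 0) | (p[ok] > 1)).any():
        raise ValidationError("p-values must lie in [0, 1]")
    pv = p[ok]
    m = pv.size
    if m == 0:
        return q
    order = np.argsort(pv, kind="stable")
    ranked = pv[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.empty(m)
    adj[order] = np.minimum(ranked, 1.0)
    q[ok] = adj
    return q


def run_de(
    counts: CountMatrix,
    numerator: str | None = None,
    denominator: str | None = None,
    min_mean: float = 0.0,
) -> list[DEResult]:
    """Convenience wrapper: TMM factors, dispersions, exact test, BH FDR."""
    factors = normalization_factors(counts)
    phi = estimate_dispersions(counts, factors)
    return nb_exact_test(counts, factors, phi, numerator, denominator, min_mean=min_mean)


def de_results_frame(results: list[DEResult]) -> pd.DataFrame:
    rows = [
        {
            "feature": r.feature,
            "log2fc": r.log2fc,
            "signed_fold": r.signed_fold,
            "p": r.p,
            "q": np.nan if r.q is None else r.q,
            "mean_expr": r.mean_expr,
        }
        for r in results
    ]
    return pd.DataFrame(rows).set_index("feature")
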