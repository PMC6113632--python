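"""Distribution-free bootstrap statistics for decorrelated invariant samples.

Tensor-invariant data is non-Gaussian with unequal variances across
regions, so all inference here is by resampling: per-bin bootstrapped
histogram confidence intervals, bootstrapped median CIs, a two-group
median comparison, and a bootstrap analog to repeated-measures ANOVA
across regions within hearts.

The ANOVA analog summarizes each (heart, region) cell by its median and
forms the classical within-subject F on the hearts x regions median
table, ``F = MS(region) / MS(heart x region residual)``.  The null
distribution comes from resampling cells after removing the region
effect: each cell's samples are recentered by subtracting the cell
median and adding the heart's overall median (preserving between-heart
effects), then resampled with replacement; the p-value is
``(1 + #{F* >= F_obs}) / (1 + B)``.  This construction is validated by
its type-I error rate rather than by any external script.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .config import BootstrapConfig, derive_rng

logger = logging.getLogger(__name__)


@dataclass
class HistogramCI:
    """Bootstrapped histogram with per-bin CIs, shared edges with a comparator."""

    edges: np.ndarray            # (n_bins + 1,)
    frequency: np.ndarray        # (n_bins,) point estimate (full-sample frequencies)
    ci_low: np.ndarray
    ci_high: np.ndarray
    nonoverlap: np.ndarray       # (n_bins,) bool: CI disjoint from the comparator's


@dataclass
class MedianCI:
    median: float
    ci_low: float
    ci_high: float


@dataclass
class AnovaResult:
    f_observed: float
    p_value: float
    cell_medians: np.ndarray     # (n_hearts, n_regions)
    hearts: tuple[str, ...]
    regions: tuple[str, ...]


@dataclass
class TwoGroupResult:
    median_difference: float
    p_value: float
    ci_low: float
    ci_high: float


_RESAMPLE_CHUNK = 256  # bounds peak memory of the resample matrix


def _resample_matrix(x: np.ndarray, n_resamples: int, rng) -> np.ndarray:
    idx = rng.integers(0, x.size, size=(n_resamples, x.size))
    return x[idx]


def _bootstrap_medians(x: np.ndarray, n_resamples: int, rng) -> np.ndarray:
    """Medians of ``n_resamples`` with-replacement resamples, chunked so
    peak memory stays modest for large sample sets."""
    out = np.empty(n_resamples)
    for start in range(0, n_resamples, _RESAMPLE_CHUNK):
        stop = min(start + _RESAMPLE_CHUNK, n_resamples)
        idx = rng.integers(0, x.size, size=(stop - start, x.size))
        out[start:stop] = np.median(x[idx], axis=1)
    return out


def _bin_frequencies(values: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Normalized bin frequencies for each row of ``values`` (rightmost
    edge inclusive)."""
    n_bins = edges.size - 1
    bins = np.clip(np.searchsorted(edges, values, side="right") - 1, 0, n_bins - 1)
    rows = np.arange(values.shape[0])[:, None]
    flat = (rows * n_bins + bins).ravel()
    counts = np.bincount(flat, minlength=values.shape[0] * n_bins)
    return counts.reshape(values.shape[0], n_bins) / values.shape[1]


def bootstrap_histogram(samples: np.ndarray, comparator_samples: np.ndarray,
                        cfg: BootstrapConfig) -> tuple[HistogramCI, HistogramCI]:
    """Bootstrapped histograms of two groups on shared equal-width bins.

    Bin edges span the pooled min/max of the two groups.  Each group is
    resampled with replacement ``n_resamples_hist`` times; per-bin
    percentile CIs at ``ci_level`` are formed over the resampled
    normalized frequencies.  A bin where the two CIs do not overlap
    marks a significant difference within that invariant range.
    """
    a = np.asarray(samples, float)
    b = np.asarray(comparator_samples, float)
    if a.size < 30 or b.size < 30:
        raise ValueError("each group needs at least 30 samples")
    lo = min(a.min(), b.min())
    hi = max(a.max(), b.max())
    if lo == hi:
        warnings.warn("identical constant groups: degenerate single-bin histogram")
        edges = np.array([lo, hi])
        one = np.ones(1)
        flag = np.zeros(1, bool)
        h = HistogramCI(edges, one, one.copy(), one.copy(), flag)
        return h, HistogramCI(edges, one.copy(), one.copy(), one.copy(), flag.copy())
    edges = np.linspace(lo, hi, cfg.n_bins + 1)
    alpha = (1.0 - cfg.ci_level) / 2.0
    rng = derive_rng(cfg.seed, "histogram")
    out = []
    for x in (a, b):
        freqs = _bin_frequencies(_resample_matrix(x, cfg.n_resamples_hist, rng), edges)
        point = _bin_frequencies(x[None, :], edges)[0]
        ci_lo = np.quantile(freqs, alpha, axis=0)
        ci_hi = np.quantile(freqs, 1.0 - alpha, axis=0)
        out.append((point, ci_lo, ci_hi))
    (pa, la, ha), (pb, lb, hb) = out
    nonoverlap = (la > hb) | (lb > ha)
    return (HistogramCI(edges, pa, la, ha, nonoverlap.copy()),
            HistogramCI(edges, pb, lb, hb, nonoverlap.copy()))


def bootstrap_median_ci(samples: np.ndarray, cfg: BootstrapConfig) -> MedianCI:
    """Median with a percentile-bootstrap CI (``n_resamples_hist`` resamples)."""
    x = np.asarray(samples, float)
    if x.size < 10:
        raise ValueError("need at least 10 samples for a median CI")
    rng = derive_rng(cfg.seed, "median-ci")
    med = float(np.median(x))
    boots = _bootstrap_medians(x, cfg.n_resamples_hist, rng)
    alpha = (1.0 - cfg.ci_level) / 2.0
    lo = float(np.quantile(boots, alpha))
    hi = float(np.quantile(boots, 1.0 - alpha))
    return MedianCI(med, min(lo, med), max(hi, med))


def _rm_f_statistic(table: np.ndarray) -> np.ndarray:
    """Within-subject F on a (..., hearts, regions) median table."""
    grand = table.mean(axis=(-2, -1), keepdims=True)
    heart_means = table.mean(axis=-1, keepdims=True)
    region_means = table.mean(axis=-2, keepdims=True)
    h, r = table.shape[-2], table.shape[-1]
    ss_region = h * ((region_means - grand) ** 2).sum(axis=(-2, -1))
    resid = table - heart_means - region_means + grand
    ss_err = (resid**2).sum(axis=(-2, -1))
    ms_region = ss_region / (r - 1)
    ms_err = ss_err / ((h - 1) * (r - 1))
    with np.errstate(divide="ignore", invalid="ignore"):
        f = ms_region / ms_err
    return np.where(ms_err == 0, np.inf, f)


def bootstrap_rm_anova(cells: dict[tuple[str, str], np.ndarray],
                       cfg: BootstrapConfig,
                       regions: tuple[str, ...] = ("remote", "bz", "infarct"),
                       ) -> AnovaResult:
    """Bootstrap analog to repeated-measures ANOVA on per-cell samples.

    ``cells`` maps (heart, region) to decorrelated samples.  Every heart
    must contribute all regions with at least 5 samples each.
    """
    hearts = tuple(sorted({h for h, _ in cells}))
    for h in hearts:
        for r in regions:
            if (h, r) not in cells:
                raise ValueError(f"missing cell: heart {h!r}, region {r!r}")
            if np.asarray(cells[(h, r)]).size < 5:
                raise ValueError(f"cell heart {h!r}, region {r!r} has < 5 samples")
    observed = np.array([[np.median(cells[(h, r)]) for r in regions] for h in hearts])
    f_obs = float(_rm_f_statistic(observed))

    # null model: remove the region effect within each heart, keep heart effects
    rng = derive_rng(cfg.seed, "rm-anova")
    B = cfg.n_resamples_test
    f_null = np.empty((B, len(hearts), len(regions)))
    for i, h in enumerate(hearts):
        heart_median = np.median(np.concatenate([cells[(h, r)] for r in regions]))
        for j, r in enumerate(regions):
            x = np.asarray(cells[(h, r)], float)
            centered = x - np.median(x) + heart_median
            f_null[:, i, j] = _bootstrap_medians(centered, B, rng)
    f_star = _rm_f_statistic(f_null)
    p = (1.0 + np.sum(f_star >= f_obs)) / (1.0 + B)
    return AnovaResult(f_obs, float(p), observed, hearts, tuple(regions))


def bootstrap_two_group(samples_a: np.ndarray, samples_b: np.ndarray,
                        cfg: BootstrapConfig) -> TwoGroupResult:
    """Two-group comparison of medians by bootstrap.

    The observed statistic is ``median(a) - median(b)``; the bootstrap
    distribution of the difference comes from resampling each group
    independently; the two-sided p is twice the smaller tail of the
    bootstrap differences about zero, floored at ``1/(1+B)``.
    """
    a = np.asarray(samples_a, float)
    b = np.asarray(samples_b, float)
    if a.size < 10 or b.size < 10:
        raise ValueError("each group needs at least 10 samples")
    delta = float(np.median(a) - np.median(b))
    rng = derive_rng(cfg.seed, "two-group")
    B = cfg.n_resamples_test
    da = _bootstrap_medians(a, B, rng)
    db = _bootstrap_medians(b, B, rng)
    dstar = da - db
    p = 2.0 * min(np.mean(dstar <= 0.0), np.mean(dstar >= 0.0))
    floor = 1.0 / (1.0 + B)
    p = float(np.clip(p, floor, 1.0))
    alpha = (1.0 - cfg.ci_level) / 2.0
    return TwoGroupResult(delta, p,
                          float(np.quantile(dstar, alpha)),
                          float(np.quantile(dstar, 1.0 - alpha)))
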