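"""Single-condition voxel connectivity metrics.

For a seed voxel x, the Pearson correlations r(x, y) to every other
gray-matter voxel form a distribution p(x, r).  Three summaries of that
distribution are implemented:

* binary **degree** at a threshold tau — the count of correlations above tau;
* **wGBC** (weighted global brain connectivity) — the mean correlation;
* **ICD** (intrinsic connectivity distribution) — a parametric model of the
  survival function S(tau) of the positive correlations,

    S(tau) = exp(-(tau / alpha) ** beta),

  a stretched exponential, equivalently a Weibull distribution of the
  correlations with scale ``alpha`` and shape ``beta``.  Each point of the
  survival function is binary degree (as a fraction) at that threshold, so
  ICD models how degree decays as the threshold grows, with no threshold
  choice.  ``alpha`` tracks the spread (variance) of the distribution and is
  the statistic carried to group analysis.

The fit itself is exposed in statsmodels style:
``StretchedExponentialModel(curve).fit()`` returns a
:class:`StretchedExponentialFit` with parameters, residual diagnostics and a
``summary()`` table.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .volume_io import MaskedTimeSeries, ScalarMap, scatter_map

__all__ = [
    "CorrelationDistribution",
    "SurvivalCurve",
    "StretchedExponentialModel",
    "StretchedExponentialFit",
    "correlation_row",
    "histogram",
    "survival",
    "fit_stretched_exponential",
    "degree_from_correlations",
    "icd_map",
    "wgbc_map",
    "degree_map",
    "ICD",
    "ICDResults",
]

#: number of histogram bins for single-condition positive correlations
ICD_BINS = 100
#: correlation support modeled by single-condition ICD
ICD_SUPPORT = (0.0, 1.0)


# ---------------------------------------------------------------------------
# correlation machinery


def standardize_rows(values: np.ndarray):
    """Demean each row and scale to unit L2 norm.

    Zero-variance rows are mapped to all-zero rows (their correlations are
    defined as 0).  Returns ``(z, zero_variance_row_mask)``.
    """
    values = np.asarray(values, dtype=np.float64)
    centered = values - values.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    # constant rows leave rounding residue after demeaning; compare the
    # norm against the row's own scale
    scale = np.maximum(np.abs(values).max(axis=1), 1.0)
    zero = norms <= 1e-13 * scale
    safe = np.where(zero, 1.0, norms)
    z = centered / safe[:, None]
    z[zero] = 0.0
    return z, zero


def correlation_row(ts: MaskedTimeSeries, x: int,
                    _z=None) -> np.ndarray:
    """Pearson correlations of voxel ``x`` to every *other* masked voxel.

    Returns a length V-1 vector (self excluded), in voxel order with the
    seed removed.  Zero-variance targets get correlation 0 with a warning;
    a zero-variance seed is an error.
    """
    if _z is None:
        z, zero = standardize_rows(ts.values)
    else:
        z, zero = _z
    if zero[x]:
        raise ValueError(f"seed voxel {x} has zero variance")
    if zero.any() and _z is None:
        warnings.warn(f"{int(zero.sum())} zero-variance target voxels; "
                      "their correlations are set to 0", stacklevel=2)
    r = z @ z[x]
    np.clip(r, -1.0, 1.0, out=r)
    return np.delete(r, x)


def _pairwise_block(z: np.ndarray, rows: np.ndarray) -> np.ndarray:
    """Correlations of the given (standardized) rows against all rows."""
    block = z[rows] @ z.T
    np.clip(block, -1.0, 1.0, out=block)
    return block


def degree_from_correlations(r: np.ndarray, tau: float) -> int:
    """Binary degree: number of correlations strictly above ``tau``."""
    return int(np.count_nonzero(np.asarray(r) > tau))


# ---------------------------------------------------------------------------
# distributions and survival curves


@dataclasses.dataclass
class CorrelationDistribution:
    """Uniform-bin histogram of correlations (or correlation differences)."""

    bin_edges: np.ndarray      # B+1, strictly increasing, uniform width
    counts: np.ndarray         # B nonnegative integers
    n_total: int               # values inside the support

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=np.float64)
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.bin_edges.size != self.counts.size + 1:
            raise ValueError("edges/counts size mismatch")
        if int(self.counts.sum()) != self.n_total:
            raise ValueError("counts do not sum to n_total")

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])


@dataclasses.dataclass
class SurvivalCurve:
    """S(tau_k): fraction of values at or above each bin's left edge."""

    thresholds: np.ndarray     # bin left edges tau_k
    s: np.ndarray              # S(tau_k) in [0, 1]
    n_total: int = 0

    def __post_init__(self) -> None:
        self.thresholds = np.asarray(self.thresholds, dtype=np.float64)
        self.s = np.asarray(self.s, dtype=np.float64)

    @property
    def defined(self) -> bool:
        return self.n_total > 0


def histogram(values: np.ndarray, support=(0.0, 1.0),
              bins: int = ICD_BINS) -> CorrelationDistribution:
    """Uniform histogram on ``support``; values outside are dropped.

    Bins are right-open except the last, which is right-closed (a value
    equal to the upper support edge lands in the final bin).
    """
    lo, hi = support
    if bins < 1 or not lo < hi:
        raise ValueError("need bins >= 1 and lo < hi")
    values = np.asarray(values, dtype=np.float64).ravel()
    counts, edges = np.histogram(values, bins=bins, range=(lo, hi))
    return CorrelationDistribution(bin_edges=edges, counts=counts,
                                   n_total=int(counts.sum()))


def survival(dist: CorrelationDistribution,
             denominator: int | None = None) -> SurvivalCurve:
    """Convert a histogram to its survival function at the bin left edges.

    ``S(tau_k)`` is the fraction of in-support values in bins ``k..B-1``.
    By default the denominator is ``n_total`` (so ``S(tau_0) = 1``); pass
    ``denominator`` to normalize by something else (e.g. V-1).
    """
    tail = np.cumsum(dist.counts[::-1])[::-1]
    denom = dist.n_total if denominator is None else denominator
    if denom > 0:
        s = tail / float(denom)
    else:
        s = np.zeros_like(tail, dtype=np.float64)
    return SurvivalCurve(thresholds=dist.bin_edges[:-1], s=s,
                         n_total=dist.n_total)


# ---------------------------------------------------------------------------
# the stretched-exponential (Weibull survival) model


@dataclasses.dataclass
class StretchedExponentialFit:
    """Fitted stretched-exponential survival model.

    ``alpha`` is the Weibull scale ("variance") parameter, ``beta`` the
    shape.  ``alpha == 0`` is the sentinel for a degenerate input (too few
    informative bins); ``beta`` is 0 in that case.
    """

    alpha: float
    beta: float
    rss: float
    n_points: int
    converged: bool = True
    model: "StretchedExponentialModel | None" = None

    @property
    def degenerate(self) -> bool:
        return self.alpha == 0.0

    @property
    def params(self) -> np.ndarray:
        return np.array([self.alpha, self.beta])

    def predict(self, tau: np.ndarray) -> np.ndarray:
        """Model survival values S(tau) = exp(-(tau/alpha)^beta)."""
        tau = np.asarray(tau, dtype=np.float64)
        if self.degenerate:
            return np.where(tau <= 0, 1.0, 0.0)
        return _stretched_exp(tau, self.alpha, self.beta)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"value": [self.alpha, self.beta, self.rss,
                       self.n_points, self.converged]},
            index=["alpha (scale)", "beta (shape)", "rss",
                   "n_points", "converged"],
        )


def _stretched_exp(tau, alpha, beta):
    with np.errstate(divide="ignore"):
        ratio = np.where(tau > 0, tau / alpha, 0.0)
        return np.exp(-np.power(ratio, beta))


class StretchedExponentialModel:
    """Least-squares fit of ``S(tau) = exp(-(tau/alpha)^beta)`` to a
    survival curve.

    Parameters
    ----------
    curve : SurvivalCurve
        The empirical survival function (thresholds at bin left edges).
    include_zero_tail : bool
        Include bins where S = 0 (as data points of value 0) in the
        nonlinear objective.  They are always excluded from the
        initialization.  Default True.
    exclude_plateau : bool
        Drop bins where S = 1 beyond the first point (the flat plateau)
        from the objective.  Default False.

    The fit is a trust-region-reflective nonlinear least squares with both
    parameters constrained positive, initialized from the linearization
    ``log(-log S) = beta * log tau - beta * log alpha`` on the interior
    points (0 < S < 1, tau > 0).  Fewer than 3 interior points yields the
    degenerate sentinel (alpha = 0).
    """

    #: parameter step tolerance of the trust-region solver
    XTOL = 1e-10
    #: iteration cap
    MAX_ITER = 200

    def __init__(self, curve: SurvivalCurve, include_zero_tail: bool = True,
                 exclude_plateau: bool = False):
        self.curve = curve
        self.include_zero_tail = include_zero_tail
        self.exclude_plateau = exclude_plateau

    def _fit_points(self):
        tau, s = self.curve.thresholds, self.curve.s
        keep = np.ones(tau.size, dtype=bool)
        if not self.include_zero_tail:
            keep &= s > 0.0
        if self.exclude_plateau:
            plateau = s >= 1.0
            if plateau.any():
                first = np.argmax(plateau)
                plateau = plateau.copy()
                plateau[first] = False     # keep the first S=1 anchor
                keep &= ~plateau
        return tau[keep], s[keep]

    def fit(self) -> StretchedExponentialFit:
        tau, s = self._fit_points()
        interior = (s > 0.0) & (s < 1.0) & (tau > 0.0)
        n_pts = int(tau.size)
        if not self.curve.defined or int(interior.sum()) < 3:
            return StretchedExponentialFit(alpha=0.0, beta=0.0,
                                           rss=float("nan"),
                                           n_points=n_pts,
                                           converged=False, model=self)
        lx = np.log(tau[interior])
        ly = np.log(-np.log(s[interior]))
        slope, intercept = np.polyfit(lx, ly, 1)
        beta0 = float(max(slope, 1e-3))
        alpha0 = float(np.exp(-intercept / beta0))
        alpha0 = min(max(alpha0, 1e-8), 1e3)

        def resid(p):
            return _stretched_exp(tau, p[0], p[1]) - s

        def jac(p):
            a, b = p
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = np.where(tau > 0, tau / a, 0.0)
                pow_rb = np.power(ratio, b)
                e = np.exp(-pow_rb)
                da = e * pow_rb * b / a
                db = np.where(ratio > 0,
                              -e * pow_rb * np.log(np.maximum(ratio, 1e-300)),
                              0.0)
            return np.column_stack([da, db])

        sol = least_squares(resid, x0=[alpha0, beta0], jac=jac,
                            bounds=([1e-12, 1e-6], [np.inf, np.inf]),
                            method="trf", xtol=self.XTOL, ftol=1e-14,
                            gtol=1e-14, max_nfev=self.MAX_ITER * 3)
        alpha, beta = map(float, sol.x)
        return StretchedExponentialFit(alpha=alpha, beta=beta,
                                       rss=float(np.sum(sol.fun ** 2)),
                                       n_points=n_pts,
                                       converged=bool(sol.status > 0),
                                       model=self)


def fit_stretched_exponential(curve: SurvivalCurve,
                              **kwargs) -> StretchedExponentialFit:
    """Functional wrapper: fit the stretched-exponential survival model."""
    fit = StretchedExponentialModel(curve, **kwargs).fit()
    if fit.degenerate:
        warnings.warn("degenerate survival curve: fewer than 3 interior "
                      "points; alpha = 0 sentinel returned", stacklevel=2)
    return fit


# ---------------------------------------------------------------------------
# per-voxel maps

#: seed chunk size for streaming the correlation rows
CHUNK = 256


def _row_histogram_counts(block: np.ndarray, lo: float, hi: float,
                          bins: int) -> np.ndarray:
    """Per-row uniform histograms of a 2-D block (rows kept separate).

    Matches :func:`histogram`'s bin conventions (right-open bins, last bin
    closed, out-of-support values dropped).
    """
    n_rows = block.shape[0]
    width = (hi - lo) / bins
    idx = np.floor((block - lo) / width).astype(np.int64)
    idx[block == hi] = bins - 1          # closed final bin
    valid = (block >= lo) & (block <= hi)
    offsets = (np.arange(n_rows)[:, None] * bins + idx)[valid]
    return np.bincount(offsets, minlength=n_rows * bins).reshape(n_rows, bins)


def _survival_from_counts(counts: np.ndarray) -> np.ndarray:
    """Row-wise survival fractions from row-wise histogram counts."""
    tail = np.cumsum(counts[:, ::-1], axis=1)[:, ::-1].astype(np.float64)
    totals = counts.sum(axis=1).astype(np.float64)
    safe = np.where(totals > 0, totals, 1.0)
    return tail / safe[:, None], counts.sum(axis=1)


def _fit_survival_rows(counts: np.ndarray, edges: np.ndarray, **fit_kwargs):
    """Fit the stretched exponential to each row's survival curve."""
    s_rows, totals = _survival_from_counts(counts)
    alphas = np.empty(counts.shape[0])
    betas = np.empty(counts.shape[0])
    n_degenerate = 0
    for i in range(counts.shape[0]):
        curve = SurvivalCurve(thresholds=edges[:-1], s=s_rows[i],
                              n_total=int(totals[i]))
        fit = StretchedExponentialModel(curve, **fit_kwargs).fit()
        alphas[i] = fit.alpha
        betas[i] = fit.beta
        n_degenerate += fit.degenerate
    return alphas, betas, n_degenerate


def _iter_seed_chunks(v: int, chunk: int = CHUNK):
    for start in range(0, v, chunk):
        yield np.arange(start, min(start + chunk, v))


def icd_map(ts: MaskedTimeSeries, bins: int = ICD_BINS,
            **fit_kwargs):
    """Per-voxel ICD: alpha and beta maps of the positive-correlation
    survival fit (100 bins on [0, 1]).

    Returns ``(alpha_map, beta_map, n_degenerate)``.
    """
    z, zero = standardize_rows(ts.values)
    v = ts.n_voxels
    lo, hi = ICD_SUPPORT
    edges = np.linspace(lo, hi, bins + 1)
    alphas = np.empty(v)
    betas = np.empty(v)
    n_deg = 0
    for rows in _iter_seed_chunks(v):
        block = _pairwise_block(z, rows)
        block[np.arange(rows.size), rows] = -2.0  # self: outside support
        counts = _row_histogram_counts(block, lo, hi, bins)
        a, b, d = _fit_survival_rows(counts, edges, **fit_kwargs)
        alphas[rows], betas[rows] = a, b
        n_deg += d
    amap = scatter_map(alphas, ts.mask, "icd_alpha")
    bmap = scatter_map(betas, ts.mask, "icd_beta")
    return amap, bmap, n_deg


def wgbc_map(ts: MaskedTimeSeries, positive_only: bool = False) -> ScalarMap:
    """Weighted global brain connectivity: per voxel, the mean of its
    correlations to all other voxels (positive and negative).

    ``positive_only=True`` averages only the positive correlations
    (sensitivity variant).
    """
    z, zero = standardize_rows(ts.values)
    v = ts.n_voxels
    out = np.empty(v)
    for rows in _iter_seed_chunks(v):
        block = _pairwise_block(z, rows)
        block[np.arange(rows.size), rows] = 0.0      # exclude self
        if positive_only:
            pos = block > 0
            npos = pos.sum(axis=1)
            sums = np.where(pos, block, 0.0).sum(axis=1)
            out[rows] = np.where(npos > 0, sums / np.maximum(npos, 1), 0.0)
        else:
            out[rows] = block.sum(axis=1) / (v - 1)
    return scatter_map(out, ts.mask, "wgbc")


def degree_map(ts: MaskedTimeSeries, tau: float) -> ScalarMap:
    """Binary degree: per voxel, the count of other voxels with r > tau."""
    z, zero = standardize_rows(ts.values)
    v = ts.n_voxels
    out = np.empty(v)
    for rows in _iter_seed_chunks(v):
        block = _pairwise_block(z, rows)
        block[np.arange(rows.size), rows] = -np.inf  # exclude self
        out[rows] = (block > tau).sum(axis=1)
    return scatter_map(out, ts.mask, f"degree_tau{tau:g}")


# ---------------------------------------------------------------------------
# estimator facade


class ICD:
    """Single-condition intrinsic connectivity distribution estimator.

    ``ICD(ts).fit()`` computes, for every masked voxel, the survival
    function of its positive correlations and the stretched-exponential
    parameters, returning an :class:`ICDResults`.
    """

    def __init__(self, ts: MaskedTimeSeries, bins: int = ICD_BINS,
                 **fit_kwargs):
        self.ts = ts
        self.bins = bins
        self.fit_kwargs = fit_kwargs

    def fit(self) -> "ICDResults":
        amap, bmap, n_deg = icd_map(self.ts, bins=self.bins,
                                    **self.fit_kwargs)
        return ICDResults(alpha_map=amap, beta_map=bmap,
                          n_degenerate=n_deg, model=self)


@dataclasses.dataclass
class ICDResults:
    alpha_map: ScalarMap
    beta_map: ScalarMap
    n_degenerate: int
    model: ICD | None = None

    def summary(self) -> pd.DataFrame:
        a = self.alpha_map.masked_values()
        b = self.beta_map.masked_values()
        ok = a > 0
        rows = {
            "alpha mean": a[ok].mean() if ok.any() else np.nan,
            "alpha sd": a[ok].std() if ok.any() else np.nan,
            "beta mean": b[ok].mean() if ok.any() else np.nan,
            "beta sd": b[ok].std() if ok.any() else np.nan,
            "n voxels": float(a.size),
            "n degenerate": float(self.n_degenerate),
        }
        return pd.DataFrame({"value": rows})
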