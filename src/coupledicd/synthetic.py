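"""Synthetic masked time series with controlled cross-correlation structure.

The generator draws zero-mean Gaussian time series whose population
correlation matrix is specified exactly, so every downstream metric has a
known ground truth.  Paired conditions are two independent realizations
from two matrices that differ on chosen edges, emulating within-subject
connectivity change between scans.

Two constructions are used:

* **block specs** (:class:`CovarianceSpec`) — equicorrelated blocks over a
  background correlation, for generic sessions;
* **single-factor loadings** — for the paired failure-mode scenarios.  A
  hub holding many moderately strong edges to otherwise weakly coupled
  voxels is not positive semi-definite as a direct block construction, so
  the scenarios set per-voxel factor loadings (correlation
  ``r_ij = lam_i * lam_j``), which is PSD by construction and hits the hub
  edge targets exactly.

Scenarios (``make_scenario``):

* ``null`` — both conditions share one matrix;
* ``threshold_crossing`` — one edge moves from tau - delta/2 to
  tau + delta/2 (default tau 0.25, delta 0.02): a tiny change that flips
  binary degree at threshold tau;
* ``balanced_cancellation`` — half of a hub's edges rise by delta, half
  fall by delta (defaults: 200 edges, delta 0.2): a large change invisible
  to mean-based summaries;
* ``uniform_shift`` — all of a hub's edges rise by delta (defaults: 100
  edges, delta 0.2).

All randomness flows from a single seed through ``numpy`` SeedSequence
spawning (condition 1 then condition 2).
"""

from __future__ import annotations

import dataclasses
import math
import warnings

import numpy as np

from .coupled import PairedTimeSeries
from .volume_io import BrainMask, MaskedTimeSeries

__all__ = [
    "CovarianceSpec",
    "PairedDeltaSpec",
    "PairedScenario",
    "SCENARIOS",
    "make_scenario",
    "simulate_session",
    "simulate_paired",
    "simulate_scenario",
    "weibull_difference_sample",
    "default_mask",
]

#: eigenvalue slack treated as numerical noise when validating PSD
PSD_TOL = 1e-8
#: worst PSD violation a delta spec may introduce before repair is refused
PSD_REPAIR_LIMIT = 1e-6

SCENARIOS = ("null", "threshold_crossing", "balanced_cancellation",
             "uniform_shift")


def default_mask(v: int, shape=None) -> BrainMask:
    """A filled mask holding exactly ``v`` voxels (a v x 1 x 1 column
    unless a 3-D ``shape`` with prod == v is given)."""
    if shape is None:
        shape = (v, 1, 1)
    if int(np.prod(shape)) != v:
        raise ValueError("shape does not hold v voxels")
    return BrainMask(labels=np.ones(shape, dtype=bool))


def _validate_psd(r: np.ndarray, what: str = "correlation matrix"):
    w = np.linalg.eigvalsh(r)
    if w.min() < -PSD_TOL:
        raise ValueError(f"{what} is not positive semi-definite "
                         f"(min eigenvalue {w.min():.3g})")


def _repair_psd(r: np.ndarray) -> np.ndarray:
    """Nearest-PSD projection (eigenvalue clipping + diagonal reset).

    Allowed only for violations smaller than ``PSD_REPAIR_LIMIT``."""
    w, u = np.linalg.eigh(r)
    worst = w.min()
    if worst >= -PSD_TOL:
        return r
    if worst < -PSD_REPAIR_LIMIT:
        raise ValueError("delta spec breaks positive semi-definiteness "
                         f"(min eigenvalue {worst:.3g})")
    warnings.warn("delta spec marginally breaks PSD "
                  f"(min eigenvalue {worst:.3g}); projecting to nearest PSD",
                  stacklevel=2)
    fixed = (u * np.maximum(w, 0.0)) @ u.T
    d = np.sqrt(np.diag(fixed))
    fixed = fixed / np.outer(d, d)
    np.fill_diagonal(fixed, 1.0)
    return fixed


@dataclasses.dataclass
class CovarianceSpec:
    """Block-structured population correlation specification.

    ``blocks`` is a list of ``(index_array, rho)`` pairs: each block is
    equicorrelated at ``rho`` on top of ``background_rho`` elsewhere.
    ``noise_sd`` adds independent white measurement noise per voxel, which
    attenuates all empirical correlations by 1 / (1 + noise_sd**2);
    the default 0 reproduces the matrix exactly in population.
    """

    v: int
    blocks: list = dataclasses.field(default_factory=list)
    background_rho: float = 0.0
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        for _, rho in self.blocks:
            if not -1.0 < rho < 1.0:
                raise ValueError("block rho must lie in (-1, 1)")
        if not -1.0 < self.background_rho < 1.0:
            raise ValueError("background rho must lie in (-1, 1)")
        _validate_psd(self.matrix(), "CovarianceSpec matrix")

    def matrix(self) -> np.ndarray:
        r = np.full((self.v, self.v), self.background_rho)
        for idx, rho in self.blocks:
            idx = np.asarray(idx, dtype=np.intp)
            r[np.ix_(idx, idx)] = rho
        np.fill_diagonal(r, 1.0)
        return r


@dataclasses.dataclass
class PairedDeltaSpec:
    """Edge-level correlation changes applied to a base matrix for
    condition 2.  ``edges`` holds ``((i, j), delta)`` pairs."""

    edges: list = dataclasses.field(default_factory=list)
    scenario: str = "null"

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}")

    def apply(self, r1: np.ndarray) -> np.ndarray:
        r2 = r1.copy()
        for (i, j), delta in self.edges:
            new = r1[i, j] + delta
            if not -1.0 < new < 1.0:
                raise ValueError(
                    f"delta pushes edge ({i},{j}) to {new}, outside (-1, 1)")
            r2[i, j] = r2[j, i] = new
        return _repair_psd(r2)


def _factor_matrix(loadings: np.ndarray) -> np.ndarray:
    """Single-factor correlation matrix r_ij = lam_i lam_j (unit diagonal)."""
    lam = np.asarray(loadings, dtype=float)
    if np.any(np.abs(lam) > 1):
        raise ValueError("factor loadings must lie in [-1, 1]")
    r = np.outer(lam, lam)
    np.fill_diagonal(r, 1.0)
    return r


@dataclasses.dataclass
class PairedScenario:
    """A fully specified paired condition: two population correlation
    matrices plus bookkeeping about what was perturbed."""

    name: str
    r1: np.ndarray
    r2: np.ndarray
    node: int | None = None                  # the perturbed (hub) voxel
    edges: tuple = ()                        # ((i, j), delta) perturbations


def make_scenario(name: str, v: int = 500, tau: float = 0.25,
                  delta: float | None = None, n_edges: int | None = None,
                  rho0: float | None = None,
                  hub_loading: float = 0.8) -> PairedScenario:
    """Build one of the paired failure-mode scenarios (see module docs).

    Defaults are the study conditions: ``threshold_crossing`` perturbs one
    edge by 0.02 about tau = 0.25; ``balanced_cancellation`` perturbs 200
    of a hub's edges by +/-0.2; ``uniform_shift`` raises 100 hub edges by
    0.2.
    """
    if name == "null":
        r = np.eye(v)
        return PairedScenario(name=name, r1=r, r2=r.copy())

    if name == "threshold_crossing":
        delta = 0.02 if delta is None else delta
        r1 = np.eye(v)
        r2 = np.eye(v)
        lo, hi = tau - delta / 2.0, tau + delta / 2.0
        r1[0, 1] = r1[1, 0] = lo
        r2[0, 1] = r2[1, 0] = hi
        return PairedScenario(name=name, r1=r1, r2=r2, node=0,
                              edges=(((0, 1), hi - lo),))

    if name == "balanced_cancellation":
        delta = 0.2 if delta is None else delta
        n_edges = 200 if n_edges is None else n_edges
        rho0 = 0.32 if rho0 is None else rho0
        if n_edges % 2 or n_edges + 1 > v:
            raise ValueError("n_edges must be even and < v")
        lam1 = np.zeros(v)
        lam1[0] = hub_loading
        lam1[1:n_edges + 1] = rho0 / hub_loading
        lam2 = lam1.copy()
        half = n_edges // 2
        lam2[1:half + 1] = (rho0 + delta) / hub_loading
        lam2[half + 1:n_edges + 1] = (rho0 - delta) / hub_loading
        edges = tuple(((0, j), delta if j <= half else -delta)
                      for j in range(1, n_edges + 1))
        return PairedScenario(name=name, r1=_factor_matrix(lam1),
                              r2=_factor_matrix(lam2), node=0, edges=edges)

    if name == "uniform_shift":
        delta = 0.2 if delta is None else delta
        n_edges = 100 if n_edges is None else n_edges
        rho0 = 0.2 if rho0 is None else rho0
        if n_edges + 1 > v:
            raise ValueError("n_edges must be < v")
        lam1 = np.zeros(v)
        lam1[0] = hub_loading
        lam1[1:n_edges + 1] = rho0 / hub_loading
        lam2 = lam1.copy()
        lam2[1:n_edges + 1] = (rho0 + delta) / hub_loading
        edges = tuple(((0, j), delta) for j in range(1, n_edges + 1))
        return PairedScenario(name=name, r1=_factor_matrix(lam1),
                              r2=_factor_matrix(lam2), node=0, edges=edges)

    raise ValueError(f"unknown scenario {name!r}; expected one of {SCENARIOS}")


# ---------------------------------------------------------------------------
# sampling


def _correlation_factor(r: np.ndarray) -> np.ndarray:
    """A factor L with L L' = r (eigen square root, robust to semidefinite
    matrices)."""
    w, u = np.linalg.eigh(r)
    if w.min() < -PSD_TOL:
        raise ValueError("matrix is not positive semi-definite")
    return u * np.sqrt(np.maximum(w, 0.0))


def _draw(r: np.ndarray, t: int, rng: np.random.Generator,
          ar1: float = 0.0, noise_sd: float = 0.0) -> np.ndarray:
    """T frames from N(0, r), optionally AR(1)-filtered in time.

    The AR filter ``x_t = phi x_{t-1} + sqrt(1-phi^2) e_t`` preserves the
    cross-sectional correlation matrix at stationarity.  Returns V x T.
    """
    v = r.shape[0]
    l_factor = _correlation_factor(r)
    e = rng.standard_normal((t, v)) @ l_factor.T     # T x V innovations
    if ar1:
        if not -1.0 < ar1 < 1.0:
            raise ValueError("AR(1) coefficient must lie in (-1, 1)")
        x = np.empty_like(e)
        x[0] = e[0]
        c = math.sqrt(1.0 - ar1 ** 2)
        for i in range(1, t):
            x[i] = ar1 * x[i - 1] + c * e[i]
        e = x
    if noise_sd:
        e = e + noise_sd * rng.standard_normal(e.shape)
    return e.T


def _as_matrix(spec) -> tuple:
    if isinstance(spec, CovarianceSpec):
        return spec.matrix(), spec.noise_sd
    r = np.asarray(spec, dtype=float)
    _validate_psd(r)
    return r, 0.0


def simulate_session(spec, t: int, seed: int, ar1: float = 0.0,
                     tr_seconds: float = 2.0,
                     mask: BrainMask | None = None) -> MaskedTimeSeries:
    """Draw one masked session from a :class:`CovarianceSpec` or an
    explicit correlation matrix.  Deterministic given ``seed``."""
    if t < 10:
        raise ValueError("need t >= 10 frames")
    r, noise_sd = _as_matrix(spec)
    v = r.shape[0]
    rng = np.random.default_rng(seed)
    values = _draw(r, t, rng, ar1=ar1, noise_sd=noise_sd)
    mask = mask if mask is not None else default_mask(v)
    if mask.n_voxels != v:
        raise ValueError("mask voxel count does not match spec")
    return MaskedTimeSeries(values=values, mask=mask,
                            tr_seconds=tr_seconds, affine=np.eye(4))


def simulate_paired(spec, delta, t: int, seed: int, ar1: float = 0.0,
                    tr_seconds: float = 2.0,
                    mask: BrainMask | None = None) -> PairedTimeSeries:
    """Two independent condition realizations of one subject.

    ``spec`` is a CovarianceSpec or matrix for condition 1; ``delta`` is a
    :class:`PairedDeltaSpec` applied to it, or an explicit condition-2
    matrix.  Condition noise realizations are independent, split from
    ``seed``.
    """
    r1, noise_sd = _as_matrix(spec)
    if isinstance(delta, PairedDeltaSpec):
        r2 = delta.apply(r1)
    else:
        r2 = np.asarray(delta, dtype=float)
        _validate_psd(r2, "condition-2 matrix")
    seeds = np.random.SeedSequence(seed).spawn(2)
    mask = mask if mask is not None else default_mask(r1.shape[0])
    c1 = MaskedTimeSeries(
        values=_draw(r1, t, np.random.default_rng(seeds[0]),
                     ar1=ar1, noise_sd=noise_sd),
        mask=mask, tr_seconds=tr_seconds, affine=np.eye(4))
    c2 = MaskedTimeSeries(
        values=_draw(r2, t, np.random.default_rng(seeds[1]),
                     ar1=ar1, noise_sd=noise_sd),
        mask=mask, tr_seconds=tr_seconds, affine=np.eye(4))
    return PairedTimeSeries(cond1=c1, cond2=c2)


def simulate_scenario(scenario: PairedScenario, t: int, seed: int,
                      **kwargs) -> PairedTimeSeries:
    """Sample a paired session from a :class:`PairedScenario`."""
    return simulate_paired(scenario.r1, scenario.r2, t, seed, **kwargs)


def weibull_difference_sample(alpha: float, beta: float, n: int,
                              sign_mix: float = 1.0, seed: int = 0):
    """Signed correlation differences with |D| i.i.d. Weibull(alpha, beta).

    Values are clipped to [0, 2]; the clip count is returned alongside.
    ``sign_mix`` is the fraction of positive differences.  Returns
    ``(d, n_clipped)``.
    """
    if alpha <= 0 or beta <= 0:
        raise ValueError("alpha and beta must be positive")
    if n < 100:
        raise ValueError("need n >= 100 draws")
    if not 0.0 <= sign_mix <= 1.0:
        raise ValueError("sign_mix must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    mag = alpha * rng.weibull(beta, size=n)
    n_clipped = int((mag > 2.0).sum())
    mag = np.clip(mag, 0.0, 2.0)
    signs = np.where(rng.random(n) < sign_mix, 1.0, -1.0)
    return mag * signs, n_clipped
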