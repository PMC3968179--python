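"""Nuisance regression, temporal/spatial smoothing, and motion summaries.

The nuisance design follows the standard resting-state recipe: intercept,
centered linear and quadratic drift, six rigid-body motion parameters, and
mean CSF and white-matter signals (11 columns).  The global signal is *not*
included; callers who want it must append it explicitly.

Temporal smoothing uses a unit-sum Gaussian kernel whose transfer function
crosses 0.5 at the requested cutoff frequency; spatial smoothing is an
isotropic Gaussian of a given FWHM, renormalized within the mask.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy import ndimage

from .volume_io import BrainMask, MaskedTimeSeries, ScalarMap

__all__ = [
    "MotionTrace",
    "NuisanceDesign",
    "build_nuisance",
    "regress_nuisance",
    "temporal_smooth",
    "spatial_smooth",
    "mean_fd",
]

#: column order of the default nuisance design
DESIGN_LABELS = (
    "intercept", "drift_linear", "drift_quadratic",
    "motion_tx", "motion_ty", "motion_tz",
    "motion_rx", "motion_ry", "motion_rz",
    "mean_csf", "mean_wm",
)

#: head-radius (mm) used to convert rotations to arc displacement
FD_SPHERE_RADIUS_MM = 50.0


@dataclasses.dataclass
class MotionTrace:
    """Six rigid-body motion parameters per frame."""

    translations_mm: np.ndarray   # T x 3
    rotations_rad: np.ndarray     # T x 3

    def __post_init__(self) -> None:
        self.translations_mm = np.atleast_2d(
            np.asarray(self.translations_mm, dtype=float))
        self.rotations_rad = np.atleast_2d(
            np.asarray(self.rotations_rad, dtype=float))
        if self.translations_mm.shape != self.rotations_rad.shape or \
                self.translations_mm.shape[1] != 3:
            raise ValueError("motion trace must be T x 3 + T x 3")

    @classmethod
    def from_array(cls, arr: np.ndarray) -> "MotionTrace":
        """Build from a T x 6 array (3 translations then 3 rotations)."""
        arr = np.atleast_2d(np.asarray(arr, dtype=float))
        return cls(arr[:, :3], arr[:, 3:6])

    @property
    def n_frames(self) -> int:
        return self.translations_mm.shape[0]


@dataclasses.dataclass
class NuisanceDesign:
    """A T x K design of covariates of no interest."""

    matrix: np.ndarray
    column_labels: tuple
    degenerate: tuple = ()   # labels of constant/all-zero non-intercept cols

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if self.matrix.ndim != 2 or \
                self.matrix.shape[1] != len(self.column_labels):
            raise ValueError("design/labels mismatch")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("non-finite design entries")

    def retained(self) -> np.ndarray:
        """The design with degenerate (constant non-intercept) columns
        dropped."""
        keep = [i for i, lab in enumerate(self.column_labels)
                if lab not in self.degenerate]
        return self.matrix[:, keep]


def build_nuisance(motion: MotionTrace, csf_ts: np.ndarray,
                   wm_ts: np.ndarray) -> NuisanceDesign:
    """Assemble the 11-column nuisance design.

    Drift columns are centered polynomials of frame index (hence orthogonal
    to the intercept).  Constant or all-zero motion/CSF/WM columns are
    flagged as degenerate and later dropped with a warning.
    """
    t = motion.n_frames
    if len(csf_ts) != t or len(wm_ts) != t:
        raise ValueError("CSF/WM series length does not match motion trace")
    idx = np.arange(t, dtype=float)
    lin = idx - idx.mean()
    quad = lin ** 2
    quad -= quad.mean()
    cols = [np.ones(t), lin, quad,
            *motion.translations_mm.T, *motion.rotations_rad.T,
            np.asarray(csf_ts, dtype=float), np.asarray(wm_ts, dtype=float)]
    mat = np.column_stack(cols)
    degenerate = tuple(
        lab for i, lab in enumerate(DESIGN_LABELS)
        if i > 0 and np.ptp(mat[:, i]) == 0.0
    )
    if degenerate:
        warnings.warn(f"degenerate nuisance columns flagged: {degenerate}",
                      stacklevel=2)
    return NuisanceDesign(matrix=mat, column_labels=DESIGN_LABELS,
                          degenerate=degenerate)


def regress_nuisance(ts: MaskedTimeSeries,
                     design: NuisanceDesign) -> MaskedTimeSeries:
    """Replace every voxel course by its least-squares residual on the
    design.  Residuals are orthogonal to every retained column."""
    x = design.retained()
    if x.shape[0] != ts.n_frames:
        raise ValueError("design frame count does not match series")
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise ValueError("nuisance design is rank-deficient after "
                         "degenerate-column drop")
    # residual = y - X (X^+ y), computed via QR for stability
    q, _ = np.linalg.qr(x)
    resid = ts.values - (ts.values @ q) @ q.T
    return MaskedTimeSeries(values=resid, mask=ts.mask,
                            tr_seconds=ts.tr_seconds, affine=ts.affine)


def _temporal_sigma_frames(cutoff_hz: float, tr_seconds: float) -> float:
    # Gaussian transfer exp(-2 pi^2 sigma_t^2 f^2) = 0.5 at f = cutoff
    sigma_seconds = np.sqrt(np.log(2.0) / 2.0) / (np.pi * cutoff_hz)
    return sigma_seconds / tr_seconds


def temporal_smooth(ts: MaskedTimeSeries,
                    cutoff_hz: float = 0.12) -> MaskedTimeSeries:
    """Low-pass each voxel course with a unit-sum Gaussian kernel.

    The kernel width is set so the (continuous) Gaussian transfer function
    equals 0.5 at ``cutoff_hz``; boundaries use reflect padding.
    """
    nyquist = 0.5 / ts.tr_seconds
    if cutoff_hz >= nyquist:
        raise ValueError(
            f"cutoff {cutoff_hz} Hz is at or above Nyquist {nyquist} Hz")
    if cutoff_hz <= 0:
        raise ValueError("cutoff must be positive")
    sigma = _temporal_sigma_frames(cutoff_hz, ts.tr_seconds)
    smoothed = ndimage.gaussian_filter1d(ts.values, sigma=sigma, axis=1,
                                         mode="reflect")
    return MaskedTimeSeries(values=smoothed, mask=ts.mask,
                            tr_seconds=ts.tr_seconds, affine=ts.affine)


def temporal_transfer(cutoff_hz: float, tr_seconds: float,
                      freq_hz: np.ndarray) -> np.ndarray:
    """Amplitude response of the discrete smoothing kernel at ``freq_hz``.

    Numerical oracle for the attenuation of :func:`temporal_smooth`.
    """
    sigma = _temporal_sigma_frames(cutoff_hz, tr_seconds)
    radius = int(4.0 * sigma + 0.5)
    k = np.arange(-radius, radius + 1)
    w = np.exp(-0.5 * (k / sigma) ** 2)
    w /= w.sum()
    freq_hz = np.atleast_1d(np.asarray(freq_hz, dtype=float))
    omega = 2.0 * np.pi * freq_hz[:, None] * tr_seconds
    return np.abs((w[None, :] * np.cos(omega * k[None, :])).sum(axis=1))


def spatial_smooth(smap: ScalarMap, fwhm_mm: float = 6.0,
                   voxel_size_mm=None) -> ScalarMap:
    """Isotropic Gaussian smoothing of a map, renormalized within the mask.

    Out-of-mask voxels contribute nothing: the map is smoothed as
    ``G*(m.v) / G*m`` where ``m`` is the mask indicator, so a constant map
    stays constant inside the mask.
    """
    if fwhm_mm < 0:
        raise ValueError("FWHM must be nonnegative")
    if fwhm_mm == 0:
        return ScalarMap(values=smap.values.copy(), mask=smap.mask,
                         metric_label=smap.metric_label)
    if voxel_size_mm is None:
        voxel_size_mm = np.ones(3)
    voxel_size_mm = np.broadcast_to(np.asarray(voxel_size_mm, float), (3,))
    sigma_vox = (fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0)))) / voxel_size_mm
    m = smap.mask.labels.astype(np.float64)
    num = ndimage.gaussian_filter(smap.values * m, sigma=sigma_vox)
    den = ndimage.gaussian_filter(m, sigma=sigma_vox)
    out = np.zeros_like(num)
    inside = smap.mask.labels
    out[inside] = num[inside] / den[inside]
    return ScalarMap(values=out, mask=smap.mask,
                     metric_label=smap.metric_label)


def mean_fd(motion: MotionTrace, include_rotations: bool = True,
            sphere_radius_mm: float = FD_SPHERE_RADIUS_MM) -> float:
    """Mean frame-to-frame displacement (mm).

    Per frame transition, the Euclidean norm of the translation difference;
    rotations are converted to arc displacement on a ``sphere_radius_mm``
    sphere and added in quadrature (disable with
    ``include_rotations=False``).
    """
    if motion.n_frames < 2:
        raise ValueError("need at least 2 frames")
    dt = np.diff(motion.translations_mm, axis=0)
    sq = (dt ** 2).sum(axis=1)
    if include_rotations:
        dr = np.diff(motion.rotations_rad, axis=0) * sphere_radius_mm
        sq = sq + (dr ** 2).sum(axis=1)
    return float(np.sqrt(sq).mean())
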