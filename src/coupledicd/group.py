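"""Group-level statistics for voxel maps and atlas matrices.

Implements the Top Percent single-group hub detector (effect size =
mean/SD, top-percentile selection, cluster-extent filter), voxelwise
two-sample/paired t-tests with Benjamini-Hochberg FDR, a permutation
estimate of the null maximum-cluster-size distribution (a self-contained
stand-in for Monte-Carlo cluster correction), atlas parcellation with
edgewise matrix tests, and seed-to-whole-brain Fisher-z maps.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy import ndimage, stats
from statsmodels.stats.multitest import multipletests

from . import metrics
from .volume_io import BrainMask, MaskedTimeSeries, ScalarMap, scatter_map

__all__ = [
    "GroupMaps",
    "ParcellationAtlas",
    "ConnectivityMatrix",
    "SeedROI",
    "effect_size_map",
    "top_percent",
    "voxelwise_ttest",
    "fdr_correct",
    "cluster_filter",
    "permutation_max_cluster",
    "parcellate",
    "connectivity_matrix",
    "edgewise_ttest",
    "seed_map",
]

#: face-adjacency (6-connectivity) structure for cluster labeling
CONNECTIVITY_6 = ndimage.generate_binary_structure(3, 1)
#: clip applied to |r| before the Fisher transform
FISHER_CLIP = 1.0 - 1e-7


@dataclasses.dataclass
class GroupMaps:
    """Per-subject scalar maps on a common mask."""

    maps: list
    group_label: str = ""

    def __post_init__(self) -> None:
        if not self.maps:
            raise ValueError("empty group")
        m0 = self.maps[0].mask.labels
        for m in self.maps[1:]:
            if not np.array_equal(m.mask.labels, m0):
                raise ValueError("maps do not share a mask")

    @property
    def mask(self) -> BrainMask:
        return self.maps[0].mask

    @property
    def n(self) -> int:
        return len(self.maps)

    def stacked(self) -> np.ndarray:
        """n_subjects x V matrix of masked values."""
        return np.stack([m.masked_values() for m in self.maps])


@dataclasses.dataclass
class ParcellationAtlas:
    """Integer-labeled parcellation; 0 is background."""

    labels: np.ndarray
    n_nodes: int

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("atlas must be 3-D")
        mx = int(self.labels.max())
        if mx > self.n_nodes:
            raise ValueError("atlas labels exceed n_nodes")


@dataclasses.dataclass
class ConnectivityMatrix:
    """N x N symmetric Fisher-z matrix; diagonal excluded (NaN)."""

    z: np.ndarray

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=np.float64)
        if self.z.ndim != 2 or self.z.shape[0] != self.z.shape[1]:
            raise ValueError("matrix must be square")

    @property
    def n_nodes(self) -> int:
        return self.z.shape[0]


@dataclasses.dataclass
class SeedROI:
    """A seed region: nonempty subset of the gray-matter mask."""

    mask: BrainMask
    name: str = "seed"


# ---------------------------------------------------------------------------
# Top Percent


def effect_size_map(group: GroupMaps) -> tuple:
    """Within-group effect size mean/SD per voxel.

    Returns ``(effect_values, valid)`` over mask voxels, where ``valid``
    flags voxels with SD > 0; invalid voxels get effect 0 and a warning.
    """
    data = group.stacked()
    if group.n < 2:
        raise ValueError("need n >= 2 maps for an SD")
    mean = data.mean(axis=0)
    sd = data.std(axis=0, ddof=1)
    valid = sd > 0
    if not valid.all():
        warnings.warn(f"{int((~valid).sum())} zero-SD voxels excluded from "
                      "effect size", stacklevel=2)
    eff = np.zeros_like(mean)
    eff[valid] = mean[valid] / sd[valid]
    return eff, valid


def cluster_filter(selected: np.ndarray, mask: BrainMask,
                   cluster_min: int) -> np.ndarray:
    """Drop face-connected components smaller than ``cluster_min`` voxels.

    ``selected`` is a boolean vector over mask voxels (linearization
    order); the result is the filtered boolean vector.
    """
    grid = np.zeros(mask.labels.shape, dtype=bool)
    grid.ravel()[mask.linear_indices()[selected]] = True
    labeled, n = ndimage.label(grid, structure=CONNECTIVITY_6)
    if n == 0:
        return np.zeros_like(selected)
    sizes = np.bincount(labeled.ravel())
    keep_labels = np.flatnonzero(sizes >= cluster_min)
    keep_labels = keep_labels[keep_labels > 0]
    kept = np.isin(labeled, keep_labels)
    return kept.ravel()[mask.linear_indices()]


def top_percent(group: GroupMaps, percent: float = 15.0,
                cluster_min: int = 50) -> ScalarMap:
    """Top Percent hub detection.

    Effect size mean/SD per voxel; the voxels at or above the nearest-rank
    (100-percent)th percentile are selected (ties at the cutoff included),
    then components smaller than ``cluster_min`` (6-connectivity) are
    dropped.  Returns a binary map.
    """
    eff, valid = effect_size_map(group)
    sel = np.zeros(eff.size, dtype=bool)
    if valid.any():
        vals = eff[valid]
        k = int(np.ceil(percent / 100.0 * vals.size))
        if k >= 1:
            cutoff = np.sort(vals)[::-1][k - 1]   # k-th largest, nearest rank
            sel[valid] = eff[valid] >= cutoff
    sel = cluster_filter(sel, group.mask, cluster_min)
    return scatter_map(sel.astype(float), group.mask,
                       f"top{percent:g}pct")


# ---------------------------------------------------------------------------
# t-tests and FDR


def _ttest_arrays(a: np.ndarray, b: np.ndarray, paired: bool):
    if paired:
        if a.shape[0] != b.shape[0]:
            raise ValueError("paired test needs equal group sizes")
        t, p = stats.ttest_rel(a, b, axis=0)
    else:
        t, p = stats.ttest_ind(a, b, axis=0, equal_var=False)
    # zero-difference degenerate voxels: t = 0, p = 1 by convention
    t = np.where(np.isnan(t), 0.0, t)
    p = np.where(np.isnan(p), 1.0, p)
    return t, p


def voxelwise_ttest(group_a: GroupMaps, group_b: GroupMaps,
                    paired: bool = False) -> tuple:
    """Per-voxel two-sided t-test (Welch for unpaired; paired optional).

    Returns ``(t_map, p_map)``.  Degenerate voxels (zero difference
    everywhere) report t = 0, p = 1.
    """
    if group_a.n < 2 or group_b.n < 2:
        raise ValueError("need n >= 2 per group")
    if not np.array_equal(group_a.mask.labels, group_b.mask.labels):
        raise ValueError("groups on different masks")
    t, p = _ttest_arrays(group_a.stacked(), group_b.stacked(), paired)
    return (scatter_map(t, group_a.mask, "t"),
            scatter_map(p, group_a.mask, "p"))


def fdr_correct(p_values: np.ndarray, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection flags at level ``q``."""
    p = np.asarray(p_values, dtype=float).ravel()
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, _, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return reject


def permutation_max_cluster(group_a: GroupMaps, group_b: GroupMaps,
                            paired: bool = True, alpha_voxel: float = 0.05,
                            n_perm: int = 1000, seed: int = 0) -> np.ndarray:
    """Null distribution of the maximum supra-threshold cluster size.

    Sign-flipping (paired) or label permutation (unpaired) of the subject
    maps; per permutation, voxels with p < ``alpha_voxel`` are clustered
    (6-connectivity) and the largest component size recorded.  The returned
    vector's empirical quantiles give cluster-extent thresholds.
    """
    rng = np.random.default_rng(seed)
    a, b = group_a.stacked(), group_b.stacked()
    mask = group_a.mask
    out = np.empty(n_perm, dtype=np.int64)
    if paired:
        d = b - a
        for i in range(n_perm):
            signs = rng.choice([-1.0, 1.0], size=d.shape[0])[:, None]
            t, p = stats.ttest_1samp(d * signs, 0.0, axis=0)
            p = np.where(np.isnan(p), 1.0, p)
            out[i] = _max_cluster_size(p < alpha_voxel, mask)
    else:
        both = np.concatenate([a, b], axis=0)
        na = a.shape[0]
        idx = np.arange(both.shape[0])
        for i in range(n_perm):
            perm = rng.permutation(idx)
            t, p = _ttest_arrays(both[perm[:na]], both[perm[na:]], False)
            out[i] = _max_cluster_size(p < alpha_voxel, mask)
    return out


def _max_cluster_size(selected: np.ndarray, mask: BrainMask) -> int:
    grid = np.zeros(mask.labels.shape, dtype=bool)
    grid.ravel()[mask.linear_indices()[selected]] = True
    labeled, n = ndimage.label(grid, structure=CONNECTIVITY_6)
    if n == 0:
        return 0
    return int(np.bincount(labeled.ravel())[1:].max())


# ---------------------------------------------------------------------------
# matrix connectivity


def parcellate(ts: MaskedTimeSeries, atlas: ParcellationAtlas) -> np.ndarray:
    """Node time courses: mean over member voxels, per atlas node.

    Returns an N x T matrix.  Every node must overlap the mask.
    """
    if atlas.labels.shape != ts.mask.labels.shape:
        raise ValueError("atlas grid does not match mask grid")
    node_of_voxel = atlas.labels.ravel()[ts.mask.linear_indices()]
    out = np.zeros((atlas.n_nodes, ts.n_frames))
    for node in range(1, atlas.n_nodes + 1):
        member = node_of_voxel == node
        if not member.any():
            raise ValueError(f"atlas node {node} has no voxels in the mask")
        out[node - 1] = ts.values[member].mean(axis=0)
    return out


def connectivity_matrix(node_courses: np.ndarray) -> ConnectivityMatrix:
    """Fisher-z node-by-node matrix: z[i, j] = atanh(r(i, j)).

    Correlations with |r| at 1 are clipped to 1 - 1e-7 before the
    transform (logged).  The diagonal is NaN (excluded).
    """
    r = np.corrcoef(node_courses)
    r = (r + r.T) / 2.0          # enforce exact symmetry (BLAS rounding)
    at_limit = np.abs(r) > FISHER_CLIP
    np.fill_diagonal(at_limit, False)
    if at_limit.any():
        warnings.warn(f"{int(at_limit.sum())} correlations clipped to "
                      f"+/-{FISHER_CLIP} before Fisher transform",
                      stacklevel=2)
    z = np.arctanh(np.clip(r, -FISHER_CLIP, FISHER_CLIP))
    np.fill_diagonal(z, np.nan)
    return ConnectivityMatrix(z=z)


def edgewise_ttest(matrices_a: list, matrices_b: list,
                   q: float = 0.05, paired: bool = False,
                   return_p: bool = False) -> tuple:
    """Edgewise two-sided t-tests over the upper triangle with BH-FDR.

    Returns ``(edge_flags, node_counts)``: an N x N symmetric boolean
    matrix of significant edges and the per-node count of significant
    edges (node sizes in the usual glass-brain rendering; counts sum to
    twice the edge count).  ``return_p`` appends the uncorrected
    upper-triangle p-values (for calibration studies).
    """
    if len(matrices_a) < 2 or len(matrices_b) < 2:
        raise ValueError("need >= 2 matrices per group")
    n = matrices_a[0].n_nodes
    if any(m.n_nodes != n for m in matrices_a + matrices_b):
        raise ValueError("matrix size mismatch")
    iu = np.triu_indices(n, k=1)
    a = np.stack([m.z[iu] for m in matrices_a])
    b = np.stack([m.z[iu] for m in matrices_b])
    _, p = _ttest_arrays(a, b, paired)
    reject = fdr_correct(p, q=q)
    flags = np.zeros((n, n), dtype=bool)
    flags[iu] = reject
    flags |= flags.T
    node_counts = flags.sum(axis=0).astype(np.int64)
    if return_p:
        return flags, node_counts, p
    return flags, node_counts


# ---------------------------------------------------------------------------
# seed-based connectivity


def seed_map(ts: MaskedTimeSeries, seed: SeedROI) -> ScalarMap:
    """Seed-to-whole-brain Fisher-z map.

    The seed course is the mean over the ROI's voxels; it is correlated
    with every masked voxel and atanh-transformed (|r| clipped at
    1 - 1e-7).  Voxels inside the seed are included like any other.
    """
    in_mask = ts.mask.labels
    if not seed.mask.labels[in_mask].any():
        raise ValueError("seed does not overlap the gray-matter mask")
    member = seed.mask.labels.ravel()[ts.mask.linear_indices()]
    course = ts.values[member].mean(axis=0)
    course = course - course.mean()
    norm = np.linalg.norm(course)
    if norm == 0:
        raise ValueError("seed course is constant")
    z, _ = metrics.standardize_rows(ts.values)
    r = z @ (course / norm)
    z_vals = np.arctanh(np.clip(r, -FISHER_CLIP, FISHER_CLIP))
    return scatter_map(z_vals, ts.mask, f"seed_{seed.name}_z")
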