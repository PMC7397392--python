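"""Group-level voxel-wise inference on zfALFF maps.

Two analyses, both permutation-based in the SnPM tradition:

* **Group contrast** — a pooled-variance two-sample t map (contrast
  A - B), thresholded at the t quantile of a cluster-forming p (default
  0.001 one-sided), with cluster-extent family-wise error correction
  against the permutation null distribution of the maximum
  suprathreshold cluster size under random relabelling of the two
  groups. Enumeration is exhaustive whenever the number of distinct
  relabellings does not exceed ``n_perm``; the observed labelling is
  always a member of the null, so no corrected p can be exactly 0.

* **Covariate regression** — a per-voxel simple-regression t statistic
  of map value on a subject-level covariate (the SCR delta index),
  with voxel-level FWE control from the permutation null of the
  map-wide maximum absolute t under covariate shuffling (two-sided).

Cluster connectivity follows the SPM convention of 18-neighbour
adjacency by default (6 and 26 are available).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import ndimage
from scipy import stats as sps

from .io import VolumeMap

_CONNECTIVITY_RANK = {6: 1, 18: 2, 26: 3}


@dataclass
class StatMap:
    """A voxel-statistic map with its degrees of freedom."""

    map: VolumeMap
    df: int
    kind: str  # two_sample_t | regression_t


@dataclass
class ClusterRecord:
    """One suprathreshold connected component."""

    cluster_id: int
    extent: int
    peak_stat: float
    peak_world: tuple
    p_fwe: float | None = None


@dataclass
class PermutationConfig:
    n_perm: int = 5000
    seed: int = 0
    connectivity: int = 18
    cluster_forming_p: float = 0.001
    fwe_alpha: float = 0.05

    def __post_init__(self):
        if self.n_perm < 100:
            raise ValueError("n_perm must be >= 100")
        if self.connectivity not in _CONNECTIVITY_RANK:
            raise ValueError("connectivity must be one of 6, 18, 26")
        if not 0 < self.cluster_forming_p <= 0.05:
            raise ValueError("cluster_forming_p must be in (0, 0.05]")


def _resolve_mask(mask, shape) -> np.ndarray:
    if isinstance(mask, VolumeMap):
        msk = mask.mask if mask.mask is not None else mask.data.astype(bool)
    else:
        msk = np.asarray(mask, dtype=bool)
    if msk.shape != tuple(shape):
        raise ValueError("mask shape does not match map shape")
    return msk


def _stack(maps: list) -> tuple[np.ndarray, np.ndarray]:
    """Stack VolumeMaps into an (n_subject, x, y, z) array after
    checking shapes and affines agree."""
    ref = maps[0]
    for m in maps[1:]:
        if m.data.shape != ref.data.shape:
            raise ValueError("maps differ in shape")
        if not np.allclose(m.affine, ref.affine):
            raise ValueError("maps differ in affine")
    return np.stack([m.data for m in maps]), ref.affine


def _t_two_sample(xa: np.ndarray, xb: np.ndarray) -> np.ndarray:
    """Pooled-variance two-sample t, vectorised over the last axis.
    xa, xb: (n, V). Zero-variance voxels yield t = 0."""
    na, nb = xa.shape[0], xb.shape[0]
    ma = xa.mean(axis=0)
    mb = xb.mean(axis=0)
    ssa = ((xa - ma) ** 2).sum(axis=0)
    ssb = ((xb - mb) ** 2).sum(axis=0)
    df = na + nb - 2
    sp2 = (ssa + ssb) / df
    se = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, (ma - mb) / se, 0.0)
    return t


def two_sample_t_map(group_a: list, group_b: list, mask) -> StatMap:
    """Voxel-wise pooled-variance two-sample t map, contrast A - B."""
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs at least 2 maps")
    xa, affine = _stack(list(group_a))
    xb, affine_b = _stack(list(group_b))
    if xa.shape[1:] != xb.shape[1:] or not np.allclose(affine, affine_b):
        raise ValueError("groups differ in shape or affine")
    msk = _resolve_mask(mask, xa.shape[1:])
    t = np.zeros(xa.shape[1:])
    t[msk] = _t_two_sample(xa[:, msk], xb[:, msk])
    df = xa.shape[0] + xb.shape[0] - 2
    return StatMap(map=VolumeMap(data=t, affine=affine, mask=msk), df=df,
                   kind="two_sample_t")


def label_clusters(stat: StatMap, threshold: float, connectivity: int = 18) -> list:
    """Connected components of {stat > threshold}.

    Returns one ClusterRecord per component (p_fwe unset), ordered by
    decreasing extent. Peak coordinates are world (RAS) mm via the
    affine.
    """
    if not threshold > 0:
        raise ValueError("threshold must be > 0")
    data = stat.map.data
    supra = data > threshold
    if stat.map.mask is not None:
        supra &= stat.map.mask
    structure = ndimage.generate_binary_structure(3, _CONNECTIVITY_RANK[connectivity])
    labels, n = ndimage.label(supra, structure=structure)
    records = []
    for cid in range(1, n + 1):
        idx = np.argwhere(labels == cid)
        vals = data[labels == cid]
        peak_local = idx[np.argmax(vals)]
        records.append(
            ClusterRecord(
                cluster_id=cid,
                extent=int(idx.shape[0]),
                peak_stat=float(vals.max()),
                peak_world=tuple(stat.map.voxel_to_world(peak_local)),
            )
        )
    records.sort(key=lambda r: r.extent, reverse=True)
    return records


def _max_cluster_extent(supra: np.ndarray, structure: np.ndarray) -> int:
    labels, n = ndimage.label(supra, structure=structure)
    if n == 0:
        return 0
    return int(np.bincount(labels.ravel())[1:].max())


def _relabellings(n_total: int, n_a: int, cfg: PermutationConfig):
    """Index sets for group A under each permutation. Exhaustive when
    C(n_total, n_a) <= n_perm, else seeded random draws; the observed
    labelling (first n_a indices) always comes first."""
    n_comb = math.comb(n_total, n_a)
    if n_comb <= cfg.n_perm:
        if n_comb < 100:
            warnings.warn(
                f"only {n_comb} distinct relabellings; corrected p-values are coarse",
                stacklevel=3,
            )
        return [np.array(c) for c in combinations(range(n_total), n_a)], True
    rng = np.random.default_rng(cfg.seed)
    observed = np.arange(n_a)
    draws = [observed]
    for _ in range(cfg.n_perm - 1):
        draws.append(rng.permutation(n_total)[:n_a])
    return draws, False


def cluster_fwe_permutation(group_a: list, group_b: list, mask,
                            cfg: PermutationConfig):
    """Cluster-extent FWE-corrected group contrast (A - B, one-sided).

    The cluster-forming threshold is the upper-tail t quantile at
    ``cfg.cluster_forming_p``. Each observed cluster's corrected p is
    the proportion of permutations whose maximum suprathreshold cluster
    extent is at least the observed extent.

    Returns ``(StatMap, clusters, info)`` where ``info`` records the
    threshold, permutation count, mode, and the null distribution of
    the map-wide maximum t (usable for voxel-level FWE).
    """
    stat = two_sample_t_map(group_a, group_b, mask)
    msk = stat.map.mask
    threshold = float(sps.t.ppf(1.0 - cfg.cluster_forming_p, stat.df))
    clusters = label_clusters(stat, threshold, cfg.connectivity)

    xa, _ = _stack(list(group_a))
    xb, _ = _stack(list(group_b))
    x = np.concatenate([xa[:, msk], xb[:, msk]], axis=0)  # (N, V)
    n_a, n_total = xa.shape[0], xa.shape[0] + xb.shape[0]
    structure = ndimage.generate_binary_structure(3, _CONNECTIVITY_RANK[cfg.connectivity])
    assignments, exhaustive = _relabellings(n_total, n_a, cfg)

    max_extents = np.empty(len(assignments), dtype=int)
    max_ts = np.empty(len(assignments))
    supra_vol = np.zeros(stat.map.data.shape, dtype=bool)
    for i, idx_a in enumerate(assignments):
        sel = np.zeros(n_total, dtype=bool)
        sel[idx_a] = True
        t = _t_two_sample(x[sel], x[~sel])
        max_ts[i] = t.max()
        supra_vol[msk] = t > threshold
        max_extents[i] = _max_cluster_extent(supra_vol, structure)
    for rec in clusters:
        rec.p_fwe = float(np.mean(max_extents >= rec.extent))
    info = {
        "cluster_forming_t": threshold,
        "n_perm": len(assignments),
        "exhaustive": exhaustive,
        "null_max_extent": max_extents,
        "null_max_t": max_ts,
    }
    return stat, clusters, info


def _t_regression(x: np.ndarray, cov: np.ndarray) -> np.ndarray:
    """Simple-regression t of each column of x (n, V) on cov (n,),
    df = n - 2. Zero-variance voxels yield t = 0."""
    n = cov.size
    c = cov - cov.mean()
    xc = x - x.mean(axis=0)
    sxx = (c**2).sum()
    sxy = c @ xc
    syy = (xc**2).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(syy > 0, sxy / np.sqrt(sxx * syy), 0.0)
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1e-300, 1.0 - r**2))
    return t


def regression_fwe_permutation(maps: list, covariate, mask, cfg: PermutationConfig):
    """Voxel-level FWE-corrected simple regression of maps on a
    subject covariate.

    The null distribution of the map-wide maximum |t| is built by
    permuting the covariate across subjects; a voxel is significant
    when the proportion of null maxima at or above its |t| is at most
    ``cfg.fwe_alpha``.

    Returns ``(StatMap, significant_mask, info)``.
    """
    covariate = np.asarray(covariate, dtype=float)
    x4, affine = _stack(list(maps))
    if covariate.size != x4.shape[0]:
        raise ValueError("one covariate value per map required")
    if np.ptp(covariate) == 0:
        raise ValueError("constant covariate")
    msk = _resolve_mask(mask, x4.shape[1:])
    x = x4[:, msk]
    t_obs = _t_regression(x, covariate)
    n = covariate.size

    rng = np.random.default_rng(cfg.seed)
    null_max = np.empty(cfg.n_perm)
    null_max[0] = np.abs(t_obs).max()  # observed ordering is permutation 0
    for i in range(1, cfg.n_perm):
        null_max[i] = np.abs(_t_regression(x, rng.permutation(covariate))).max()

    p_vox = (null_max[None, :] >= np.abs(t_obs)[:, None]).mean(axis=1)
    sig = np.zeros(x4.shape[1:], dtype=bool)
    sig[msk] = p_vox <= cfg.fwe_alpha
    t_map = np.zeros(x4.shape[1:])
    t_map[msk] = t_obs
    stat = StatMap(map=VolumeMap(data=t_map, affine=affine, mask=msk),
                   df=n - 2, kind="regression_t")
    info = {"null_max_abs_t": null_max, "n_perm": cfg.n_perm,
            "fwe_threshold": float(np.quantile(null_max, 1.0 - cfg.fwe_alpha))}
    return stat, sig, info


def extract_roi(maps: list, roi) -> np.ndarray:
    """Mean value inside a boolean ROI for each map."""
    roi_arr = roi.data.astype(bool) if isinstance(roi, VolumeMap) else np.asarray(roi, dtype=bool)
    if not roi_arr.any():
        raise ValueError("empty ROI")
    x, _ = _stack(list(maps))
    if roi_arr.shape != x.shape[1:]:
        raise ValueError("ROI shape does not match map shape")
    return x[:, roi_arr].mean(axis=1)


def roi_covariate_association(roi_values, covariate, sided: str = "one"):
    """Spearman correlation between per-subject ROI means and a
    covariate (one-tailed by default, testing a positive association)."""
    from .stats import spearman

    return spearman(roi_values, covariate, sided=sided)
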