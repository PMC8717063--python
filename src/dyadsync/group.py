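"""Second-level inference: t-maps, conjunctions and cluster-level FWE.

Group maps are voxelwise one-sample t-tests (contrast images against
zero) or Welch unequal-variance two-sample t-tests (real-pair vs
pseudo-pair Fisher-z maps, Satterthwaite degrees of freedom).  Family-wise
error is controlled at the cluster level: voxels above a height threshold
(p < 0.001 by default) are grouped into 26-connected clusters, and a
cluster's corrected p-value is the fraction of max-cluster-size statistics
— over sign-flip (one-sample) or group-label (two-sample) permutations —
at least as large as its size.  A Gaussian random-field approximation is
available as an alternative correction for users wanting the parametric
convention, with the usual caveats on small grids.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import comb, gamma as gamma_fn

import numpy as np
import pandas as pd
from scipy import ndimage, special, stats

#: 26-neighbourhood connectivity structure for cluster labeling.
CONNECTIVITY_26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class GroupTMap:
    t: np.ndarray                   # voxel map (flat)
    df: np.ndarray | float          # scalar or per-voxel degrees of freedom
    analysis: str = ""
    height_p: float = 0.001
    shape: tuple | None = None
    valid: np.ndarray | None = None # voxels with a defined statistic

    def volume(self) -> np.ndarray:
        if self.shape is None:
            raise ValueError("no grid shape recorded")
        return self.t.reshape(self.shape)


def one_sample_t(maps: np.ndarray, analysis: str = "",
                 shape: tuple | None = None) -> GroupTMap:
    """Voxelwise one-sample t against zero; df = n - 1.

    Zero-variance voxels are masked (t set to 0, flagged invalid).
    """
    M = np.atleast_2d(np.asarray(maps, dtype=float))
    n = M.shape[0]
    if n < 2:
        raise ValueError("need at least two images")
    mean = M.mean(axis=0)
    sd = M.std(axis=0, ddof=1)
    valid = sd > 0
    t = np.zeros_like(mean)
    t[valid] = mean[valid] / (sd[valid] / np.sqrt(n))
    return GroupTMap(t=t, df=float(n - 1), analysis=analysis, shape=shape,
                     valid=valid)


def welch_two_sample_t(x: np.ndarray, y: np.ndarray, analysis: str = "",
                       shape: tuple | None = None) -> GroupTMap:
    """Voxelwise Welch t (x minus y) with Satterthwaite df per voxel.

    Positive t means the first group (real pairs) exceeds the second
    (pseudo pairs).  Voxels with zero variance in both groups are masked.
    """
    X = np.atleast_2d(np.asarray(x, dtype=float))
    Y = np.atleast_2d(np.asarray(y, dtype=float))
    if X.shape[1] != Y.shape[1]:
        raise ValueError("group maps live on different grids")
    n1, n2 = X.shape[0], Y.shape[0]
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least two images per group")
    m1, m2 = X.mean(axis=0), Y.mean(axis=0)
    v1 = X.var(axis=0, ddof=1)
    v2 = Y.var(axis=0, ddof=1)
    se2 = v1 / n1 + v2 / n2
    valid = se2 > 0
    t = np.zeros_like(m1)
    df = np.full_like(m1, float(n1 + n2 - 2))
    t[valid] = (m1[valid] - m2[valid]) / np.sqrt(se2[valid])
    num = se2[valid] ** 2
    den = ((v1[valid] / n1) ** 2 / (n1 - 1)
           + (v2[valid] / n2) ** 2 / (n2 - 1))
    df[valid] = np.where(den > 0, num / np.maximum(den, 1e-300),
                         float(n1 + n2 - 2))
    return GroupTMap(t=t, df=df, analysis=analysis, shape=shape, valid=valid)


def suprathreshold(tmap: GroupTMap, height_p: float) -> np.ndarray:
    """One-sided height thresholding: voxels with p < ``height_p``."""
    t, df = tmap.t, tmap.df
    if np.isscalar(df) or np.ndim(df) == 0:
        above = t > stats.t.isf(height_p, float(df))
    else:
        above = special.stdtr(np.asarray(df), -t) < height_p
    if tmap.valid is not None:
        above = above & tmap.valid
    return above


def conjunction(maps, height_p: float = 0.001) -> np.ndarray:
    """Minimum-statistic conjunction over thresholded maps.

    A voxel passes iff every component map individually exceeds its
    height threshold — the intersection of the suprathreshold sets
    (conjunction of nulls at the component level).
    """
    maps = list(maps)
    if not maps:
        raise ValueError("conjunction of an empty map list")
    out = None
    for m in maps:
        above = suprathreshold(m, height_p)
        out = above if out is None else (out & above)
    return out


def label_clusters(binary: np.ndarray):
    """26-connected components of a 3D binary map -> (labels, sizes)."""
    labels, n = ndimage.label(binary, structure=CONNECTIVITY_26)
    sizes = np.bincount(labels.ravel(), minlength=n + 1)[1:]
    return labels, sizes


@dataclass
class ClusterTable:
    """Clusters above the height threshold, with permutation-corrected p."""

    clusters: pd.DataFrame          # cluster_id, n_voxels, peak_t, peak_ijk, p_fwe
    height_p: float
    alpha: float
    method: str
    n_perm: int | None = None
    null_max_sizes: np.ndarray | None = None

    def significant(self, alpha: float | None = None) -> pd.DataFrame:
        a = self.alpha if alpha is None else alpha
        return self.clusters[self.clusters["p_fwe"] <= a]

    @property
    def n_significant(self) -> int:
        return int(len(self.significant()))


def _observed_clusters(t_flat, above_flat, shape):
    labels, sizes = label_clusters(above_flat.reshape(shape))
    rows = []
    lab_flat = labels.ravel()
    for cid in np.argsort(sizes)[::-1]:
        vox = np.flatnonzero(lab_flat == cid + 1)
        peak = vox[np.argmax(t_flat[vox])]
        rows.append({"cluster_id": int(cid + 1),
                     "n_voxels": int(sizes[cid]),
                     "peak_t": float(t_flat[peak]),
                     "peak_i": int(peak // (shape[1] * shape[2])),
                     "peak_j": int((peak // shape[2]) % shape[1]),
                     "peak_k": int(peak % shape[2])})
    rows.sort(key=lambda r: (-r["n_voxels"], -r["peak_t"]))
    return rows


def _check_n_distinct(test, n_units, n1=None):
    n_distinct = 2 ** n_units if test == "one_sample" else comb(n_units, n1)
    if n_distinct < 10:
        raise ValueError(
            f"only {n_distinct} distinct permutations available; "
            "need at least 10 for a meaningful permutation test")


def cluster_fwe(data, shape, test: str = "one_sample",
                height_p: float = 0.001, alpha: float = 0.05,
                n_perm: int = 1000, seed: int = 0,
                method: str = "permutation") -> ClusterTable:
    """Cluster-level FWE correction of a group t-map.

    Parameters
    ----------
    data
        For ``test="one_sample"``: the (units, voxels) stack of images.
        For ``test="welch"``: a ``(real_maps, pseudo_maps)`` tuple.
    shape
        3D grid shape of the maps.
    method
        ``"permutation"`` (default): sign-flip or group-label
        permutations of the unit-level data, corrected p = proportion of
        permutation max-cluster-sizes >= the observed size (the observed
        labeling is included as the first permutation, so the smallest
        attainable p is 1 / n_perm).  ``"rft"``: Gaussian random-field
        approximation from estimated smoothness.
    """
    if test not in ("one_sample", "welch"):
        raise ValueError("test must be 'one_sample' or 'welch'")
    if method == "rft":
        return cluster_fwe_rft(data, shape, test=test, height_p=height_p,
                               alpha=alpha)
    if method != "permutation":
        raise ValueError("method must be 'permutation' or 'rft'")
    shape = tuple(shape)
    if test == "one_sample":
        M = np.atleast_2d(np.asarray(data, dtype=float))
        tmap = one_sample_t(M, shape=shape)
        _check_n_distinct(test, M.shape[0])
    else:
        X = np.atleast_2d(np.asarray(data[0], dtype=float))
        Y = np.atleast_2d(np.asarray(data[1], dtype=float))
        tmap = welch_two_sample_t(X, Y, shape=shape)
        _check_n_distinct(test, X.shape[0] + Y.shape[0], X.shape[0])

    above = suprathreshold(tmap, height_p)
    rows = _observed_clusters(tmap.t, above, shape)

    rng = np.random.default_rng(seed)
    null_max = np.empty(n_perm)
    if test == "one_sample":
        null_max[:] = _perm_one_sample(M, shape, height_p, n_perm, rng)
    else:
        null_max[:] = _perm_welch(X, Y, shape, height_p, n_perm, rng)

    for r in rows:
        r["p_fwe"] = float(np.mean(null_max >= r["n_voxels"]))
    table = pd.DataFrame(rows, columns=["cluster_id", "n_voxels", "peak_t",
                                        "peak_i", "peak_j", "peak_k", "p_fwe"])
    return ClusterTable(clusters=table, height_p=height_p, alpha=alpha,
                        method="permutation", n_perm=n_perm,
                        null_max_sizes=null_max)


def _max_cluster_size(above_flat, shape):
    _, sizes = label_clusters(above_flat.reshape(shape))
    return int(sizes.max()) if sizes.size else 0


def _perm_one_sample(M, shape, height_p, n_perm, rng):
    """Sign-flip permutation max cluster sizes (identity flip first)."""
    n, V = M.shape
    tcrit = stats.t.isf(height_p, n - 1)
    ss_tot = (M * M).sum(axis=0)
    out = np.empty(n_perm)
    for k in range(n_perm):
        signs = (np.ones(n) if k == 0
                 else rng.choice([-1.0, 1.0], size=n))
        mean = signs @ M / n
        var = np.maximum(ss_tot / n - mean * mean, 0.0) * (n / (n - 1.0))
        with np.errstate(divide="ignore", invalid="ignore"):
            t = mean / np.sqrt(var / n)
        above = np.isfinite(t) & (t > tcrit)
        out[k] = _max_cluster_size(above, shape)
    return out


def _perm_welch(X, Y, shape, height_p, n_perm, rng):
    """Group-label permutation max cluster sizes (observed labels first)."""
    n1, n2 = X.shape[0], Y.shape[0]
    C = np.vstack([X, Y])
    C2 = C * C
    s_tot, ss_tot = C.sum(axis=0), C2.sum(axis=0)
    out = np.empty(n_perm)
    for k in range(n_perm):
        idx1 = (np.arange(n1) if k == 0
                else rng.choice(n1 + n2, size=n1, replace=False))
        s1 = C[idx1].sum(axis=0)
        ss1 = C2[idx1].sum(axis=0)
        m1 = s1 / n1
        m2 = (s_tot - s1) / n2
        v1 = np.maximum(ss1 - n1 * m1 * m1, 0.0) / (n1 - 1)
        v2 = np.maximum((ss_tot - ss1) - n2 * m2 * m2, 0.0) / (n2 - 1)
        se2 = v1 / n1 + v2 / n2
        valid = se2 > 0
        t = np.zeros_like(m1)
        t[valid] = (m1[valid] - m2[valid]) / np.sqrt(se2[valid])
        num = se2 ** 2
        den = (v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1)
        df = np.where(den > 0, num / np.maximum(den, 1e-300), n1 + n2 - 2)
        p = special.stdtr(df, -t)
        above = valid & (p < height_p)
        out[k] = _max_cluster_size(above, shape)
    return out


# ---------------------------------------------------------------------------
# Gaussian random-field approximation (optional correction method)
# ---------------------------------------------------------------------------

def estimate_fwhm(unit_maps: np.ndarray, shape) -> np.ndarray:
    """Per-axis smoothness (FWHM in voxels) of standardized unit maps."""
    M = np.atleast_2d(np.asarray(unit_maps, dtype=float))
    resid = M - M.mean(axis=0)
    sd = resid.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    eps = (resid / sd).reshape((-1,) + tuple(shape))
    fwhm = np.empty(3)
    for ax in range(3):
        d = np.diff(eps, axis=ax + 1)
        msq = float(np.mean(d * d))
        fwhm[ax] = (np.sqrt(4.0 * np.log(2.0) / msq) if msq > 0 else np.inf)
    return fwhm


def _rft_cluster_p(tmap, rows, shape, height_p):
    """Expected-cluster-size Gaussian-field p-values (stationary, 3D)."""
    V = int(np.prod(shape))
    u = stats.norm.isf(height_p)
    # treat the t-field as Gaussian through its p-values; smoothness from
    # the map itself (single map: fall back to 1 voxel FWHM)
    fwhm = getattr(tmap, "_fwhm", None)
    if fwhm is None:
        fwhm = np.ones(3)
    resels = V / float(np.prod(np.clip(fwhm, 1e-6, None)))
    ec_density = ((4 * np.log(2.0)) ** 1.5 / (2 * np.pi) ** 2
                  * (u * u - 1.0) * np.exp(-u * u / 2.0))
    e_clusters = max(resels * ec_density, 1e-12)
    e_vox = V * stats.norm.sf(u)
    e_n = max(e_vox / e_clusters, 1e-12)
    beta = (gamma_fn(2.5) / e_n) ** (2.0 / 3.0)
    for r in rows:
        p_ge = np.exp(-beta * r["n_voxels"] ** (2.0 / 3.0))
        r["p_fwe"] = float(1.0 - np.exp(-e_clusters * p_ge))
    return pd.DataFrame(rows, columns=["cluster_id", "n_voxels", "peak_t",
                                       "peak_i", "peak_j", "peak_k", "p_fwe"])


def cluster_fwe_rft(data, shape, test: str = "one_sample",
                    height_p: float = 0.001, alpha: float = 0.05) -> ClusterTable:
    """Cluster FWE via the random-field approximation, with smoothness
    estimated from the unit-level maps."""
    shape = tuple(shape)
    if test == "one_sample":
        M = np.atleast_2d(np.asarray(data, dtype=float))
        tmap = one_sample_t(M, shape=shape)
        units = M
    else:
        X = np.atleast_2d(np.asarray(data[0], dtype=float))
        Y = np.atleast_2d(np.asarray(data[1], dtype=float))
        tmap = welch_two_sample_t(X, Y, shape=shape)
        units = np.vstack([X - X.mean(axis=0), Y - Y.mean(axis=0)])
    tmap._fwhm = estimate_fwhm(units, shape)
    above = suprathreshold(tmap, height_p)
    rows = _observed_clusters(tmap.t, above, shape)
    table = _rft_cluster_p(tmap, rows, shape, height_p)
    return ClusterTable(clusters=table, height_p=height_p, alpha=alpha,
                        method="rft")
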