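"""Spatial proximity statistics between two cluster populations.

All statistics work on binarized pixel maps / cluster catalogs of a
reference channel (e.g. BK) and a target channel (e.g. CaV1.3):

* per-target-cluster nearest edge-to-edge distances,
* occupancy profiles in concentric rings (annuli) of fixed width around
  the reference clusters,
* isolation / nearness fractions at a cut-off radius,
* mean number of target clusters within a radius of each reference
  cluster,
* pixel overlap percentage,
* a Gaussian ("bell-shaped") fit to the distance histogram.

Distances are Euclidean between pixel centers on the rendering grid; a
target pixel that coincides with a reference pixel has distance 0.  The
edge-to-edge convention falls out naturally: the minimum over a cluster's
pixels of the distance-to-reference map is attained on the cluster
boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from scipy import optimize
from scipy.spatial.distance import cdist

from .locmap import RasterMap
from .segmentation import GAUSSIAN_FWHM_FACTOR, ClusterCatalog, _gauss


def _grid(mask) -> tuple[np.ndarray, float]:
    if isinstance(mask, RasterMap):
        return mask.binary, mask.pixel_size_nm
    return np.asarray(mask, dtype=bool), 20.0


def _check_same_grid(a_shape, b_shape):
    if a_shape != b_shape:
        raise ValueError(f"grid mismatch: {a_shape} vs {b_shape}")


@dataclass
class AnnulusProfile:
    """Occupied-area percentage in concentric rings around a reference mask.

    Ring 0 is the reference mask itself (overlap); ring k >= 1 collects
    footprint pixels whose edge distance lies in ``((k-1)*w, k*w]`` nm.
    Rings with no pixels report NaN, not 0.
    """

    inner_nm: np.ndarray
    outer_nm: np.ndarray
    occupied_percent: np.ndarray
    ring_pixels: np.ndarray
    ring_width_nm: float
    max_radius_nm: float

    def __post_init__(self):
        ok = np.isfinite(self.occupied_percent)
        if np.any((self.occupied_percent[ok] < 0) | (self.occupied_percent[ok] > 100)):
            raise ValueError("occupied_percent out of [0, 100]")

    @property
    def n_rings(self) -> int:
        return len(self.occupied_percent)

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "inner_nm": self.inner_nm,
                "outer_nm": self.outer_nm,
                "occupied_percent": self.occupied_percent,
                "ring_pixels": self.ring_pixels,
            }
        )


@dataclass
class DistanceDistribution:
    """Nearest edge-to-edge distance per target cluster (nm).

    Overlap with the reference is recorded as distance 0.
    """

    distances_nm: np.ndarray
    per_pixel: bool = False
    gaussian_fit: dict | None = field(default=None)

    def __post_init__(self):
        if np.any(self.distances_nm < 0):
            raise ValueError("distances must be >= 0")

    def __len__(self) -> int:
        return len(self.distances_nm)

    def histogram(self, bin_width_nm: float = 20.0):
        hi = float(self.distances_nm.max()) + bin_width_nm
        edges = np.arange(0.0, hi + bin_width_nm, bin_width_nm)
        counts, _ = np.histogram(self.distances_nm, bins=edges)
        return counts, edges


def edge_distance_map(ref_mask) -> np.ndarray:
    """Per-pixel Euclidean distance (nm) to the nearest reference pixel.

    Zero on the reference mask itself.
    """
    g, p = _grid(ref_mask)
    if not g.any():
        raise ValueError("edge_distance_map: reference mask is empty")
    return ndi.distance_transform_edt(~g) * p


def nearest_edge_distances(
    target_catalog: ClusterCatalog,
    ref_mask,
    per_pixel: bool = False,
) -> DistanceDistribution:
    """Nearest edge-to-edge distance from each target cluster to the reference.

    With ``per_pixel=True``, returns the distance of every target-positive
    pixel instead of the per-cluster minimum.
    """
    g, p = _grid(ref_mask)
    _check_same_grid(target_catalog.shape, g.shape)
    if len(target_catalog) == 0:
        raise ValueError("empty target catalog")
    dmap = edge_distance_map(ref_mask)
    if per_pixel:
        tg = target_catalog.mask().binary
        return DistanceDistribution(dmap[tg], per_pixel=True)
    d = np.array(
        [dmap[c.pixels[:, 0], c.pixels[:, 1]].min() for c in target_catalog.clusters]
    )
    return DistanceDistribution(d)


def ring_index_map(
    ref_mask,
    ring_width_nm: float = 20.0,
    max_radius_nm: float = 300.0,
    footprint: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Label each footprint pixel with its ring index.

    Returns ``(ring_idx, ring_pixel_counts)`` where ``ring_idx`` is -1
    outside the footprint or beyond ``max_radius_nm``, 0 on the reference
    mask, and k for edge distances in ``((k-1)*w, k*w]``.  Precomputing
    this map makes repeated occupancy evaluations (the Monte-Carlo null)
    cheap.
    """
    g, p = _grid(ref_mask)
    dmap = edge_distance_map(ref_mask)
    n_rings = int(np.ceil(max_radius_nm / ring_width_nm)) + 1
    with np.errstate(invalid="ignore"):
        idx = np.ceil(dmap / ring_width_nm - 1e-9).astype(np.int64)
    idx[g] = 0
    idx[dmap > max_radius_nm + 1e-9] = -1
    if footprint is not None:
        idx[~np.asarray(footprint, dtype=bool)] = -1
    counts = np.bincount(idx[idx >= 0], minlength=n_rings)
    return idx, counts


def annulus_occupancy(
    ref_mask,
    target_mask,
    ring_width_nm: float = 20.0,
    max_radius_nm: float = 300.0,
    footprint: np.ndarray | None = None,
) -> AnnulusProfile:
    """Percentage of each concentric ring occupied by target-positive pixels.

    Ring 0 reports the overlap of the target with the reference mask
    itself.  Computed over the whole footprint (whole cell) rather than
    selected ROIs.
    """
    gr, p = _grid(ref_mask)
    gt, _ = _grid(target_mask)
    _check_same_grid(gr.shape, gt.shape)
    idx, ring_n = ring_index_map(ref_mask, ring_width_nm, max_radius_nm, footprint)
    n_rings = len(ring_n)
    occ_n = np.bincount(idx[(idx >= 0) & gt], minlength=n_rings)
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = np.where(ring_n > 0, 100.0 * occ_n / np.maximum(ring_n, 1), np.nan)
    w = ring_width_nm
    inner = np.concatenate([[0.0], np.arange(n_rings - 1) * w])
    outer = np.concatenate([[0.0], (np.arange(n_rings - 1) + 1) * w])
    return AnnulusProfile(inner, outer, pct, ring_n, w, max_radius_nm)


def occupancy_from_ring_index(
    ring_idx: np.ndarray, ring_n: np.ndarray, target_mask
) -> np.ndarray:
    """Fast occupancy evaluation against a precomputed ring-index map."""
    gt, _ = _grid(target_mask)
    occ_n = np.bincount(ring_idx[(ring_idx >= 0) & gt], minlength=len(ring_n))
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(ring_n > 0, 100.0 * occ_n / np.maximum(ring_n, 1), np.nan)


def fraction_refs_isolated(
    ref_catalog: ClusterCatalog, target_mask, radius_nm: float = 200.0
) -> float:
    """Fraction of reference clusters with no target pixel within the radius.

    A reference cluster counts as isolated when the nearest target-positive
    pixel is strictly farther than ``radius_nm`` from its boundary.
    """
    if len(ref_catalog) == 0:
        raise ValueError("empty reference catalog")
    gt, p = _grid(target_mask)
    _check_same_grid(ref_catalog.shape, gt.shape)
    if not gt.any():
        return 1.0
    dmap = edge_distance_map(target_mask)
    dmin = np.array(
        [dmap[c.pixels[:, 0], c.pixels[:, 1]].min() for c in ref_catalog.clusters]
    )
    return float(np.mean(dmin > radius_nm))


def fraction_targets_near(
    target_catalog: ClusterCatalog, ref_mask, radius_nm: float = 200.0
) -> float:
    """Fraction of target clusters at < ``radius_nm`` from the reference."""
    d = nearest_edge_distances(target_catalog, ref_mask).distances_nm
    return float(np.mean(d < radius_nm))


def cluster_pair_distances(
    ref_catalog: ClusterCatalog,
    target_catalog: ClusterCatalog,
    cutoff_nm: float | None = None,
) -> np.ndarray:
    """(n_ref, n_target) matrix of edge-to-edge distances in nm.

    With ``cutoff_nm`` set, pairs provably farther apart than the cutoff
    (by a bounding-radius triangle bound) are reported as ``inf`` without
    an exact computation — they cannot affect any within-radius count.
    """
    _check_same_grid(ref_catalog.shape, target_catalog.shape)
    p = ref_catalog.pixel_size_nm
    n_r, n_t = len(ref_catalog), len(target_catalog)
    out = np.full((n_r, n_t), np.inf)
    if n_r == 0 or n_t == 0:
        return out
    ref_lab = ref_catalog.label_map()
    rb = [r.boundary.astype(float) for r in ref_catalog.clusters]
    tb = [t.boundary.astype(float) for t in target_catalog.clusters]
    # bounding circles (pixel units) for the cutoff prefilter
    rc = [b.mean(axis=0) for b in rb]
    tc = [b.mean(axis=0) for b in tb]
    rr = [np.sqrt(((b - c) ** 2).sum(axis=1)).max() for b, c in zip(rb, rc)]
    tr = [np.sqrt(((b - c) ** 2).sum(axis=1)).max() for b, c in zip(tb, tc)]
    ref_index = {r.id: i for i, r in enumerate(ref_catalog.clusters)}
    for j, t in enumerate(target_catalog.clusters):
        overl = np.unique(ref_lab[t.pixels[:, 0], t.pixels[:, 1]])
        for rid in overl[overl > 0]:
            out[ref_index[int(rid)], j] = 0.0
        for i in range(n_r):
            if out[i, j] == 0.0:
                continue
            if cutoff_nm is not None:
                lower = (np.hypot(*(rc[i] - tc[j])) - rr[i] - tr[j]) * p
                if lower > cutoff_nm:
                    continue
            out[i, j] = cdist(rb[i], tb[j]).min() * p
    return out


def mean_targets_within(
    ref_catalog: ClusterCatalog,
    target_catalog: ClusterCatalog,
    radius_nm: float = 50.0,
) -> dict:
    """Mean number of target clusters within ``radius_nm`` of each reference.

    A target cluster counts when its nearest edge-to-edge distance to the
    reference cluster is <= ``radius_nm``.  Returns the mean and the full
    per-reference count list.
    """
    if len(ref_catalog) == 0:
        raise ValueError("empty reference catalog")
    if len(target_catalog) == 0:
        counts = np.zeros(len(ref_catalog), dtype=int)
    else:
        dm = cluster_pair_distances(ref_catalog, target_catalog,
                                    cutoff_nm=radius_nm)
        counts = (dm <= radius_nm).sum(axis=1)
    return {"mean": float(counts.mean()), "counts": counts}


def overlap_percent(ref, target_mask) -> float:
    """Percent of reference-positive pixels that are also target-positive."""
    if isinstance(ref, ClusterCatalog):
        gr = ref.mask().binary
    else:
        gr, _ = _grid(ref)
    gt, _ = _grid(target_mask)
    _check_same_grid(gr.shape, gt.shape)
    n_ref = int(gr.sum())
    if n_ref == 0:
        raise ValueError("empty reference mask")
    return 100.0 * int((gr & gt).sum()) / n_ref


def fit_distance_bell(
    dist: DistanceDistribution | np.ndarray, bin_width_nm: float = 20.0
) -> dict:
    """Least-squares Gaussian fit to the distance histogram.

    Reports the peak position, sigma, FWHM and HWHM (both half-width
    conventions).
    """
    d = dist.distances_nm if isinstance(dist, DistanceDistribution) else np.asarray(dist, float)
    if len(d) < 10:
        raise ValueError("need at least 10 distances to fit")
    if np.ptp(d) == 0:
        raise ValueError("degenerate distance distribution (all identical)")
    hi = float(d.max()) + bin_width_nm
    edges = np.arange(0.0, hi + bin_width_nm, bin_width_nm)
    hist, _ = np.histogram(d, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    mu0 = float(centers[np.argmax(hist)])
    s0 = max(float(np.sqrt(np.average((centers - mu0) ** 2, weights=hist))),
             bin_width_nm / 2)
    popt, _ = optimize.curve_fit(
        _gauss, centers, hist, p0=[hist.max(), mu0, s0],
        bounds=([0.0, -np.inf, 1e-9], [np.inf, np.inf, np.inf]),
        maxfev=10000,
    )
    sigma = abs(float(popt[2]))
    fwhm = GAUSSIAN_FWHM_FACTOR * sigma
    fit = {
        "peak_nm": float(popt[1]),
        "sigma_nm": sigma,
        "fwhm_nm": fwhm,
        "hwhm_nm": fwhm / 2.0,
        "amplitude": float(popt[0]),
    }
    if isinstance(dist, DistanceDistribution):
        dist.gaussian_fit = fit
    return fit
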