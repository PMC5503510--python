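"""Cluster segmentation of binary localization maps.

Binarized localization maps are smoothed with a count-thresholded binary
closing (the "close with N counts" operation familiar from ImageJ binary
options), touching clusters are separated with a distance-transform
watershed, and the resulting label map is condensed into a cluster
catalog carrying per-cluster pixel sets, areas in nm², centroids and
boundaries.  A transverse-profile FWHM fit for line structures
(microtubule-style resolution checks) lives here as well.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from scipy import optimize, stats

from .locmap import LocalizationTable, RasterMap

log = logging.getLogger(__name__)

_N8 = np.ones((3, 3), dtype=np.int64)
_N8_NOCENTER = np.array([[1, 1, 1], [1, 0, 1], [1, 1, 1]], dtype=np.int64)


def _as_bool_grid(mask) -> tuple[np.ndarray, float]:
    """Return (bool grid, pixel size); accepts RasterMap or ndarray."""
    if isinstance(mask, RasterMap):
        g = mask.grid
        p = mask.pixel_size_nm
    else:
        g = np.asarray(mask)
        p = 20.0
    vals = np.unique(g)
    if not np.all(np.isin(vals, [0, 1])):
        raise ValueError("mask must be binary (0/1 or bool)")
    return g.astype(bool), p


def binary_close(mask, iterations: int = 1, count_param: int = 5):
    """Count-thresholded binary closing on the 8-neighborhood.

    One iteration is a count-thresholded dilation followed by a
    count-thresholded erosion:

    * dilation: a background pixel becomes foreground iff at least
      ``count_param`` of its 8 neighbors are foreground;
    * erosion: a foreground pixel becomes background iff at least
      ``count_param`` of its 8 neighbors are background.

    Border convention: neighbors beyond the image edge count as
    background during dilation (nothing grows in from outside) and as
    foreground during erosion (the field edge does not erode), so an
    all-foreground mask is a fixed point.  Away from the border,
    ``count_param=1`` reduces to the textbook morphological closing with
    a 3x3 structuring element.
    """
    if not (1 <= count_param <= 8):
        raise ValueError("count_param must be in 1..8")
    if iterations < 0:
        raise ValueError("iterations must be >= 0")
    g, p = _as_bool_grid(mask)
    for _ in range(iterations):
        fg_nbr = ndi.convolve(g.astype(np.int64), _N8_NOCENTER,
                              mode="constant", cval=0)
        g = g | (fg_nbr >= count_param)
        bg_nbr = ndi.convolve((~g).astype(np.int64), _N8_NOCENTER,
                              mode="constant", cval=0)
        g = g & ~(bg_nbr >= count_param)
    if isinstance(mask, RasterMap):
        return RasterMap(g, pixel_size_nm=mask.pixel_size_nm,
                         origin_nm=mask.origin_nm, footprint=mask.footprint)
    return g


def watershed_split(mask) -> np.ndarray:
    """Split touching clusters with a Euclidean-distance-transform watershed.

    Seeds are the local maxima of the EDT inside the foreground with a
    minimum separation of 2 pixels; plateau maxima are merged into one
    seed.  Basins partition the foreground exactly.  Labels are
    renumbered deterministically so that the label containing the lowest
    linear pixel index comes first.
    """
    from skimage.feature import peak_local_max
    from skimage.segmentation import watershed

    g, _ = _as_bool_grid(mask)
    labels = np.zeros(g.shape, dtype=np.int32)
    if not g.any():
        return labels
    comps, _ = ndi.label(g, structure=_N8)
    edt = ndi.distance_transform_edt(g)
    coords = peak_local_max(edt, min_distance=2, labels=comps,
                            exclude_border=False)
    seed_mask = np.zeros(g.shape, dtype=bool)
    seed_mask[tuple(coords.T)] = True
    # merge plateau maxima that survive suppression as touching seeds
    markers, _ = ndi.label(seed_mask, structure=_N8)
    labels = watershed(-edt, markers=markers, mask=g)
    return _relabel_by_first_pixel(labels)


def _relabel_by_first_pixel(labels: np.ndarray) -> np.ndarray:
    """Renumber labels 1..n by ascending lowest linear pixel index."""
    flat = labels.ravel()
    ids = np.unique(flat)
    ids = ids[ids > 0]
    if ids.size == 0:
        return labels.astype(np.int32)
    order = np.argsort([np.argmax(flat == i) for i in ids], kind="stable")
    remap = np.zeros(int(ids.max()) + 1, dtype=np.int32)
    remap[ids[order]] = np.arange(1, ids.size + 1, dtype=np.int32)
    return remap[labels]


@dataclass
class Cluster:
    """One segmented cluster on the pixel grid."""

    id: int
    pixels: np.ndarray          # (n, 2) int array of (row, col)
    area_nm2: float
    centroid_nm: tuple[float, float]   # (x, y)
    boundary: np.ndarray        # (m, 2) subset of pixels adjacent to outside

    @property
    def n_pixels(self) -> int:
        return len(self.pixels)


@dataclass
class ClusterCatalog:
    """Segmented clusters with pixel sets, areas (nm²) and boundaries."""

    clusters: list[Cluster]
    pixel_size_nm: float
    shape: tuple[int, int]
    origin_nm: tuple[float, float] = (0.0, 0.0)
    footprint: np.ndarray | None = field(default=None, repr=False)

    def __len__(self) -> int:
        return len(self.clusters)

    @property
    def areas_nm2(self) -> np.ndarray:
        return np.array([c.area_nm2 for c in self.clusters], dtype=float)

    def mask(self) -> RasterMap:
        g = np.zeros(self.shape, dtype=bool)
        for c in self.clusters:
            g[c.pixels[:, 0], c.pixels[:, 1]] = True
        return RasterMap(g, pixel_size_nm=self.pixel_size_nm,
                         origin_nm=self.origin_nm, footprint=self.footprint)

    def label_map(self) -> np.ndarray:
        lab = np.zeros(self.shape, dtype=np.int32)
        for c in self.clusters:
            lab[c.pixels[:, 0], c.pixels[:, 1]] = c.id
        return lab

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "id": [c.id for c in self.clusters],
                "area_nm2": [c.area_nm2 for c in self.clusters],
                "centroid_x_nm": [c.centroid_nm[0] for c in self.clusters],
                "centroid_y_nm": [c.centroid_nm[1] for c in self.clusters],
                "n_pixels": [c.n_pixels for c in self.clusters],
            }
        )


def _boundary_pixels(comp_mask: np.ndarray) -> np.ndarray:
    """Pixels of a cluster with at least one 8-neighbor outside it."""
    inner = ndi.binary_erosion(comp_mask, structure=_N8, border_value=0)
    return np.argwhere(comp_mask & ~inner)


def build_catalog(
    labels,
    pixel_size_nm: float = 20.0,
    min_area_px: int = 1,
    origin_nm: tuple[float, float] = (0.0, 0.0),
    footprint: np.ndarray | None = None,
) -> ClusterCatalog:
    """Condense a label map into a :class:`ClusterCatalog`.

    Labels with fewer than ``min_area_px`` pixels are dropped; remaining
    clusters are renumbered 1..n in the input label order.  Areas are
    ``n_pixels * pixel_size_nm**2`` exactly.
    """
    labels = np.asarray(labels)
    clusters: list[Cluster] = []
    x0, y0 = origin_nm
    p = pixel_size_nm
    new_id = 0
    objects = ndi.find_objects(labels)
    for i, sl in enumerate(objects, start=1):
        if sl is None:
            continue
        sub = labels[sl] == i
        n = int(sub.sum())
        if n < min_area_px:
            continue
        new_id += 1
        pix = np.argwhere(sub)
        pix[:, 0] += sl[0].start
        pix[:, 1] += sl[1].start
        bnd = _boundary_pixels(sub)
        bnd[:, 0] += sl[0].start
        bnd[:, 1] += sl[1].start
        cx = x0 + (pix[:, 1].mean() + 0.5) * p
        cy = y0 + (pix[:, 0].mean() + 0.5) * p
        clusters.append(
            Cluster(id=new_id, pixels=pix, area_nm2=n * p * p,
                    centroid_nm=(cx, cy), boundary=bnd)
        )
    return ClusterCatalog(clusters, pixel_size_nm=p, shape=labels.shape,
                          origin_nm=origin_nm, footprint=footprint)


def segment(
    mask,
    close_iterations: int = 1,
    close_count: int = 5,
    min_area_px: int = 1,
) -> ClusterCatalog:
    """Full recipe: count-thresholded close, watershed, catalog."""
    closed = binary_close(mask, iterations=close_iterations,
                          count_param=close_count)
    labels = watershed_split(closed)
    if isinstance(mask, RasterMap):
        return build_catalog(labels, pixel_size_nm=mask.pixel_size_nm,
                             min_area_px=min_area_px, origin_nm=mask.origin_nm,
                             footprint=mask.footprint)
    return build_catalog(labels, min_area_px=min_area_px)


def cluster_size_stats(catalog: ClusterCatalog) -> dict:
    """Median area, cluster count and the raw area list.

    The median is used rather than the mean because cluster-area
    distributions are strongly right-skewed.
    """
    if len(catalog) == 0:
        raise ValueError("cluster_size_stats on an empty catalog")
    areas = catalog.areas_nm2
    return {
        "median_area_nm2": float(np.median(areas)),
        "n_clusters": len(catalog),
        "area_list": areas,
    }


def compare_cluster_areas(*groups) -> dict:
    """Kruskal-Wallis rank test across two or more area samples.

    Each group may be a :class:`ClusterCatalog` or a plain sequence of
    areas.  Returns the H statistic and p-value.
    """
    samples = [g.areas_nm2 if isinstance(g, ClusterCatalog) else np.asarray(g, float)
               for g in groups]
    if len(samples) < 2:
        raise ValueError("need at least two groups")
    h, p = stats.kruskal(*samples)
    return {"statistic": float(h), "pvalue": float(p)}


def _gauss(x, a, mu, sigma):
    return a * np.exp(-0.5 * ((x - mu) / sigma) ** 2)

#: FWHM of a Gaussian of unit standard deviation
GAUSSIAN_FWHM_FACTOR = 2.0 * np.sqrt(2.0 * np.log(2.0))


def profile_fwhm(
    source,
    transect: tuple[tuple[float, float], tuple[float, float]],
    bin_width_nm: float = 5.0,
    max_offset_nm: float = 200.0,
) -> dict:
    """Transverse-profile Gaussian fit across a line structure.

    Events (or occupied pixels, weighted by counts) within the transect's
    axial span are projected onto the transect normal, histogrammed in
    ``bin_width_nm`` bins centered at 0, and fitted with a Gaussian by
    least squares.  Returns the fitted ``sigma_nm``, the full width at
    half maximum ``fwhm_nm = 2*sqrt(2*ln 2)*sigma`` and the fitted center.
    """
    (x0, y0), (x1, y1) = transect
    d = np.array([x1 - x0, y1 - y0], dtype=float)
    length = np.hypot(*d)
    if length == 0:
        raise ValueError("degenerate transect")
    u = d / length
    n = np.array([-u[1], u[0]])

    if isinstance(source, LocalizationTable):
        pts = np.column_stack([source.x_nm, source.y_nm])
        w = np.ones(len(pts))
    elif isinstance(source, RasterMap):
        rr, cc = np.nonzero(source.grid)
        p = source.pixel_size_nm
        ox, oy = source.origin_nm
        pts = np.column_stack([ox + (cc + 0.5) * p, oy + (rr + 0.5) * p])
        w = source.grid[rr, cc].astype(float)
    else:
        raise TypeError("source must be LocalizationTable or RasterMap")

    rel = pts - np.array([x0, y0])
    along = rel @ u
    across = rel @ n
    sel = (along >= 0) & (along <= length) & (np.abs(across) <= max_offset_nm)
    across = across[sel]
    w = w[sel]
    if w.sum() < 20:
        raise ValueError("fewer than 20 events/pixels in the profile")

    nbins = int(np.ceil(2 * max_offset_nm / bin_width_nm))
    edges = np.linspace(-max_offset_nm, max_offset_nm, nbins + 1)
    hist, _ = np.histogram(across, bins=edges, weights=w)
    centers = 0.5 * (edges[:-1] + edges[1:])
    if (hist > 0).sum() < 2:
        raise ValueError("degenerate profile: all mass in one bin")

    mu0 = float(np.average(centers, weights=hist))
    s0 = float(np.sqrt(np.average((centers - mu0) ** 2, weights=hist)))
    s0 = max(s0, bin_width_nm / 2)
    popt, pcov = optimize.curve_fit(
        _gauss, centers, hist, p0=[hist.max(), mu0, s0],
        bounds=([0.0, -np.inf, 1e-9], [np.inf, np.inf, np.inf]),
        maxfev=10000,
    )
    sigma = abs(float(popt[2]))
    return {
        "fwhm_nm": GAUSSIAN_FWHM_FACTOR * sigma,
        "sigma_nm": sigma,
        "center_nm": float(popt[1]),
        "amplitude": float(popt[0]),
        "bin_centers_nm": centers,
        "histogram": hist,
    }
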