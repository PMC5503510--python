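"""Independent brute-force oracles used to check the fast implementations.

Everything here is written as plainly as possible (per-pixel / per-event
loops, exhaustive pairwise searches) and shares no code path with the
package operations it checks.
"""

import numpy as np


def brute_edge_distance_map(mask: np.ndarray, pixel_size_nm: float) -> np.ndarray:
    """Exhaustive nearest-foreground-pixel Euclidean distance."""
    fg = np.argwhere(mask)
    out = np.empty(mask.shape, dtype=float)
    for r in range(mask.shape[0]):
        for c in range(mask.shape[1]):
            d2 = (fg[:, 0] - r) ** 2 + (fg[:, 1] - c) ** 2
            out[r, c] = np.sqrt(d2.min())
    return out * pixel_size_nm


def brute_rasterize(x_nm, y_nm, pixel_size_nm, shape):
    """Per-event floor-division binning."""
    grid = np.zeros(shape, dtype=np.int64)
    for x, y in zip(x_nm, y_nm):
        grid[int(y // pixel_size_nm), int(x // pixel_size_nm)] += 1
    return grid


def brute_count_close(mask: np.ndarray, iterations: int, count: int) -> np.ndarray:
    """Per-pixel neighbor-counting close (dilate then erode, 8-neighborhood)."""
    g = mask.astype(bool).copy()
    H, W = g.shape

    def neighbor_sum(grid, r, c, value):
        s = 0
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == 0 and dc == 0:
                    continue
                rr, cc = r + dr, c + dc
                if 0 <= rr < H and 0 <= cc < W:
                    s += grid[rr, cc] == value
                # outside the image counts as background for dilation and
                # as foreground for erosion: never toward either count
        return s

    for _ in range(iterations):
        out = g.copy()
        for r in range(H):
            for c in range(W):
                if not g[r, c] and neighbor_sum(g, r, c, True) >= count:
                    out[r, c] = True
        g = out
        out = g.copy()
        for r in range(H):
            for c in range(W):
                if g[r, c] and neighbor_sum(g, r, c, False) >= count:
                    out[r, c] = False
        g = out
    return g


def brute_nearest_cluster_distances(pixel_sets, ref_mask, pixel_size_nm):
    """Per-cluster exhaustive min pairwise pixel distance to the reference."""
    fg = np.argwhere(ref_mask)
    out = []
    for pix in pixel_sets:
        best = np.inf
        for r, c in pix:
            d2 = (fg[:, 0] - r) ** 2 + (fg[:, 1] - c) ** 2
            best = min(best, d2.min())
        out.append(np.sqrt(best) * pixel_size_nm)
    return np.array(out)
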