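"""The Landscape Integrity Index: equal-weight combination of the HII,
normalized species richness, and normalized inverse vegetation departure,
smoothed by a moving-window (default 1 km) mean on the 90-m model grid —
plus the summary statistics used to characterize the surface (random point
sampling, one-way ANOVA over ownership with a permutation post-hoc,
Welch's t between protection levels, Pearson correlation).

Because the per-cell combination and the focal mean are both linear, it does
not matter whether the three indicators are averaged before or after the
window pass where footprints coincide; the implementation averages first and
runs a single focal pass.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import shapely
from scipy import ndimage, stats

from .grid import Raster

DEFAULT_WINDOW_RADIUS_M = 1000.0
DEFAULT_WEIGHTS = (1 / 3, 1 / 3, 1 / 3)


@dataclass
class LiiSurface:
    """The integrity surface: values in [0, 1] on the model grid."""

    values: Raster
    window_radius: float = DEFAULT_WINDOW_RADIUS_M
    weights: tuple[float, float, float] = DEFAULT_WEIGHTS


@dataclass
class SampleSet:
    """Random sample locations (cell centers) with optional stratum labels."""

    points: list[tuple[float, float]]
    stratum_labels: list[str]
    seed: int
    cells: list[tuple[int, int]] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Focal statistics and the LII combination
# ---------------------------------------------------------------------------

def _circular_footprint(radius_m: float, pixel_size: float, square: bool = False):
    n = int(math.floor(radius_m / pixel_size))
    offs = np.arange(-n, n + 1)
    dr, dc = np.meshgrid(offs, offs, indexing="ij")
    if square:
        return np.ones_like(dr, dtype=np.float64)
    dist = np.hypot(dr, dc) * pixel_size
    return (dist <= radius_m + 1e-9).astype(np.float64)


def focal_mean(r: Raster, radius: float, square: bool = False) -> Raster:
    """Moving-window mean: each cell becomes the mean of valid input cells
    whose centers lie within ``radius`` meters of its center.

    The window is circular by default (square available); it truncates at
    the grid edge, and nodata cells are excluded from the mean. A cell with
    no valid neighbor in the window stays nodata.
    """
    px = r.grid.pixel_size
    if radius < px:
        raise ValueError(f"radius {radius} m is smaller than the pixel size {px} m")
    kernel = _circular_footprint(radius, px, square=square)
    valid = r.valid_mask.astype(np.float64)
    vals = np.where(r.valid_mask, np.asarray(r.values, dtype=np.float64), 0.0)
    num = ndimage.convolve(vals, kernel, mode="constant", cval=0.0)
    den = ndimage.convolve(valid, kernel, mode="constant", cval=0.0)
    nodata = -1.0
    out = np.full(r.grid.shape, nodata)
    ok = den > 0
    out[ok] = num[ok] / den[ok]
    return Raster(r.grid, out, nodata=nodata)


def compute_lii(
    hii: Raster,
    richness: Raster,
    vdep: Raster,
    radius: float = DEFAULT_WINDOW_RADIUS_M,
    weights: tuple[float, float, float] = DEFAULT_WEIGHTS,
    square_window: bool = False,
) -> LiiSurface:
    """Weighted per-cell mean of the three indicators followed by the
    moving-window mean. All inputs must already share the 90-m model grid
    and be scaled to [0, 1]."""
    if hii.grid != richness.grid or hii.grid != vdep.grid:
        raise ValueError("compute_lii: indicator rasters are not on a common grid")
    w = np.asarray(weights, dtype=np.float64)
    if w.shape != (3,) or not math.isclose(w.sum(), 1.0, abs_tol=1e-9):
        raise ValueError(f"weights must be three values summing to 1, got {weights}")
    valid = hii.valid_mask & richness.valid_mask & vdep.valid_mask
    combined = (
        w[0] * np.asarray(hii.values, dtype=np.float64)
        + w[1] * np.asarray(richness.values, dtype=np.float64)
        + w[2] * np.asarray(vdep.values, dtype=np.float64)
    )
    nodata = -1.0
    combined = np.where(valid, combined, nodata)
    smoothed = focal_mean(Raster(hii.grid, combined, nodata=nodata), radius,
                          square=square_window)
    return LiiSurface(values=smoothed, window_radius=radius, weights=tuple(w))


# ---------------------------------------------------------------------------
# Random sampling
# ---------------------------------------------------------------------------

def sample_points(
    valid_mask: Raster,
    n: int,
    strata=None,
    seed: int = 0,
) -> SampleSet:
    """Draw ``n`` cell centers uniformly without replacement from the valid
    cells — per stratum when a stratum polygon layer is given (``n`` each).

    ``strata`` is a sequence of ``(label, polygon)`` pairs or GeoJSON-style
    feature records carrying a ``label`` property; a cell belongs to the
    first stratum whose polygon covers its center. Deterministic given seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    grid = valid_mask.grid
    mask = valid_mask.valid_mask & (np.asarray(valid_mask.values) != 0)
    cx, cy = grid.center_grids()

    def _draw(cell_mask, label):
        rows, cols = np.nonzero(cell_mask)
        if len(rows) < n:
            raise ValueError(
                f"stratum {label!r}: only {len(rows)} valid cells for n={n}"
            )
        idx = rng.choice(len(rows), size=n, replace=False)
        return [(int(rows[i]), int(cols[i])) for i in idx]

    points: list[tuple[float, float]] = []
    labels: list[str] = []
    cells: list[tuple[int, int]] = []
    if strata is None:
        chosen = _draw(mask, None)
        for rc in chosen:
            cells.append(rc)
            points.append((float(cx[rc]), float(cy[rc])))
            labels.append("all")
    else:
        pairs = []
        for s in strata:
            if isinstance(s, dict):
                pairs.append((str(s["properties"]["label"]), s["geometry"]))
            else:
                pairs.append((str(s[0]), s[1]))
        assigned = np.zeros(grid.shape, dtype=bool)
        pts = shapely.points(cx.ravel(), cy.ravel())
        for label, geom in pairs:
            inside = shapely.covers(geom, pts).reshape(grid.shape)
            stratum_mask = mask & inside & ~assigned
            assigned |= inside
            for rc in _draw(stratum_mask, label):
                cells.append(rc)
                points.append((float(cx[rc]), float(cy[rc])))
                labels.append(label)
    return SampleSet(points=points, stratum_labels=labels, seed=seed, cells=cells)


def values_at(r: Raster, samples: SampleSet) -> np.ndarray:
    """LII (or any raster) values at sampled cells."""
    rows = np.array([rc[0] for rc in samples.cells])
    cols = np.array([rc[1] for rc in samples.cells])
    return np.asarray(r.values, dtype=np.float64)[rows, cols]


# ---------------------------------------------------------------------------
# Statistics
# ---------------------------------------------------------------------------

def welch_t_test(a, b) -> tuple[float, float, float]:
    """Welch's unequal-variance two-sample t-test.

    Returns (t, Welch-Satterthwaite df, two-sided p).
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs at least 2 values")
    if np.var(a) == 0 and np.var(b) == 0 and np.mean(a) == np.mean(b):
        return 0.0, float(len(a) + len(b) - 2), 1.0
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def one_way_anova(groups) -> tuple[float, int, int, float]:
    """Classical one-way ANOVA. Returns (F, df_between, df_within, p)."""
    groups = [np.asarray(g, dtype=np.float64) for g in groups]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >=2 groups with >=2 values each")
    k = len(groups)
    n_total = sum(len(g) for g in groups)
    df_b, df_w = k - 1, n_total - k
    if all(np.var(g) == 0 for g in groups) and len({g[0] for g in groups}) == 1:
        return 0.0, df_b, df_w, 1.0
    res = stats.f_oneway(*groups)
    return float(res.statistic), df_b, df_w, float(res.pvalue)


def _pairwise_q(groups):
    """Observed studentized-range-type statistics for all group pairs."""
    k = len(groups)
    means = [g.mean() for g in groups]
    ns = [len(g) for g in groups]
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_w = sum(ns) - k
    msw = ssw / df_w
    q = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            se2 = msw / 2.0 * (1.0 / ns[i] + 1.0 / ns[j])
            if se2 == 0:
                qij = 0.0 if means[i] == means[j] else np.inf
            else:
                qij = abs(means[i] - means[j]) / math.sqrt(se2)
            q[i, j] = q[j, i] = qij
    return q


def pairwise_posthoc(
    groups, alpha: float = 0.01, n_permutations: int = 10_000, seed: int = 0
) -> list[str]:
    """All-pairs comparison with a permutation approximation of the Tukey
    studentized-range null; returns a compact letter display.

    The familywise null distribution is the maximum pairwise range statistic
    under random relabelling of the pooled observations (group sizes kept).
    Groups that are not significantly different at ``alpha`` share a letter.
    Deterministic given seed.
    """
    groups = [np.asarray(g, dtype=np.float64) for g in groups]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >=2 groups with >=2 values each")
    k = len(groups)
    ns = [len(g) for g in groups]
    q_obs = _pairwise_q(groups)

    pooled = np.concatenate(groups)
    bounds = np.cumsum([0] + ns)
    rng = np.random.default_rng(seed)
    exceed = np.zeros((k, k))
    for _ in range(n_permutations):
        perm = rng.permutation(pooled)
        pgroups = [perm[bounds[i]:bounds[i + 1]] for i in range(k)]
        qmax = _pairwise_q(pgroups).max()
        exceed += qmax >= q_obs
    pvals = (exceed + 1.0) / (n_permutations + 1.0)
    significant = [
        (i, j)
        for i in range(k)
        for j in range(i + 1, k)
        if (q_obs[i, j] == np.inf) or (pvals[i, j] <= alpha)
    ]
    return _letter_display(k, significant)


def _letter_display(k: int, significant_pairs) -> list[str]:
    # insert-and-absorb: split every letter set containing a significant pair
    sets: list[set[int]] = [set(range(k))]
    for i, j in significant_pairs:
        new_sets: list[set[int]] = []
        for s in sets:
            if i in s and j in s:
                new_sets.extend([s - {i}, s - {j}])
            else:
                new_sets.append(s)
        # absorb subsets and duplicates
        sets = []
        for s in sorted(new_sets, key=len, reverse=True):
            if s and not any(s <= t for t in sets):
                sets.append(s)
    sets.sort(key=lambda s: min(s))
    letters = ["" for _ in range(k)]
    for idx, s in enumerate(sets):
        ch = chr(ord("a") + idx)
        for g in sorted(s):
            letters[g] += ch
    return letters


def pearson_correlation(x, y) -> float:
    """Sample Pearson product-moment correlation coefficient."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("x and y must be equal-length with >=3 values")
    if np.var(x) == 0 or np.var(y) == 0:
        raise ValueError("zero variance input")
    return float(stats.pearsonr(x, y).statistic)
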