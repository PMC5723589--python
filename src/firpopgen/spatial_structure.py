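"""Isolation by distance and genetic-barrier detection in geographic space.

Isolation by distance (IBD) is assessed in the two-dimensional habit:
linearized genetic distance F/(1−F) regressed on the natural logarithm of
great-circle distance.  Significance comes from a Mantel permutation test
(rows and columns of one matrix permuted jointly; exact enumeration when the
number of populations is small enough), the strength from a reduced
major-axis (RMA) regression whose slope confidence interval is bootstrapped
over populations so that pairs stay internally consistent.

Barriers are traced with Monmonier's maximum-difference algorithm on a
Delaunay triangulation of the population coordinates: a barrier starts by
crossing the triangulation edge with the largest genetic distance and is
extended from both ends, always crossing the adjacent edge with the larger
distance, until it exits at the convex hull or runs into an existing
barrier.  Support per crossed edge comes from bootstrap over loci.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import Delaunay

from .differentiation import linearized_fst_matrix
from .genotypes_io import GenotypeDataset

logger = logging.getLogger(__name__)

EARTH_RADIUS_KM = 6371.0


def haversine_matrix(lat: np.ndarray, lon: np.ndarray) -> np.ndarray:
    """Great-circle distance matrix in km (Earth radius 6371.0 km)."""
    la = np.radians(np.asarray(lat, dtype=float))[:, None]
    lo = np.radians(np.asarray(lon, dtype=float))[:, None]
    dla = la - la.T
    dlo = lo - lo.T
    h = np.sin(dla / 2) ** 2 + np.cos(la) * np.cos(la.T) * np.sin(dlo / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0, 1)))


# ---------------------------------------------------------------------------
# Mantel + RMA
# ---------------------------------------------------------------------------

@dataclass
class IbdResult:
    mantel_r: float
    mantel_p: float
    slope: float
    intercept: float
    r_squared: float
    ci_low: float
    ci_high: float
    n_pairs: int


def _offdiag_pairs(n: int) -> tuple[np.ndarray, np.ndarray]:
    iu = np.triu_indices(n, k=1)
    return iu


def mantel_rma(genetic: np.ndarray, geographic: np.ndarray, n_perm: int = 9999,
               n_boot: int = 1000, seed: int | None = None,
               log_distance: bool = True) -> IbdResult:
    """Mantel test and RMA regression of genetic on (log) geographic distance.

    Permutes one matrix's rows and columns jointly; if n! <= n_perm the
    permutation distribution is enumerated exactly.  The RMA slope is
    sign(r)·s_y/s_x; its 95% CI is a percentile bootstrap that resamples
    populations with replacement (pairs drawn among distinct resampled
    populations).  Zero off-diagonal geographic distances are dropped with a
    warning (log undefined).
    """
    g = np.asarray(genetic, dtype=float)
    d = np.asarray(geographic, dtype=float)
    n = g.shape[0]
    if g.shape != d.shape or n < 4:
        raise ValueError("matrices must be square, same shape, >= 4 populations")
    rng = np.random.default_rng(seed)
    iu = _offdiag_pairs(n)

    def xy(gm: np.ndarray, dm: np.ndarray, rows: np.ndarray, cols: np.ndarray):
        x = dm[rows, cols]
        y = gm[rows, cols]
        ok = np.isfinite(x) & np.isfinite(y)
        if log_distance:
            zero = ok & (x <= 0)
            if zero.any():
                logger.warning("dropping %d zero-distance pairs (log undefined)", int(zero.sum()))
            ok &= x > 0
            x = np.where(ok, x, 1.0)
            x = np.log(x)
        return x[ok], y[ok]

    x, y = xy(g, d, *iu)
    if len(x) < 3:
        raise ValueError("too few usable pairs")
    r_obs = float(np.corrcoef(x, y)[0, 1])

    def stat(perm: np.ndarray) -> float:
        gp = g[np.ix_(perm, perm)]
        xp, yp = xy(gp, d, *iu)
        return float(np.corrcoef(xp, yp)[0, 1])

    if math.factorial(n) <= n_perm:
        stats_all = [stat(np.array(p)) for p in itertools.permutations(range(n))]
        p_val = float(np.mean(np.asarray(stats_all) >= r_obs - 1e-12))
    else:
        ge = 0
        for _ in range(n_perm):
            if stat(rng.permutation(n)) >= r_obs - 1e-12:
                ge += 1
        p_val = (ge + 1) / (n_perm + 1)

    def rma(xv: np.ndarray, yv: np.ndarray) -> tuple[float, float]:
        sx, sy = xv.std(ddof=1), yv.std(ddof=1)
        if sx == 0 or sy == 0:
            return math.nan, math.nan
        r = np.corrcoef(xv, yv)[0, 1]
        slope = math.copysign(sy / sx, r if r != 0 else 1.0)
        return slope, float(yv.mean() - slope * xv.mean())

    slope, intercept = rma(x, y)

    slopes = []
    for _ in range(n_boot):
        pick = rng.integers(0, n, n)
        rows, cols = [], []
        for a in range(n):
            for b in range(a + 1, n):
                if pick[a] != pick[b]:
                    rows.append(pick[a])
                    cols.append(pick[b])
        if len(rows) < 3:
            continue
        xb, yb = xy(g, d, np.array(rows), np.array(cols))
        if len(xb) >= 3 and xb.std() > 0:
            s, _ = rma(xb, yb)
            if math.isfinite(s):
                slopes.append(s)
    if slopes:
        ci_low, ci_high = np.percentile(slopes, [2.5, 97.5])
    else:
        ci_low = ci_high = math.nan

    return IbdResult(r_obs, p_val, slope, intercept, r_obs**2,
                     float(ci_low), float(ci_high), len(x))


# ---------------------------------------------------------------------------
# Monmonier barriers
# ---------------------------------------------------------------------------

Edge = tuple[int, int]


@dataclass
class BarrierResult:
    edges: list[Edge]                     # all Delaunay edges (i<j)
    barriers: list[list[Edge]]            # ordered crossed-edge polylines
    supports: dict[Edge, float] = field(default_factory=dict)
    n_groups: int = 1


def _project(lat: np.ndarray, lon: np.ndarray) -> np.ndarray:
    """Equirectangular projection scaled by cos(mean latitude)."""
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    scale = math.cos(math.radians(lat.mean()))
    return np.column_stack([lon * scale, lat])


def delaunay_edges(lat: np.ndarray, lon: np.ndarray):
    """Delaunay triangulation; returns (tri, sorted edge list, edge→triangles)."""
    pts = _project(lat, lon)
    try:
        tri = Delaunay(pts)
    except Exception as exc:  # scipy QhullError on degenerate input
        raise ValueError(f"Delaunay triangulation failed (collinear points?): {exc}") from exc
    if tri.simplices.size == 0:
        raise ValueError("Delaunay triangulation failed: collinear points")
    edge_tris: dict[Edge, list[int]] = {}
    for t, simplex in enumerate(tri.simplices):
        for a, b in itertools.combinations(sorted(simplex), 2):
            edge_tris.setdefault((a, b), []).append(t)
    edges = sorted(edge_tris)
    return tri, edges, edge_tris


def _n_components(n: int, edges: list[Edge], crossed: set[Edge]) -> int:
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for e in edges:
        if e not in crossed:
            ra, rb = find(e[0]), find(e[1])
            if ra != rb:
                parent[ra] = rb
    return len({find(i) for i in range(n)})


def monmonier_barriers(lat: np.ndarray, lon: np.ndarray, distance: np.ndarray,
                       k_max: int = 2) -> BarrierResult:
    """Trace Monmonier maximum-difference barriers on the Delaunay graph.

    Each barrier is seeded at the largest-distance uncrossed edge (ties
    broken by lowest edge index) and extended from both of its sides by
    repeatedly crossing the adjacent triangle's larger-distance edge, until
    it exits at the convex hull or meets an already crossed edge.  New
    barriers are added until the Delaunay graph minus crossed edges falls
    into ``k_max`` connected components (or no uncrossed edges remain).
    """
    distance = np.asarray(distance, dtype=float)
    if np.abs(distance - distance.T).max(initial=0) > 1e-10:
        raise ValueError("distance matrix must be symmetric")
    tri, edges, edge_tris = delaunay_edges(lat, lon)
    n = len(lat)
    edge_index = {e: i for i, e in enumerate(edges)}

    def dist_of(e: Edge) -> float:
        return distance[e[0], e[1]]

    crossed: set[Edge] = set()
    barriers: list[list[Edge]] = []

    def other_edges(t: int, e: Edge) -> list[Edge]:
        out = []
        for a, b in itertools.combinations(sorted(tri.simplices[t]), 2):
            if (a, b) != e:
                out.append((a, b))
        return out

    def extend(e: Edge, t: int, path: list[Edge], append: bool) -> None:
        """Walk from edge ``e`` into triangle ``t``, crossing onward."""
        while t is not None:
            candidates = [c for c in other_edges(t, e) if c not in crossed]
            if not candidates:
                return
            nxt = max(candidates, key=lambda c: (dist_of(c), -edge_index[c]))
            crossed.add(nxt)
            if append:
                path.append(nxt)
            else:
                path.insert(0, nxt)
            nbrs = [tt for tt in edge_tris[nxt] if tt != t]
            t = nbrs[0] if nbrs else None
            e = nxt

    while len(crossed) < len(edges):
        if _n_components(n, edges, crossed) >= k_max:
            break
        free = [e for e in edges if e not in crossed]
        seed = max(free, key=lambda e: (dist_of(e), -edge_index[e]))
        crossed.add(seed)
        path = [seed]
        tris = edge_tris[seed]
        extend(seed, tris[0], path, append=True)
        if len(tris) > 1:
            extend(seed, tris[1], path, append=False)
        barriers.append(path)

    return BarrierResult(edges, barriers, n_groups=_n_components(n, edges, crossed))


def barrier_bootstrap(dataset: GenotypeDataset, lat: np.ndarray, lon: np.ndarray,
                      n_boot: int = 999, k_max: int = 2,
                      seed: int | None = None) -> BarrierResult:
    """Barriers on linearized F_ST with locus-bootstrap edge supports.

    Loci are resampled with replacement; the pairwise linearized F_ST matrix
    and the barriers are recomputed, and the support of each originally
    crossed edge is the fraction of replicates in which any barrier crosses
    it.  Refuses single-locus datasets (degenerate bootstrap).
    """
    if dataset.n_loci < 2:
        raise ValueError("locus bootstrap requires >= 2 loci")
    rng = np.random.default_rng(seed)
    base = linearized_fst_matrix(dataset).to_numpy()
    result = monmonier_barriers(lat, lon, base, k_max)
    watched = {e for path in result.barriers for e in path}
    hits = {e: 0 for e in watched}
    for _ in range(n_boot):
        pick = rng.integers(0, dataset.n_loci, dataset.n_loci)
        boot = GenotypeDataset(
            individuals=list(dataset.individuals),
            loci=[f"L{i}" for i in range(dataset.n_loci)],
            calls=dataset.calls[:, pick, :].copy(),
            populations=dict(dataset.populations),
            groups=dict(dataset.groups),
        )
        m = linearized_fst_matrix(boot).to_numpy()
        rep = monmonier_barriers(lat, lon, m, k_max)
        crossed = {e for path in rep.barriers for e in path}
        for e in watched & crossed:
            hits[e] += 1
    result.supports = {e: hits[e] / n_boot for e in watched}
    return result


def ibd_from_dataset(dataset: GenotypeDataset, lat: np.ndarray, lon: np.ndarray,
                     n_perm: int = 9999, n_boot: int = 1000,
                     seed: int | None = None) -> IbdResult:
    """End-to-end IBD: pairwise linearized F_ST vs log great-circle distance."""
    gen = linearized_fst_matrix(dataset).to_numpy()
    geo = haversine_matrix(lat, lon)
    return mantel_rma(gen, geo, n_perm=n_perm, n_boot=n_boot, seed=seed)
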