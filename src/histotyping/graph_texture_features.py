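"""Gland-architecture graph features and Haralick texture features.

Completes the 242-feature catalog:

* global graph block (52): Voronoi cell geometry, Delaunay edges and
  triangles, Euclidean MST edges, nearest-neighbor distances, and local
  gland density;
* sub-graph block (68): 17 metrics of the connected components of an
  epsilon-neighborhood graph on gland centroids, aggregated by
  {mean, SD, skewness, excess kurtosis};
* Haralick block (26): 13 classical gray-level co-occurrence statistics of
  the tumor-region texture, each summarized by its mean and range over the
  four principal co-occurrence directions.

Catalog order is fixed: shape (96) + graph (52) + subgraph (68) +
haralick (26) = 242.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.spatial import Delaunay, cKDTree
from scipy.stats import kurtosis as _kurtosis
from scipy.stats import skew as _skew
from shapely.geometry import MultiPoint, Polygon
from shapely.ops import voronoi_diagram
from skimage.color import rgb2gray
from skimage.draw import polygon as draw_polygon

from .io_core import SENTINEL, AnnotationPolygon, LumenSet, RegionImage, ValidationError
from .shape_features import SHAPE_FEATURE_NAMES, STAT_NAMES, aggregate, shape_block

# ---------------------------------------------------------------------------
# Catalog definition
# ---------------------------------------------------------------------------

_GRAPH_FAMILIES: tuple[tuple[str, str], ...] = (
    ("voronoi", "cell_area"),
    ("voronoi", "cell_perimeter"),
    ("voronoi", "cell_chord"),
    ("delaunay", "edge_length"),
    ("delaunay", "triangle_area"),
    ("mst", "edge_length"),
    ("nn", "dist_1"),
    ("nn", "dist_3"),
    ("nn", "dist_5"),
    ("density", "count_r50"),
    ("density", "count_r100"),
    ("density", "area_fraction_r100"),
)

_DENSITY_SCALARS: tuple[str, ...] = (
    "gland_count",
    "glands_per_mm2",
    "mean_gland_area",
    "gland_area_fraction",
)

GRAPH_FEATURE_NAMES: tuple[str, ...] = tuple(
    f"graph:{family}:{stat}:{metric}"
    for family, metric in _GRAPH_FAMILIES
    for stat in STAT_NAMES
) + tuple(f"graph:density:{name}" for name in _DENSITY_SCALARS)

#: edge_length is pooled over all sub-graph edges; the other 16 metrics are
#: one value per connected component.
SUBGRAPH_METRICS: tuple[str, ...] = (
    "edge_length",
    "node_count",
    "edge_count",
    "total_edge_length",
    "mean_edge_length",
    "max_edge_length",
    "min_edge_length",
    "density",
    "mean_degree",
    "max_degree",
    "diameter",
    "radius",
    "mean_eccentricity",
    "clustering_coefficient",
    "mean_path_length",
    "hull_area",
    "spatial_extent",
)

SUBGRAPH_STATS: tuple[str, ...] = ("mean", "sd", "skewness", "kurtosis")

SUBGRAPH_FEATURE_NAMES: tuple[str, ...] = tuple(
    f"subgraph:{stat}:{metric}"
    for metric in SUBGRAPH_METRICS
    for stat in SUBGRAPH_STATS
)

HARALICK_STATS: tuple[str, ...] = (
    "asm",
    "contrast",
    "correlation",
    "variance",
    "idm",
    "sum_average",
    "sum_variance",
    "sum_entropy",
    "entropy",
    "difference_variance",
    "difference_entropy",
    "imc1",
    "imc2",
)

HARALICK_FEATURE_NAMES: tuple[str, ...] = tuple(
    f"haralick:{agg}:{stat}" for stat in HARALICK_STATS for agg in ("mean", "range")
)


def catalog_names() -> list[str]:
    """The fixed 242-name feature catalog, in extraction order."""
    return (
        list(SHAPE_FEATURE_NAMES)
        + list(GRAPH_FEATURE_NAMES)
        + list(SUBGRAPH_FEATURE_NAMES)
        + list(HARALICK_FEATURE_NAMES)
    )


def catalog_table() -> list[dict[str, str]]:
    """Catalog rows (name, family, statistic, metric) for export."""
    rows = []
    for name in catalog_names():
        parts = name.split(":")
        if len(parts) == 3:
            family, stat, metric = parts
        else:
            family, sub, stat, metric = parts[0], parts[1], parts[2], parts[3]
            family = f"{family}:{sub}"
        rows.append({"name": name, "family": family, "statistic": stat, "metric": metric})
    return rows


@dataclass
class FeatureVector:
    """An ordered, named feature vector for one region."""

    names: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.names = tuple(self.names)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.names) != self.values.size:
            raise ValidationError("feature names/values length mismatch")

    def __len__(self) -> int:
        return self.values.size

    def __getitem__(self, name: str) -> float:
        return float(self.values[self.names.index(name)])

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.names, self.values))


# ---------------------------------------------------------------------------
# Gland graphs
# ---------------------------------------------------------------------------

@dataclass
class GlandGraphs:
    """Voronoi / Delaunay / MST / nearest-neighbor structure on centroids."""

    centroids: np.ndarray
    present: bool = False
    voronoi_cells: list[Polygon] = field(default_factory=list)
    delaunay_edges: np.ndarray = field(default_factory=lambda: np.empty((0, 2), int))
    triangles: np.ndarray = field(default_factory=lambda: np.empty((0, 3), int))
    mst_edges: np.ndarray = field(default_factory=lambda: np.empty((0, 3)))
    nn_distances: np.ndarray = field(default_factory=lambda: np.empty((0, 3)))


def _collinear(pts: np.ndarray) -> bool:
    centered = pts - pts.mean(axis=0)
    return np.linalg.matrix_rank(centered, tol=1e-9) < 2


def build_graphs(ls: LumenSet) -> GlandGraphs:
    """Voronoi (clipped to the annotation), Delaunay, MST and k-NN structure.

    With < 3 lumens or collinear centroids the graphs are marked absent and
    dependent features fall back to sentinels.
    """
    pts = ls.centroids
    k = len(pts)
    if k < 3 or _collinear(pts):
        return GlandGraphs(centroids=pts, present=False)

    region = ls.region.polygon
    cells = voronoi_diagram(MultiPoint([tuple(p) for p in pts]), envelope=region)
    clipped: list[Polygon] = [None] * k  # type: ignore[list-item]
    tree = cKDTree(pts)
    for cell in cells.geoms:
        inter = cell.intersection(region)
        if inter.is_empty:
            continue
        rep = cell.representative_point()
        owner = int(tree.query([rep.x, rep.y])[1])
        if inter.geom_type == "MultiPolygon":
            inter = max(inter.geoms, key=lambda g: g.area)
        clipped[owner] = inter
    vor_cells = [c for c in clipped if c is not None]

    tri = Delaunay(pts)
    edges = set()
    for simplex in tri.simplices:
        for a, b in itertools.combinations(simplex, 2):
            edges.add((min(a, b), max(a, b)))
    delaunay_edges = np.array(sorted(edges), dtype=int)

    dist = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
    mst = minimum_spanning_tree(sparse.csr_matrix(dist)).tocoo()
    mst_edges = np.column_stack([mst.row, mst.col, mst.data])

    nnd, _ = tree.query(pts, k=min(6, k))
    want = [1, 3, 5]
    nn = np.full((k, 3), np.nan)
    for col, kk in enumerate(want):
        if kk < nnd.shape[1]:
            nn[:, col] = nnd[:, kk]
    return GlandGraphs(
        centroids=pts,
        present=True,
        voronoi_cells=vor_cells,
        delaunay_edges=delaunay_edges,
        triangles=tri.simplices.copy(),
        mst_edges=mst_edges,
        nn_distances=nn,
    )


def _cell_chord(cell: Polygon) -> float:
    verts = np.asarray(cell.exterior.coords)[:-1]
    if len(verts) < 2:
        return 0.0
    d = np.linalg.norm(verts[:, None] - verts[None, :], axis=-1)
    iu = np.triu_indices(len(verts), 1)
    return float(np.mean(d[iu]))


def global_graph_block(
    g: GlandGraphs,
    ls: LumenSet,
    density_radii: tuple[float, float] = (50.0, 100.0),
) -> dict[str, float]:
    """The 52 global architecture features of a region."""
    out = {name: SENTINEL for name in GRAPH_FEATURE_NAMES}
    pts = g.centroids
    k = len(pts)
    region_area = ls.region.area
    areas = np.array([p.area for p in ls.lumens]) if ls.lumens else np.array([])

    # density scalars are defined for any gland count
    if k >= 1:
        out["graph:density:gland_count"] = float(k)
        out["graph:density:glands_per_mm2"] = float(k / (region_area / 1e6))
        out["graph:density:mean_gland_area"] = float(np.mean(areas))
        out["graph:density:gland_area_fraction"] = float(np.sum(areas) / region_area)

    if not g.present:
        return out

    def put(family: str, metric: str, values: np.ndarray) -> None:
        stats = aggregate(values)
        for stat in STAT_NAMES:
            out[f"graph:{family}:{stat}:{metric}"] = stats[stat]

    put("voronoi", "cell_area", np.array([c.area for c in g.voronoi_cells]))
    put("voronoi", "cell_perimeter", np.array([c.length for c in g.voronoi_cells]))
    put("voronoi", "cell_chord", np.array([_cell_chord(c) for c in g.voronoi_cells]))

    d_len = np.linalg.norm(
        pts[g.delaunay_edges[:, 0]] - pts[g.delaunay_edges[:, 1]], axis=1
    )
    put("delaunay", "edge_length", d_len)
    tri_pts = pts[g.triangles]
    u = tri_pts[:, 1] - tri_pts[:, 0]
    v = tri_pts[:, 2] - tri_pts[:, 0]
    tri_area = 0.5 * np.abs(u[:, 0] * v[:, 1] - u[:, 1] * v[:, 0])
    put("delaunay", "triangle_area", tri_area)
    put("mst", "edge_length", g.mst_edges[:, 2])
    for col, kk in enumerate([1, 3, 5]):
        put("nn", f"dist_{kk}", g.nn_distances[:, col])

    dist = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
    r50, r100 = density_radii
    put("density", "count_r50", (dist <= r50).sum(axis=1) - 1.0)
    put("density", "count_r100", (dist <= r100).sum(axis=1) - 1.0)
    # local gland-area fraction: lumen area (by centroid membership) within
    # the r100 disk around each gland, over the disk area
    local_area = np.array(
        [np.sum(areas[dist[i] <= r100]) for i in range(k)]
    )
    put("density", "area_fraction_r100", local_area / (np.pi * r100**2))
    return out


# ---------------------------------------------------------------------------
# Sub-graph features
# ---------------------------------------------------------------------------

def _moment_stats(values: np.ndarray) -> dict[str, float]:
    """mean/SD/skewness/excess-kurtosis with pinned degenerate conventions.

    Sample-moment estimators; skewness and kurtosis are 0 for zero-variance
    input (and for n < 2); SD uses ddof=1 (0 for a single value).
    """
    vals = np.asarray(values, dtype=float)
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        return {s: SENTINEL for s in SUBGRAPH_STATS}
    mean = float(np.mean(vals))
    sd = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
    # zero-variance convention: constant input (to float noise) -> 0
    if vals.size < 2 or np.ptp(vals) <= 1e-9 * max(1.0, abs(mean)):
        sk, ku = 0.0, 0.0
    else:
        sk = float(_skew(vals, bias=True))
        ku = float(_kurtosis(vals, fisher=True, bias=True))
    return {"mean": mean, "sd": sd, "skewness": sk, "kurtosis": ku}


def subgraph_epsilon(centroids: np.ndarray, factor: float = 2.0) -> float:
    """Data-adaptive neighborhood radius: factor x median 1-NN distance."""
    if len(centroids) < 2:
        return 0.0
    tree = cKDTree(centroids)
    d1 = tree.query(centroids, k=2)[0][:, 1]
    return float(factor * np.median(d1))


def subgraph_block(
    ls: LumenSet, epsilon: float | None = None, epsilon_factor: float = 2.0
) -> dict[str, float]:
    """The 68 sub-graph features: 17 metrics x {mean, sd, skewness, kurtosis}.

    The graph joins centroids closer than epsilon (default 2x the median
    1-NN distance).  ``edge_length`` is pooled over all edges of all
    components; the remaining metrics are one value per component.
    """
    out = {name: SENTINEL for name in SUBGRAPH_FEATURE_NAMES}
    pts = ls.centroids
    k = len(pts)
    if k < 1:
        return out
    if epsilon is None:
        epsilon = subgraph_epsilon(pts, epsilon_factor)

    G = nx.Graph()
    G.add_nodes_from(range(k))
    if k >= 2 and epsilon > 0:
        tree = cKDTree(pts)
        for i, j in tree.query_pairs(epsilon):
            G.add_edge(i, j, length=float(np.linalg.norm(pts[i] - pts[j])))

    pooled_lengths = np.array([d["length"] for _, _, d in G.edges(data=True)])
    per_comp: dict[str, list[float]] = {m: [] for m in SUBGRAPH_METRICS[1:]}
    for comp_nodes in nx.connected_components(G):
        sub = G.subgraph(comp_nodes)
        n, m = sub.number_of_nodes(), sub.number_of_edges()
        lengths = np.array([d["length"] for _, _, d in sub.edges(data=True)])
        degs = np.array([d for _, d in sub.degree()])
        cpts = pts[list(comp_nodes)]
        per_comp["node_count"].append(float(n))
        per_comp["edge_count"].append(float(m))
        per_comp["total_edge_length"].append(float(lengths.sum()) if m else 0.0)
        per_comp["mean_edge_length"].append(float(lengths.mean()) if m else SENTINEL)
        per_comp["max_edge_length"].append(float(lengths.max()) if m else SENTINEL)
        per_comp["min_edge_length"].append(float(lengths.min()) if m else SENTINEL)
        per_comp["density"].append(float(nx.density(sub)) if n > 1 else 0.0)
        per_comp["mean_degree"].append(float(degs.mean()))
        per_comp["max_degree"].append(float(degs.max()))
        if n > 1:
            ecc = nx.eccentricity(sub)
            eccs = np.array(list(ecc.values()), dtype=float)
            per_comp["diameter"].append(float(eccs.max()))
            per_comp["radius"].append(float(eccs.min()))
            per_comp["mean_eccentricity"].append(float(eccs.mean()))
            per_comp["mean_path_length"].append(
                float(nx.average_shortest_path_length(sub))
            )
        else:
            per_comp["diameter"].append(0.0)
            per_comp["radius"].append(0.0)
            per_comp["mean_eccentricity"].append(0.0)
            per_comp["mean_path_length"].append(0.0)
        per_comp["clustering_coefficient"].append(
            float(nx.average_clustering(sub)) if n > 1 else 0.0
        )
        hull_area = MultiPoint([tuple(p) for p in cpts]).convex_hull.area
        per_comp["hull_area"].append(float(hull_area))
        if n > 1:
            dd = np.linalg.norm(cpts[:, None] - cpts[None, :], axis=-1)
            per_comp["spatial_extent"].append(float(dd.max()))
        else:
            per_comp["spatial_extent"].append(0.0)

    if pooled_lengths.size:
        stats = _moment_stats(pooled_lengths)
        for stat in SUBGRAPH_STATS:
            out[f"subgraph:{stat}:edge_length"] = stats[stat]
    for metric in SUBGRAPH_METRICS[1:]:
        stats = _moment_stats(np.array(per_comp[metric]))
        for stat in SUBGRAPH_STATS:
            out[f"subgraph:{stat}:{metric}"] = stats[stat]
    return out


# ---------------------------------------------------------------------------
# Haralick texture
# ---------------------------------------------------------------------------

_ANGLE_OFFSETS: tuple[tuple[int, int], ...] = ((0, 1), (-1, 1), (-1, 0), (-1, -1))


def region_mask(img: RegionImage, region: AnnotationPolygon) -> np.ndarray:
    """Boolean raster of the annotation polygon on the image grid."""
    h, w = img.shape_px
    mpp = img.microns_per_pixel
    rr, cc = draw_polygon(
        region.vertices[:, 1] / mpp - 0.5,
        region.vertices[:, 0] / mpp - 0.5,
        shape=(h, w),
    )
    mask = np.zeros((h, w), dtype=bool)
    mask[rr, cc] = True
    return mask


def quantize_region(gray: np.ndarray, mask: np.ndarray, levels: int = 32) -> np.ndarray:
    """Min-max quantize the in-region grayscale to ``levels`` bins."""
    q = np.zeros_like(gray, dtype=np.int32)
    vals = gray[mask]
    lo, hi = float(vals.min()), float(vals.max())
    if hi > lo:
        q[mask] = np.minimum(
            ((gray[mask] - lo) / (hi - lo) * levels).astype(np.int32), levels - 1
        )
    return q


def glcm_matrix(
    q: np.ndarray, mask: np.ndarray, offset: tuple[int, int], levels: int = 32
) -> np.ndarray:
    """Symmetric, normalized gray-level co-occurrence matrix at one offset.

    Only pixel pairs with both endpoints inside the region mask count.
    """
    di, dj = offset
    h, w = q.shape
    src = np.zeros((h, w), dtype=bool)
    i0, i1 = max(0, -di), min(h, h - di)
    j0, j1 = max(0, -dj), min(w, w - dj)
    src[i0:i1, j0:j1] = mask[i0:i1, j0:j1] & mask[i0 + di : i1 + di, j0 + dj : j1 + dj]
    a = q[src]
    ii, jj = np.nonzero(src)
    b = q[ii + di, jj + dj]
    P = np.zeros((levels, levels))
    np.add.at(P, (a, b), 1.0)
    P = P + P.T
    total = P.sum()
    if total > 0:
        P = P / total
    return P


def haralick_statistics(P: np.ndarray) -> dict[str, float]:
    """The 13 classical Haralick statistics of a normalized GLCM.

    Natural logarithms; 0*log(0) := 0; correlation and IMC1 are 0 when
    their denominators vanish (single-level region).
    """
    levels = P.shape[0]
    i = np.arange(levels)
    I, J = np.meshgrid(i, i, indexing="ij")
    px = P.sum(axis=1)
    py = P.sum(axis=0)
    mu_x = float(np.sum(i * px))
    mu_y = float(np.sum(i * py))
    sd_x = float(np.sqrt(np.sum((i - mu_x) ** 2 * px)))
    sd_y = float(np.sqrt(np.sum((i - mu_y) ** 2 * py)))

    def xlogx(p: np.ndarray) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(p > 0, p * np.log(p), 0.0)

    p_sum = np.zeros(2 * levels - 1)
    np.add.at(p_sum, I.ravel() + J.ravel(), P.ravel())
    p_diff = np.zeros(levels)
    np.add.at(p_diff, np.abs(I - J).ravel(), P.ravel())
    ks = np.arange(2 * levels - 1)
    kd = np.arange(levels)

    asm = float(np.sum(P**2))
    contrast = float(np.sum((I - J) ** 2 * P))
    if sd_x > 0 and sd_y > 0:
        correlation = float((np.sum(I * J * P) - mu_x * mu_y) / (sd_x * sd_y))
    else:
        correlation = 0.0
    grand_mu = float(np.sum(I * P))
    variance = float(np.sum((I - grand_mu) ** 2 * P))
    idm = float(np.sum(P / (1.0 + (I - J) ** 2)))
    sum_average = float(np.sum(ks * p_sum))
    sum_variance = float(np.sum((ks - sum_average) ** 2 * p_sum))
    sum_entropy = float(-np.sum(xlogx(p_sum)))
    entropy = float(-np.sum(xlogx(P)))
    diff_mean = float(np.sum(kd * p_diff))
    difference_variance = float(np.sum((kd - diff_mean) ** 2 * p_diff))
    difference_entropy = float(-np.sum(xlogx(p_diff)))
    hx = float(-np.sum(xlogx(px)))
    hy = float(-np.sum(xlogx(py)))
    PxPy = np.outer(px, py)
    with np.errstate(divide="ignore", invalid="ignore"):
        hxy1 = float(-np.sum(np.where(PxPy > 0, P * np.log(PxPy), 0.0)))
        hxy2 = float(-np.sum(np.where(PxPy > 0, PxPy * np.log(PxPy), 0.0)))
    denom = max(hx, hy)
    imc1 = float((entropy - hxy1) / denom) if denom > 0 else 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - entropy)))))
    return {
        "asm": asm,
        "contrast": contrast,
        "correlation": correlation,
        "variance": variance,
        "idm": idm,
        "sum_average": sum_average,
        "sum_variance": sum_variance,
        "sum_entropy": sum_entropy,
        "entropy": entropy,
        "difference_variance": difference_variance,
        "difference_entropy": difference_entropy,
        "imc1": imc1,
        "imc2": imc2,
    }


def haralick_block(
    img: RegionImage,
    region: AnnotationPolygon,
    levels: int = 32,
    distance: int = 1,
) -> dict[str, float]:
    """The 26 Haralick features: per-statistic mean and range over 4 angles.

    The luminance inside the annotation is quantized to ``levels`` gray
    levels; co-occurrence matrices are symmetric, normalized, at the given
    pixel distance along 0/45/90/135 degrees.  Regions smaller than
    64x64 um^2 yield sentinels.
    """
    out = {name: SENTINEL for name in HARALICK_FEATURE_NAMES}
    if region.area < 64.0**2:
        return out
    if abs(img.microns_per_pixel - 1.0) > 1e-9:
        raise ValidationError("haralick_block requires a 1 um/px image")
    gray = rgb2gray(img.pixels)
    mask = region_mask(img, region)
    if mask.sum() < 2:
        return out
    q = quantize_region(gray, mask, levels)
    per_angle = []
    for di, dj in _ANGLE_OFFSETS:
        P = glcm_matrix(q, mask, (di * distance, dj * distance), levels)
        per_angle.append(haralick_statistics(P))
    for stat in HARALICK_STATS:
        vals = np.array([pa[stat] for pa in per_angle])
        out[f"haralick:mean:{stat}"] = float(np.mean(vals))
        out[f"haralick:range:{stat}"] = float(np.max(vals) - np.min(vals))
    return out


# ---------------------------------------------------------------------------
# Full vector
# ---------------------------------------------------------------------------

def full_feature_vector(
    ls: LumenSet,
    img: RegionImage | None = None,
    region: AnnotationPolygon | None = None,
    epsilon_factor: float = 2.0,
    density_radii: tuple[float, float] = (50.0, 100.0),
) -> FeatureVector:
    """Extract the complete 242-feature vector of one region.

    ``img`` may be None (geometry-only input), in which case the Haralick
    block is sentinel-valued — downstream statistics exclude missing values
    pairwise.
    """
    if region is None:
        region = ls.region
    values: dict[str, float] = {}
    values.update(shape_block(ls))
    graphs = build_graphs(ls)
    values.update(global_graph_block(graphs, ls, density_radii))
    values.update(subgraph_block(ls, epsilon_factor=epsilon_factor))
    if img is not None:
        values.update(haralick_block(img, region))
    else:
        values.update({name: SENTINEL for name in HARALICK_FEATURE_NAMES})
    names = catalog_names()
    return FeatureVector(names=tuple(names), values=np.array([values[n] for n in names]))
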