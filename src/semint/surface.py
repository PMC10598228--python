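"""Surface-based mixed-effects multilevel analysis (SB-MEMA) on a mesh.

Per-subject effect estimates (with within-subject variances) are projected
onto the nearest vertex of a shared triangulated cortical surface, smoothed
with a geodesic Gaussian kernel (3 mm FWHM by default), and combined
node-wise with a random-effects meta-analysis (DerSimonian-Laird
heterogeneity).  Familywise error over the surface is controlled with a
Monte-Carlo white-noise cluster simulation of the same mesh and smoothness:
the minimum surviving cluster size is the upper quantile of the maximal
suprathreshold cluster under smoothed white noise.  Thresholded contrast
maps are combined into per-node Boolean conjunction codes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse.csgraph import connected_components, dijkstra
from scipy.spatial.distance import cdist

FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))  # 2.3548...


@dataclass
class SurfaceMesh:
    """Triangulated surface: vertices (n x 3, mm) and faces (m x 3)."""

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("vertices must be n x 3")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise ValueError("faces must be m x 3")
        if self.faces.size and (
            self.faces.min() < 0 or self.faces.max() >= len(self.vertices)
        ):
            raise ValueError("face indices out of range")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def edges(self) -> np.ndarray:
        """Unique undirected edges (k x 2, sorted vertex pairs)."""
        e = np.vstack(
            [self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]]
        )
        e = np.sort(e, axis=1)
        e = e[e[:, 0] != e[:, 1]]  # drop degenerate self-edges
        return np.unique(e, axis=0)

    def adjacency(self, weighted: bool = True) -> sparse.csr_matrix:
        """Sparse symmetric adjacency; weights are Euclidean edge lengths."""
        e = self.edges
        if weighted:
            w = np.linalg.norm(
                self.vertices[e[:, 0]] - self.vertices[e[:, 1]], axis=1
            )
            if np.any(w <= 0):
                raise ValueError("mesh has zero-length edges")
        else:
            w = np.ones(len(e))
        n = self.n_vertices
        mat = sparse.coo_matrix(
            (np.r_[w, w], (np.r_[e[:, 0], e[:, 1]], np.r_[e[:, 1], e[:, 0]])),
            shape=(n, n),
        )
        return mat.tocsr()

    def euler_characteristic(self) -> int:
        return self.n_vertices - len(self.edges) + len(self.faces)

    def to_gifti(self, path) -> None:
        import nibabel as nib

        img = nib.gifti.GiftiImage(
            darrays=[
                nib.gifti.GiftiDataArray(
                    self.vertices.astype(np.float32), intent="NIFTI_INTENT_POINTSET"
                ),
                nib.gifti.GiftiDataArray(
                    self.faces.astype(np.int32), intent="NIFTI_INTENT_TRIANGLE"
                ),
            ]
        )
        nib.save(img, str(path))

    @classmethod
    def from_gifti(cls, path) -> "SurfaceMesh":
        import nibabel as nib

        img = nib.load(str(path))
        verts = faces = None
        for da in img.darrays:
            if da.intent == 1008:  # pointset
                verts = da.data
            elif da.intent == 1009:  # triangle
                faces = da.data
        if verts is None or faces is None:
            raise ValueError(f"{path}: GIFTI lacks pointset/triangle arrays")
        return cls(verts, faces)


@dataclass
class SubjectNodeMap:
    """Per-subject node-wise effect estimate with within-subject variance."""

    subject_id: str
    effect: np.ndarray
    variance: np.ndarray
    covered: np.ndarray

    def __post_init__(self) -> None:
        self.covered = np.asarray(self.covered, dtype=bool)
        self.effect = np.asarray(self.effect, dtype=np.float64)
        self.variance = np.asarray(self.variance, dtype=np.float64)
        if not (self.effect.shape == self.variance.shape == self.covered.shape):
            raise ValueError("effect, variance and covered must share shape")
        if np.any(self.variance[self.covered] < 0):
            raise ValueError("variance must be >= 0 where covered")


@dataclass
class MemaMap:
    """Group-level node-wise random-effects result."""

    effect: np.ndarray
    t_stat: np.ndarray
    df: np.ndarray
    coverage: np.ndarray
    percent_bga: np.ndarray
    tau2: np.ndarray
    min_coverage: int


@dataclass
class ClusterThreshold:
    """Monte-Carlo cluster criterion for familywise error control."""

    vertex_threshold: float
    alpha: float
    min_cluster_size: int
    n_iterations: int
    seed: int
    max_sizes: np.ndarray = field(repr=False, default=None)


@dataclass
class ConjunctionMap:
    """Per-node Boolean combination code over named contrasts."""

    contrasts: list[str]
    bits: np.ndarray  # n_nodes x n_contrasts boolean
    code: np.ndarray  # integer code, bit i = contrast i

    def labels(self) -> np.ndarray:
        """Human-readable codes like 'R+C+N' (first letter of each contrast)."""
        initials = [c[0].upper() for c in self.contrasts]
        out = np.empty(len(self.code), dtype=object)
        for i, row in enumerate(self.bits):
            parts = [initials[j] for j in range(len(initials)) if row[j]]
            out[i] = "+".join(parts)
        return out


def project_electrodes(mesh: SurfaceMesh, coords: np.ndarray) -> np.ndarray:
    """Nearest mesh vertex (Euclidean) per electrode; ties -> lowest index."""
    coords = np.atleast_2d(np.asarray(coords, dtype=np.float64))
    if mesh.n_vertices == 0:
        raise ValueError("empty mesh")
    if not np.all(np.isfinite(coords)):
        raise ValueError("electrode coordinates must be finite")
    d = cdist(coords, mesh.vertices)
    return np.argmin(d, axis=1)  # argmin returns the first (lowest) index on ties


def smoothing_kernel(
    mesh: SurfaceMesh, fwhm: float, cutoff_sigmas: float = 3.0
) -> sparse.csr_matrix:
    """Row-normalized geodesic Gaussian kernel matrix.

    Geodesic distance is the shortest path over mesh edges (Dijkstra with
    Euclidean edge lengths).  K(d) ~ exp(-d^2 / (2 sigma^2)) with
    sigma = fwhm / 2.3548, truncated at ``cutoff_sigmas * sigma`` and
    normalized so each row sums to 1 (an isolated node keeps its value).
    """
    if fwhm <= 0:
        raise ValueError("fwhm must be positive")
    sigma = fwhm / FWHM_TO_SIGMA
    limit = cutoff_sigmas * sigma
    adj = mesh.adjacency(weighted=True)
    dist = dijkstra(adj, directed=False, limit=limit)
    with np.errstate(over="ignore"):
        k = np.exp(-(dist**2) / (2.0 * sigma**2))
    k[~np.isfinite(dist)] = 0.0
    np.fill_diagonal(k, 1.0)  # self-distance 0; keeps isolated nodes
    k /= k.sum(axis=1, keepdims=True)
    return sparse.csr_matrix(k)


def geodesic_smooth(
    mesh: SurfaceMesh,
    values: np.ndarray,
    fwhm: float,
    weights: np.ndarray | None = None,
    kernel: sparse.csr_matrix | None = None,
) -> np.ndarray:
    """Geodesic Gaussian smoothing of node values.

    With ``weights`` (e.g. a coverage mask) the result is the
    weight-normalized smooth K(w*v)/K(w), leaving nodes with zero smoothed
    weight at 0.  A precomputed ``kernel`` avoids repeated Dijkstra runs.
    """
    k = kernel if kernel is not None else smoothing_kernel(mesh, fwhm)
    v = np.asarray(values, dtype=np.float64)
    if weights is None:
        return np.asarray(k @ v)
    w = np.asarray(weights, dtype=np.float64)
    num = np.asarray(k @ (w * v))
    den = np.asarray(k @ w)
    out = np.zeros_like(num)
    nz = den > 0
    out[nz] = num[nz] / den[nz]
    return out


def mema(
    subject_maps: list[SubjectNodeMap],
    min_coverage: int = 3,
    floor_variance: float = 1e-12,
) -> MemaMap:
    """Node-wise DerSimonian-Laird random-effects combination.

    At each node covered by at least ``min_coverage`` subjects, subject
    effects beta_i with within-subject variances s_i^2 are pooled with
    weights 1/(s_i^2 + tau^2); tau^2 is the DerSimonian-Laird moment
    estimate clipped at zero.  t = pooled / sqrt(1/sum(w)) with k-1 degrees
    of freedom.  Nodes below coverage (or with k < 2) get NaN statistics.
    """
    if not subject_maps:
        raise ValueError("need at least one subject map")
    if min_coverage < 1:
        raise ValueError("min_coverage must be >= 1")
    n = subject_maps[0].effect.shape[0]
    for m in subject_maps:
        if m.effect.shape[0] != n:
            raise ValueError("subject maps must share the mesh")
    beta = np.full((len(subject_maps), n), np.nan)
    var = np.full((len(subject_maps), n), np.nan)
    for i, m in enumerate(subject_maps):
        beta[i, m.covered] = m.effect[m.covered]
        var[i, m.covered] = np.maximum(m.variance[m.covered], floor_variance)
    covered = np.isfinite(beta)
    coverage = covered.sum(axis=0)
    ok = coverage >= max(min_coverage, 2)

    effect = np.full(n, np.nan)
    t_stat = np.full(n, np.nan)
    tau2 = np.full(n, np.nan)
    df = np.where(ok, coverage - 1, 0).astype(float)
    beta_sum = np.where(covered, beta, 0.0).sum(axis=0)
    percent_bga = np.where(coverage > 0, beta_sum / np.maximum(coverage, 1), np.nan)
    if ok.any():
        b = np.where(covered[:, ok], beta[:, ok], 0.0)
        w_fe = np.where(covered[:, ok], 1.0 / var[:, ok], 0.0)
        k = coverage[ok].astype(float)
        sw = w_fe.sum(axis=0)
        mu_fe = (w_fe * b).sum(axis=0) / sw
        q = (w_fe * (b - mu_fe) ** 2).sum(axis=0)
        c = sw - (w_fe**2).sum(axis=0) / sw
        with np.errstate(invalid="ignore", divide="ignore"):
            t2 = np.maximum(0.0, (q - (k - 1)) / c)
        w = np.where(covered[:, ok], 1.0 / (var[:, ok] + t2[None, :]), 0.0)
        sww = w.sum(axis=0)
        pooled = (w * b).sum(axis=0) / sww
        se = np.sqrt(1.0 / sww)
        effect[ok] = pooled
        t_stat[ok] = pooled / se
        tau2[ok] = t2
    return MemaMap(effect, t_stat, df, coverage, percent_bga, tau2, min_coverage)


def max_cluster_size(adjacency: sparse.csr_matrix, mask: np.ndarray) -> int:
    """Largest connected component among masked vertices (edge connectivity)."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return 0
    idx = np.flatnonzero(mask)
    sub = adjacency[np.ix_(idx, idx)]
    _, labels = connected_components(sub, directed=False)
    return int(np.bincount(labels).max())


def cluster_filter(
    adjacency: sparse.csr_matrix, mask: np.ndarray, min_size: int
) -> np.ndarray:
    """Keep only suprathreshold vertices in clusters of >= min_size."""
    mask = np.asarray(mask, dtype=bool)
    if min_size <= 1 or not mask.any():
        return mask.copy()
    idx = np.flatnonzero(mask)
    sub = adjacency[np.ix_(idx, idx)]
    _, labels = connected_components(sub, directed=False)
    sizes = np.bincount(labels)
    out = np.zeros_like(mask)
    out[idx[sizes[labels] >= min_size]] = True
    return out


def estimate_cluster_threshold(
    mesh: SurfaceMesh,
    fwhm: float,
    vertex_threshold: float,
    alpha: float = 0.01,
    n_iter: int = 5000,
    seed: int = 0,
    kernel: sparse.csr_matrix | None = None,
) -> ClusterThreshold:
    """Monte-Carlo white-noise calibration of the minimum cluster size.

    Each iteration draws i.i.d. standard-normal noise per vertex, smooths
    it with the geodesic Gaussian kernel, re-standardizes each vertex to
    unit variance, thresholds at ``vertex_threshold`` and records the
    largest suprathreshold cluster.  The minimum surviving cluster size is
    the ceiling of the (1 - alpha) quantile of these maxima, plus one.
    """
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    if n_iter < 100:
        raise ValueError("need at least 100 Monte-Carlo iterations")
    rng = np.random.default_rng(seed)
    k = kernel if kernel is not None else smoothing_kernel(mesh, fwhm)
    # per-vertex std of smoothed unit-variance white noise = row 2-norm
    row_norm = np.sqrt(np.asarray(k.multiply(k).sum(axis=1)).ravel())
    adj = mesh.adjacency(weighted=False)
    maxima = np.empty(n_iter, dtype=np.int64)
    for i in range(n_iter):
        z = np.asarray(k @ rng.standard_normal(mesh.n_vertices)) / row_norm
        maxima[i] = max_cluster_size(adj, z > vertex_threshold)
    min_size = int(np.ceil(np.quantile(maxima, 1.0 - alpha))) + 1
    return ClusterThreshold(
        vertex_threshold=float(vertex_threshold),
        alpha=float(alpha),
        min_cluster_size=min_size,
        n_iterations=int(n_iter),
        seed=int(seed),
        max_sizes=maxima,
    )


def threshold_map(
    m: MemaMap,
    t_min: float,
    pct_min: float = 0.0,
    min_coverage: int = 3,
    cluster: ClusterThreshold | None = None,
    adjacency: sparse.csr_matrix | None = None,
    mesh: SurfaceMesh | None = None,
) -> np.ndarray:
    """Binarize a group map: t, percent-change, coverage and cluster rules.

    A node passes iff t > t_min, |%BGA| > pct_min, coverage >= min_coverage
    and (when a cluster criterion is supplied) its connected suprathreshold
    cluster reaches the minimum size.
    """
    if not np.isfinite(t_min) or not np.isfinite(pct_min):
        raise ValueError("thresholds must be finite")
    with np.errstate(invalid="ignore"):
        mask = (
            (m.t_stat > t_min)
            & (np.abs(m.percent_bga) > pct_min)
            & (m.coverage >= min_coverage)
        )
    mask &= np.isfinite(m.t_stat)
    if cluster is not None:
        if adjacency is None:
            if mesh is None:
                raise ValueError("cluster filtering needs adjacency or mesh")
            adjacency = mesh.adjacency(weighted=False)
        mask = cluster_filter(adjacency, mask, cluster.min_cluster_size)
    return mask


def conjunction(binary_maps: dict[str, np.ndarray]) -> ConjunctionMap:
    """Per-node Boolean combination code of thresholded contrast maps."""
    if not binary_maps:
        raise ValueError("need at least one binary map")
    names = list(binary_maps)
    arrays = [np.asarray(binary_maps[k], dtype=bool) for k in names]
    n = arrays[0].shape[0]
    for name, a in zip(names, arrays):
        if a.shape != (n,):
            raise ValueError(f"map {name!r} does not share the mesh")
    bits = np.stack(arrays, axis=1)
    code = np.zeros(n, dtype=np.int64)
    for j in range(len(names)):
        code |= bits[:, j].astype(np.int64) << j
    return ConjunctionMap(contrasts=names, bits=bits, code=code)


def mema_to_frame(m: MemaMap) -> pd.DataFrame:
    """Node-wise table (node, effect, t, df, coverage, percent_bga)."""
    return pd.DataFrame(
        {
            "node": np.arange(len(m.effect)),
            "effect": m.effect,
            "t": m.t_stat,
            "df": m.df,
            "coverage": m.coverage,
            "percent_bga": m.percent_bga,
        }
    )
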