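"""Seed-driven graph-cut eyeball segmentation of CT volumes.

Foreground and background seeds drawn on a single axial slice define an
intensity model; segmentation of the whole volume is the global minimum of
the interactive-segmentation energy

    E(L) = sum_v U_v(L_v) + lambda * sum_{(v,w) in N} B_vw * [L_v != L_w]

with unary terms U_v(1) = -log P_fg(I_v), U_v(0) = -log P_bg(I_v) from the
seed histograms, and contrast-sensitive pairwise weights
B_vw = exp(-(I_v - I_w)^2 / (2 sigma_edge^2)) / dist(v, w) where dist is the
world distance between voxel centers.  Seeds are hard constraints.  The
minimum cut is computed by max-flow on the voxel graph.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import label as cc_label
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import breadth_first_order, maximum_flow

from .volume_io import BinaryMask, CTVolume

__all__ = [
    "SeedSet",
    "GraphCutParams",
    "IntensityModel",
    "estimate_intensity_model",
    "segment_eyeball",
    "labeling_energy",
    "keep_seeded_component",
    "dice",
]

# The max-flow solver works on int32 capacities, so energies are scaled to
# integers adaptively: the scale is the largest power of two keeping a true
# upper bound on the min-cut value below 2^28 (capped at 2^28 per nat).  On
# micro-instances this gives near-exact arithmetic (rounding < 1e-6 nats per
# cut); on full CT volumes the energy resolution is still ~1e-5 nats.
_MAX_SCALE = float(2**28)
_FLOW_BUDGET = float(2**28)


@dataclass
class SeedSet:
    """Foreground/background seed voxels delineated on one axial slice."""

    foreground: np.ndarray  # (n, 3) int voxel indices
    background: np.ndarray  # (m, 3) int voxel indices
    slice_index: int = 0

    def __post_init__(self):
        self.foreground = np.atleast_2d(np.asarray(self.foreground, dtype=np.intp))
        self.background = np.atleast_2d(np.asarray(self.background, dtype=np.intp))
        if self.foreground.size == 0 or self.background.size == 0:
            raise ValueError("both foreground and background seeds are required")
        fg = {tuple(r) for r in self.foreground}
        bg = {tuple(r) for r in self.background}
        if fg & bg:
            raise ValueError(f"seed conflict: {len(fg & bg)} voxels marked both fg and bg")

    def validate_for(self, volume: CTVolume) -> None:
        shape = np.asarray(volume.shape)
        for arr, name in ((self.foreground, "foreground"), (self.background, "background")):
            if np.any(arr < 0) or np.any(arr >= shape):
                raise ValueError(f"{name} seed indices out of bounds for volume {tuple(shape)}")


@dataclass
class GraphCutParams:
    """Tunable parameters of the segmentation energy.

    lam : smoothness weight lambda >= 0.
    sigma_edge : contrast scale of the pairwise term, HU, > 0.
    connectivity : 6 (faces) or 26 (faces+edges+corners).
    n_bins, hu_range : seed-intensity histogram geometry.
    smoothing : Laplace pseudo-count added to every histogram bin.
    model : "histogram" (default) or "gaussian" seed-intensity model.
    """

    lam: float = 2.0
    sigma_edge: float = 50.0
    connectivity: int = 6
    n_bins: int = 64
    hu_range: tuple = (-1000.0, 1000.0)
    smoothing: float = 1.0
    model: str = "histogram"

    def __post_init__(self):
        if self.lam < 0:
            raise ValueError("smoothness weight lambda must be >= 0")
        if self.sigma_edge <= 0:
            raise ValueError("sigma_edge must be > 0")
        if self.connectivity not in (6, 26):
            raise ValueError("connectivity must be 6 or 26")
        if self.n_bins < 2 or self.hu_range[1] <= self.hu_range[0]:
            raise ValueError("invalid histogram geometry")
        if self.model not in ("histogram", "gaussian"):
            raise ValueError("model must be 'histogram' or 'gaussian'")


@dataclass
class IntensityModel:
    """Seed-derived foreground/background intensity distributions.

    Histogram form: smoothed, normalized bin probabilities over the clamped
    HU range (every bin strictly positive).  Gaussian form: per-class mean
    and standard deviation.
    """

    kind: str
    bin_edges: np.ndarray | None = None
    p_fg: np.ndarray | None = None
    p_bg: np.ndarray | None = None
    fg_mean: float = 0.0
    fg_sd: float = 1.0
    bg_mean: float = 0.0
    bg_sd: float = 1.0

    def _bin_of(self, intensities: np.ndarray) -> np.ndarray:
        i = np.searchsorted(self.bin_edges, intensities, side="right") - 1
        return np.clip(i, 0, len(self.p_fg) - 1)

    def log_p_fg(self, intensities) -> np.ndarray:
        x = np.asarray(intensities, dtype=float)
        if self.kind == "histogram":
            return np.log(self.p_fg[self._bin_of(x)])
        return -0.5 * ((x - self.fg_mean) / self.fg_sd) ** 2 - np.log(self.fg_sd)

    def log_p_bg(self, intensities) -> np.ndarray:
        x = np.asarray(intensities, dtype=float)
        if self.kind == "histogram":
            return np.log(self.p_bg[self._bin_of(x)])
        return -0.5 * ((x - self.bg_mean) / self.bg_sd) ** 2 - np.log(self.bg_sd)

    def log_likelihood_ratio(self, intensities) -> np.ndarray:
        """log P_fg(I) - log P_bg(I); positive favors eyeball."""
        return self.log_p_fg(intensities) - self.log_p_bg(intensities)


def _seed_intensities(volume: CTVolume, idx: np.ndarray) -> np.ndarray:
    return volume.data[idx[:, 0], idx[:, 1], idx[:, 2]].astype(float)


def estimate_intensity_model(
    volume: CTVolume, seeds: SeedSet, params: GraphCutParams | None = None
) -> IntensityModel:
    """Build the seed-intensity model backing the unary terms.

    Histogram model: seed intensities are clamped to ``params.hu_range``,
    binned into ``params.n_bins`` bins, Laplace-smoothed with
    ``params.smoothing`` pseudo-counts per bin and normalized, so every bin
    probability is strictly positive.
    """
    params = params or GraphCutParams()
    seeds.validate_for(volume)
    lo, hi = params.hu_range
    fg_i = _seed_intensities(volume, seeds.foreground)
    bg_i = _seed_intensities(volume, seeds.background)
    if np.all((fg_i < lo) | (fg_i > hi)) or np.all((bg_i < lo) | (bg_i > hi)):
        raise ValueError("all seed intensities fall outside the HU clamp range")

    if params.model == "gaussian":
        return IntensityModel(
            kind="gaussian",
            fg_mean=float(fg_i.mean()),
            fg_sd=float(max(fg_i.std(ddof=0), 1.0)),
            bg_mean=float(bg_i.mean()),
            bg_sd=float(max(bg_i.std(ddof=0), 1.0)),
        )

    edges = np.linspace(lo, hi, params.n_bins + 1)
    h_fg, _ = np.histogram(np.clip(fg_i, lo, hi), bins=edges)
    h_bg, _ = np.histogram(np.clip(bg_i, lo, hi), bins=edges)
    p_fg = (h_fg + params.smoothing) / (h_fg.sum() + params.smoothing * params.n_bins)
    p_bg = (h_bg + params.smoothing) / (h_bg.sum() + params.smoothing * params.n_bins)
    return IntensityModel(kind="histogram", bin_edges=edges, p_fg=p_fg, p_bg=p_bg)


def _neighbor_offsets(connectivity: int) -> np.ndarray:
    """Forward half-space of the neighborhood (each pair listed once)."""
    if connectivity == 6:
        return np.array([[1, 0, 0], [0, 1, 0], [0, 0, 1]], dtype=int)
    offs = []
    for di in (-1, 0, 1):
        for dj in (-1, 0, 1):
            for dk in (-1, 0, 1):
                if (di, dj, dk) > (0, 0, 0):
                    offs.append((di, dj, dk))
    return np.array(offs, dtype=int)


def _pairwise_edges(volume: CTVolume, params: GraphCutParams, model_free=None):
    """Vectorized pairwise edge list: (u, v, weight B_vw) over the forward
    neighborhood; both directions are added by the caller."""
    data = volume.data.astype(float)
    shape = data.shape
    flat = np.arange(np.prod(shape), dtype=np.int64).reshape(shape)
    us, vs, ws = [], [], []
    for off in _neighbor_offsets(params.connectivity):
        sl_a = tuple(slice(0, s - o if o > 0 else s) if o >= 0 else slice(-o, s)
                     for s, o in zip(shape, off))
        sl_b = tuple(slice(o, s) if o >= 0 else slice(0, s + o)
                     for s, o in zip(shape, off))
        ia = flat[sl_a].ravel()
        ib = flat[sl_b].ravel()
        di = data[sl_a].ravel() - data[sl_b].ravel()
        dist = float(np.linalg.norm(off * volume.spacing))
        b = np.exp(-(di**2) / (2.0 * params.sigma_edge**2)) / dist
        us.append(ia)
        vs.append(ib)
        ws.append(b)
    return np.concatenate(us), np.concatenate(vs), np.concatenate(ws)


def _unaries(volume: CTVolume, model: IntensityModel) -> tuple:
    i = volume.data.astype(float).ravel()
    u1 = -model.log_p_fg(i)  # cost of labeling foreground
    u0 = -model.log_p_bg(i)  # cost of labeling background
    return u0, u1


def segment_eyeball(
    volume: CTVolume,
    seeds: SeedSet,
    params: GraphCutParams | None = None,
    model: IntensityModel | None = None,
) -> BinaryMask:
    """Globally optimal seed-constrained segmentation by min cut.

    Returns the {0,1} labeling minimizing the segmentation energy subject to
    the hard seed constraints (every foreground seed labeled 1, every
    background seed 0).  Ties between equal-energy cuts are broken
    deterministically by residual reachability from the source under a fixed
    node ordering.
    """
    params = params or GraphCutParams()
    seeds.validate_for(volume)
    if model is None:
        model = estimate_intensity_model(volume, seeds, params)

    shape = volume.shape
    n = int(np.prod(shape))
    u0, u1 = _unaries(volume, model)
    # shifting both unaries by their per-voxel minimum leaves the argmin (and
    # every energy difference) unchanged but keeps the min-cut value small
    m = np.minimum(u0, u1)
    u0s, u1s = u0 - m, u1 - m

    us, vs, ws = _pairwise_edges(volume, params, None)
    pw = params.lam * ws

    fg_flat = np.ravel_multi_index(seeds.foreground.T, shape)
    bg_flat = np.ravel_multi_index(seeds.background.T, shape)

    # upper bound on the min cut: energy of the per-voxel argmin labeling
    # with seed labels forced (a feasible labeling)
    lab0 = u1s < u0s
    lab0[fg_flat] = True
    lab0[bg_flat] = False
    bound = float(np.where(lab0, u1s, u0s).sum())
    bound += float(pw[lab0[us] != lab0[vs]].sum())
    scale = min(_MAX_SCALE, _FLOW_BUDGET / max(bound, 1.0))

    cap_pw = np.rint(pw * scale).astype(np.int64)
    cap_src = np.rint(u0s * scale).astype(np.int64)  # cut if v is background
    cap_snk = np.rint(u1s * scale).astype(np.int64)  # cut if v is foreground

    # hard constraints: a seed's terminal capacity exceeds everything incident
    # to it, so isolating the seed is always cheaper than cutting its terminal
    inc = np.zeros(n, dtype=np.int64)
    np.add.at(inc, us, cap_pw)
    np.add.at(inc, vs, cap_pw)
    K = inc + cap_src + cap_snk + 1
    cap_src[fg_flat] = K[fg_flat]
    cap_snk[fg_flat] = 0
    cap_snk[bg_flat] = K[bg_flat]
    cap_src[bg_flat] = 0
    if int(max(cap_src.max(), cap_snk.max(), cap_pw.max() if cap_pw.size else 0)) >= 2**31:
        raise RuntimeError("capacity overflow in graph construction")

    source, sink = n, n + 1
    rows = np.concatenate([us, vs, np.full(n, source, dtype=np.int64), np.arange(n)])
    cols = np.concatenate([vs, us, np.arange(n), np.full(n, sink, dtype=np.int64)])
    caps = np.concatenate([cap_pw, cap_pw, cap_src, cap_snk]).astype(np.int32)

    graph = csr_matrix((caps, (rows, cols)), shape=(n + 2, n + 2))
    res = maximum_flow(graph, source, sink)

    # min-cut source side = nodes reachable from source in the residual graph
    residual = graph - res.flow  # flow is antisymmetric on the stored arcs
    residual.data = np.where(residual.data > 0, 1, 0)
    residual.eliminate_zeros()
    order = breadth_first_order(residual, source, directed=True, return_predecessors=False)
    labels = np.zeros(n + 2, dtype=np.uint8)
    labels[order] = 1
    values = labels[:n].reshape(shape)
    values[np.unravel_index(fg_flat, shape)] = 1
    values[np.unravel_index(bg_flat, shape)] = 0
    if values.sum() == 0:
        raise RuntimeError("empty segmentation after hard constraints: degenerate model")
    return BinaryMask.from_volume(volume, values)


def labeling_energy(
    volume: CTVolume,
    labels: np.ndarray,
    model: IntensityModel,
    params: GraphCutParams | None = None,
) -> float:
    """Exact energy of an arbitrary {0,1} labeling (unary + pairwise)."""
    params = params or GraphCutParams()
    lab = np.asarray(labels).astype(bool).ravel()
    u0, u1 = _unaries(volume, model)
    e = float(np.where(lab, u1, u0).sum())
    us, vs, ws = _pairwise_edges(volume, params, None)
    e += float(params.lam * ws[lab[us] != lab[vs]].sum())
    return e


def keep_seeded_component(mask: BinaryMask, seeds: SeedSet) -> BinaryMask:
    """Keep only the 26-connected component(s) containing a foreground seed."""
    if mask.n_voxels == 0:
        raise ValueError("mask is empty")
    lab, _ = cc_label(mask.data, structure=np.ones((3, 3, 3), dtype=int))
    fg = seeds.foreground
    seed_labels = np.unique(lab[fg[:, 0], fg[:, 1], fg[:, 2]])
    seed_labels = seed_labels[seed_labels > 0]
    if seed_labels.size == 0:
        raise ValueError("no connected component contains a foreground seed")
    values = np.isin(lab, seed_labels).astype(np.uint8)
    return BinaryMask.from_volume(mask, values)


def dice(a: BinaryMask, b: BinaryMask) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|); 1.0 when both masks are empty."""
    if not a.same_geometry(b):
        raise ValueError("masks are on different grids")
    na, nb = a.n_voxels, b.n_voxels
    if na + nb == 0:
        return 1.0
    inter = int(np.logical_and(a.data, b.data).sum())
    return 2.0 * inter / (na + nb)
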