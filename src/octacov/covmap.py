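"""Pixel-wise CoV mapping and vessel-segment decomposition.

The perfusion-variability signal is the coefficient of variation (CoV) of
each pixel's intensity over a sequence of aligned en-face OCT angiograms:
sample standard deviation over time divided by the temporal mean, in
percent.  CoV is zero for a constant series, order-free, and invariant to
linear intensity scaling, which makes it comparable across retinal
locations and across eyes.

Vessel-level statistics are attached to *segments*: maximal runs of
single-pixel centreline pixels between junctions and/or endpoints of the
skeletonized vasculature.  Each segment carries the arithmetic mean of the
per-pixel CoV values along its path ("vessel-segment mean CoV").
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage import filters, morphology

from .registration import FrameSequence

__all__ = [
    "CoVMap",
    "SkeletonGraph",
    "VesselSegment",
    "CentrelineConfig",
    "compute_cov_map",
    "quartile_coefficient_of_dispersion",
    "segment_centrelines",
    "decompose_segments",
    "segment_mean_cov",
]


@dataclass
class CoVMap:
    """Per-pixel CoV (%) over the aligned frames plus a validity mask."""

    values: np.ndarray
    valid_mask: np.ndarray
    n_frames: int

    def __post_init__(self):
        if self.values.shape != self.valid_mask.shape:
            raise ValueError("values and valid_mask shapes differ")


@dataclass
class VesselSegment:
    """A junction-to-junction (or endpoint) run of centreline pixels."""

    id: int
    pixel_path: list  # ordered (row, col) tuples
    mean_cov: float | None = None
    n_valid: int = 0

    @property
    def length(self) -> int:
        return len(self.pixel_path)


@dataclass
class SkeletonGraph:
    """Single-pixel-wide centreline mask with its segment decomposition."""

    centreline_mask: np.ndarray
    endpoints: np.ndarray = None
    junctions: np.ndarray = None
    segments: list = field(default_factory=list)


def compute_cov_map(seq: FrameSequence, mean_floor: float | None = None) -> CoVMap:
    """CoV map of an aligned frame sequence.

    Per pixel: sample (ddof=1) SD over time / temporal mean × 100, computed
    only where the pixel is valid in every frame and the temporal mean
    exceeds ``mean_floor`` (default: 1% of the stack's global mean over
    valid pixels, guarding against division blow-ups near zero signal).
    """
    if not seq.aligned:
        raise ValueError("frame sequence must be aligned before CoV mapping")
    frames = np.asarray(seq.frames, dtype=np.float64)
    if frames.shape[0] < 2:
        raise ValueError("need at least 2 frames to compute a CoV map")
    valid = np.all(seq.valid, axis=0)
    mean = frames.mean(axis=0)
    sd = frames.std(axis=0, ddof=1)
    if mean_floor is None:
        global_mean = frames[:, valid].mean() if valid.any() else 0.0
        mean_floor = 0.01 * global_mean
    ok = valid & (mean > mean_floor)
    values = np.zeros_like(mean)
    np.divide(sd, mean, out=values, where=ok)
    values *= 100.0
    values[~ok] = np.nan
    if not ok.any():
        warnings.warn("CoV map has no valid pixels", stacklevel=2)
    return CoVMap(values=values, valid_mask=ok, n_frames=frames.shape[0])


def quartile_coefficient_of_dispersion(series) -> float:
    """QCD = (Q3 − Q1)/(Q3 + Q1) × 100, linear-interpolation quartiles.

    An outlier-resistant alternative to the CoV; undefined when
    Q1 + Q3 = 0.
    """
    x = np.asarray(series, dtype=float)
    if x.size < 4:
        raise ValueError("QCD requires a series of length >= 4")
    q1, q3 = np.percentile(x, [25, 75])
    denom = q3 + q1
    if denom == 0:
        raise ValueError("QCD undefined: Q1 + Q3 = 0")
    return float((q3 - q1) / denom * 100.0)


@dataclass
class CentrelineConfig:
    """Vessel centreline detection parameters.

    Vesselness (Frangi) ridge enhancement of the temporal-mean image over
    ``sigmas`` (pixel radii of the vessels sought), hysteresis threshold at
    fractions of the maximum response, small-object cleanup, then
    topological thinning to single-pixel width.
    """

    sigmas: tuple = (1.0, 2.0, 3.0)
    hysteresis_low: float = 0.01
    hysteresis_high: float = 0.05
    min_object_size: int = 20


def segment_centrelines(
    seq: FrameSequence, config: CentrelineConfig | None = None
) -> SkeletonGraph:
    """Detect single-pixel-thick vessel centrelines from the temporal mean."""
    if config is None:
        config = CentrelineConfig()
    frames = np.asarray(seq.frames, dtype=np.float64)
    valid = np.all(seq.valid, axis=0)
    mean = frames.mean(axis=0)
    mean[~valid] = 0.0
    if mean.max() <= 0:
        warnings.warn("blank frame sequence: empty skeleton", stacklevel=2)
        return _classify(np.zeros(mean.shape, bool))
    v = filters.frangi(mean, sigmas=config.sigmas, black_ridges=False)
    vmax = v.max()
    if vmax <= 0:
        warnings.warn("no vesselness response: empty skeleton", stacklevel=2)
        return _classify(np.zeros(mean.shape, bool))
    mask = filters.apply_hysteresis_threshold(
        v, config.hysteresis_low * vmax, config.hysteresis_high * vmax
    )
    mask = _drop_small(mask, config.min_object_size)
    mask = ndi.binary_closing(mask, morphology.disk(1))
    skel = morphology.skeletonize(mask)
    skel &= valid
    if not skel.any():
        warnings.warn("empty skeleton after thinning", stacklevel=2)
    return _classify(skel)


def _drop_small(mask: np.ndarray, min_size: int) -> np.ndarray:
    labels, n = ndi.label(mask, structure=np.ones((3, 3), int))
    if n == 0:
        return mask
    sizes = np.bincount(labels.ravel())
    keep = sizes >= min_size
    keep[0] = False
    return keep[labels]


_DIRS8 = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def _skeleton_adjacency(skel: np.ndarray) -> dict:
    """8-adjacency between skeleton pixels, with redundant diagonals pruned.

    A diagonal link is redundant when the two pixels already share an
    orthogonal skeleton neighbour (m-adjacency); pruning it keeps the
    pixel graph a faithful curve graph, so that e.g. the four arms of a
    crossing do not short-circuit around the junction pixel.
    """
    pix = {tuple(p) for p in np.argwhere(skel)}
    adj = {}
    for r, c in pix:
        nbrs = []
        for dr, dc in _DIRS8:
            q = (r + dr, c + dc)
            if q not in pix:
                continue
            if dr != 0 and dc != 0 and ((r, c + dc) in pix or (r + dr, c) in pix):
                continue  # diagonal shortcut across an orthogonal neighbour
            nbrs.append(q)
        adj[(r, c)] = nbrs
    return adj


def _classify(skel: np.ndarray) -> SkeletonGraph:
    adj = _skeleton_adjacency(skel)
    endpoints = np.zeros(skel.shape, bool)
    junctions = np.zeros(skel.shape, bool)
    for p, nbrs in adj.items():
        if len(nbrs) == 1:
            endpoints[p] = True
        elif len(nbrs) >= 3:
            junctions[p] = True
    return SkeletonGraph(centreline_mask=skel, endpoints=endpoints, junctions=junctions)


def decompose_segments(
    skeleton: SkeletonGraph | np.ndarray, min_segment_length: int = 3
) -> list[VesselSegment]:
    """Split a 1-px skeleton into junction-to-junction pixel paths.

    Skeleton pixels are classified by their pruned 8-neighbour degree
    (1 endpoint, 2 interior, >=3 junction); junction pixels terminate
    paths and belong to no segment.  The maximal interior runs between
    terminals are returned as ordered pixel paths; runs shorter than
    ``min_segment_length`` are dropped (thinning-spur suppression).
    """
    if isinstance(skeleton, SkeletonGraph):
        skel = skeleton.centreline_mask
    else:
        skel = np.asarray(skeleton, dtype=bool)
    adj = _skeleton_adjacency(skel)
    junction = {p for p, nbrs in adj.items() if len(nbrs) >= 3}
    segments = []
    sid = 0
    visited = set(junction)
    for start in sorted(adj):
        if start in visited:
            continue
        # walk the interior path through `start` out to both terminals
        path = _trace_path(start, adj, junction)
        visited.update(path)
        if len(path) >= min_segment_length:
            segments.append(VesselSegment(id=sid, pixel_path=path))
            sid += 1
    if isinstance(skeleton, SkeletonGraph):
        skeleton.segments = segments
    return segments


def _trace_path(start, adj, junction):
    """Maximal interior run containing ``start`` (handles open paths, cycles)."""

    def walk(first):
        chain = []
        prev, cur = start, first
        while cur not in junction and cur != start:
            chain.append(cur)
            nxt = [q for q in adj[cur] if q != prev and q not in junction]
            if not nxt:
                break
            prev, cur = cur, nxt[0]
        return chain

    nbrs = [q for q in adj[start] if q not in junction]
    if not nbrs:
        return [start]
    left = walk(nbrs[0])
    right = []
    if len(nbrs) > 1 and nbrs[1] not in left:  # not a closed cycle
        right = walk(nbrs[1])
    return list(reversed(right)) + [start] + left


def segment_mean_cov(cov: CoVMap, segments: list[VesselSegment]) -> list[VesselSegment]:
    """Attach per-segment arithmetic mean CoV over valid pixels.

    Segments with zero valid pixels are flagged (``mean_cov=None``) and
    excluded from the returned list.
    """
    kept = []
    h, w = cov.values.shape
    for seg in segments:
        rr = np.array([p[0] for p in seg.pixel_path])
        cc = np.array([p[1] for p in seg.pixel_path])
        if rr.min() < 0 or cc.min() < 0 or rr.max() >= h or cc.max() >= w:
            raise ValueError(f"segment {seg.id} lies outside the CoV map domain")
        ok = cov.valid_mask[rr, cc]
        seg.n_valid = int(ok.sum())
        if seg.n_valid == 0:
            seg.mean_cov = None
            continue
        seg.mean_cov = float(cov.values[rr[ok], cc[ok]].mean())
        kept.append(seg)
    return kept
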