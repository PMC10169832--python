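"""Seven histology-informed ROI categories for the macular vasculature.

The macular field is partitioned with respect to user-supplied masks of
the major radial arterioles ("a1", "a2", ...), major radial venules
("v1", ...) and the foveal avascular zone (FAZ):

1. *Arteriole* — the major radial arteriole masks themselves;
2. *Arteriole-net* — the capillary territory closest (Euclidean influence
   zone / generalized Voronoi polygon) to each arteriole, excluding the
   vessel itself;
3. *Venule* — the major radial venule masks;
4. *Venule-net* — the influence zone of each venule;
5. *FAZ-net* — the influence zone of the FAZ ("F-net");
6. *FAZ-cp* — a band of pure capillaries hugging the FAZ boundary
   ("F-cp"), normally drawn from histology knowledge and consumed here as
   a mask (a helper builds a default annulus);
7. *Quadrant* — four quadrants through the foveola centre ("Q1"–"Q4"),
   excluding the major vessels and the FAZ.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage as ndi

from .covmap import VesselSegment
from .rmstats import CATEGORIES

__all__ = [
    "ROISet",
    "build_roi_set",
    "load_roi_masks",
    "influence_zones",
    "quadrant_rois",
    "faz_capillary_band",
    "assign_segments",
    "summarize_roi",
]

_VESSEL_CATEGORY = {"a": "Arteriole", "v": "Venule"}


@dataclass
class ROISet:
    """Named ROI masks with their category labels."""

    masks: dict  # name -> bool (H, W)
    category_of: dict  # name -> category string
    foveola_centre: tuple | None = None
    faz_mask: np.ndarray | None = None
    shape: tuple = field(default=None)

    def __post_init__(self):
        if self.shape is None and self.masks:
            self.shape = next(iter(self.masks.values())).shape

    def names(self, category: str) -> list:
        return [n for n, c in self.category_of.items() if c == category]

    def mask_of_category(self, category: str) -> np.ndarray:
        out = np.zeros(self.shape, bool)
        for n in self.names(category):
            out |= self.masks[n]
        return out


def influence_zones(seed_masks: list, domain_mask: np.ndarray) -> np.ndarray:
    """Label each domain pixel with its nearest seed (generalized Voronoi).

    Returns an int array: -1 outside the domain, otherwise the index of
    the seed mask whose pixels are nearest in Euclidean distance.
    Distance ties are broken toward the lowest seed index, which makes the
    partition deterministic across platforms.
    """
    if len(seed_masks) == 0:
        raise ValueError("need at least one seed mask")
    shape = np.asarray(domain_mask).shape
    dists = []
    for i, seed in enumerate(seed_masks):
        seed = np.asarray(seed, bool)
        if seed.shape != shape:
            raise ValueError(f"seed {i} shape {seed.shape} != domain {shape}")
        if not seed.any():
            raise ValueError(f"seed {i} is empty")
        dists.append(ndi.distance_transform_edt(~seed))
    labels = np.argmin(np.stack(dists), axis=0).astype(np.int32)
    labels[~np.asarray(domain_mask, bool)] = -1
    return labels


def quadrant_rois(
    foveola_centre: tuple, shape: tuple, exclusions: np.ndarray | None = None
) -> dict:
    """Four quadrant masks split by the axis lines through the foveola.

    Pixels exactly on the (rounded) horizontal/vertical split lines belong
    to no quadrant; exclusion masks are subtracted from each quadrant.
    """
    r0, c0 = (int(round(foveola_centre[0])), int(round(foveola_centre[1])))
    h, w = shape
    if not (0 <= r0 < h and 0 <= c0 < w):
        raise ValueError(f"foveola centre {foveola_centre} outside image {shape}")
    rr, cc = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    quads = {
        "Q1": (rr < r0) & (cc > c0),  # upper right
        "Q2": (rr < r0) & (cc < c0),  # upper left
        "Q3": (rr > r0) & (cc < c0),  # lower left
        "Q4": (rr > r0) & (cc > c0),  # lower right
    }
    if exclusions is not None:
        ex = np.asarray(exclusions, bool)
        quads = {k: v & ~ex for k, v in quads.items()}
    return quads


def faz_capillary_band(faz_mask: np.ndarray, width: int = 6) -> np.ndarray:
    """Annulus of ``width`` pixels outward from the FAZ boundary (F-cp helper)."""
    faz = np.asarray(faz_mask, bool)
    dist = ndi.distance_transform_edt(~faz)
    return (dist > 0) & (dist <= width)


def build_roi_set(
    arteriole_masks: dict,
    venule_masks: dict,
    faz_mask: np.ndarray,
    foveola_centre: tuple | None = None,
    fcp_mask: np.ndarray | None = None,
    fcp_width: int = 6,
    domain_mask: np.ndarray | None = None,
) -> ROISet:
    """Assemble the full seven-category ROI set from the primary masks.

    ``arteriole_masks``/``venule_masks`` map names ("a1", "v3", ...) to
    boolean masks.  The capillary influence zones ("a1-net", ..., "F-net")
    are computed automatically; "F-cp" defaults to an annulus of
    ``fcp_width`` px outside the FAZ; quadrants need ``foveola_centre``
    (defaults to the FAZ centroid).
    """
    faz = np.asarray(faz_mask, bool)
    shape = faz.shape
    masks, cat = {}, {}
    for name, m in {**arteriole_masks, **venule_masks}.items():
        m = np.asarray(m, bool)
        if m.shape != shape:
            raise ValueError(f"mask {name!r} shape {m.shape} != {shape}")
        if not m.any():
            raise ValueError(f"mask {name!r} is empty")
        masks[name] = m
        cat[name] = _VESSEL_CATEGORY[name[0]]
    _check_disjoint(masks, faz)

    if foveola_centre is None:
        foveola_centre = tuple(np.mean(np.argwhere(faz), axis=0))

    # Euclidean influence zones over the capillary domain
    seed_names = sorted(arteriole_masks) + sorted(venule_masks) + ["FAZ"]
    seeds = [masks[n] for n in seed_names[:-1]] + [faz]
    vessel_union = np.zeros(shape, bool)
    for m in masks.values():
        vessel_union |= m
    if domain_mask is None:
        domain_mask = ~(vessel_union | faz)
    labels = influence_zones(seeds, domain_mask)
    for i, n in enumerate(seed_names):
        zone = labels == i
        zname = "F-net" if n == "FAZ" else f"{n}-net"
        masks[zname] = zone
        cat[zname] = "FAZ-net" if n == "FAZ" else f"{_VESSEL_CATEGORY[n[0]]}-net"

    if fcp_mask is None:
        fcp_mask = faz_capillary_band(faz, fcp_width)
    masks["F-cp"] = np.asarray(fcp_mask, bool) & ~faz
    cat["F-cp"] = "FAZ-cp"

    for qname, qmask in quadrant_rois(
        foveola_centre, shape, exclusions=vessel_union | faz
    ).items():
        masks[qname] = qmask
        cat[qname] = "Quadrant"

    return ROISet(
        masks=masks,
        category_of=cat,
        foveola_centre=foveola_centre,
        faz_mask=faz,
        shape=shape,
    )


def _check_disjoint(vessel_masks: dict, faz: np.ndarray):
    names = sorted(vessel_masks)
    for i, a in enumerate(names):
        if (vessel_masks[a] & faz).any():
            raise ValueError(f"vessel mask {a!r} overlaps the FAZ")
        for b in names[i + 1 :]:
            if a[0] != b[0] and (vessel_masks[a] & vessel_masks[b]).any():
                raise ValueError(f"arteriole/venule masks {a!r} and {b!r} overlap")


def load_roi_masks(label_tiff, manifest_json, scale: int = 1, **kwargs) -> ROISet:
    """Build an ROISet from a labeled TIFF plus a JSON manifest.

    The manifest maps label ids (as strings) to mask names: arterioles
    "a1", "a2", ..., venules "v1", ..., and "FAZ".  Optional manifest keys:
    ``foveola_centre`` (row, col) and an "F-cp" label.  ``scale`` replicates
    each mask pixel scale × scale so masks drawn on the acquisition grid
    follow the frames onto the upscaled analysis grid.
    """
    labels = tifffile.imread(str(label_tiff)).astype(np.int64)
    if scale > 1:
        labels = np.kron(labels, np.ones((scale, scale), dtype=np.int64))
    with open(manifest_json) as fh:
        manifest = json.load(fh)
    name_of = {int(k): v for k, v in manifest["labels"].items()}
    art, ven, faz, fcp = {}, {}, None, None
    for lab, name in name_of.items():
        m = labels == lab
        if name == "FAZ":
            faz = m
        elif name == "F-cp":
            fcp = m
        elif name.startswith("a"):
            art[name] = m
        elif name.startswith("v"):
            ven[name] = m
        else:
            raise ValueError(f"unrecognized ROI mask name {name!r}")
    if faz is None:
        raise ValueError("manifest must name a FAZ mask")
    centre = manifest.get("foveola_centre")
    if centre is not None:
        centre = tuple(float(c) * scale for c in centre)
    return build_roi_set(
        art, ven, faz, foveola_centre=centre, fcp_mask=fcp, **kwargs,
    )


def assign_segments(
    segments: list, roi_set: ROISet, categories=CATEGORIES
) -> pd.DataFrame:
    """Assign each vessel segment to at most one ROI per category.

    Rule: majority of the segment's pixels; ties broken toward the ROI
    containing the segment's midpoint pixel, then toward the
    lexicographically first ROI name.  Returns one row per (segment, ROI)
    assignment with the segment's mean CoV.
    """
    rows = []
    for seg in segments:
        rr = np.array([p[0] for p in seg.pixel_path])
        cc = np.array([p[1] for p in seg.pixel_path])
        mid = seg.pixel_path[len(seg.pixel_path) // 2]
        for category in categories:
            counts = {}
            for name in roi_set.names(category):
                c = int(roi_set.masks[name][rr, cc].sum())
                if c > 0:
                    counts[name] = c
            if not counts:
                continue
            top = max(counts.values())
            winners = sorted(n for n, c in counts.items() if c == top)
            choice = winners[0]
            if len(winners) > 1:
                for n in winners:
                    if roi_set.masks[n][mid[0], mid[1]]:
                        choice = n
                        break
            rows.append(
                {
                    "segment_id": seg.id,
                    "category": category,
                    "roi": choice,
                    "length": seg.length,
                    "mean_cov": seg.mean_cov,
                }
            )
    return pd.DataFrame(
        rows, columns=["segment_id", "category", "roi", "length", "mean_cov"]
    )


def summarize_roi(assignments: pd.DataFrame) -> pd.DataFrame:
    """Median and IQR of vessel-segment mean CoV per ROI.

    The median measures the temporal variation of the ROI's segments, the
    IQR (linear-interpolation quartiles) their spatial variation.
    """
    rows = []
    for (category, name), grp in assignments.groupby(["category", "roi"]):
        vals = grp["mean_cov"].dropna().to_numpy(float)
        if vals.size == 0:
            rows.append(
                {"category": category, "roi": name, "n_segments": 0,
                 "median_mean_cov": np.nan, "iqr_mean_cov": np.nan,
                 "q1_mean_cov": np.nan, "q3_mean_cov": np.nan}
            )
            continue
        q1, q3 = np.percentile(vals, [25, 75])
        rows.append(
            {
                "category": category,
                "roi": name,
                "n_segments": int(vals.size),
                "median_mean_cov": float(np.median(vals)),
                "iqr_mean_cov": float(q3 - q1),
                "q1_mean_cov": float(q1),
                "q3_mean_cov": float(q3),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["category", "roi", "n_segments", "median_mean_cov",
                 "iqr_mean_cov", "q1_mean_cov", "q3_mean_cov"],
    )
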