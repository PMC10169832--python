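"""Per-subject and cohort orchestration of the CoV analysis.

A subject run executes the analysis stages in order — upscaling,
rigid + non-linear alignment, pixel-wise CoV mapping, centreline
segmentation, vessel-segment statistics within the seven ROI categories —
writing every intermediate to the output directory so any stage can be
resumed from disk.  A cohort run pools the per-subject category summaries
into subjects × categories tables (medians and IQRs) and runs the
repeated-measures battery on each.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
import yaml
from matplotlib import colormaps

from . import io as iomod
from .covmap import (
    CentrelineConfig,
    CoVMap,
    compute_cov_map,
    decompose_segments,
    segment_centrelines,
    segment_mean_cov,
)
from .registration import FrameSequence, align_sequence
from .rmstats import (
    CATEGORIES,
    pairwise_p_matrix,
    pool_categories,
    posthoc_pairwise,
    rm_anova,
)
from .roi import assign_segments, load_roi_masks, summarize_roi

log = logging.getLogger("octacov")

__all__ = [
    "AnalysisConfig",
    "RenderPolicy",
    "SubjectResult",
    "run_subject",
    "run_cohort",
    "render_centreline_map",
    "render_boxplots",
]


@dataclass
class RenderPolicy:
    """Colour clamping for centreline CoV heat maps.

    ``global_cap`` clamps pixel CoV at ``cap_value`` (default 50%);
    ``category_percentile`` clamps vessel-segment mean CoV to the range
    [min over ROIs of Q1, max over ROIs of Q3] of the rendered category.
    The colormap must run monotonically from dark blue (low) to red
    (high).
    """

    mode: str = "global_cap"
    cap_value: float = 50.0
    colormap: str = "turbo"

    def __post_init__(self):
        if self.mode not in ("global_cap", "category_percentile"):
            raise ValueError(f"unknown render mode {self.mode!r}")
        if not np.isfinite(self.cap_value) or self.cap_value <= 0:
            raise ValueError("cap_value must be finite and positive")


@dataclass
class AnalysisConfig:
    """Everything needed to run one subject, round-trippable through YAML."""

    frames: str = None
    dialect: str = "tiff"
    sidecar: str = None
    roi_labels: str = None
    roi_manifest: str = None
    output_dir: str = "out"
    subject: str = "subject"
    upscale_factor: int = 2
    reference_policy: str = "first"
    nonlinear: bool = True
    grid_spacing: int = 32
    already_aligned: bool = False
    centreline: dict = field(default_factory=dict)
    min_segment_length: int = 3
    mean_floor: float = None
    render: dict = field(default_factory=dict)
    seed: int = 0
    version: int = 1

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path):
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    def validate(self):
        for name in ("frames", "roi_labels", "roi_manifest"):
            p = getattr(self, name)
            if p is None:
                raise ValueError(f"config field {name!r} is required")
            if not Path(p).exists():
                raise FileNotFoundError(f"config {name}: {p} does not exist")
        if self.dialect == "raw" and (
            self.sidecar is None or not Path(self.sidecar).exists()
        ):
            raise FileNotFoundError("raw dialect requires an existing sidecar")
        return self


@dataclass
class SubjectResult:
    subject: str
    sequence: FrameSequence
    cov: CoVMap
    skeleton: object
    segments: list
    assignments: pd.DataFrame
    roi_summary: pd.DataFrame


def run_subject(config: AnalysisConfig, save: bool = True) -> SubjectResult:
    """Execute the per-subject stages in order, writing intermediates."""
    config.validate()
    out = Path(config.output_dir)
    if save:
        out.mkdir(parents=True, exist_ok=True)
        config.to_yaml(out / "config.yaml")
    stage = "load"
    try:
        frames = iomod.read_frames(config.frames, config.dialect, config.sidecar)
        log.info("loaded %d frames of %s", frames.shape[0], frames.shape[1:])

        stage = "align"
        if config.already_aligned:
            seq = FrameSequence.from_frames(
                np.stack([_upscaled(f, config.upscale_factor) for f in frames]),
                aligned=True,
            )
            seq.upscale_factor = config.upscale_factor
        else:
            seq = align_sequence(
                frames,
                reference_policy=config.reference_policy,
                upscale_factor=config.upscale_factor,
                nonlinear=config.nonlinear,
                grid_spacing=config.grid_spacing,
            )
        if save:
            iomod.write_frames_tiff(out / "aligned.tif", seq.frames)

        stage = "covmap"
        cov = compute_cov_map(seq, config.mean_floor)
        if save:
            iomod.write_float_tiff(out / "cov_map.tif", cov.values)

        stage = "centrelines"
        skel = segment_centrelines(seq, CentrelineConfig(**config.centreline))
        if save:
            iomod.write_label_tiff(out / "skeleton.tif", skel.centreline_mask)

        stage = "segments"
        segments = decompose_segments(skel, config.min_segment_length)
        segments = segment_mean_cov(cov, segments)

        stage = "roi"
        roi_set = load_roi_masks(
            config.roi_labels, config.roi_manifest, scale=config.upscale_factor
        )
        if roi_set.shape != cov.values.shape:
            raise ValueError(
                f"ROI masks {roi_set.shape} do not match the analysis grid "
                f"{cov.values.shape} (after upscaling)"
            )
        assignments = assign_segments(segments, roi_set)
        summary = summarize_roi(assignments)
        if save:
            assignments.to_csv(out / "segments.csv", index=False)
            summary.to_csv(out / "roi_summary.csv", index=False)
    except Exception as exc:
        raise RuntimeError(f"subject {config.subject!r} failed at stage "
                           f"{stage!r}: {exc}") from exc
    return SubjectResult(
        subject=config.subject,
        sequence=seq,
        cov=cov,
        skeleton=skel,
        segments=segments,
        assignments=assignments,
        roi_summary=summary,
    )


def _upscaled(frame, factor):
    from .registration import upscale

    return upscale(frame, factor)


def run_cohort(subject_assignments: dict, out_dir=None) -> dict:
    """Cohort statistics from per-subject segment-assignment tables.

    ``subject_assignments`` maps subject id to the ``segments.csv``-style
    DataFrame (columns category, mean_cov, ...).  Builds the medians and
    IQRs subjects × categories tables and runs the RM ANOVA + Bonferroni
    post-hoc battery on each.
    """
    if len(subject_assignments) < 2:
        raise ValueError("cohort analysis needs at least 2 subjects")
    results = {}
    for measure in ("median", "iqr"):
        table = pool_categories(subject_assignments, measure=measure)
        anova = rm_anova(table)
        posthoc = posthoc_pairwise(table)
        results[measure] = {
            "table": table,
            "anova": anova,
            "posthoc": posthoc,
            "p_matrix": pairwise_p_matrix(posthoc, columns=list(CATEGORIES)),
        }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for measure, r in results.items():
            r["table"].to_csv(out / f"table_{measure}.csv")
            r["posthoc"].to_csv(out / f"posthoc_{measure}.csv", index=False)
            r["p_matrix"].round(2).to_csv(out / f"p_matrix_{measure}.csv")
            with open(out / f"anova_{measure}.json", "w") as fh:
                json.dump(dataclasses.asdict(r["anova"]), fh, indent=1)
    return results


def render_centreline_map(
    cov: CoVMap,
    skeleton_or_segments,
    policy: RenderPolicy | None = None,
    roi_summary: pd.DataFrame | None = None,
) -> np.ndarray:
    """False-colour rendering of centreline CoV values; returns an RGB image.

    In ``global_cap`` mode each skeleton pixel is coloured by its own CoV
    clamped to [0, cap_value].  In ``category_percentile`` mode the
    segments are coloured by their mean CoV clamped to
    [smallest Q1, largest Q3] across the ROIs of ``roi_summary``.
    """
    if policy is None:
        policy = RenderPolicy()
    if not cov.valid_mask.any():
        raise ValueError("cannot render an all-invalid CoV map")
    cmap = colormaps[policy.colormap]
    rgb = np.zeros(cov.values.shape + (3,))
    if policy.mode == "global_cap":
        lo, hi = 0.0, policy.cap_value
        mask = _as_mask(skeleton_or_segments, cov.values.shape) & cov.valid_mask
        vals = np.clip(cov.values[mask], lo, hi)
        rgb[mask] = cmap((vals - lo) / (hi - lo))[:, :3]
        return rgb
    if roi_summary is None or roi_summary.empty:
        raise ValueError("category_percentile mode needs a per-ROI summary")
    lo = float(roi_summary["q1_mean_cov"].min())
    hi = max(float(roi_summary["q3_mean_cov"].max()), lo + 1e-9)
    for seg in skeleton_or_segments:
        if seg.mean_cov is None:
            continue
        v = (np.clip(seg.mean_cov, lo, hi) - lo) / (hi - lo)
        colour = cmap(v)[:3]
        for r, c in seg.pixel_path:
            rgb[r, c] = colour
    return rgb


def _as_mask(skeleton_or_segments, shape):
    if hasattr(skeleton_or_segments, "centreline_mask"):
        return skeleton_or_segments.centreline_mask
    if isinstance(skeleton_or_segments, np.ndarray):
        return skeleton_or_segments.astype(bool)
    mask = np.zeros(shape, bool)
    for seg in skeleton_or_segments:
        for r, c in seg.pixel_path:
            mask[r, c] = True
    return mask


def render_boxplots(groups: dict, out_png=None, out_csv=None, title=None):
    """Comparative box plot of vessel-segment mean CoVs per group.

    ``groups`` maps group name to a 1-D array of segment mean CoVs; the
    sample size is annotated inside each box and the box statistics
    (median, quartiles, n) are exported as CSV so the figure and the
    tables share a single source of truth.  Empty groups are omitted with
    a logged warning.  Returns (figure, stats DataFrame).
    """
    names, data, rows = [], [], []
    for name, vals in groups.items():
        vals = np.asarray(vals, dtype=float)
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            log.warning("boxplot group %r is empty; omitted", name)
            continue
        names.append(name)
        data.append(vals)
        q1, med, q3 = np.percentile(vals, [25, 50, 75])
        rows.append(
            {"group": name, "n": int(vals.size), "median": med,
             "q1": q1, "q3": q3, "iqr": q3 - q1}
        )
    if not names:
        raise ValueError("no non-empty groups to plot")
    stats = pd.DataFrame(rows)
    fig, ax = plt.subplots(figsize=(1.2 * len(names) + 2, 4))
    ax.boxplot(data, tick_labels=names)
    for i, row in stats.iterrows():
        ax.annotate(str(row["n"]), (i + 1, row["median"]),
                    textcoords="offset points", xytext=(0, -12),
                    ha="center", fontsize=8)
    ax.set_ylabel("vessel-segment mean CoV (%)")
    if title:
        ax.set_title(title)
    ax.tick_params(axis="x", rotation=45)
    fig.tight_layout()
    if out_png:
        fig.savefig(out_png, dpi=150)
    if out_csv:
        stats.to_csv(out_csv, index=False)
    return fig, stats
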