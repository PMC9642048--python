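"""Diagnostic panel: visualise the four extraction steps for one micrograph.

Mirrors the picker's interactive debugging view: thresholded score pixels,
skeleton, individual Hough segments in distinct colours, merged segments,
and the final start-end lines overlaid on the micrograph (or score map).
Used when tuning the threshold, radius or line-length parameters.
"""

from __future__ import annotations

from typing import Optional, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .helix_geometry import FilamentTrace
from .trace_extraction import (
    LineSegment,
    PickerParams,
    ScoreMap,
    binarize,
    detect_lines,
    extract_traces,
    merge_lines,
    skeletonize,
)

__all__ = ["plot_panel"]


def _draw_segments(ax, segments: Sequence[LineSegment], cmap_name: str = "tab10"):
    cmap = plt.get_cmap(cmap_name)
    for i, seg in enumerate(segments):
        ax.plot([seg.x1, seg.x2], [seg.y1, seg.y2],
                color=cmap(i % 10), linewidth=1.5)


def plot_panel(
    score_map: ScoreMap,
    params: PickerParams,
    out_path,
    micrograph: Optional[np.ndarray] = None,
) -> Sequence[FilamentTrace]:
    """Run the four steps, save a five-panel PNG, return the traces.

    Panels: binarized mask (threshold ``thr`` in the title), skeleton, Hough
    segments (with ``len``/``gap`` parameters shown), merged segments (with
    the merge distance ``mind``), and the final start-end lines on the
    original image.
    """
    mask = binarize(score_map, params.threshold_t)
    skel = skeletonize(mask)
    segments = detect_lines(skel, params)
    merged = merge_lines(segments, params.merge_angle_deg, params.merge_dist)
    traces = extract_traces(score_map, params)

    fig, axes = plt.subplots(1, 5, figsize=(22, 4.6))
    axes[0].imshow(mask, cmap="Reds", interpolation="nearest")
    axes[0].set_title(f"binarized (thr={params.threshold_t:g})")
    axes[1].imshow(skel, cmap="gray_r", interpolation="nearest")
    axes[1].set_title("skeleton")

    for ax, segs, title in (
        (axes[2], segments,
         f"Hough (len={params.line_length_fl}, gap={params.line_gap})"),
        (axes[3], merged, f"merged (mind={params.merge_dist:g})"),
    ):
        ax.imshow(np.zeros(score_map.shape), cmap="gray", vmin=-1, vmax=0)
        _draw_segments(ax, segs)
        ax.set_title(title)

    if micrograph is not None:
        axes[4].imshow(micrograph, cmap="gray", interpolation="nearest")
        scale = 1.0
        shift = 0.0
    else:
        axes[4].imshow(score_map.values, cmap="gray", interpolation="nearest")
        # traces are in micrograph pixels; map back to score-map pixels
        scale = 1.0 / score_map.downsample_factor
        shift = 0.5
    for t in traces:
        axes[4].plot(
            [(t.x_start + shift) * scale - shift, (t.x_end + shift) * scale - shift],
            [(t.y_start + shift) * scale - shift, (t.y_end + shift) * scale - shift],
            color="yellow", linewidth=1.2,
        )
    axes[4].set_title(f"final start-end ({len(traces)} lines)")

    for ax in axes:
        ax.set_xticks([])
        ax.set_yticks([])
    fig.tight_layout()
    fig.savefig(out_path, dpi=110)
    plt.close(fig)
    return traces
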