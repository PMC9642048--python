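"""Batch picking orchestration: files in, STAR files (and panels) out.

Thin layer over the library: for every input micrograph or score map it
obtains a score map (read directly, or computed with the surrogate scorer),
runs the four-step trace extraction, writes a pick STAR file, optionally
samples helical segments into a particle STAR file and renders the
diagnostic panel.  Errors are isolated per input file — one broken
micrograph must not kill a batch of thousands.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence

import numpy as np

from .helix_geometry import sample_particles
from .star_io import MicrographImage, read_mrc, write_particles_star, write_pick_star
from .synthetic import surrogate_score_map
from .trace_extraction import PickerParams, ScoreMap, extract_traces

logger = logging.getLogger("helipick")

__all__ = ["RunConfig", "MicrographResult", "RunSummary", "run_pick", "load_score_map"]


@dataclass
class RunConfig:
    """Configuration of one picking batch.

    ``mode`` is ``"scoremap"`` (inputs are scorer outputs, down-sampled by
    ``downsample_factor``) or ``"micrograph"`` (inputs are raw micrographs;
    the surrogate ridge scorer needs the expected filament ``width_A``).
    ``spacing_A`` switches on helical segment sampling along the picked
    lines; ``panel`` writes the four-step diagnostic image.
    """

    inputs: Sequence[str]
    out_dir: str = "."
    mode: str = "scoremap"
    params: PickerParams = None  # type: ignore[assignment]
    downsample_factor: int = 1
    pixel_size_A: float = 1.0
    width_A: Optional[float] = None
    spacing_A: Optional[float] = None
    panel: bool = False

    def __post_init__(self):
        if self.mode not in ("scoremap", "micrograph"):
            raise ValueError(f"mode must be scoremap|micrograph, got {self.mode!r}")
        if self.mode == "micrograph" and not self.width_A:
            raise ValueError("micrograph mode requires the filament width_A "
                             "for the surrogate scorer")
        if self.params is None:
            raise ValueError("params (PickerParams) is required")


@dataclass
class MicrographResult:
    name: str
    n_traces: int = 0
    total_length_px: float = 0.0
    n_particles: int = 0
    error: Optional[str] = None


@dataclass
class RunSummary:
    results: List[MicrographResult] = field(default_factory=list)

    @property
    def n_failed(self) -> int:
        return sum(1 for r in self.results if r.error)

    @property
    def total_traces(self) -> int:
        return sum(r.n_traces for r in self.results)

    def format(self) -> str:
        lines = [f"{'micrograph':<40} {'traces':>7} {'length_px':>12} {'particles':>10}"]
        for r in self.results:
            if r.error:
                lines.append(f"{r.name:<40} ERROR: {r.error}")
            else:
                lines.append(
                    f"{r.name:<40} {r.n_traces:>7d} {r.total_length_px:>12.1f} "
                    f"{r.n_particles:>10d}"
                )
        lines.append(
            f"total: {self.total_traces} traces in "
            f"{len(self.results) - self.n_failed}/{len(self.results)} micrographs"
        )
        return "\n".join(lines)


def load_score_map(path, downsample_factor: int, pixel_size_A: float) -> ScoreMap:
    """Read a score map from MRC or a delimited text matrix."""
    path = Path(path)
    if path.suffix.lower() in (".mrc", ".mrcs", ".map"):
        # A score-map MRC header carries the *down-sampled* pixel size; the
        # ScoreMap wants Angstrom per original micrograph pixel.
        img = read_mrc(
            path, default_pixel_size_A=pixel_size_A * downsample_factor
        )
        return ScoreMap(
            values=img.values,
            downsample_factor=downsample_factor,
            pixel_size_A=img.pixel_size_A / downsample_factor,
        )
    values = np.loadtxt(path, delimiter=None)
    return ScoreMap(
        values=np.atleast_2d(values),
        downsample_factor=downsample_factor,
        pixel_size_A=pixel_size_A,
    )


def _load_micrograph(path, pixel_size_A: float) -> MicrographImage:
    path = Path(path)
    if path.suffix.lower() in (".mrc", ".mrcs", ".map"):
        return read_mrc(path, default_pixel_size_A=pixel_size_A)
    values = np.atleast_2d(np.loadtxt(path, delimiter=None))
    return MicrographImage(values=values, pixel_size_A=pixel_size_A,
                           source_name=path.name)


def run_pick(config: RunConfig) -> RunSummary:
    """Pick every input; write one pick STAR (and optional extras) each."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    summary = RunSummary()

    for raw_path in config.inputs:
        path = Path(raw_path)
        result = MicrographResult(name=path.name)
        summary.results.append(result)
        try:
            if config.mode == "micrograph":
                mic = _load_micrograph(path, config.pixel_size_A)
                score_map = surrogate_score_map(
                    mic, width_A=config.width_A,
                    downsample_factor=config.downsample_factor,
                )
                micrograph_values = mic.values
                pixel_A = mic.pixel_size_A
            else:
                score_map = load_score_map(
                    path, config.downsample_factor, config.pixel_size_A
                )
                micrograph_values = None
                pixel_A = score_map.pixel_size_A

            traces = extract_traces(score_map, config.params)
            if not traces:
                logger.warning("%s: no traces above threshold %g",
                               path.name, config.params.threshold_t)

            stem = path.stem
            write_pick_star(traces, out_dir / f"{stem}_picks.star")
            result.n_traces = len(traces)
            result.total_length_px = sum(t.length_px for t in traces)

            if config.spacing_A and traces:
                records = []
                for t in traces:
                    records.extend(sample_particles(t, config.spacing_A, pixel_A))
                write_particles_star(
                    records, path.name, out_dir / f"{stem}_particles.star"
                )
                result.n_particles = len(records)

            if config.panel:
                from .diagnostics import plot_panel

                plot_panel(score_map, config.params,
                           out_dir / f"{stem}_panel.png",
                           micrograph=micrograph_values)
            logger.info("%s: %d traces", path.name, result.n_traces)
        except Exception as exc:  # per-file isolation
            logger.error("%s: %s", path.name, exc)
            result.error = str(exc)
    return summary
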