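"""Stack I/O, pipeline configuration, and the end-to-end run.

The pipeline composes the stages in the order the experiment implies:
calibrate (or load fits) → smooth → detect → link → fold change → map doses
→ bin → summarize → test against control.  CSV is the exchange format
between stages so each is independently testable; a machine-readable run
log captures the configuration hash, package versions and seed, making
every output regenerable from config + seed alone.
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import __version__
from .calibration import (
    IrradianceMap,
    build_irradiance_map,
    evaluate_irradiance,
    read_fit_json,
    reference_fit,
)
from .detection import (
    CellTrack,
    ImageFrame,
    assign_doses,
    auto_threshold,
    compute_fold_changes,
    detect_cells,
    gaussian_smooth,
    link_tracks,
)
from .dose_response import (
    DoseBinScheme,
    assign_bins,
    compare_to_control,
    plot_grid,
    summarize_grid,
    write_comparisons_csv,
)
from .synthetic import ResponseModel, SceneParams, generate_scene

__all__ = [
    "PipelineConfig",
    "PipelineError",
    "read_stack",
    "write_stack",
    "mapped_dose_ranges",
    "tracks_to_frame",
    "run_pipeline",
]


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name for the CLI error message."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def read_stack(path: str | Path, labels: Sequence[str], pixel_size: float = 1.6) -> list[ImageFrame]:
    """Read a multi-page TIFF; page k becomes the frame labeled labels[k]."""
    data = tifffile.imread(path)
    if data.ndim == 2:
        data = data[None]
    if data.shape[0] != len(labels):
        raise ValueError(
            f"stack {path} has {data.shape[0]} pages but {len(labels)} "
            f"timepoint labels were given"
        )
    return [
        ImageFrame(pixels=page, timepoint_label=label, pixel_size=pixel_size)
        for page, label in zip(data, labels)
    ]


def write_stack(frames: Sequence[ImageFrame], path: str | Path) -> None:
    tifffile.imwrite(
        path, np.stack([f.pixels for f in frames]), photometric="minisblack"
    )


def _polynomial_range(fit, extent: float) -> tuple[float, float]:
    """Exact (min, max) of the gradient polynomial over [0, extent] μm.

    Candidates are the interval endpoints plus the real stationary points
    (roots of the derivative) inside the interval, so interior extrema are
    not missed the way a grid scan would miss them.
    """
    candidates = [0.0, extent]
    deriv = np.polynomial.polynomial.polyder(fit.coefficients)
    if deriv.size:
        roots = np.polynomial.polynomial.polyroots(deriv)
        candidates += [float(r.real) for r in roots
                       if abs(r.imag) < 1e-9 and 0.0 <= r.real <= extent]
    values = [float(evaluate_irradiance(fit, c)) for c in candidates]
    return min(values), max(values)


def mapped_dose_ranges(
    irr_map: IrradianceMap,
) -> tuple[tuple[float, float], tuple[float, float]]:
    """(min, max) dose per wavelength delivered across the beam field."""
    return (
        _polynomial_range(irr_map.fit_x, irr_map.field_extent[0]),
        _polynomial_range(irr_map.fit_y, irr_map.field_extent[1]),
    )


@dataclass
class PipelineConfig:
    """Everything needed to reproduce one analysis run."""

    # input: either a TIFF stack or a synthetic scene
    stack: str | None = None
    synthetic: bool = True
    n_runs: int = 1  # independent synthetic experiments pooled before testing
    timepoints: tuple[str, ...] = ("pre", "1min", "5min")
    baseline: str = "pre"
    # calibration: JSON fit files, or the built-in reference polynomials
    fit_files: tuple[str, ...] = ()
    pixel_size: float = 1.6
    field_extent: tuple[float, float] = (1200.0, 1200.0)
    # detection
    threshold: float | str = "auto"  # "auto" = median + n_sigmas·(scaled MAD)
    threshold_sigmas: float = 5.0
    window: int = 5
    smooth_sigma: float = 0.85
    tolerance_px: float = 2.0
    measure_on: str = "raw"
    # binning / statistics
    n_bins: int = 5
    alpha: float = 0.05
    seed: int = 0
    out_dir: str = "nirdose_out"

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**doc)
        cfg.timepoints = tuple(cfg.timepoints)
        cfg.fit_files = tuple(cfg.fit_files)
        cfg.field_extent = tuple(cfg.field_extent)
        return cfg

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


@dataclass
class PipelineResult:
    """Outputs of one end-to-end run."""

    tracks: list[CellTrack]
    cells: pd.DataFrame
    grids: dict  # timepoint -> DoseResponseGrid
    summaries: dict[str, pd.DataFrame]
    comparisons: dict[str, pd.DataFrame]
    scheme: DoseBinScheme
    outputs: dict[str, Path] = field(default_factory=dict)
    truth: pd.DataFrame | None = None


def _load_map(config: PipelineConfig) -> IrradianceMap:
    if config.fit_files:
        fits = [read_fit_json(p) for p in config.fit_files]
        if len(fits) != 2:
            raise ValueError("exactly two calibration fit files are required")
        by_wl = {f.wavelength: f for f in fits}
        if 1064 not in by_wl or 1270 not in by_wl:
            raise ValueError("fit files must cover wavelengths 1064 and 1270 nm")
        fit_x, fit_y = by_wl[1064], by_wl[1270]
    else:
        fit_x, fit_y = reference_fit(1064), reference_fit(1270)
    return build_irradiance_map(
        fit_x, fit_y, pixel_size=config.pixel_size, field_extent=config.field_extent
    )


def analyze_frames(
    frames: Sequence[ImageFrame], config: PipelineConfig, irr_map: IrradianceMap
) -> list[CellTrack]:
    """Smooth → detect → link → fold change → dose for one acquisition series."""
    by_label = {f.timepoint_label: f for f in frames}
    if config.baseline not in by_label:
        raise ValueError(f"baseline frame {config.baseline!r} missing from stack")
    smoothed = {lbl: gaussian_smooth(f, config.smooth_sigma) for lbl, f in by_label.items()}
    if config.threshold == "auto":
        thr = auto_threshold(smoothed[config.baseline], config.threshold_sigmas)
    else:
        thr = float(config.threshold)
    per_frame = [
        detect_cells(smoothed[lbl], by_label[lbl], thr, config.window)
        for lbl in config.timepoints
        if lbl in by_label
    ]
    tracks = link_tracks(per_frame, config.baseline, config.tolerance_px)
    tracks = compute_fold_changes(tracks, config.baseline, config.measure_on)  # type: ignore[arg-type]
    return assign_doses(tracks, irr_map, config.baseline)


def tracks_to_frame(tracks: Sequence[CellTrack], timepoints: Sequence[str]) -> pd.DataFrame:
    """Per-cell results table (one row per tracked cell)."""
    rows = []
    for t in tracks:
        base = t.detections[min(t.detections, key=lambda k: list(timepoints).index(k))]
        rec = {
            "cell_id": t.cell_id,
            "col": base.col,
            "row": base.row,
            "dose_1064_mw_cm2": t.dose.dose_1064 if t.dose else float("nan"),
            "dose_1270_mw_cm2": t.dose.dose_1270 if t.dose else float("nan"),
            "is_control": t.dose.is_control if t.dose else False,
        }
        for tp in timepoints:
            if tp in t.detections:
                rec[f"intensity_{tp}"] = t.detections[tp].intensity_raw
            if tp in t.fold_changes:
                rec[f"fold_{tp}"] = t.fold_changes[tp]
        rows.append(rec)
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig, write_outputs: bool = True) -> PipelineResult:
    """Execute the full analysis; stage failures abort with the stage name.

    When ``write_outputs`` is set, the per-cell table, per-timepoint grid and
    comparison CSVs, color-map PNGs, and a run log land in ``config.out_dir``;
    partial outputs are removed if a later stage fails.
    """
    post_labels = [tp for tp in config.timepoints if tp != config.baseline]
    if not post_labels:
        raise ValueError("nothing to compare: no post-laser timepoints configured")

    stage = "calibrate"
    written: list[Path] = []
    try:
        irr_map = _load_map(config)

        stage = "acquire"
        truth = None
        all_tracks: list[CellTrack] = []
        if config.synthetic:
            truths = []
            next_id = 0
            for run in range(config.n_runs):
                params = SceneParams(
                    pixel_size=config.pixel_size,
                    field_extent=config.field_extent,
                    timepoints=config.timepoints,
                    seed=config.seed + 7919 * run,
                )
                scene = generate_scene(params, ResponseModel(), irr_map)
                truths.append(scene.truth.assign(run=run))
                stage = "detect"
                tracks = analyze_frames(scene.frames, config, irr_map)
                for t in tracks:
                    t.cell_id = next_id
                    next_id += 1
                all_tracks.extend(tracks)
                stage = "acquire"
            truth = pd.concat(truths, ignore_index=True)
        else:
            if config.stack is None:
                raise ValueError("no input stack configured")
            frames = read_stack(config.stack, config.timepoints, config.pixel_size)
            stage = "detect"
            all_tracks = analyze_frames(frames, config, irr_map)

        stage = "bin"
        r1064, r1270 = mapped_dose_ranges(irr_map)
        scheme = DoseBinScheme.equal_width(r1064, r1270, config.n_bins)
        grids = {tp: assign_bins(all_tracks, scheme) for tp in post_labels}
        summaries = {tp: summarize_grid(grids[tp], tp) for tp in post_labels}

        stage = "test"
        comparisons: dict[str, pd.DataFrame] = {}
        for tp in post_labels:
            grid = grids[tp]
            if len(grid.control_cells) >= 2:
                _, table = compare_to_control(grid, tp, config.alpha)
                comparisons[tp] = table

        stage = "write"
        outputs: dict[str, Path] = {}
        if write_outputs:
            out = Path(config.out_dir)
            out.mkdir(parents=True, exist_ok=True)

            def _write(name: str, writer) -> Path:
                path = out / name
                writer(path)
                written.append(path)
                return path

            cells = tracks_to_frame(all_tracks, config.timepoints)
            outputs["cells"] = _write("cells.csv", lambda p: cells.to_csv(p, index=False))
            if truth is not None:
                outputs["truth"] = _write(
                    "ground_truth.csv", lambda p: truth.to_csv(p, index=False)
                )
            for tp in post_labels:
                outputs[f"grid_{tp}"] = _write(
                    f"grid_{tp}.csv", lambda p, tp=tp: summaries[tp].to_csv(p, index=False)
                )
                outputs[f"colormap_{tp}"] = _write(
                    f"colormap_{tp}.png", lambda p, tp=tp: plot_grid(grids[tp], tp, p)
                )
                if tp in comparisons:
                    outputs[f"comparisons_{tp}"] = _write(
                        f"comparisons_{tp}.csv",
                        lambda p, tp=tp: write_comparisons_csv(comparisons[tp], p),
                    )
            log = {
                "nirdose_version": __version__,
                "python": platform.python_version(),
                "numpy": np.__version__,
                "config": asdict(config),
                "config_hash": config.config_hash(),
                "seed": config.seed,
                "n_tracks": len(all_tracks),
                "bin_edges_1064": list(scheme.edges_1064),
                "bin_edges_1270": list(scheme.edges_1270),
            }
            outputs["runlog"] = _write(
                "runlog.json", lambda p: p.write_text(json.dumps(log, indent=2, default=str))
            )
        else:
            cells = tracks_to_frame(all_tracks, config.timepoints)

        return PipelineResult(
            tracks=all_tracks,
            cells=cells,
            grids=grids,
            summaries=summaries,
            comparisons=comparisons,
            scheme=scheme,
            outputs=outputs,
            truth=truth,
        )
    except PipelineError:
        raise
    except Exception as exc:
        for path in written:
            path.unlink(missing_ok=True)
        raise PipelineError(stage, exc) from exc
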