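"""Seeded synthetic data: beam-profile scans and fluorescence time-lapse scenes.

Everything the real experiment produces — replicated beam-profiler line
scans and pre/post-exposure fluorescence frames of point-like cells — can be
generated here with known ground truth, so the whole pipeline (calibration,
detection, tracking, binning, statistics) is testable without a microscope.

The default scene mirrors the experimental geometry: a 1.2×1.2 mm gradient
beam field imaged at 1.6 μm/px (750×750 px) inside a slightly larger
800×800 px frame, whose beam-free margin supplies the no-laser control
cells.  Cells are rendered as isotropic Gaussian point-spread functions on
a noisy 16-bit background.  The programmed dose response suppresses the
signal at 1 min only for cells inside the 250–400 mW/cm² (1064 nm) ×
55–65 mW/cm² (1270 nm) irradiance window and recovers it by 5 min.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .calibration import (
    IrradianceMap,
    PolynomialFit,
    ProfileSample,
    build_irradiance_map,
    reference_fit,
)
from .detection import ImageFrame

__all__ = [
    "ResponseModel",
    "SceneParams",
    "SyntheticScene",
    "simulate_beam_profiles",
    "simulate_cell_field",
    "render_frames",
    "generate_scene",
    "default_irradiance_map",
    "DEFAULT_TIMEPOINTS",
]

DEFAULT_TIMEPOINTS: tuple[str, ...] = ("pre", "1min", "5min")


@dataclass(frozen=True)
class ResponseModel:
    """Programmed dose response of the fold change.

    Inside ``suppression_window`` (a dose rectangle in 1064 × 1270 nm
    irradiance) the mean fold change at 1 min drops to ``fold_1min_inside``;
    everywhere else, and at 5 min, the signal sits at the control level.
    ``cell_sd`` is the between-cell spread of the realized fold changes.
    """

    suppression_window: tuple[tuple[float, float], tuple[float, float]] = (
        (250.0, 400.0),
        (55.0, 65.0),
    )
    fold_1min_inside: float = 0.85
    fold_1min_outside: float = 1.0
    fold_5min: float = 1.0
    cell_sd: float = 0.10

    def in_window(self, dose_1064: float, dose_1270: float) -> bool:
        (lo1, hi1), (lo2, hi2) = self.suppression_window
        return lo1 <= dose_1064 <= hi1 and lo2 <= dose_1270 <= hi2

    def mean_fold(self, timepoint: str, dose_1064: float, dose_1270: float,
                  is_control: bool) -> float:
        if timepoint == "pre":
            return 1.0
        if is_control:
            return 1.0
        if timepoint == "1min":
            return (
                self.fold_1min_inside
                if self.in_window(dose_1064, dose_1270)
                else self.fold_1min_outside
            )
        return self.fold_5min


@dataclass(frozen=True)
class SceneParams:
    """Rendering and acquisition parameters of a synthetic experiment."""

    frame_shape: tuple[int, int] = (800, 800)  # rows, cols (px)
    pixel_size: float = 1.6  # μm/px
    field_extent: tuple[float, float] = (1200.0, 1200.0)  # beam size (μm)
    cell_density: float = 1.0 / 1600.0  # cells per px² (≈ 1 per 40×40 px)
    psf_sigma: float = 2.0  # px
    background: float = 100.0  # camera counts
    amplitude_mean: float = 2000.0  # peak counts above background
    amplitude_sd: float = 400.0
    noise_sd_frac: float = 0.02  # Gaussian read noise, fraction of background
    poisson_noise: bool = False
    bleach_per_acquisition: float = 0.02  # 2% signal loss per exposure
    bit_depth: int = 16
    timepoints: tuple[str, ...] = DEFAULT_TIMEPOINTS
    min_separation_px: float = 5.0  # >= detection window keeps peaks resolvable
    enforce_separation: bool = True
    seed: int = 0

    @property
    def n_cells(self) -> int:
        rows, cols = self.frame_shape
        return int(round(self.cell_density * rows * cols))


@dataclass
class SyntheticScene:
    """A rendered synthetic experiment: frames plus the ground-truth table."""

    params: SceneParams
    response: ResponseModel
    truth: pd.DataFrame
    frames: list[ImageFrame] = field(default_factory=list)


def simulate_beam_profiles(
    truth: PolynomialFit,
    n_replicates: int = 5,
    noise_sd_frac: float = 0.02,
    positions: Sequence[float] | None = None,
    seed: int = 0,
) -> list[ProfileSample]:
    """Replicated noisy line scans of a gradient polynomial.

    Each reading is truth(position)·(1 + ε) with ε ~ N(0, noise_sd_frac),
    emulating a beam profiler rescanned ``n_replicates`` times.
    """
    if n_replicates < 1:
        raise ValueError("need at least one replicate")
    if noise_sd_frac < 0:
        raise ValueError("noise fraction must be non-negative")
    if positions is None:
        positions = np.arange(0.0, 1201.0, 20.0)
    pos = np.asarray(positions, dtype=float)
    rng = np.random.default_rng(seed)
    samples = []
    for rep in range(n_replicates):
        eps = rng.normal(0.0, noise_sd_frac, size=pos.size) if noise_sd_frac else 0.0
        values = truth(pos) * (1.0 + eps)
        for p, v in zip(pos, np.atleast_1d(values)):
            samples.append(ProfileSample(position=float(p), irradiance=float(v), replicate_id=rep))
    return samples


def default_irradiance_map(params: SceneParams | None = None) -> IrradianceMap:
    """The published dual-gradient dose map at the scene's pixel size and extent."""
    params = params or SceneParams()
    return build_irradiance_map(
        reference_fit(1064),
        reference_fit(1270),
        pixel_size=params.pixel_size,
        field_extent=params.field_extent,
    )


def _place_cells(params: SceneParams, rng: np.random.Generator) -> np.ndarray:
    """Uniform random (col, row) positions with a minimum pairwise separation."""
    rows, cols = params.frame_shape
    n = params.n_cells
    margin = 3.0 * params.psf_sigma  # keep the PSF core inside the frame
    if not params.enforce_separation:
        out = np.empty((n, 2))
        out[:, 0] = rng.uniform(margin, cols - 1 - margin, size=n)
        out[:, 1] = rng.uniform(margin, rows - 1 - margin, size=n)
        return out
    sep2 = params.min_separation_px**2
    # grid-hash rejection sampling; density 1/1600 px² leaves plenty of room
    cell = max(params.min_separation_px, 1.0)
    occupied: dict[tuple[int, int], list[tuple[float, float]]] = {}
    placed: list[tuple[float, float]] = []
    attempts = 0
    max_attempts = 200 * n
    while len(placed) < n:
        if attempts >= max_attempts:
            raise RuntimeError(
                f"could not place {n} cells with separation "
                f"{params.min_separation_px} px after {max_attempts} attempts"
            )
        attempts += 1
        x = rng.uniform(margin, cols - 1 - margin)
        y = rng.uniform(margin, rows - 1 - margin)
        gx, gy = int(x // cell), int(y // cell)
        ok = True
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for px, py in occupied.get((gx + dx, gy + dy), ()):
                    if (px - x) ** 2 + (py - y) ** 2 < sep2:
                        ok = False
                        break
                if not ok:
                    break
            if not ok:
                break
        if ok:
            placed.append((x, y))
            occupied.setdefault((gx, gy), []).append((x, y))
    return np.asarray(placed)


def simulate_cell_field(
    params: SceneParams,
    irr_map: IrradianceMap,
    response: ResponseModel = ResponseModel(),
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Ground-truth table: positions, amplitudes, doses and true fold changes.

    Cells land uniformly over the frame; those outside the beam field are
    flagged as no-laser controls.  Realized fold changes are drawn per cell
    around the response model's mean with sd ``cell_sd`` (truncated at a
    small positive floor so ratios stay valid).
    """
    rng = rng if rng is not None else np.random.default_rng(params.seed)
    pos = _place_cells(params, rng)
    amps = np.clip(
        rng.normal(params.amplitude_mean, params.amplitude_sd, size=len(pos)),
        params.amplitude_mean * 0.2,
        None,
    )
    records = []
    for cid, ((x, y), amp) in enumerate(zip(pos, amps)):
        dose = irr_map.dose_at(x, y)
        rec = {
            "cell_id": cid,
            "col": x,
            "row": y,
            "amplitude": amp,
            "dose_1064": dose.dose_1064,
            "dose_1270": dose.dose_1270,
            "is_control": dose.is_control,
        }
        for tp in params.timepoints:
            mean = response.mean_fold(tp, dose.dose_1064, dose.dose_1270, dose.is_control)
            if tp == "pre":
                fold = 1.0
            else:
                fold = max(rng.normal(mean, response.cell_sd), 0.05)
            rec[f"fold_{tp}"] = fold
        records.append(rec)
    return pd.DataFrame.from_records(records)


def render_frames(
    params: SceneParams,
    truth: pd.DataFrame,
    rng: np.random.Generator | None = None,
) -> list[ImageFrame]:
    """Render the time-lapse: background + Gaussian PSFs + noise, per timepoint.

    frame(t) = background + Σ_cells amplitude·fold(t)·bleach(t)·PSF + noise,
    quantized and clipped to the configured bit depth.  The PSF is peak-
    normalized, so a cell's nominal peak height is its amplitude.  Bleaching
    compounds per acquisition (the baseline is the first exposure), which the
    0-min normalization downstream is expected to absorb.
    """
    rng = rng if rng is not None else np.random.default_rng(params.seed + 1)
    rows, cols = params.frame_shape
    max_count = 2**params.bit_depth - 1
    r_patch = int(math.ceil(4 * params.psf_sigma))
    frames = []
    for k, tp in enumerate(params.timepoints):
        img = np.full((rows, cols), float(params.background))
        bleach = (1.0 - params.bleach_per_acquisition) ** k
        for rec in truth.itertuples():
            fold = getattr(rec, f"fold_{tp}")
            peak = rec.amplitude * fold * bleach
            cx, cy = rec.col, rec.row
            c0, c1 = int(cx) - r_patch, int(cx) + r_patch + 1
            r0, r1 = int(cy) - r_patch, int(cy) + r_patch + 1
            c0, r0 = max(c0, 0), max(r0, 0)
            c1, r1 = min(c1, cols), min(r1, rows)
            xs = np.arange(c0, c1) - cx
            ys = np.arange(r0, r1) - cy
            img[r0:r1, c0:c1] += peak * np.exp(
                -(xs[None, :] ** 2 + ys[:, None] ** 2) / (2 * params.psf_sigma**2)
            )
        if params.poisson_noise:
            img = rng.poisson(np.clip(img, 0, None)).astype(float)
        if params.noise_sd_frac > 0:
            img = img + rng.normal(
                0.0, params.noise_sd_frac * params.background, size=img.shape
            )
        img = np.clip(np.rint(img), 0, max_count)
        dtype = np.uint16 if params.bit_depth > 8 else np.uint8
        frames.append(
            ImageFrame(
                pixels=img.astype(dtype),
                timepoint_label=tp,
                pixel_size=params.pixel_size,
            )
        )
    return frames


def generate_scene(
    params: SceneParams = SceneParams(),
    response: ResponseModel = ResponseModel(),
    irr_map: IrradianceMap | None = None,
) -> SyntheticScene:
    """Full seeded scene: ground truth plus rendered frames.

    Identical (params, response) produce identical frames; the cell-field
    and rendering noise streams are derived from ``params.seed``.
    """
    irr_map = irr_map or default_irradiance_map(params)
    rng = np.random.default_rng(params.seed)
    truth = simulate_cell_field(params, irr_map, response, rng)
    frames = render_frames(params, truth, np.random.default_rng(params.seed + 1))
    return SyntheticScene(params=params, response=response, truth=truth, frames=frames)


def write_scene(scene: SyntheticScene, out_dir: str | Path) -> dict[str, Path]:
    """Write the scene as a multi-page TIFF stack plus ground-truth CSV."""
    import tifffile

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stack_path = out / "stack.tif"
    tifffile.imwrite(
        stack_path,
        np.stack([f.pixels for f in scene.frames]),
        photometric="minisblack",
    )
    truth_path = out / "ground_truth.csv"
    scene.truth.to_csv(truth_path, index=False)
    return {"stack": stack_path, "truth": truth_path}


def uniform_dose_population(
    n_cells: int,
    irr_map: IrradianceMap | None = None,
    frame_shape: tuple[int, int] = (750, 750),
    seed: int = 42,
) -> pd.DataFrame:
    """Dose pairs of cells placed uniformly over the beam field (no rendering).

    Convenience population for occupancy studies: every pixel of
    ``frame_shape`` lies inside the beam, so all cells receive a dose.
    """
    irr_map = irr_map or default_irradiance_map()
    rng = np.random.default_rng(seed)
    rows, cols = frame_shape
    xs = rng.uniform(0, cols - 1, size=n_cells)
    ys = rng.uniform(0, rows - 1, size=n_cells)
    d1 = np.array([irr_map.dose_at(x, y).dose_1064 for x, y in zip(xs, ys)])
    d2 = np.array([irr_map.dose_at(x, y).dose_1270 for x, y in zip(xs, ys)])
    return pd.DataFrame(
        {"cell_id": np.arange(n_cells), "col": xs, "row": ys,
         "dose_1064": d1, "dose_1270": d2}
    )
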