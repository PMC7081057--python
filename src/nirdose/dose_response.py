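"""Dose binning and group statistics for the dual-gradient irradiance grid.

Tracked cells are grouped by the (1064 nm, 1270 nm) irradiance pair they
received — by default a 5×5 grid of equal-width bins spanning the doses the
field actually delivers, i.e. 25 groups.  Each group's fold-change mean and
SEM form the dose-response grid (the color map), and groups are compared
against the no-laser control with one-way ANOVA followed by Tukey's
multiple-comparison test (the Tukey–Kramer form for unequal group sizes).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .detection import CellTrack

__all__ = [
    "DoseBinScheme",
    "DoseResponseGrid",
    "AnovaResult",
    "TukeyPair",
    "ComparisonResult",
    "assign_bins",
    "summarize_grid",
    "one_way_anova",
    "tukey_hsd",
    "compare_to_control",
    "write_grid_csv",
    "write_comparisons_csv",
    "plot_grid",
    "DEFAULT_ALPHA",
]

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.05


@dataclass(frozen=True)
class DoseBinScheme:
    """Ascending bin edges per wavelength; n_x × n_y half-open dose rectangles."""

    edges_1064: tuple[float, ...]
    edges_1270: tuple[float, ...]

    def __post_init__(self) -> None:
        for name, edges in (("edges_1064", self.edges_1064), ("edges_1270", self.edges_1270)):
            e = np.asarray(edges, dtype=float)
            if e.size < 2 or not np.all(np.diff(e) > 0):
                raise ValueError(f"{name} needs >= 2 strictly ascending edges")

    @classmethod
    def equal_width(
        cls,
        range_1064: tuple[float, float],
        range_1270: tuple[float, float],
        n_bins: int = 5,
    ) -> "DoseBinScheme":
        """n equal-width bins per wavelength over the given dose ranges (default 5×5=25)."""
        return cls(
            edges_1064=tuple(np.linspace(*range_1064, n_bins + 1)),
            edges_1270=tuple(np.linspace(*range_1270, n_bins + 1)),
        )

    @property
    def shape(self) -> tuple[int, int]:
        return len(self.edges_1064) - 1, len(self.edges_1270) - 1

    def bin_centers(self) -> tuple[np.ndarray, np.ndarray]:
        e1 = np.asarray(self.edges_1064)
        e2 = np.asarray(self.edges_1270)
        return (e1[:-1] + e1[1:]) / 2, (e2[:-1] + e2[1:]) / 2

    def locate(self, dose_1064: float, dose_1270: float) -> tuple[int, int] | None:
        """Bin indices for a dose pair under the half-open convention, or None.

        A dose on an interior edge belongs to the higher bin; the topmost
        edge is closed so the maximum mapped dose stays in range.
        """
        i = _locate_1d(np.asarray(self.edges_1064), dose_1064)
        j = _locate_1d(np.asarray(self.edges_1270), dose_1270)
        return None if i is None or j is None else (i, j)


def _locate_1d(edges: np.ndarray, x: float) -> int | None:
    if x < edges[0] or x > edges[-1]:
        return None
    if x == edges[-1]:
        return len(edges) - 2
    return int(np.searchsorted(edges, x, side="right")) - 1


@dataclass
class DoseResponseGrid:
    """Cells assigned to dose-combination groups, plus the no-laser controls."""

    scheme: DoseBinScheme
    cells: dict[tuple[int, int], list[CellTrack]]
    control_cells: list[CellTrack] = field(default_factory=list)
    n_out_of_range: int = 0

    @property
    def n_assigned(self) -> int:
        return sum(len(v) for v in self.cells.values())

    def group_fold_changes(self, bin_ij: tuple[int, int], timepoint: str) -> np.ndarray:
        return np.array([t.fold_changes[timepoint] for t in self.cells.get(bin_ij, [])])

    def control_fold_changes(self, timepoint: str) -> np.ndarray:
        return np.array([t.fold_changes[timepoint] for t in self.control_cells])


def assign_bins(tracks: Sequence[CellTrack], scheme: DoseBinScheme) -> DoseResponseGrid:
    """Assign each tracked cell to its dose rectangle.

    In-field cells whose dose pair falls outside the binning ranges are
    excluded and counted; out-of-field cells become the no-laser control
    group.
    """
    nx, ny = scheme.shape
    cells: dict[tuple[int, int], list[CellTrack]] = {
        (i, j): [] for i in range(nx) for j in range(ny)
    }
    controls: list[CellTrack] = []
    n_out = 0
    for track in tracks:
        if track.dose is None:
            raise ValueError(f"cell {track.cell_id} has no dose assigned")
        if track.dose.is_control:
            controls.append(track)
            continue
        loc = scheme.locate(track.dose.dose_1064, track.dose.dose_1270)
        if loc is None:
            n_out += 1
        else:
            cells[loc].append(track)
    return DoseResponseGrid(
        scheme=scheme, cells=cells, control_cells=controls, n_out_of_range=n_out
    )


def summarize_grid(grid: DoseResponseGrid, timepoint: str) -> pd.DataFrame:
    """Per-group mean fold change, SEM = sd/√n, and count for one timepoint.

    Returns a tidy frame with one row per dose rectangle; empty groups carry
    NaN means and groups with n < 2 a NaN SEM.
    """
    e1 = np.asarray(grid.scheme.edges_1064)
    e2 = np.asarray(grid.scheme.edges_1270)
    rows = []
    for (i, j), members in sorted(grid.cells.items()):
        fc = grid.group_fold_changes((i, j), timepoint)
        n = fc.size
        rows.append(
            {
                "bin_1064_lo": e1[i],
                "bin_1064_hi": e1[i + 1],
                "bin_1270_lo": e2[j],
                "bin_1270_hi": e2[j + 1],
                "n": n,
                "mean_fold": float(fc.mean()) if n else float("nan"),
                "sem": float(fc.std(ddof=1) / math.sqrt(n)) if n >= 2 else float("nan"),
            }
        )
    return pd.DataFrame(rows)


def grid_matrices(
    grid: DoseResponseGrid, timepoint: str
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(mean, sem, n) matrices shaped (n_1064_bins, n_1270_bins) for the color map."""
    nx, ny = grid.scheme.shape
    mean = np.full((nx, ny), np.nan)
    sem = np.full((nx, ny), np.nan)
    n = np.zeros((nx, ny), dtype=int)
    for (i, j), members in grid.cells.items():
        fc = grid.group_fold_changes((i, j), timepoint)
        n[i, j] = fc.size
        if fc.size:
            mean[i, j] = fc.mean()
        if fc.size >= 2:
            sem[i, j] = fc.std(ddof=1) / math.sqrt(fc.size)
    return mean, sem, n


@dataclass(frozen=True)
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p_value: float
    ms_within: float


@dataclass(frozen=True)
class TukeyPair:
    group_i: int
    group_j: int
    mean_diff: float  # mean_i - mean_j
    q: float
    adj_p: float
    significant: bool


@dataclass(frozen=True)
class ComparisonResult:
    anova: AnovaResult
    tukey: tuple[TukeyPair, ...]
    alpha: float
    group_labels: tuple[str, ...] = ()


def _validate_groups(groups: Sequence[Sequence[float]]) -> list[np.ndarray]:
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2:
        raise ValueError("need at least 2 groups")
    for k, g in enumerate(gs):
        if g.size < 2:
            raise ValueError(f"group {k} has fewer than 2 observations")
        if not np.all(np.isfinite(g)):
            raise ValueError(f"group {k} contains non-finite values")
    return gs


def one_way_anova(groups: Sequence[Sequence[float]]) -> AnovaResult:
    """Classical one-way fixed-effects ANOVA.

    F = MS_between / MS_within with (g−1, N−g) degrees of freedom from the
    usual sum-of-squares decomposition; the p-value comes from the central F
    distribution.
    """
    gs = _validate_groups(groups)
    all_y = np.concatenate(gs)
    grand = all_y.mean()
    ss_between = sum(g.size * (g.mean() - grand) ** 2 for g in gs)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in gs)
    df_b = len(gs) - 1
    df_w = all_y.size - len(gs)
    if ss_within <= 0:
        raise ValueError("zero within-group variance: F statistic is degenerate")
    ms_b = ss_between / df_b
    ms_w = ss_within / df_w
    F = ms_b / ms_w
    return AnovaResult(
        F=float(F),
        df_between=df_b,
        df_within=df_w,
        p_value=float(stats.f.sf(F, df_b, df_w)),
        ms_within=float(ms_w),
    )


def tukey_hsd(
    groups: Sequence[Sequence[float]], alpha: float = DEFAULT_ALPHA
) -> ComparisonResult:
    """All-pairs Tukey HSD after one-way ANOVA (Tukey–Kramer for unequal n).

    For each pair, q = |m_i − m_j| / sqrt(MS_within/2 · (1/n_i + 1/n_j)) and
    the adjusted p is the studentized-range tail probability with parameters
    (g groups, N−g error df); a pair is significant when adj_p < alpha.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    gs = _validate_groups(groups)
    anova = one_way_anova(gs)
    k = len(gs)
    means = [g.mean() for g in gs]
    ns = [g.size for g in gs]
    pairs = []
    for i in range(k):
        for j in range(i + 1, k):
            se = math.sqrt(anova.ms_within / 2.0 * (1.0 / ns[i] + 1.0 / ns[j]))
            diff = means[i] - means[j]
            q = abs(diff) / se
            p = float(stats.studentized_range.sf(q, k, anova.df_within))
            p = min(max(p, 0.0), 1.0)
            pairs.append(
                TukeyPair(
                    group_i=i,
                    group_j=j,
                    mean_diff=float(diff),
                    q=float(q),
                    adj_p=p,
                    significant=p < alpha,
                )
            )
    return ComparisonResult(anova=anova, tukey=tuple(pairs), alpha=alpha)


def compare_to_control(
    grid: DoseResponseGrid,
    timepoint: str,
    alpha: float = DEFAULT_ALPHA,
    min_n: int = 2,
) -> tuple[ComparisonResult, pd.DataFrame]:
    """ANOVA + Tukey of every occupied dose group against the no-laser control.

    Groups with fewer than ``min_n`` cells are excluded from inference with
    a warning.  Returns the full comparison plus a tidy table of the
    control-vs-group contrasts.
    """
    control = grid.control_fold_changes(timepoint)
    if control.size < min_n:
        raise ValueError(
            f"control group has {control.size} cells; need >= {min_n} for inference"
        )
    labels = ["control"]
    groups: list[np.ndarray] = [control]
    bin_keys: list[tuple[int, int]] = []
    for key in sorted(grid.cells):
        fc = grid.group_fold_changes(key, timepoint)
        if fc.size < min_n:
            if fc.size:
                logger.warning("dose group %s has n=%d < %d; excluded", key, fc.size, min_n)
            continue
        labels.append(f"bin_{key[0]}_{key[1]}")
        groups.append(fc)
        bin_keys.append(key)
    result = tukey_hsd(groups, alpha=alpha)
    result = ComparisonResult(
        anova=result.anova, tukey=result.tukey, alpha=alpha, group_labels=tuple(labels)
    )
    rows = []
    for pair in result.tukey:
        if pair.group_i != 0:
            continue  # keep only control-vs-dose contrasts in the table
        rows.append(
            {
                "group": labels[pair.group_j],
                "control": "control",
                "mean_diff": -pair.mean_diff,  # group minus control
                "q": pair.q,
                "adj_p": pair.adj_p,
                "significant": pair.significant,
            }
        )
    return result, pd.DataFrame(rows)


def write_grid_csv(grid: DoseResponseGrid, timepoint: str, path: str | Path) -> None:
    summarize_grid(grid, timepoint).to_csv(path, index=False)


def write_comparisons_csv(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False)


def plot_grid(grid: DoseResponseGrid, timepoint: str, path: str | Path) -> None:
    """Render the mean fold-change color map (1064 nm on x, 1270 nm on y)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    mean, _, n = grid_matrices(grid, timepoint)
    c1, c2 = grid.scheme.bin_centers()
    fig, ax = plt.subplots(figsize=(5, 4))
    im = ax.imshow(
        mean.T,
        origin="lower",
        aspect="auto",
        extent=(grid.scheme.edges_1064[0], grid.scheme.edges_1064[-1],
                grid.scheme.edges_1270[0], grid.scheme.edges_1270[-1]),
        cmap="viridis",
    )
    fig.colorbar(im, ax=ax, label=f"mean fold change ({timepoint})")
    ax.set_xlabel("1064 nm irradiance (mW/cm$^2$)")
    ax.set_ylabel("1270 nm irradiance (mW/cm$^2$)")
    ax.set_xticks(np.round(c1, 1))
    ax.set_yticks(np.round(c2, 1))
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
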