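"""Beam-profile calibration: polynomial irradiance-gradient fits and the 2-D dose map.

A gradient square beam delivers an irradiance that varies along one image
axis.  Replicated line scans of each beam (position in μm vs. irradiance in
mW/cm²) are fitted with ordinary least-squares polynomials; the polynomial
degree is chosen by Akaike's information criterion (AIC).  Two orthogonal
fits — 1064 nm along the image x (column) axis and 1270 nm along y (rows) —
compose into a per-pixel dual-wavelength dose map, so each detected cell's
position converts into the (1064 nm, 1270 nm) irradiance pair it received.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ProfileSample",
    "PolynomialFit",
    "IrradianceMap",
    "DosePair",
    "REFERENCE_COEFFS_1064",
    "REFERENCE_COEFFS_1270",
    "reference_fit",
    "fit_polynomial",
    "select_degree_aic",
    "evaluate_irradiance",
    "confidence_band",
    "build_irradiance_map",
    "map_pixel_to_dose",
    "read_profile_csv",
    "write_profile_csv",
    "write_fit_json",
    "read_fit_json",
    "DEFAULT_CANDIDATE_DEGREES",
    "DEFAULT_PIXEL_SIZE_UM",
]

#: Published calibration of the 1064 nm gradient (mW/cm² as a function of μm
#: along the image x axis): quartic, irradiance ranging ~208–393 mW/cm² over
#: the 1.2 mm field.
REFERENCE_COEFFS_1064: tuple[float, ...] = (
    384.3, 0.1546, -7.934e-4, 9.238e-7, -3.934e-10,
)
#: Published calibration of the 1270 nm gradient along the image y axis:
#: quadratic, ~53.5–98.2 mW/cm² over the field.
REFERENCE_COEFFS_1270: tuple[float, ...] = (95.82, 2.091e-2, -4.679e-5)

DEFAULT_CANDIDATE_DEGREES: tuple[int, ...] = (0, 1, 2, 3, 4, 5, 6)
#: μm per pixel: a cell spans ~5 px ≈ 8 μm with the 4x objective.
DEFAULT_PIXEL_SIZE_UM: float = 1.6

_RSS_FLOOR_REL = 1e-12  # relative floor so interpolating fits keep AIC finite


@dataclass(frozen=True)
class ProfileSample:
    """One beam-profiler reading: irradiance at a position along the gradient axis."""

    position: float  # μm along the gradient axis, >= 0
    irradiance: float  # mW/cm², > 0
    replicate_id: int = 0

    def __post_init__(self) -> None:
        if not (math.isfinite(self.position) and math.isfinite(self.irradiance)):
            raise ValueError("profile sample has non-finite position or irradiance")
        if self.irradiance <= 0:
            raise ValueError(
                f"irradiance must be positive, got {self.irradiance} at "
                f"position {self.position}"
            )


@dataclass
class PolynomialFit:
    """A fitted 1-D irradiance gradient E(u) = Σ c_k u^k.

    ``coefficients`` are in ascending order (c0 in mW/cm², c_k in
    mW/cm²/μm^k).  ``covariance`` is the OLS parameter covariance used for
    delta-method confidence bands; it is ``None`` for analytically specified
    reference polynomials.
    """

    wavelength: int
    coefficients: np.ndarray
    degree: int
    rss: float = 0.0
    n_points: int = 0
    covariance: np.ndarray | None = None
    aic: float = float("nan")
    aic_table: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if self.coefficients.ndim != 1 or len(self.coefficients) != self.degree + 1:
            raise ValueError("coefficient count must equal degree + 1")
        if self.rss < 0:
            raise ValueError("rss must be non-negative")
        if self.covariance is not None:
            self.covariance = np.asarray(self.covariance, dtype=float)

    def __call__(self, position):
        return evaluate_irradiance(self, position)


def reference_fit(wavelength: int) -> PolynomialFit:
    """Return the published gradient polynomial for 1064 or 1270 nm."""
    if wavelength == 1064:
        c = REFERENCE_COEFFS_1064
    elif wavelength == 1270:
        c = REFERENCE_COEFFS_1270
    else:
        raise ValueError(f"no reference calibration for wavelength {wavelength} nm")
    return PolynomialFit(wavelength=wavelength, coefficients=np.array(c), degree=len(c) - 1)


def _design_matrix(x: np.ndarray, degree: int, scale: float) -> np.ndarray:
    return np.vander(x / scale, N=degree + 1, increasing=True)


def fit_polynomial(
    samples: Sequence[ProfileSample],
    degree: int,
    *,
    wavelength: int = 0,
    use_replicate_means: bool = False,
) -> PolynomialFit:
    """Least-squares polynomial fit of irradiance against position.

    Replicate scans are pooled as independent observations by default;
    ``use_replicate_means=True`` fits the per-position means instead.  AIC is
    the least-squares form n·ln(RSS/n) + 2k with k = degree + 2 (polynomial
    coefficients plus the noise variance); RSS is floored at
    n·1e-12·mean(y²) so exactly interpolating fits remain comparable.
    """
    if degree < 0:
        raise ValueError("degree must be >= 0")
    samples = list(samples)
    if not samples:
        raise ValueError("no profile samples given")
    x = np.array([s.position for s in samples], dtype=float)
    y = np.array([s.irradiance for s in samples], dtype=float)
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values in profile samples")
    if use_replicate_means:
        df = pd.DataFrame({"x": x, "y": y}).groupby("x", sort=True)["y"].mean()
        x, y = df.index.to_numpy(), df.to_numpy()

    n_distinct = np.unique(x).size
    if n_distinct < degree + 1:
        raise ValueError(
            f"degree {degree} needs at least {degree + 1} distinct positions, "
            f"got {n_distinct}"
        )

    n = x.size
    p = degree + 1
    scale = float(np.max(np.abs(x))) or 1.0
    X = _design_matrix(x, degree, scale)
    beta_s, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta_s
    rss = float(resid @ resid)

    # back to unscaled coefficient space: c_k = beta_k / scale^k
    powers = scale ** np.arange(p)
    coeffs = beta_s / powers

    covariance = None
    if n > p:
        sigma2 = rss / (n - p)
        cov_s = sigma2 * np.linalg.inv(X.T @ X)
        covariance = cov_s / np.outer(powers, powers)

    rss_floor = n * _RSS_FLOOR_REL * float(np.mean(y**2))
    aic = n * math.log(max(rss, rss_floor) / n) + 2 * (degree + 2)

    return PolynomialFit(
        wavelength=wavelength,
        coefficients=coeffs,
        degree=degree,
        rss=rss,
        n_points=n,
        covariance=covariance,
        aic=aic,
    )


def select_degree_aic(
    samples: Sequence[ProfileSample],
    candidate_degrees: Iterable[int] = DEFAULT_CANDIDATE_DEGREES,
    *,
    wavelength: int = 0,
    use_replicate_means: bool = False,
) -> PolynomialFit:
    """Fit every candidate degree and return the minimum-AIC fit.

    Ties break toward the lowest degree (candidates are scanned in ascending
    order with a strict improvement rule), so when several degrees
    interpolate exactly the most parsimonious one wins.
    """
    degrees = sorted(set(int(d) for d in candidate_degrees))
    if not degrees:
        raise ValueError("candidate degree set is empty")
    best: PolynomialFit | None = None
    table: dict[int, float] = {}
    for d in degrees:
        fit = fit_polynomial(
            samples, d, wavelength=wavelength, use_replicate_means=use_replicate_means
        )
        table[d] = fit.aic
        if best is None or fit.aic < best.aic:
            best = fit
    assert best is not None
    best.aic_table = table
    return best


def evaluate_irradiance(fit: PolynomialFit, position) -> float | np.ndarray:
    """Evaluate the gradient polynomial at one or many positions (Horner scheme)."""
    pos = np.asarray(position, dtype=float)
    if not np.all(np.isfinite(pos)):
        raise ValueError("position must be finite")
    result = np.zeros_like(pos)
    for c in fit.coefficients[::-1]:
        result = result * pos + c
    return float(result) if np.isscalar(position) else result


def confidence_band(
    fit: PolynomialFit, positions: Sequence[float], level: float = 0.95
) -> np.ndarray:
    """Pointwise delta-method confidence band for the fitted mean curve.

    Returns an (n, 2) array of (lower, upper) bounds, fitted ± t·se with the
    Student-t quantile on n − (degree+1) residual degrees of freedom and
    se(u)² = v(u)ᵀ Cov v(u) for the monomial vector v(u) = (1, u, …, u^d).
    """
    if not 0 < level < 1:
        raise ValueError("confidence level must be in (0, 1)")
    if fit.covariance is None or fit.n_points <= fit.degree + 1:
        raise ValueError(
            "confidence band needs a fit with residual degrees of freedom "
            "(n_points > degree + 1) and a covariance matrix"
        )
    pos = np.asarray(positions, dtype=float)
    V = np.vander(pos, N=fit.degree + 1, increasing=True)
    se = np.sqrt(np.einsum("ij,jk,ik->i", V, fit.covariance, V))
    mid = np.asarray(evaluate_irradiance(fit, pos))
    tq = stats.t.ppf(0.5 + level / 2, df=fit.n_points - (fit.degree + 1))
    return np.column_stack([mid - tq * se, mid + tq * se])


@dataclass(frozen=True)
class DosePair:
    """The (1064 nm, 1270 nm) irradiance combination at one pixel."""

    dose_1064: float
    dose_1270: float
    in_field: bool = True

    @property
    def is_control(self) -> bool:
        """Outside the beam field: a no-laser control cell."""
        return not self.in_field


@dataclass
class IrradianceMap:
    """Pixel → (1064 nm, 1270 nm) dose mapping from two orthogonal 1-D fits.

    The 1064 nm gradient runs along the image x (column) axis and the
    1270 nm gradient along y (rows); pixels beyond ``field_extent`` μm are
    flagged out-of-field and treated as no-laser controls downstream.
    """

    fit_x: PolynomialFit
    fit_y: PolynomialFit
    pixel_size: float = DEFAULT_PIXEL_SIZE_UM
    field_extent: tuple[float, float] = (1200.0, 1200.0)

    def __post_init__(self) -> None:
        if self.fit_x.wavelength == self.fit_y.wavelength:
            raise ValueError("the two gradient fits must have distinct wavelengths")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if min(self.field_extent) <= 0:
            raise ValueError("field extents must be positive")

    def dose_at(self, col: float, row: float) -> DosePair:
        return map_pixel_to_dose(self, (col, row))

    def dose_images(self, shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-pixel dose arrays (dose_x, dose_y, in_field) for a frame shape (rows, cols)."""
        rows, cols = shape
        xs = np.arange(cols) * self.pixel_size
        ys = np.arange(rows) * self.pixel_size
        dx = np.broadcast_to(evaluate_irradiance(self.fit_x, xs), (rows, cols))
        dy = np.broadcast_to(evaluate_irradiance(self.fit_y, ys)[:, None], (rows, cols))
        infield = np.broadcast_to(xs <= self.field_extent[0], (rows, cols)) & (
            ys[:, None] <= self.field_extent[1]
        )
        return dx.copy(), dy.copy(), infield.copy()


def build_irradiance_map(
    fit_x: PolynomialFit,
    fit_y: PolynomialFit,
    pixel_size: float = DEFAULT_PIXEL_SIZE_UM,
    field_extent: tuple[float, float] = (1200.0, 1200.0),
) -> IrradianceMap:
    """Compose two orthogonal gradient fits into a per-pixel dual-dose map."""
    return IrradianceMap(fit_x=fit_x, fit_y=fit_y, pixel_size=pixel_size, field_extent=field_extent)


def map_pixel_to_dose(irr_map: IrradianceMap, pixel: tuple[float, float]) -> DosePair:
    """Dose pair at a (col, row) pixel; out-of-field pixels come back flagged."""
    col, row = pixel
    if col < 0 or row < 0:
        raise ValueError("pixel indices must be non-negative")
    x_um = col * irr_map.pixel_size
    y_um = row * irr_map.pixel_size
    in_field = x_um <= irr_map.field_extent[0] and y_um <= irr_map.field_extent[1]
    return DosePair(
        dose_1064=float(evaluate_irradiance(irr_map.fit_x, x_um)),
        dose_1270=float(evaluate_irradiance(irr_map.fit_y, y_um)),
        in_field=in_field,
    )


# ---------------------------------------------------------------------------
# I/O

PROFILE_COLUMNS = ("replicate", "position_um", "irradiance_mw_cm2")


def read_profile_csv(path: str | Path) -> list[ProfileSample]:
    """Read beam-profile line scans (replicate, position_um, irradiance_mw_cm2).

    Positions must be strictly increasing within each replicate scan.
    """
    df = pd.read_csv(path)
    missing = set(PROFILE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"profile CSV {path} is missing columns: {sorted(missing)}")
    samples = []
    for rep, grp in df.groupby("replicate", sort=True):
        pos = grp["position_um"].to_numpy(dtype=float)
        if not np.all(np.diff(pos) > 0):
            raise ValueError(
                f"positions must be strictly increasing within replicate {rep}"
            )
        for p, irr in zip(pos, grp["irradiance_mw_cm2"].to_numpy(dtype=float)):
            samples.append(ProfileSample(position=p, irradiance=irr, replicate_id=int(rep)))
    return samples


def write_profile_csv(samples: Sequence[ProfileSample], path: str | Path) -> None:
    pd.DataFrame(
        {
            "replicate": [s.replicate_id for s in samples],
            "position_um": [s.position for s in samples],
            "irradiance_mw_cm2": [s.irradiance for s in samples],
        }
    ).to_csv(path, index=False)


def write_fit_json(fit: PolynomialFit, path: str | Path) -> None:
    doc = {
        "wavelength_nm": fit.wavelength,
        "degree": fit.degree,
        "coefficients": [float(c) for c in fit.coefficients],
        "rss": fit.rss,
        "n_points": fit.n_points,
        "aic": fit.aic,
        "aic_table": {str(k): v for k, v in fit.aic_table.items()},
        "covariance": None if fit.covariance is None else fit.covariance.tolist(),
    }
    Path(path).write_text(json.dumps(doc, indent=2))


def read_fit_json(path: str | Path) -> PolynomialFit:
    doc = json.loads(Path(path).read_text())
    return PolynomialFit(
        wavelength=int(doc["wavelength_nm"]),
        coefficients=np.array(doc["coefficients"], dtype=float),
        degree=int(doc["degree"]),
        rss=float(doc["rss"]),
        n_points=int(doc["n_points"]),
        covariance=None if doc.get("covariance") is None else np.array(doc["covariance"]),
        aic=float(doc["aic"]),
        aic_table={int(k): float(v) for k, v in doc.get("aic_table", {}).items()},
    )
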