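"""TG-43 two-dimensional dose formalism.

The dose rate around a cylindrically symmetric brachytherapy source is

    Ḋ(r, θ) = Sk · Λ · [G_X(r, θ) / G_X(r₀, θ₀)] · g_X(r) · F(r, θ)

with Sk the air-kerma strength (U = μGy·m²·h⁻¹), Λ the dose-rate constant in
water, G the geometry function (point ``r⁻²`` or line-source β/(L·r·sinθ)),
g the radial dose function normalised at r₀ = 1 cm, and F the 2-D anisotropy
function normalised on the transverse axis θ₀ = 90°.

θ is the polar angle from the source longitudinal axis, with θ = 0° pointing
from the pellet centre toward the applicator tip.  This convention is used
consistently by the train-superposition module.

Interpolation between table nodes is linear in r for g(r) and bilinear
(linear in θ then linear in r) for F(r, θ), skipping missing cells.  F is
clamped to the nearest measured angle/radius outside the measured range;
g raises a range error outside its grid unless extrapolation is enabled.
The formalism's validity floor is r > 0.2 cm: closer to the source electronic
equilibrium does not hold and collision kerma no longer approximates dose.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .datasets import (
    R0_CM,
    THETA0_DEG,
    AnisotropyGrid,
    RadialTable,
    SourceDataset,
    TG43Error,
)

__all__ = [
    "VALIDITY_FLOOR_CM",
    "GeometryModel",
    "DosePoint",
    "DoseRateResult",
    "DomainError",
    "RangeError",
    "CapabilityError",
    "NormalizationError",
    "beta_angle",
    "geometry_factor",
    "radial_dose",
    "anisotropy",
    "dose_rate",
    "derive_g_from_transverse_profile",
    "derive_F_from_grid",
]

#: Minimum distance (cm) at which collision kerma approximates absorbed dose
#: for the 662 keV photons of Cs-137 (electronic-equilibrium floor).
VALIDITY_FLOOR_CM: float = 0.2


class DomainError(TG43Error, ValueError):
    """Input outside the mathematical domain of an operation."""


class RangeError(TG43Error, ValueError):
    """Requested point outside a table's grid with extrapolation disabled."""


class CapabilityError(TG43Error, ValueError):
    """Dataset lacks the table required by the requested operation."""


class NormalizationError(TG43Error, ValueError):
    """Profile or grid lacks the reference sample needed for normalisation."""


@dataclass(frozen=True)
class GeometryModel:
    """Source geometry model for G(r, θ): ``point`` or ``line`` with length L."""

    kind: str = "point"
    L_cm: float = 0.15

    def __post_init__(self) -> None:
        if self.kind not in ("point", "line"):
            raise ValueError(f"geometry model kind must be point|line, got {self.kind!r}")
        if self.kind == "line" and not (self.L_cm > 0):
            raise ValueError("line model requires L_cm > 0")

    @classmethod
    def for_dataset(cls, ds: SourceDataset) -> "GeometryModel":
        return cls(kind=ds.geometry_model, L_cm=ds.L_cm)


@dataclass(frozen=True)
class DosePoint:
    """Polar coordinate (r, θ) relative to a source centre, θ in degrees."""

    r_cm: float
    theta_deg: float

    def __post_init__(self) -> None:
        if not (self.r_cm > 0):
            raise ValueError(f"r_cm must be positive, got {self.r_cm}")
        if not (0.0 <= self.theta_deg <= 180.0):
            raise ValueError(f"theta_deg must lie in [0, 180], got {self.theta_deg}")


@dataclass
class DoseRateResult:
    dose_rate: float  # cGy/h
    per_unit_sk: float  # cGy/h/U
    components: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# geometry functions
# ---------------------------------------------------------------------------


def beta_angle(p: DosePoint, L_cm: float) -> float:
    """Angle β (radians) subtended by a line source of length L at point p.

    β = arctan((x + L/2)/y) − arctan((x − L/2)/y) with x = r·cosθ and
    y = r·sinθ.  Undefined on the source axis (θ = 0° or 180°), where the
    line-source geometry function has its own closed-form branch.
    """
    theta = math.radians(p.theta_deg)
    y = p.r_cm * math.sin(theta)
    if p.theta_deg in (0.0, 180.0) or y == 0.0:
        raise DomainError(
            "beta is undefined on the source axis; use the theta=0 branch of "
            "the line-source geometry function"
        )
    x = p.r_cm * math.cos(theta)
    return math.atan2(x + L_cm / 2.0, y) - math.atan2(x - L_cm / 2.0, y)


def geometry_factor(p: DosePoint, model: GeometryModel) -> float:
    """Geometry function G(r, θ) in cm⁻².

    Point model: r⁻².  Line model: β/(L·r·sinθ) off-axis and (r² − L²/4)⁻¹
    on the axis (requires r > L/2 there).
    """
    if model.kind == "point":
        return p.r_cm ** -2
    y = p.r_cm * math.sin(math.radians(p.theta_deg))
    # on (or numerically indistinguishable from) the axis the subtended-angle
    # form cancels catastrophically; use the closed-form axial limit
    if p.theta_deg in (0.0, 180.0) or y < 1e-7 * p.r_cm:
        if p.r_cm <= model.L_cm / 2.0:
            raise DomainError(
                f"line-source geometry factor singular on the axis for "
                f"r <= L/2 = {model.L_cm / 2.0} cm (got r = {p.r_cm})"
            )
        return 1.0 / (p.r_cm ** 2 - model.L_cm ** 2 / 4.0)
    beta = beta_angle(p, model.L_cm)
    return beta / (model.L_cm * y)  # L * r * sin(theta) = L * y


def _geometry_ratio(p: DosePoint, model: GeometryModel) -> float:
    """G(r, θ) / G(r₀, θ₀)."""
    ref = DosePoint(R0_CM, THETA0_DEG)
    return geometry_factor(p, model) / geometry_factor(ref, model)


# ---------------------------------------------------------------------------
# table interpolation
# ---------------------------------------------------------------------------


def _interp_skipping_nan(x: float, xs: np.ndarray, ys: np.ndarray, what: str) -> float:
    """Linear interpolation over the present (non-NaN) samples only."""
    present = ~np.isnan(ys)
    if not np.any(present):
        raise RangeError(f"{what}: no present values to interpolate")
    xs_p, ys_p = xs[present], ys[present]
    node = np.isclose(xs_p, x)
    if np.any(node):
        return float(ys_p[node][0])
    return float(np.interp(x, xs_p, ys_p))


def radial_dose(ds: SourceDataset, r_cm: float, *, extrapolate: bool = False) -> float:
    """Radial dose function g(r): exact at nodes, linear in r between them.

    Missing cells are skipped (the bare-pellet blank at r = 2.5 cm is bridged
    linearly between its neighbours).  Outside the grid a :class:`RangeError`
    is raised unless ``extrapolate`` permits linear extrapolation from the two
    outermost present nodes.
    """
    xs, ys = ds.radial.r_cm, ds.radial.g
    present = ~np.isnan(ys)
    xs_p, ys_p = xs[present], ys[present]
    lo, hi = float(xs_p[0]), float(xs_p[-1])
    if not (lo <= r_cm <= hi):
        if not extrapolate:
            raise RangeError(
                f"r = {r_cm} cm outside the radial grid [{lo}, {hi}] cm "
                "(pass extrapolate=True to permit linear extrapolation)"
            )
        if r_cm < lo:
            x0, x1, y0, y1 = xs_p[0], xs_p[1], ys_p[0], ys_p[1]
        else:
            x0, x1, y0, y1 = xs_p[-2], xs_p[-1], ys_p[-2], ys_p[-1]
        return float(y0 + (y1 - y0) * (r_cm - x0) / (x1 - x0))
    return _interp_skipping_nan(r_cm, xs, ys, f"g(r) of {ds.label!r}")


def _theta_interp(grid: AnisotropyGrid, j: int, theta: float) -> float:
    """F at radius column j, linear in θ over present cells, clamped outside."""
    col = grid.F[:, j]
    present = ~np.isnan(col)
    th, val = grid.theta_deg[present], col[present]
    if th.size == 0:
        return math.nan
    t = float(np.clip(theta, th[0], th[-1]))
    node = np.isclose(th, t)
    if np.any(node):
        return float(val[node][0])
    return float(np.interp(t, th, val))


def anisotropy(ds: SourceDataset, p: DosePoint) -> float:
    """Anisotropy function F(r, θ) by bilinear interpolation with clamping.

    Linear in θ within each radius column (skipping missing cells, clamping θ
    beyond each column's measured span), then linear in r between the two
    bracketing radii; r outside the grid clamps to the nearest radius.
    """
    if ds.anisotropy is None:
        raise CapabilityError(
            f"dataset {ds.label!r} carries no anisotropy grid"
        )
    grid = ds.anisotropy
    r = float(np.clip(p.r_cm, grid.r_cm[0], grid.r_cm[-1]))
    jr = np.searchsorted(grid.r_cm, r)
    if jr < grid.r_cm.size and np.isclose(grid.r_cm[jr], r):
        return _theta_interp(grid, int(jr), p.theta_deg)
    if jr > 0 and np.isclose(grid.r_cm[jr - 1], r):
        return _theta_interp(grid, int(jr - 1), p.theta_deg)
    j0, j1 = int(jr - 1), int(jr)
    f0 = _theta_interp(grid, j0, p.theta_deg)
    f1 = _theta_interp(grid, j1, p.theta_deg)
    r0, r1 = grid.r_cm[j0], grid.r_cm[j1]
    if math.isnan(f0):
        return f1
    if math.isnan(f1):
        return f0
    return float(f0 + (f1 - f0) * (r - r0) / (r1 - r0))


def _anisotropy_or_unity(ds: SourceDataset, p: DosePoint) -> float:
    """F(r, θ), defaulting to 1 for datasets without a grid (spherically
    symmetric bare pellet)."""
    if ds.anisotropy is None:
        return 1.0
    return anisotropy(ds, p)


# ---------------------------------------------------------------------------
# forward evaluation
# ---------------------------------------------------------------------------


def dose_rate(
    ds: SourceDataset,
    sk: float,
    p: DosePoint,
    model: GeometryModel | None = None,
    *,
    extrapolate: bool = False,
) -> DoseRateResult:
    """Absolute dose rate Ḋ(r, θ) = Sk·Λ·(G ratio)·g(r)·F(r, θ).

    ``model`` defaults to the dataset's own geometry model.  At the reference
    point (1 cm, 90°) the result is exactly Sk·Λ.  Datasets without an
    anisotropy grid are treated as isotropic (F ≡ 1).
    """
    if model is None:
        model = GeometryModel.for_dataset(ds)
    if p.r_cm <= VALIDITY_FLOOR_CM:
        raise DomainError(
            f"r = {p.r_cm} cm is inside the electronic-equilibrium validity "
            f"floor ({VALIDITY_FLOOR_CM} cm)"
        )
    try:
        g_ratio = _geometry_ratio(p, model)
    except TG43Error as exc:
        raise type(exc)(f"geometry factor failed at {p}: {exc}") from exc
    try:
        g = radial_dose(ds, p.r_cm, extrapolate=extrapolate)
    except RangeError as exc:
        raise RangeError(f"radial dose function failed at {p}: {exc}") from exc
    F = _anisotropy_or_unity(ds, p)
    per_sk = ds.Lambda * g_ratio * g * F
    return DoseRateResult(
        dose_rate=sk * per_sk,
        per_unit_sk=per_sk,
        components={"G_ratio": g_ratio, "g": g, "F": F},
    )


# ---------------------------------------------------------------------------
# inverse operations
# ---------------------------------------------------------------------------


def _rate_at_reference_radius(
    radii: np.ndarray, rates: np.ndarray
) -> float:
    node = np.isclose(radii, R0_CM)
    if np.any(node):
        return float(rates[node][0])
    if radii.min() < R0_CM < radii.max():
        order = np.argsort(radii)
        return float(np.interp(R0_CM, radii[order], rates[order]))
    raise NormalizationError(
        f"profile does not cover the reference radius r0 = {R0_CM} cm"
    )


def derive_g_from_transverse_profile(
    doses: dict[float, float] | "MappingLike",
    model: GeometryModel,
) -> RadialTable:
    """Invert the formalism on a transverse-axis profile to obtain g(r).

    ``doses`` maps r (cm) to the dose rate at (r, θ₀).  The result is
    normalised to 1 at r₀ = 1 cm; re-applying the forward formalism with the
    derived table reproduces the input profile to numerical precision.
    """
    radii = np.array(sorted(doses))
    rates = np.array([doses[r] for r in radii])
    d0 = _rate_at_reference_radius(radii, rates)
    g0 = geometry_factor(DosePoint(R0_CM, THETA0_DEG), model)
    g_vals = np.array(
        [
            rates[i]
            / d0
            * g0
            / geometry_factor(DosePoint(float(radii[i]), THETA0_DEG), model)
            for i in range(radii.size)
        ]
    )
    return RadialTable(r_cm=radii, g=g_vals)


def derive_F_from_grid(
    doses: dict[tuple[float, float], float],
    model: GeometryModel,
) -> AnisotropyGrid:
    """Invert the formalism on a polar dose grid to obtain F(r, θ).

    ``doses`` maps (r, θ) to dose rate.  Each radius must include a sample at
    θ₀ = 90° for normalisation; F(r, 90°) = 1 for every radius by
    construction.  Missing (r, θ) combinations are left NaN.
    """
    radii = sorted({r for r, _ in doses})
    thetas = sorted({t for _, t in doses})
    F = np.full((len(thetas), len(radii)), np.nan)
    for j, r in enumerate(radii):
        key90 = next(
            (k for k in doses if k[0] == r and np.isclose(k[1], THETA0_DEG)), None
        )
        if key90 is None:
            raise NormalizationError(
                f"radius r = {r} cm has no sample at theta0 = {THETA0_DEG} deg"
            )
        d90 = doses[key90]
        g90 = geometry_factor(DosePoint(r, THETA0_DEG), model)
        for i, t in enumerate(thetas):
            if (r, t) not in doses:
                continue
            gt = geometry_factor(DosePoint(r, t), model)
            F[i, j] = doses[(r, t)] / d90 * g90 / gt
    return AnisotropyGrid(
        r_cm=np.array(radii, dtype=float),
        theta_deg=np.array(thetas, dtype=float),
        F=F,
    )
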