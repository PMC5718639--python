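"""Pellet-train superposition inside the Selectron vaginal applicator.

A treatment configuration is an ordered train of 2.5 mm spherical pellets in
the 0.6 cm diameter central metallic tubing of a cylindrical applicator:
some pellets are active Cs-137 sources, the rest are inactive (dummy)
spacers.  Treatment planning systems compute total dose by summing the
single-pellet TG-43 dose of every active pellet; this module implements that
superposition in two flavours and quantifies their difference:

* ``naive``  — every active pellet uses the *bare* single-pellet dataset,
  ignoring the applicator and dummy pellets (TPS behaviour);
* ``aware``  — each active pellet uses the dataset for its position inside
  the applicator (``pos1``..``pos6``), which folds in the attenuation of the
  tubing and surrounding dummies as simulated for a single active pellet.

Lab frame: z is the axial distance from the applicator tip (tip at z = 0,
z growing deeper into the applicator), y is the transverse distance from the
axis.  Position 1 is the pellet nearest the tip, and θ = 0° points from a
pellet centre toward the tip (decreasing z).

No pairwise shadowing between simultaneously active pellets is modelled:
multi-active configurations need a full transport calculation, which is out
of scope here — the aware mode captures exactly the per-position
single-active-pellet attenuation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .datasets import DatasetLibrary, TG43Error, ValidationError
from .engine import VALIDITY_FLOOR_CM, DosePoint, dose_rate

__all__ = [
    "PelletTrain",
    "TrainDoseResult",
    "pellet_centers",
    "point_in_pellet_frame",
    "superpose",
    "attenuation_summary",
    "prescription_point",
    "load_train_config",
]

#: Default centre-to-centre spacing: touching 2.5 mm pellets.
DEFAULT_PITCH_CM = 0.25
#: Default distance from the applicator tip to the first pellet centre.
DEFAULT_TIP_OFFSET_CM = 0.4
#: Default central-tubing radius (0.6 cm diameter metallic tubing).
DEFAULT_APPLICATOR_RADIUS_CM = 0.3


@dataclass
class PelletTrain:
    """Ordered pellet train; index 0 is position 1, nearest the applicator tip."""

    n_pellets: int
    active_mask: list[bool]
    sk_per_pellet: float = 1.0  # air-kerma strength of each active pellet (U)
    pitch_cm: float = DEFAULT_PITCH_CM
    tip_offset_cm: float = DEFAULT_TIP_OFFSET_CM
    dataset_map: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_pellets < 1:
            raise ValidationError("n_pellets must be >= 1")
        if not (self.pitch_cm > 0):
            raise ValidationError(f"pitch_cm must be positive, got {self.pitch_cm}")
        if self.tip_offset_cm < 0:
            raise ValidationError("tip_offset_cm must be non-negative")
        if len(self.active_mask) != self.n_pellets:
            raise ValidationError(
                f"active_mask length {len(self.active_mask)} != n_pellets "
                f"{self.n_pellets}"
            )
        if not (self.sk_per_pellet > 0):
            raise ValidationError("sk_per_pellet must be positive")

    @classmethod
    def from_pattern(cls, pattern: str, **kwargs) -> "PelletTrain":
        """Build a train from a pattern string, e.g. ``"A--A-A"`` (A = active)."""
        mask = [ch.upper() == "A" for ch in pattern]
        return cls(n_pellets=len(mask), active_mask=mask, **kwargs)

    def active_positions(self) -> list[int]:
        """1-based positions of the active pellets."""
        return [i + 1 for i, a in enumerate(self.active_mask) if a]

    def dataset_label(self, position: int) -> str:
        """Position-aware dataset label for a 1-based pellet position.

        Explicit entries in ``dataset_map`` win; otherwise positions 1–6 map
        to ``pos1``..``pos6`` and deeper positions reuse ``pos6`` (flagged in
        the superposition provenance).
        """
        if position in self.dataset_map:
            return self.dataset_map[position]
        return f"pos{min(position, 6)}"


@dataclass
class TrainDoseResult:
    """Aligned per-point dose rates from both superposition modes."""

    points: np.ndarray  # (n, 2) lab-frame (y, z) in cm
    naive: np.ndarray | None
    aware: np.ndarray | None
    flagged: np.ndarray  # points inside some pellet's validity floor
    provenance: dict = field(default_factory=dict)

    @property
    def ratio(self) -> np.ndarray:
        """aware / naive per point (NaN where naive is 0 or missing)."""
        if self.naive is None or self.aware is None:
            raise ValueError("ratio requires both naive and aware dose arrays")
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(self.naive > 0, self.aware / self.naive, np.nan)


def pellet_centers(train: PelletTrain) -> np.ndarray:
    """Axial pellet-centre coordinates (cm from the applicator tip)."""
    return train.tip_offset_cm + train.pitch_cm * np.arange(train.n_pellets)


def point_in_pellet_frame(y: float, z: float, center_z: float) -> DosePoint:
    """Express a lab point (y, z) in the polar frame of a pellet at ``center_z``.

    θ is measured from the tip-pointing direction, so points beyond the tip
    on the axis (z < center_z, y = 0) are at θ = 0°.
    """
    dz = z - center_z
    r = math.hypot(y, dz)
    if r == 0.0:
        raise TG43Error("point coincides with the pellet centre")
    # tip direction is -z in the lab frame
    theta = math.degrees(math.acos(np.clip(-dz / r, -1.0, 1.0)))
    return DosePoint(r_cm=r, theta_deg=theta)


def superpose(
    train: PelletTrain,
    library: DatasetLibrary,
    points: np.ndarray,
    mode: str = "both",
) -> TrainDoseResult:
    """Total dose rate at each lab point by per-pellet TG-43 superposition.

    ``points`` is an (n, 2) array of lab (y, z) coordinates.  ``mode`` is
    ``naive`` (bare dataset for every active pellet), ``aware``
    (per-position datasets) or ``both``.  Points inside the validity floor of
    any active pellet are flagged and reported as NaN rather than failing the
    whole evaluation.
    """
    if mode not in ("naive", "aware", "both"):
        raise ValueError(f"mode must be naive|aware|both, got {mode!r}")
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    centers = pellet_centers(train)
    flagged = np.zeros(pts.shape[0], dtype=bool)
    provenance: dict = {"modes": {}, "reused_pos6": []}

    def total_for(mode_name: str) -> np.ndarray:
        out = np.zeros(pts.shape[0])
        labels_used = {}
        for idx, active in enumerate(train.active_mask):
            if not active:
                continue
            position = idx + 1
            label = "bare" if mode_name == "naive" else train.dataset_label(position)
            if mode_name == "aware" and position > 6 and position not in train.dataset_map:
                provenance["reused_pos6"].append(position)
            labels_used[position] = label
            ds = library[label]
            for k in range(pts.shape[0]):
                y, z = pts[k]
                p = point_in_pellet_frame(y, z, centers[idx])
                if p.r_cm <= VALIDITY_FLOOR_CM:
                    flagged[k] = True
                    out[k] = np.nan
                    continue
                out[k] += dose_rate(
                    ds, train.sk_per_pellet, p, extrapolate=True
                ).dose_rate
        provenance["modes"][mode_name] = labels_used
        return out

    naive = total_for("naive") if mode in ("naive", "both") else None
    aware = total_for("aware") if mode in ("aware", "both") else None
    return TrainDoseResult(
        points=pts, naive=naive, aware=aware, flagged=flagged, provenance=provenance
    )


def attenuation_summary(
    result: TrainDoseResult, axial_tol_cm: float = 1e-6
) -> dict:
    """Overestimation of the naive (applicator-blind) superposition.

    Per point: overestimate % = (naive − aware)/aware × 100.  The summary
    reports the maximum over axial points (|y| ≤ ``axial_tol_cm``) and over
    transverse points separately, plus the full per-point table.
    """
    if result.naive is None or result.aware is None:
        raise ValueError("summary requires a result computed with mode='both'")
    y = result.points[:, 0]
    with np.errstate(divide="ignore", invalid="ignore"):
        over = np.where(
            result.aware > 0, (result.naive - result.aware) / result.aware * 100.0,
            np.nan,
        )
    if np.any(result.aware == 0):
        warnings.warn("points with zero aware dose excluded from the ratio")
    axial = np.abs(y) <= axial_tol_cm
    table = pd.DataFrame(
        {
            "y_cm": result.points[:, 0],
            "z_cm": result.points[:, 1],
            "naive": result.naive,
            "aware": result.aware,
            "overestimate_pct": over,
            "axial": axial,
        }
    )

    def _nanmax(sel: np.ndarray) -> float:
        vals = over[sel]
        vals = vals[~np.isnan(vals)]
        return float(vals.max()) if vals.size else math.nan

    return {
        "max_axial_overestimate_pct": _nanmax(axial),
        "max_transverse_overestimate_pct": _nanmax(~axial),
        "table": table,
    }


def prescription_point(
    train: PelletTrain, applicator_radius_cm: float = DEFAULT_APPLICATOR_RADIUS_CM
) -> tuple[float, float]:
    """Dose-prescription point: 5 mm from the applicator surface at the
    mid-portion of the active length.

    Returns lab (y, z) with y = applicator radius + 0.5 cm and z at the
    midpoint of the active pellet centres.
    """
    actives = [i for i, a in enumerate(train.active_mask) if a]
    if not actives:
        raise ValidationError("train has no active pellets")
    centers = pellet_centers(train)[actives]
    return (applicator_radius_cm + 0.5, float((centers[0] + centers[-1]) / 2.0))


def load_train_config(path: str | Path) -> PelletTrain:
    """Read a train configuration from a YAML file.

    Recognised keys: ``pattern`` (e.g. ``"A--A-A"``) or ``n_pellets`` +
    ``active`` (list of 1-based positions), plus ``pitch_cm``,
    ``tip_offset_cm``, ``sk_per_pellet``, ``dataset_map``.
    """
    cfg = yaml.safe_load(Path(path).read_text())
    if not isinstance(cfg, dict):
        raise ValidationError(f"{path}: train config must be a mapping")
    kwargs = {
        k: cfg[k]
        for k in ("pitch_cm", "tip_offset_cm", "sk_per_pellet")
        if k in cfg
    }
    dsmap = {int(k): str(v) for k, v in (cfg.get("dataset_map") or {}).items()}
    if "pattern" in cfg:
        return PelletTrain.from_pattern(cfg["pattern"], dataset_map=dsmap, **kwargs)
    n = int(cfg["n_pellets"])
    active = set(int(i) for i in cfg.get("active", []))
    mask = [(i + 1) in active for i in range(n)]
    return PelletTrain(n_pellets=n, active_mask=mask, dataset_map=dsmap, **kwargs)
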