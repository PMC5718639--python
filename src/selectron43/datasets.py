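"""TG-43 source parameter datasets for the LDR Selectron Cs-137 pellet source.

A *source dataset* bundles the quantities of the AAPM TG-43 formalism for one
source configuration: the dose-rate constant Λ (cGy·h⁻¹·U⁻¹), the active
length L used by the line-source geometry function, a radial dose function
table g(r) on a radial grid, and (optionally) a two-dimensional anisotropy
function F(r, θ) on a sparse (r, θ) grid.

The package ships one dataset per configuration studied for this source:

* ``bare``      — single encapsulated pellet in water, no applicator
                  (Monte Carlo, point-source g(r) table);
* ``pos1``..``pos6`` — single active pellet in positions 1–6 inside the
                  central metallic tubing of a vaginal cylindrical applicator,
                  surrounded by inactive (dummy) pellets (Monte Carlo);
* ``measured``  — TLD measurement of the pellet in position 1 inside the
                  applicator, carrying the measured anisotropy grid.

Datasets are stored as human-readable sectioned text files (``[meta]``,
``[radial]``, ``[anisotropy]``) so fixtures stay diff-able against the
printed tables they were transcribed from.  Missing table cells are explicit
(``-``) and are never imputed by the loader; interpolation across gaps is the
dose engine's job.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

import numpy as np

__all__ = [
    "R0_CM",
    "THETA0_DEG",
    "LITERATURE_LAMBDA_PEREZ",
    "RadialTable",
    "AnisotropyGrid",
    "SourceDataset",
    "DatasetLibrary",
    "ValidationReport",
    "TG43Error",
    "SchemaError",
    "ValidationError",
    "load_dataset",
    "save_dataset",
    "packaged_dataset",
    "packaged_library",
    "available_labels",
    "validate_dataset",
]

#: TG-43 reference point: 1 cm from the source centre on the transverse axis.
R0_CM: float = 1.0
#: TG-43 reference polar angle (degrees from the source longitudinal axis).
THETA0_DEG: float = 90.0

#: Published dose-rate constant for a single bare pellet in water
#: (Pérez-Calatayud et al., Geant4), used as the literature comparator.
LITERATURE_LAMBDA_PEREZ: float = 1.107

_PACKAGED_LABELS = ("bare", "pos1", "pos2", "pos3", "pos4", "pos5", "pos6", "measured")


class TG43Error(Exception):
    """Base class for all errors raised by this package."""


class SchemaError(TG43Error, ValueError):
    """A dataset file does not parse against the expected schema."""


class ValidationError(TG43Error, ValueError):
    """A dataset violates a TG-43 normalisation or consistency invariant."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class RadialTable:
    """Radial dose function g(r) sampled on a strictly increasing radial grid.

    ``g`` may contain NaN for cells the source table leaves blank (the bare
    pellet column has no entry at r = 2.5 cm).
    """

    r_cm: np.ndarray
    g: np.ndarray

    def __post_init__(self) -> None:
        self.r_cm = np.asarray(self.r_cm, dtype=float)
        self.g = np.asarray(self.g, dtype=float)
        if self.r_cm.ndim != 1 or self.r_cm.shape != self.g.shape:
            raise SchemaError("radial table requires aligned 1-D r and g arrays")

    def value_at_node(self, r: float) -> float:
        """Exact table value at a grid node (NaN if the cell is blank)."""
        idx = np.nonzero(np.isclose(self.r_cm, r))[0]
        if idx.size == 0:
            raise KeyError(f"r = {r} cm is not a grid node")
        return float(self.g[idx[0]])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RadialTable):
            return NotImplemented
        return bool(
            np.array_equal(self.r_cm, other.r_cm)
            and np.array_equal(self.g, other.g, equal_nan=True)
        )


@dataclass
class AnisotropyGrid:
    """Anisotropy function F(r, θ) on a sparse polar grid.

    ``F`` is indexed ``[i_theta, j_r]`` matching the printed layout (θ rows,
    r columns); missing cells are NaN.
    """

    r_cm: np.ndarray
    theta_deg: np.ndarray
    F: np.ndarray

    def __post_init__(self) -> None:
        self.r_cm = np.asarray(self.r_cm, dtype=float)
        self.theta_deg = np.asarray(self.theta_deg, dtype=float)
        self.F = np.asarray(self.F, dtype=float)
        if self.F.shape != (self.theta_deg.size, self.r_cm.size):
            raise SchemaError(
                f"anisotropy matrix shape {self.F.shape} does not match "
                f"(n_theta={self.theta_deg.size}, n_r={self.r_cm.size})"
            )

    def value_at_node(self, r: float, theta: float) -> float:
        i = np.nonzero(np.isclose(self.theta_deg, theta))[0]
        j = np.nonzero(np.isclose(self.r_cm, r))[0]
        if i.size == 0 or j.size == 0:
            raise KeyError(f"(r={r}, theta={theta}) is not a grid node")
        return float(self.F[i[0], j[0]])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AnisotropyGrid):
            return NotImplemented
        return bool(
            np.array_equal(self.r_cm, other.r_cm)
            and np.array_equal(self.theta_deg, other.theta_deg)
            and np.array_equal(self.F, other.F, equal_nan=True)
        )


@dataclass
class SourceDataset:
    """One source configuration's TG-43 parameter set."""

    label: str
    Lambda: float  # dose-rate constant, cGy·h⁻¹·U⁻¹
    L_cm: float  # active length for the line-source geometry model
    radial: RadialTable
    anisotropy: AnisotropyGrid | None = None
    geometry_model: str = "point"  # "point" | "line"
    medium: str = "water"  # "water" | "plexiglas"
    provenance: str = ""

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SourceDataset):
            return NotImplemented
        return (
            self.label == other.label
            and self.Lambda == other.Lambda
            and self.L_cm == other.L_cm
            and self.geometry_model == other.geometry_model
            and self.medium == other.medium
            and self.provenance == other.provenance
            and self.radial == other.radial
            and self.anisotropy == other.anisotropy
        )


@dataclass
class DatasetLibrary:
    """Label → dataset mapping with per-entry provenance notes."""

    datasets: dict[str, SourceDataset] = field(default_factory=dict)

    def __getitem__(self, label: str) -> SourceDataset:
        try:
            return self.datasets[label]
        except KeyError:
            raise KeyError(
                f"unknown dataset label {label!r}; available: "
                f"{sorted(self.datasets)}"
            ) from None

    def __contains__(self, label: str) -> bool:
        return label in self.datasets

    def labels(self) -> list[str]:
        return sorted(self.datasets)

    def add(self, ds: SourceDataset) -> None:
        if ds.label in self.datasets:
            raise ValidationError(f"duplicate dataset label {ds.label!r}")
        self.datasets[ds.label] = ds


@dataclass
class ValidationReport:
    """List of invariant violations; empty iff the dataset is valid."""

    issues: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.issues

    def __bool__(self) -> bool:  # truthy when valid, like a passing check
        return self.ok

    def __iter__(self) -> Iterable[str]:
        return iter(self.issues)


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------


def validate_dataset(ds: SourceDataset) -> ValidationReport:
    """Check every TG-43 normalisation and consistency invariant.

    Returns a report listing each violation (never raises): positivity of Λ
    and table values, strictly increasing grids, g(r₀) = 1 and F(r, θ₀) = 1
    exactly, and angles within (0°, 180°].
    """
    issues: list[str] = []
    if not (ds.Lambda > 0):
        issues.append(f"Lambda must be positive, got {ds.Lambda}")
    if ds.geometry_model not in ("point", "line"):
        issues.append(f"geometry_model must be point|line, got {ds.geometry_model!r}")
    if ds.geometry_model == "line" and not (ds.L_cm > 0):
        issues.append(f"L_cm must be positive for the line model, got {ds.L_cm}")

    r = ds.radial.r_cm
    g = ds.radial.g
    if r.size == 0:
        issues.append("radial table is empty")
    else:
        if np.any(r <= 0):
            issues.append("radial grid contains non-positive radii")
        if np.any(np.diff(r) <= 0):
            issues.append("radial grid is not strictly increasing")
        present = ~np.isnan(g)
        if np.any(g[present] <= 0):
            issues.append("radial dose function contains non-positive values")
        at_r0 = np.isclose(r, R0_CM)
        if not np.any(at_r0):
            issues.append(f"radial grid has no node at the reference radius {R0_CM} cm")
        elif not np.all(g[at_r0] == 1.0):
            issues.append(
                f"g({R0_CM} cm) must equal 1 exactly, got {g[at_r0][0]!r}"
            )

    grid = ds.anisotropy
    if grid is not None:
        if np.any(np.diff(grid.r_cm) <= 0):
            issues.append("anisotropy radial grid is not strictly increasing")
        if np.any(np.diff(grid.theta_deg) <= 0):
            issues.append("anisotropy angular grid is not strictly increasing")
        if np.any(grid.theta_deg <= 0) or np.any(grid.theta_deg > 180):
            issues.append("anisotropy angles must lie in (0°, 180°]")
        present = ~np.isnan(grid.F)
        if np.any(grid.F[present] <= 0):
            issues.append("anisotropy function contains non-positive values")
        at_t0 = np.nonzero(np.isclose(grid.theta_deg, THETA0_DEG))[0]
        if at_t0.size:
            row = grid.F[at_t0[0]]
            bad = ~np.isnan(row) & (row != 1.0)
            if np.any(bad):
                issues.append(
                    "F(r, 90°) must equal 1 exactly at every present cell; "
                    f"violations at r = {grid.r_cm[bad].tolist()} cm"
                )
    return ValidationReport(issues)


# ---------------------------------------------------------------------------
# file format
# ---------------------------------------------------------------------------

_MISSING = "-"


def _fmt(x: float) -> str:
    return _MISSING if math.isnan(x) else format(x, "g")


def serialize_dataset(ds: SourceDataset) -> str:
    """Render a dataset in the sectioned text format (inverse of the parser)."""
    lines = ["[meta]"]
    lines.append(f"label = {ds.label}")
    lines.append(f"lambda = {ds.Lambda:g}")
    lines.append(f"L_cm = {ds.L_cm:g}")
    lines.append(f"geometry_model = {ds.geometry_model}")
    lines.append(f"medium = {ds.medium}")
    if ds.provenance:
        lines.append(f"provenance = {ds.provenance}")
    lines.append("")
    lines.append("[radial]")
    lines.append("# r_cm\tg")
    for r, g in zip(ds.radial.r_cm, ds.radial.g):
        lines.append(f"{r:g}\t{_fmt(g)}")
    if ds.anisotropy is not None:
        grid = ds.anisotropy
        lines.append("")
        lines.append("[anisotropy]")
        lines.append(
            "theta_deg\\r_cm\t" + "\t".join(format(r, "g") for r in grid.r_cm)
        )
        for i, th in enumerate(grid.theta_deg):
            row = "\t".join(_fmt(v) for v in grid.F[i])
            lines.append(f"{th:g}\t{row}")
    return "\n".join(lines) + "\n"


def save_dataset(ds: SourceDataset, path: str | Path) -> None:
    """Write ``ds`` to ``path`` in the sectioned text format."""
    Path(path).write_text(serialize_dataset(ds))


def _parse_float(token: str, where: str) -> float:
    if token == _MISSING:
        return math.nan
    try:
        return float(token)
    except ValueError:
        raise SchemaError(f"{where}: cannot parse {token!r} as a number") from None


def parse_dataset(text: str, source: str = "<string>") -> SourceDataset:
    """Parse the sectioned text format and validate the result."""
    sections: dict[str, list[str]] = {}
    current: list[str] | None = None
    for lineno, raw in enumerate(text.splitlines(), 1):
        line = raw.split("#", 1)[0].rstrip()
        if not line.strip():
            continue
        if line.strip().startswith("[") and line.strip().endswith("]"):
            name = line.strip()[1:-1].strip().lower()
            if name in sections:
                raise SchemaError(f"{source}:{lineno}: duplicate section [{name}]")
            current = sections.setdefault(name, [])
            continue
        if current is None:
            raise SchemaError(f"{source}:{lineno}: content before any section header")
        current.append(line.strip())

    for required in ("meta", "radial"):
        if required not in sections:
            raise SchemaError(f"{source}: missing required section [{required}]")

    meta: dict[str, str] = {}
    for line in sections["meta"]:
        if "=" not in line:
            raise SchemaError(f"{source}: [meta] line {line!r} is not 'key = value'")
        key, _, val = line.partition("=")
        meta[key.strip().lower()] = val.strip()
    for required in ("label", "lambda"):
        if required not in meta:
            raise SchemaError(f"{source}: [meta] is missing the {required!r} field")

    rows = []
    for line in sections["radial"]:
        parts = line.split()
        if len(parts) != 2:
            raise SchemaError(f"{source}: [radial] line {line!r} is not 'r g'")
        rows.append(
            (_parse_float(parts[0], "[radial] r"), _parse_float(parts[1], "[radial] g"))
        )
    if not rows:
        raise SchemaError(f"{source}: [radial] section is empty")
    radial = RadialTable(
        r_cm=np.array([r for r, _ in rows]), g=np.array([g for _, g in rows])
    )

    grid = None
    if "anisotropy" in sections:
        lines = sections["anisotropy"]
        header = lines[0].split()
        if not header[0].lower().startswith("theta"):
            raise SchemaError(
                f"{source}: [anisotropy] header must start with 'theta_deg\\r_cm'"
            )
        r_cols = np.array([_parse_float(t, "[anisotropy] r") for t in header[1:]])
        thetas, matrix = [], []
        for line in lines[1:]:
            parts = line.split()
            if len(parts) != r_cols.size + 1:
                raise SchemaError(
                    f"{source}: [anisotropy] row {line!r} has {len(parts) - 1} "
                    f"cells, expected {r_cols.size}"
                )
            thetas.append(_parse_float(parts[0], "[anisotropy] theta"))
            matrix.append([_parse_float(t, "[anisotropy] F") for t in parts[1:]])
        grid = AnisotropyGrid(
            r_cm=r_cols, theta_deg=np.array(thetas), F=np.array(matrix)
        )

    ds = SourceDataset(
        label=meta["label"],
        Lambda=_parse_float(meta["lambda"], "[meta] lambda"),
        L_cm=_parse_float(meta.get("l_cm", "0.15"), "[meta] L_cm"),
        radial=radial,
        anisotropy=grid,
        geometry_model=meta.get("geometry_model", "point"),
        medium=meta.get("medium", "water"),
        provenance=meta.get("provenance", ""),
    )
    report = validate_dataset(ds)
    if not report.ok:
        raise ValidationError(f"{source}: " + "; ".join(report.issues))
    return ds


def load_dataset(path: str | Path) -> SourceDataset:
    """Load and validate a dataset file.

    Raises :class:`SchemaError` naming the offending field on malformed input
    and :class:`ValidationError` if any TG-43 invariant fails (e.g. g(1) ≠ 1).
    Missing table cells are preserved as NaN, never imputed.
    """
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(p)
    return parse_dataset(p.read_text(), source=str(p))


# ---------------------------------------------------------------------------
# packaged fixtures
# ---------------------------------------------------------------------------


def _data_dir():
    return resources.files("selectron43") / "data"


def available_labels() -> tuple[str, ...]:
    """Labels of the packaged source configurations."""
    return _PACKAGED_LABELS


def packaged_dataset(label: str) -> SourceDataset:
    """Return a packaged fixture dataset transcribed from the printed tables.

    ``bare`` and ``pos1``–``pos6`` carry the Monte Carlo point-source g(r)
    columns; ``measured`` carries the TLD anisotropy grid for the pellet in
    position 1 inside the applicator.  Λ is 1.102 (bare), 1.095 (pos1, reused
    for pos2–pos6 with a provenance note) and 1.093 (measured) cGy·h⁻¹·U⁻¹.
    """
    if label not in _PACKAGED_LABELS:
        raise KeyError(
            f"unknown dataset label {label!r}; available: {list(_PACKAGED_LABELS)}"
        )
    text = (_data_dir() / f"{label}.tg43").read_text()
    return parse_dataset(text, source=f"packaged:{label}")


def packaged_library() -> DatasetLibrary:
    """All packaged configurations as a :class:`DatasetLibrary`."""
    lib = DatasetLibrary()
    for label in _PACKAGED_LABELS:
        lib.add(packaged_dataset(label))
    return lib


def packaged_table(name: str) -> str:
    """Raw text of a checked-in printed-table transcription (``table1``/``table2``)."""
    return (_data_dir() / f"{name}.tsv").read_text()
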