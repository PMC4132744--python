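"""Thin-shell continuum mechanics and derived per-group quantities.

For a thin spherical shell of wall thickness ``h`` and radius ``R`` the
point-load spring constant is ``k = alpha * E * h^2 / R`` with a
proportionality factor ``alpha`` close to 1.  Inverting gives the wall
material's Young's modulus from a measured capsid spring constant:

    E = k * R / (alpha * h^2)

In the package's nm/nN units the result is numerically in GPa
(1 nN/nm^2 = 1 GPa).  Which radius the shell formula should use (outer,
inner, or the midwall surface) is a genuine modeling choice for walls
that are not vanishingly thin; it is therefore an explicit, switchable
field of the geometry (default: midwall).

Capsid radii are configuration, not measurement: the bundled registry
ships documented default geometries per capsid group and every report
cites the entry used.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

__all__ = [
    "ShellGeometry",
    "MechanicalSummary",
    "youngs_modulus",
    "indentation_at_break",
    "percent_indentation",
    "default_geometry_registry",
    "load_geometry_registry",
    "save_geometry_registry",
    "round_sig",
]

_RADIUS_CONVENTIONS = ("outer", "midwall", "inner")


@dataclass(frozen=True)
class ShellGeometry:
    """Capsid shell geometry: outer radius and wall thickness in nm,
    thin-shell proportionality factor alpha (dimensionless), and the
    radius convention used when evaluating the shell formula."""

    outer_radius: float
    wall_thickness_h: float
    alpha: float = 1.0
    radius_convention: str = "midwall"

    def __post_init__(self) -> None:
        if not 0 < self.wall_thickness_h < self.outer_radius:
            raise ValueError("need 0 < wall_thickness_h < outer_radius")
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.radius_convention not in _RADIUS_CONVENTIONS:
            raise ValueError(
                f"radius_convention must be one of {_RADIUS_CONVENTIONS}"
            )

    @property
    def effective_radius(self) -> float:
        """Radius entering the shell formula, per the convention."""
        if self.radius_convention == "outer":
            return self.outer_radius
        if self.radius_convention == "inner":
            return self.outer_radius - self.wall_thickness_h
        return self.outer_radius - 0.5 * self.wall_thickness_h

    @property
    def outer_diameter(self) -> float:
        return 2.0 * self.outer_radius


@dataclass
class MechanicalSummary:
    """Derived mechanics for one particle or group mean."""

    spring_constant_k: float
    breaking_force: float
    youngs_modulus_E: float | None = None
    indentation_at_break: float | None = None
    percent_indentation: float | None = None
    geometry: ShellGeometry | None = None
    flags: list[str] = field(default_factory=list)


def youngs_modulus(k: float, geom: ShellGeometry) -> float:
    """Young's modulus in GPa from a spring constant in N/m.

    E = k * R / (alpha * h^2); with k in nN/nm (numerically N/m) and
    lengths in nm, E comes out in nN/nm^2 = GPa.
    """
    if k <= 0:
        raise ValueError("spring constant must be positive")
    return k * geom.effective_radius / (geom.alpha * geom.wall_thickness_h**2)


def indentation_at_break(f_break: float, k: float) -> float:
    """Indentation depth at failure in nm: breaking force divided by the
    spring constant (nN over nN/nm)."""
    if f_break <= 0 or k <= 0:
        raise ValueError("breaking force and spring constant must be positive")
    return f_break / k


def percent_indentation(delta: float, geom: ShellGeometry) -> float:
    """Indentation at break as a percentage of the capsid outer diameter."""
    if delta < 0:
        raise ValueError("indentation must be non-negative")
    return 100.0 * delta / geom.outer_diameter


def round_sig(x: float, sig: int = 2) -> float:
    """Round to ``sig`` significant figures (table display convention)."""
    if x == 0:
        return 0.0
    return round(x, sig - 1 - math.floor(math.log10(abs(x))))


def summarize_mechanics(
    k: float, f_break: float, geom: ShellGeometry | None
) -> MechanicalSummary:
    """Compute all derived columns for one (k, F_break) pair."""
    delta = indentation_at_break(f_break, k)
    out = MechanicalSummary(
        spring_constant_k=k,
        breaking_force=f_break,
        indentation_at_break=delta,
        geometry=geom,
    )
    if geom is not None:
        out.youngs_modulus_E = youngs_modulus(k, geom)
        out.percent_indentation = percent_indentation(delta, geom)
    else:
        out.flags.append("no_geometry")
    return out


# ---------------------------------------------------------------------------
# Geometry registry

# Default geometries per capsid group.  Only the two phage-lambda wall
# thicknesses (4 nm procapsid, 1.8 nm expanded) are direct structural
# measurements; the radii and the HSV-1 wall thickness are literature-level
# defaults and should be overridden when better values are available.
_DEFAULT_REGISTRY_SPEC: dict[str, dict] = {
    "WT_A": {"outer_radius": 62.5, "wall_thickness_h": 15.0},
    "WT_B": {"outer_radius": 62.5, "wall_thickness_h": 15.0},
    "WT_C": {"outer_radius": 62.5, "wall_thickness_h": 15.0},
    "UL25null_A": {"outer_radius": 62.5, "wall_thickness_h": 15.0},
    "UL25null_B": {"outer_radius": 62.5, "wall_thickness_h": 15.0},
    "UL17null_B": {"outer_radius": 62.5, "wall_thickness_h": 15.0},
    "lambda_procapsid": {"outer_radius": 27.5, "wall_thickness_h": 4.0},
    "lambda_expanded_nogpD": {"outer_radius": 31.5, "wall_thickness_h": 1.8},
    "lambda_expanded_gpD": {"outer_radius": 31.5, "wall_thickness_h": 1.8},
}


def default_geometry_registry(radius_convention: str = "midwall") -> dict[str, ShellGeometry]:
    """Bundled default geometry registry keyed by group label."""
    return {
        label: ShellGeometry(radius_convention=radius_convention, **spec)
        for label, spec in _DEFAULT_REGISTRY_SPEC.items()
    }


def save_geometry_registry(registry: dict[str, ShellGeometry], path: str | Path) -> None:
    payload = {label: asdict(geom) for label, geom in registry.items()}
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))


def load_geometry_registry(path: str | Path) -> dict[str, ShellGeometry]:
    payload = yaml.safe_load(Path(path).read_text())
    return {label: ShellGeometry(**spec) for label, spec in payload.items()}
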