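"""Lesion criteria: IRE field threshold, 50 degC isosurface, Arrhenius damage.

Three complementary estimates of the ablated myocardial volume:

* irreversible electroporation (IRE) - field magnitude above the
  1000 V/cm (1e5 V/m) cardiac threshold, the intended lesion mechanism;
* hyperthermia isosurface - temperature above 50 degC;
* Arrhenius damage integral Omega(t) = int A exp(-dE / (R T)) dt, a
  first-order thermal-kinetics estimator better suited to short intense
  exposures; Omega = 1 corresponds to a 63% damage probability.

Volumes are cell-indicator sums (no sub-cell interpolation by default)
restricted to a region, in mm^3; planar meshes report area times the
extrusion depth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .domain import Region, SimMesh

__all__ = [
    "DamageAccumulator",
    "AblationReport",
    "damage_probability",
    "threshold_volume",
    "containment_check",
    "IRE_THRESHOLD_V_PER_M",
    "TEMP_THRESHOLD_C",
]

IRE_THRESHOLD_V_PER_M = 1e5  # 1000 V/cm
TEMP_THRESHOLD_C = 50.0
KELVIN_OFFSET = 273.15


@dataclass
class DamageAccumulator:
    """Per-cell Arrhenius damage integral Omega.

    ``A`` is the frequency factor (1/s), ``delta_e`` the activation
    energy (J/mol), ``r_gas`` the universal gas constant.
    """

    omega: np.ndarray
    A: float = 2.94e39
    delta_e: float = 2.596e5
    r_gas: float = 8.314
    ire_threshold: float = IRE_THRESHOLD_V_PER_M
    temp_threshold: float = TEMP_THRESHOLD_C

    @classmethod
    def zeros(cls, n_cells: int, **kwargs) -> "DamageAccumulator":
        return cls(omega=np.zeros(n_cells), **kwargs)

    def rate(self, temp_c: np.ndarray) -> np.ndarray:
        """Instantaneous damage rate A exp(-dE/(R T_K)) at T in degC."""
        t_k = np.asarray(temp_c, dtype=float) + KELVIN_OFFSET
        return self.A * np.exp(-self.delta_e / (self.r_gas * t_k))

    def accumulate(self, temp_c: np.ndarray, dt: float) -> "DamageAccumulator":
        """Advance Omega by one rectangle-rule segment of duration ``dt``."""
        if dt <= 0:
            raise ValueError("dt must be positive")
        self.omega = self.omega + self.rate(temp_c) * dt
        return self

    def probability_percent(self) -> np.ndarray:
        return damage_probability(self.omega)


def damage_probability(omega) -> float | np.ndarray:
    """Damage probability P = (1 - e^-Omega) * 100 percent."""
    om = np.asarray(omega, dtype=float)
    if np.any(om < 0):
        raise ValueError("omega must be nonnegative")
    out = (1.0 - np.exp(-om)) * 100.0
    return out if out.ndim else float(out)


def threshold_volume(
    mesh: SimMesh,
    field_values: np.ndarray,
    threshold: float,
    restrict_to: Region | None = Region.MYOCARDIUM,
) -> float:
    """Volume (mm^3) of cells whose field value is >= threshold.

    Restricted to ``restrict_to`` (pass ``None`` for the whole domain);
    planar meshes convert area to volume with the extrusion depth.
    """
    field_values = np.asarray(field_values, dtype=float)
    if field_values.shape != (mesh.n_cells,):
        raise ValueError("field must be per-cell")
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    mask = field_values >= threshold
    if restrict_to is not None:
        mask &= mesh.region == int(restrict_to)
    return float(np.sum(mesh.cell_volumes()[mask])) * 1e9


def containment_check(
    mesh: SimMesh,
    inner_mask: np.ndarray,
    outer_mask: np.ndarray,
    restrict_to: Region | None = Region.MYOCARDIUM,
) -> tuple[bool, float]:
    """Is the inner (hyperthermia) cell set wrapped by the outer (IRE) set?

    Returns ``(contained, violating_volume_mm3)`` where the violating
    volume is that of inner cells not in the outer set.
    """
    inner = np.asarray(inner_mask, dtype=bool)
    outer = np.asarray(outer_mask, dtype=bool)
    if inner.shape != (mesh.n_cells,) or outer.shape != (mesh.n_cells,):
        raise ValueError("masks must be per-cell")
    violating = inner & ~outer
    if restrict_to is not None:
        violating &= mesh.region == int(restrict_to)
    vol = float(np.sum(mesh.cell_volumes()[violating])) * 1e9
    return (not violating.any(), vol)


@dataclass
class AblationReport:
    """Lesion volumes of one run, evaluated at the end of the last pulse."""

    ire_volume_mm3: float
    temp_volume_mm3: float
    arrhenius_volume_mm3: float
    evaluation_time_s: float
    method: str  # 'cht' or 'cfd'
    protocol: dict = field(default_factory=dict)
    hyperthermia_contained: bool = True
    containment_violation_mm3: float = 0.0

    def as_dict(self) -> dict:
        return {
            "ire_volume_mm3": self.ire_volume_mm3,
            "temp_volume_mm3": self.temp_volume_mm3,
            "arrhenius_volume_mm3": self.arrhenius_volume_mm3,
            "evaluation_time_s": self.evaluation_time_s,
            "method": self.method,
            "protocol": self.protocol,
            "hyperthermia_contained": self.hyperthermia_contained,
            "containment_violation_mm3": self.containment_violation_mm3,
        }
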