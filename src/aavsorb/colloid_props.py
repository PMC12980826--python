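"""Electrokinetic conversions and solid-surface property records.

Zeta potential from electrophoretic mobility via the Smoluchowski
approximation (thin double layer, valid for ~26 nm particles in
>10 mM ionic strength), and particle net charge from mobility plus
diffusion coefficient through the Einstein relation.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .constants import (
    BOLTZMANN,
    ELEMENTARY_CHARGE,
    TEMPERATURE_25C,
    VACUUM_PERMITTIVITY,
    WATER_RELATIVE_PERMITTIVITY_25C,
    WATER_VISCOSITY_25C,
)

__all__ = [
    "MobilityMeasurement",
    "SurfaceCondition",
    "zeta_smoluchowski",
    "net_charge",
    "read_surface_table",
    "write_surface_table",
]


@dataclass(frozen=True)
class MobilityMeasurement:
    """Electrophoretic mobility measurement with solvent context.

    mobility: m² V⁻¹ s⁻¹ (sign carries the charge sign)
    diffusion: m² s⁻¹; temperature: K; viscosity: Pa·s.
    """

    mobility: float
    diffusion: float = float("nan")
    temperature: float = TEMPERATURE_25C
    viscosity: float = WATER_VISCOSITY_25C
    relative_permittivity: float = WATER_RELATIVE_PERMITTIVITY_25C


@dataclass(frozen=True)
class SurfaceCondition:
    """Contact angle and zeta potential of one surface in one buffer."""

    surface_id: str
    buffer_id: str
    contact_angle: float  # degrees
    zeta: float  # mV

    def __post_init__(self) -> None:
        if not 0.0 <= self.contact_angle <= 180.0:
            raise ValueError(f"contact angle {self.contact_angle} outside [0, 180]°")


def zeta_smoluchowski(m: MobilityMeasurement) -> float:
    """Zeta potential (mV) from mobility: ζ = μ η / (ε0 εr)."""
    if m.viscosity <= 0:
        raise ValueError("viscosity must be positive")
    if m.relative_permittivity <= 0:
        raise ValueError("relative permittivity must be positive")
    zeta_volts = m.mobility * m.viscosity / (VACUUM_PERMITTIVITY * m.relative_permittivity)
    return zeta_volts * 1e3


def net_charge(m: MobilityMeasurement) -> float:
    """Particle net charge in elementary charges: Q = μ kB T / (e D).

    Einstein-relation reconstruction of the mobility/diffusion route;
    isolated here so a Henry-corrected variant can be swapped in.
    """
    if not m.diffusion > 0:
        raise ValueError("diffusion coefficient must be positive")
    if m.temperature <= 0:
        raise ValueError("temperature must be positive")
    return m.mobility * BOLTZMANN * m.temperature / (ELEMENTARY_CHARGE * m.diffusion)


def read_surface_table(path) -> list[SurfaceCondition]:
    """Read surface conditions from delimited text
    (surface_id, buffer_id, contact_angle_deg, zeta_mV)."""
    df = pd.read_csv(path)
    required = {"surface_id", "buffer_id", "contact_angle_deg", "zeta_mV"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"surface table missing columns: {sorted(missing)}")
    return [
        SurfaceCondition(
            surface_id=str(r.surface_id),
            buffer_id=str(r.buffer_id),
            contact_angle=float(r.contact_angle_deg),
            zeta=float(r.zeta_mV),
        )
        for r in df.itertuples()
    ]


def write_surface_table(conditions: list[SurfaceCondition]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "surface_id": [c.surface_id for c in conditions],
            "buffer_id": [c.buffer_id for c in conditions],
            "contact_angle_deg": [c.contact_angle for c in conditions],
            "zeta_mV": [c.zeta for c in conditions],
        }
    )
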