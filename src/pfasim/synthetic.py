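"""Deterministic fixtures: small meshes, canned traces, frozen fields.

Everything here is generated at call time from explicit parameters (and
a seed recorded in the provenance), so each pipeline stage can be
tested in isolation without running the upstream stages and without any
committed data files.  Regeneration from the same (name, seed) is
bit-identical; none of the physics uses randomness.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .domain import (
    GeometryParams,
    Region,
    SimMesh,
    WaveformProfile,
    make_domain,
    make_waveform,
    uniform_block,
)
from .materials import MaterialSet, default_materials
from .protocol import PulseProtocol, load_group

__all__ = [
    "Fixture",
    "make_reference_fixture",
    "make_temperature_trace",
    "make_field_snapshot",
    "make_strip_mesh",
    "make_channel_mesh",
]


@dataclass
class Fixture:
    """A named, reproducible bundle of test inputs."""

    name: str
    mesh: SimMesh
    protocol: PulseProtocol
    materials: MaterialSet
    waveform: WaveformProfile
    provenance: dict = field(default_factory=dict)


def make_reference_fixture(seed: int = 0) -> Fixture:
    """The coarse planar reference fixture: default geometry, first
    parameter group (1000 V, 1000 ms, 10 pulses), default materials and
    the 15.22 cm/s biphasic inflow waveform."""
    params = GeometryParams()
    mesh = make_domain(params)
    protocol = load_group(1)
    waveform = make_waveform()
    return Fixture(
        name="reference",
        mesh=mesh,
        protocol=protocol,
        materials=default_materials(),
        waveform=waveform,
        provenance={
            "seed": seed,
            "n_cells": mesh.n_cells,
            "geometry": "planar2d default",
            "group": 1,
        },
    )


def make_temperature_trace(kind: str, **params) -> tuple[np.ndarray, np.ndarray]:
    """Canned temperature traces (times, temps) for damage-module tests.

    kinds:
      constant        - temp_c, duration_s, dt
      two_step        - temp1_c/duration1_s then temp2_c/duration2_s, dt
      pulse_train     - sawtooth rise during pulses with exponential
                        decay in the intervals, qualitatively like a
                        measured maximum-temperature curve
    """
    dt = params.get("dt", 0.1)
    if kind == "constant":
        temp = params.get("temp_c", 50.0)
        duration = params.get("duration_s", 312.0)
        n = int(round(duration / dt))
        times = np.arange(1, n + 1) * dt
        return times, np.full(n, float(temp))
    if kind == "two_step":
        t1 = params.get("temp1_c", 60.0)
        d1 = params.get("duration1_s", 10.0)
        t2 = params.get("temp2_c", 80.0)
        d2 = params.get("duration2_s", 5.0)
        n1, n2 = int(round(d1 / dt)), int(round(d2 / dt))
        times = np.arange(1, n1 + n2 + 1) * dt
        return times, np.concatenate([np.full(n1, float(t1)), np.full(n2, float(t2))])
    if kind == "pulse_train":
        base = params.get("base_c", 37.0)
        rise = params.get("rise_c", 20.0)
        count = params.get("count", 5)
        period = params.get("period_s", 1.0)
        decay = params.get("decay_s", 0.4)
        n_per = int(round(period / dt))
        times = np.arange(1, count * n_per + 1) * dt
        temps = np.empty(count * n_per)
        level = base
        for p in range(count):
            level += rise
            seg = level + (np.exp(-(np.arange(n_per) * dt) / decay) - 1.0) * rise * 0.8
            lo = base
            temps[p * n_per:(p + 1) * n_per] = np.maximum(seg, lo)
            level = temps[(p + 1) * n_per - 1]
        return times, temps
    raise ValueError(f"unknown trace kind {kind!r}")


def make_field_snapshot(mesh: SimMesh, kind: str, **params) -> np.ndarray:
    """Per-cell field snapshots with analytically known exceedance.

    kinds: ``uniform`` (value), ``linear_ramp`` (lo..hi along x),
    ``dipole_like`` (two poles of opposite sign scaled by 1/r^2).
    """
    centers = mesh.cell_centers
    if kind == "uniform":
        return np.full(mesh.n_cells, float(params.get("value", 2e5)))
    if kind == "linear_ramp":
        lo = params.get("lo", 0.0)
        hi = params.get("hi", 2e5)
        x = centers[:, 0]
        x0, x1 = mesh.x_edges[0], mesh.x_edges[-1]
        return lo + (hi - lo) * (x - x0) / (x1 - x0)
    if kind == "dipole_like":
        strength = params.get("strength", 1e5)
        sep = params.get("separation", (mesh.x_edges[-1] - mesh.x_edges[0]) / 4)
        cx = 0.5 * (mesh.x_edges[0] + mesh.x_edges[-1])
        cy = 0.5 * (mesh.y_edges[0] + mesh.y_edges[-1])
        r2a = np.sum((centers[:, :2] - [cx - sep / 2, cy]) ** 2, axis=1)
        r2b = np.sum((centers[:, :2] - [cx + sep / 2, cy]) ** 2, axis=1)
        eps = (sep / 10) ** 2
        return strength * eps * (1.0 / (r2a + eps) + 1.0 / (r2b + eps)) / 2.0
    raise ValueError(f"unknown field kind {kind!r}")


def make_strip_mesh(nx: int = 20, ny: int = 4, length: float = 10e-3,
                    height: float = 2e-3) -> SimMesh:
    """Homogeneous conductor strip with full-height electrodes on the two
    opposite ends (first and last cell columns); the 1-D Laplace / resistor
    fixture for the electrical solver."""
    grid = np.full((ny, nx), int(Region.MYOCARDIUM), dtype=np.int32)
    grid[:, 0] = int(Region.ELECTRODE_LEFT)
    grid[:, -1] = int(Region.ELECTRODE_RIGHT)
    return uniform_block(nx, ny, length, height, grid)


def make_channel_mesh(nx: int = 30, ny: int = 16, length: float = 30e-3,
                      height: float = 6e-3) -> SimMesh:
    """Plain rectangular blood channel (no catheter): walls top and
    bottom, inlet left, outlet right; the plane-Poiseuille fixture."""
    return uniform_block(nx, ny, length, height, Region.BLOOD)
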