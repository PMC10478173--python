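"""Hooke's-law specific-force estimation from PIV velocity summaries.

The chain converts the velocity at peak contraction into displacement,
strain, stress and force, per axis:

    d = v * t            (|v| = |d| / t)
    eps = d / L          (L: gauge length)
    sigma = eps * E      (E: elastic modulus, kPa; sigma in kPa)
    F_x = sigma_x * A_yz,  F_y = sigma_y * A_xz   (A: cross-sections)

Specific force in kN m^-2 is numerically identical to the stress in kPa.
Forces are reported in nN (1 kPa*um^2 = 1e3 Pa * 1e-12 m^2 = 1 nN).

The gauge length L and the cross-sectional areas are assay conventions, not
measured quantities: by default L is the physical length of the finest
interrogation window and the cross-sections are field-of-view extent times a
nominal sheet thickness.  Absolute forces are therefore estimates; relative
comparisons between conditions are the supported use.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .piv import ContractionTrace

__all__ = [
    "ForceParameters",
    "ForceEstimate",
    "velocity_to_displacement",
    "displacement_to_strain",
    "strain_to_stress",
    "stress_to_force",
    "peak_specific_force",
]

ELASTIC_MODULUS_KPA = 30.5  # cultured skeletal muscle, literature average
KPA_UM2_TO_NN = 1.0         # 1 kPa * 1 um^2 = 1 nN exactly


@dataclass(frozen=True)
class ForceParameters:
    """Constants of the velocity -> force chain.

    gauge_length_um defaults (via :meth:`for_movie`) to the finest
    interrogation-window physical length; the cross-sections to
    field-of-view extent x sheet thickness.
    """

    elastic_modulus_kpa: float = ELASTIC_MODULUS_KPA
    dt_s: float = 0.05
    gauge_length_um: float = 16.0
    area_yz_um2: float = 1.0
    area_xz_um2: float = 1.0
    pixel_size_um: float = 1.0

    def __post_init__(self) -> None:
        for name in ("elastic_modulus_kpa", "dt_s", "gauge_length_um",
                     "area_yz_um2", "area_xz_um2"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    @classmethod
    def for_movie(
        cls,
        height_px: int,
        width_px: int,
        pixel_size_um: float,
        frame_rate_hz: float,
        finest_window_px: int = 16,
        sheet_thickness_um: float = 30.0,
        elastic_modulus_kpa: float = ELASTIC_MODULUS_KPA,
    ) -> "ForceParameters":
        """Default parameterisation for a movie's geometry."""
        return cls(
            elastic_modulus_kpa=elastic_modulus_kpa,
            dt_s=1.0 / frame_rate_hz,
            gauge_length_um=finest_window_px * pixel_size_um,
            area_yz_um2=height_px * pixel_size_um * sheet_thickness_um,
            area_xz_um2=width_px * pixel_size_um * sheet_thickness_um,
            pixel_size_um=pixel_size_um,
        )


@dataclass(frozen=True)
class ForceEstimate:
    """Displacement, strain, stress (= specific force) and force at one time.

    Component values are per axis; ``*_combined`` are vector magnitudes over
    x + y.  ``specific_force_kn_m2`` equals ``sigma_combined_kpa`` exactly.
    """

    time_s: float
    v_x_um_s: float
    v_y_um_s: float
    d_x_um: float
    d_y_um: float
    eps_x: float
    eps_y: float
    sigma_x_kpa: float
    sigma_y_kpa: float
    f_x_nn: float
    f_y_nn: float
    params: ForceParameters

    @property
    def d_combined_um(self) -> float:
        return float(np.hypot(self.d_x_um, self.d_y_um))

    @property
    def sigma_combined_kpa(self) -> float:
        return float(np.hypot(self.sigma_x_kpa, self.sigma_y_kpa))

    @property
    def specific_force_kn_m2(self) -> float:
        return self.sigma_combined_kpa

    @property
    def f_combined_nn(self) -> float:
        return float(np.hypot(self.f_x_nn, self.f_y_nn))


def velocity_to_displacement(v_x, v_y, t: float):
    """d = v * t componentwise, so |v| = |d| / t."""
    if t <= 0:
        raise ValueError("t must be > 0")
    return np.asarray(v_x) * t, np.asarray(v_y) * t


def displacement_to_strain(d, gauge_length_um: float):
    """eps = d / L (dimensionless)."""
    if gauge_length_um <= 0:
        raise ValueError("gauge length must be > 0")
    return np.asarray(d) / gauge_length_um


def strain_to_stress(eps, elastic_modulus_kpa: float = ELASTIC_MODULUS_KPA):
    """sigma = eps * E, in kPa (numerically the specific force in kN m^-2)."""
    if elastic_modulus_kpa <= 0:
        raise ValueError("elastic modulus must be > 0")
    return np.asarray(eps) * elastic_modulus_kpa


def stress_to_force(sigma_x, sigma_y, area_yz_um2: float, area_xz_um2: float):
    """F_x = sigma_x * A_yz, F_y = sigma_y * A_xz, in nN."""
    if area_yz_um2 <= 0 or area_xz_um2 <= 0:
        raise ValueError("areas must be > 0")
    fx = np.asarray(sigma_x) * area_yz_um2 * KPA_UM2_TO_NN
    fy = np.asarray(sigma_y) * area_xz_um2 * KPA_UM2_TO_NN
    return fx, fy


def peak_specific_force(
    trace: ContractionTrace, params: ForceParameters
) -> ForceEstimate:
    """Apply the full chain at the frame pair of peak mean speed.

    The velocities fed to the chain are the means of |v_x| and |v_y| over the
    valid vectors at the peak pair (signed means would cancel on a recoiling
    sheet whose halves move in opposite directions).
    """
    if len(trace) == 0:
        raise ValueError("empty trace")
    i = trace.peak_index
    vx = float(trace.mean_abs_vx_um_s[i])
    vy = float(trace.mean_abs_vy_um_s[i])
    dx, dy = velocity_to_displacement(vx, vy, params.dt_s)
    ex = displacement_to_strain(dx, params.gauge_length_um)
    ey = displacement_to_strain(dy, params.gauge_length_um)
    sx = strain_to_stress(ex, params.elastic_modulus_kpa)
    sy = strain_to_stress(ey, params.elastic_modulus_kpa)
    fx, fy = stress_to_force(sx, sy, params.area_yz_um2, params.area_xz_um2)
    return ForceEstimate(
        time_s=float(trace.times_s[i]),
        v_x_um_s=vx, v_y_um_s=vy,
        d_x_um=float(dx), d_y_um=float(dy),
        eps_x=float(ex), eps_y=float(ey),
        sigma_x_kpa=float(sx), sigma_y_kpa=float(sy),
        f_x_nn=float(fx), f_y_nn=float(fy),
        params=params,
    )
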