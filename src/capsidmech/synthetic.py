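"""Synthetic AFM force-curve and thermal-trace generator.

Emulates the measurements the analysis pipeline expects from a real
instrument, with known ground truth stored in curve metadata:

* glass (hard-substrate) indentation curves whose post-contact slope in
  calibrated units equals the cantilever stiffness;
* particle indentation curves with series-spring compliance (cantilever
  and capsid deform in series), a linear elastic regime, an abrupt force
  drop at a programmed breaking force, then reloading at a residual
  stiffness;
* ensembles of particles whose spring constants and breaking forces are
  drawn from truncated normal distributions, mirroring the 15–20 particle
  groups measured per capsid type;
* thermal cantilever deflection traces — a first-order autocorrelated
  Gaussian process whose stationary variance obeys equipartition
  (var = k_B T / k_c).

All forces are additive-white-Gaussian noisy; an optional linear baseline
tilt models imperfect background subtraction.  Only the approach segment
is generated: the analysis operates on loading curves.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from scipy.signal import lfilter

from .calibration import ThermalTrace
from .constants import BOLTZMANN_NN_NM_PER_K, ROOM_TEMPERATURE_K
from .curves import ForceCurve
from .errors import ProtocolError

__all__ = [
    "CantileverModel",
    "ParticleModel",
    "IndentationProtocol",
    "EnsembleSpec",
    "series_stiffness",
    "simulate_glass_curve",
    "simulate_particle_curve",
    "simulate_ensemble",
    "simulate_thermal_trace",
]


@dataclass(frozen=True)
class CantileverModel:
    """AFM cantilever: stiffness in N/m, deflection sensitivity in nm per
    raw-signal unit (1.0 for pre-converted curves), bath temperature in K,
    and additive force noise standard deviation in nN."""

    stiffness_kc: float
    deflection_sensitivity: float = 1.0
    temperature: float = ROOM_TEMPERATURE_K
    force_noise_sd: float = 0.05

    def __post_init__(self) -> None:
        if self.stiffness_kc <= 0:
            raise ValueError("stiffness_kc must be positive")
        if self.deflection_sensitivity <= 0:
            raise ValueError("deflection_sensitivity must be positive")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.force_noise_sd < 0:
            raise ValueError("force_noise_sd must be non-negative")


@dataclass(frozen=True)
class ParticleModel:
    """Ground-truth mechanics of one capsid.

    spring_constant_ks : N/m, slope of force vs tip–sample indentation.
    breaking_force : nN, peak force sustained before shell failure.
    break_drop_fraction : fraction of the peak force lost instantaneously
        at failure (must exceed 0 so a break produces a drop).
    post_break_residual_stiffness_fraction : fraction of ks governing
        reloading after failure; < 1 so the break is visible.
    contact_offset_z : nm of piezo travel before tip–particle contact.
    """

    spring_constant_ks: float
    breaking_force: float
    break_drop_fraction: float = 0.6
    post_break_residual_stiffness_fraction: float = 0.3
    contact_offset_z: float = 30.0

    def __post_init__(self) -> None:
        if self.spring_constant_ks <= 0:
            raise ValueError("spring_constant_ks must be positive")
        if self.breaking_force <= 0:
            raise ValueError("breaking_force must be positive")
        if not 0.0 < self.break_drop_fraction <= 1.0:
            raise ValueError("break_drop_fraction must be in (0, 1]")
        if not 0.0 <= self.post_break_residual_stiffness_fraction < 1.0:
            raise ValueError(
                "post_break_residual_stiffness_fraction must be in [0, 1)"
            )


@dataclass(frozen=True)
class IndentationProtocol:
    """Piezo ramp: z from z_start to z_end (nm) sampled at n_samples
    points, optional baseline tilt in nN/nm, and the RNG seed."""

    z_start: float = 0.0
    z_end: float = 200.0
    n_samples: int = 1600
    baseline_tilt: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 50:
            raise ValueError("n_samples must be >= 50")
        if not self.z_end > self.z_start:
            raise ValueError("z_end must exceed z_start")

    def z_grid(self) -> np.ndarray:
        return np.linspace(self.z_start, self.z_end, self.n_samples)


@dataclass(frozen=True)
class EnsembleSpec:
    """A group of particles with normally distributed spring constant
    (N/m) and breaking force (nN); non-positive draws are rejected and
    redrawn (truncation to the physical domain)."""

    n_particles: int
    ks_mean: float
    ks_sd: float
    fbreak_mean: float
    fbreak_sd: float
    seed: int = 0
    group_label: str = ""

    def __post_init__(self) -> None:
        if self.n_particles < 1:
            raise ValueError("n_particles must be >= 1")
        if self.ks_mean <= 0 or self.fbreak_mean <= 0:
            raise ValueError("means must be positive")
        if self.ks_sd < 0 or self.fbreak_sd < 0:
            raise ValueError("standard deviations must be non-negative")


def series_stiffness(k_a: float, k_b: float) -> float:
    """Effective stiffness of two springs in series: compliances add."""
    if k_a <= 0 or k_b <= 0:
        raise ValueError("series stiffness requires positive stiffnesses")
    return k_a * k_b / (k_a + k_b)


def _noise_and_tilt(
    force: np.ndarray,
    z: np.ndarray,
    protocol: IndentationProtocol,
    noise_sd: float,
    rng: np.random.Generator,
) -> np.ndarray:
    out = force + protocol.baseline_tilt * (z - protocol.z_start)
    if noise_sd > 0:
        out = out + rng.normal(0.0, noise_sd, size=force.size)
    return out


def simulate_glass_curve(
    cantilever: CantileverModel,
    protocol: IndentationProtocol,
    contact_offset_z: float = 30.0,
) -> ForceCurve:
    """Hard-substrate indentation curve.

    The substrate is effectively infinitely stiff, so the tip does not
    indent it and the post-contact force rises with slope ``stiffness_kc``
    versus piezo extension (in deflection-calibrated units).
    """
    z = protocol.z_grid()
    z0 = contact_offset_z
    if z0 >= protocol.z_end:
        raise ProtocolError(
            "empty contact region: contact offset beyond the z ramp"
        )
    force = np.where(z > z0, cantilever.stiffness_kc * (z - z0), 0.0)
    rng = np.random.default_rng(protocol.seed)
    force = _noise_and_tilt(force, z, protocol, cantilever.force_noise_sd, rng)
    meta = {
        "kind": "glass",
        "true_kc": cantilever.stiffness_kc,
        "true_contact_z0": z0,
        "force_noise_sd": cantilever.force_noise_sd,
        "baseline_tilt": protocol.baseline_tilt,
        "seed": protocol.seed,
    }
    return ForceCurve(z, force, meta)


def simulate_particle_curve(
    cantilever: CantileverModel,
    particle: ParticleModel,
    protocol: IndentationProtocol,
) -> ForceCurve:
    """Particle indentation curve with three regimes.

    (i) flat pre-contact baseline; (ii) elastic loading where force vs
    piezo extension has the series-spring slope k_c*k_s/(k_c+k_s) — force
    vs tip–sample indentation then has slope k_s; (iii) at the programmed
    breaking force an instantaneous drop of ``break_drop_fraction`` of the
    peak, followed by reloading at the residual series stiffness.

    The sample immediately preceding the drop records exactly the peak
    force, emulating an instrument that captures the failure point.  If
    the breaking force is unreachable within the z ramp the curve carries
    the metadata flag ``no_break_simulated``.
    """
    z = protocol.z_grid()
    z0 = particle.contact_offset_z
    if z0 >= protocol.z_end:
        raise ProtocolError(
            "empty contact region: contact offset beyond the z ramp"
        )
    k_eff = series_stiffness(cantilever.stiffness_kc, particle.spring_constant_ks)
    force = np.where(z > z0, k_eff * (z - z0), 0.0)

    z_break = z0 + particle.breaking_force / k_eff
    meta = {
        "kind": "particle",
        "true_kc": cantilever.stiffness_kc,
        "true_ks": particle.spring_constant_ks,
        "true_fbreak": particle.breaking_force,
        "true_contact_z0": z0,
        "true_slope_fz": k_eff,
        "break_drop_fraction": particle.break_drop_fraction,
        "force_noise_sd": cantilever.force_noise_sd,
        "baseline_tilt": protocol.baseline_tilt,
        "seed": protocol.seed,
    }

    i_post = int(np.searchsorted(z, z_break, side="right"))
    if i_post >= z.size:
        meta["no_break_simulated"] = True
    else:
        resid = particle.post_break_residual_stiffness_fraction
        k_resid = (
            series_stiffness(cantilever.stiffness_kc, resid * particle.spring_constant_ks)
            if resid > 0
            else 0.0
        )
        force[i_post - 1] = particle.breaking_force
        post_floor = (1.0 - particle.break_drop_fraction) * particle.breaking_force
        force[i_post:] = post_floor + k_resid * (z[i_post:] - z_break)
        meta["true_z_break"] = z_break

    rng = np.random.default_rng(protocol.seed)
    force = _noise_and_tilt(force, z, protocol, cantilever.force_noise_sd, rng)
    return ForceCurve(z, force, meta)


def simulate_ensemble(
    cantilever: CantileverModel,
    spec: EnsembleSpec,
    protocol: IndentationProtocol,
) -> list[ForceCurve]:
    """Simulate one capsid group: ``n_particles`` indentation curves with
    spring constants and breaking forces drawn from truncated normals.

    Reproducible: the spec seed drives both the parameter draws and the
    per-curve noise seeds.
    """
    rng = np.random.default_rng(spec.seed)

    def _truncated_normal(mean: float, sd: float, n: int) -> np.ndarray:
        if sd == 0:
            return np.full(n, mean)
        out = np.empty(n)
        remaining = np.arange(n)
        while remaining.size:
            draws = rng.normal(mean, sd, size=remaining.size)
            ok = draws > 0
            out[remaining[ok]] = draws[ok]
            remaining = remaining[~ok]
        return out

    ks = _truncated_normal(spec.ks_mean, spec.ks_sd, spec.n_particles)
    fb = _truncated_normal(spec.fbreak_mean, spec.fbreak_sd, spec.n_particles)
    curves: list[ForceCurve] = []
    for i in range(spec.n_particles):
        particle = ParticleModel(spring_constant_ks=ks[i], breaking_force=fb[i])
        proto_i = dataclasses.replace(
            protocol, seed=int(rng.integers(0, 2**31 - 1))
        )
        curve = simulate_particle_curve(cantilever, particle, proto_i)
        curve.metadata["group"] = spec.group_label
        curve.metadata["particle_index"] = i
        curves.append(curve)
    return curves


def simulate_thermal_trace(
    cantilever: CantileverModel,
    n_samples: int = 100_000,
    sampling_rate: float = 100_000.0,
    seed: int = 0,
    knee_hz: float = 5000.0,
) -> ThermalTrace:
    """Thermal deflection trace of a free cantilever.

    Modeled as a stationary AR(1) Gaussian process whose variance is set
    by equipartition, var = k_B T / k_c (nm^2); ``knee_hz`` sets the
    correlation time (phi = exp(-2 pi knee / sampling_rate)).  The full
    simple-harmonic-oscillator power spectrum is not reproduced — the
    variance-based calibration below uses only the stationary variance.
    """
    if n_samples < 1000:
        raise ValueError("n_samples must be >= 1000")
    if sampling_rate <= 0 or knee_hz <= 0:
        raise ValueError("sampling_rate and knee_hz must be positive")
    var = BOLTZMANN_NN_NM_PER_K * cantilever.temperature / cantilever.stiffness_kc
    phi = float(np.exp(-2.0 * np.pi * knee_hz / sampling_rate))
    rng = np.random.default_rng(seed)
    innovations = rng.normal(0.0, np.sqrt(var * (1.0 - phi**2)), size=n_samples)
    x0 = rng.normal(0.0, np.sqrt(var))
    deflection, _ = lfilter([1.0], [1.0, -phi], innovations, zi=[phi * x0])
    meta = {
        "true_kc": cantilever.stiffness_kc,
        "target_variance_nm2": var,
        "ar1_phi": phi,
        "seed": seed,
    }
    return ThermalTrace(
        deflection=deflection,
        sampling_rate=sampling_rate,
        temperature=cantilever.temperature,
        metadata=meta,
    )
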