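"""Study operating points and demo dataset generation.

Each capsid group is characterized by its published mean breaking force
and spring constant with standard errors over 15–20 particles.  The
generator turns a group's operating point into an ensemble spec: the
population sd is reconstructed from the reported standard error as
``sd = SE * sqrt(n)`` with n = 20 particles per group.

HSV-1 groups were measured with a 0.06 N/m cantilever, phage-lambda
groups with a 0.03 N/m cantilever.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import io as cio
from .calibration import glass_sensitivity, thermal_spring_constant
from .synthetic import (
    CantileverModel,
    EnsembleSpec,
    IndentationProtocol,
    simulate_ensemble,
    simulate_glass_curve,
    simulate_thermal_trace,
)

__all__ = ["OperatingPoint", "OPERATING_POINTS", "ensemble_spec_for", "make_demo_dataset"]

N_PARTICLES_DEFAULT = 20

# Force noise is cantilever deflection noise converted through k_c, so it
# scales with cantilever stiffness: 0.8333 nm of deflection noise gives
# 0.05 nN on the 0.06 N/m lever and 0.025 nN on the 0.03 N/m lever.
DEFLECTION_NOISE_NM = 0.8333333333333334


@dataclass(frozen=True)
class OperatingPoint:
    """Published group means: breaking force (nN) and spring constant
    (N/m) with their standard errors, and the cantilever used."""

    group: str
    fbreak_nN: float
    fbreak_se: float
    k_N_per_m: float
    k_se: float
    cantilever_kc: float


OPERATING_POINTS: dict[str, OperatingPoint] = {
    op.group: op
    for op in [
        OperatingPoint("WT_C", 5.7, 0.2, 0.35, 0.01, 0.06),
        OperatingPoint("WT_A", 5.3, 0.2, 0.34, 0.01, 0.06),
        OperatingPoint("WT_B", 3.9, 0.2, 0.33, 0.01, 0.06),
        OperatingPoint("UL25null_A", 3.4, 0.2, 0.27, 0.01, 0.06),
        OperatingPoint("UL25null_B", 3.0, 0.2, 0.26, 0.01, 0.06),
        OperatingPoint("UL17null_B", 3.8, 0.2, 0.34, 0.01, 0.06),
        OperatingPoint("lambda_procapsid", 0.48, 0.05, 0.11, 0.01, 0.03),
        OperatingPoint("lambda_expanded_nogpD", 0.45, 0.05, 0.06, 0.01, 0.03),
        OperatingPoint("lambda_expanded_gpD", 0.78, 0.05, 0.10, 0.01, 0.03),
    ]
}


def ensemble_spec_for(
    group: str, seed: int, n_particles: int = N_PARTICLES_DEFAULT
) -> tuple[CantileverModel, EnsembleSpec]:
    """Cantilever and ensemble spec reproducing one group's conditions."""
    op = OPERATING_POINTS[group]
    root = np.sqrt(n_particles)
    cantilever = CantileverModel(
        stiffness_kc=op.cantilever_kc,
        force_noise_sd=DEFLECTION_NOISE_NM * op.cantilever_kc,
    )
    spec = EnsembleSpec(
        n_particles=n_particles,
        ks_mean=op.k_N_per_m,
        ks_sd=op.k_se * root,
        fbreak_mean=op.fbreak_nN,
        fbreak_sd=op.fbreak_se * root,
        seed=seed,
        group_label=group,
    )
    return cantilever, spec


def make_demo_dataset(
    out_dir: str | Path,
    seed: int = 0,
    n_particles: int = N_PARTICLES_DEFAULT,
    groups: list[str] | None = None,
    protocol: IndentationProtocol | None = None,
) -> Path:
    """Write a complete synthetic dataset for the demo workflow.

    Per cantilever stiffness: a thermal trace and a glass curve plus a
    calibration record; per group: ``n_particles`` indentation curves.
    Returns the manifest path.  Deterministic for a fixed seed.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if groups is None:
        groups = list(OPERATING_POINTS)
    if protocol is None:
        protocol = IndentationProtocol()
    rng = np.random.default_rng(seed)

    kcs = sorted({OPERATING_POINTS[g].cantilever_kc for g in groups})
    calibrations: dict[float, str] = {}
    for kc in kcs:
        cantilever = CantileverModel(
            stiffness_kc=kc, force_noise_sd=DEFLECTION_NOISE_NM * kc
        )
        trace = simulate_thermal_trace(
            cantilever, seed=int(rng.integers(0, 2**31 - 1))
        )
        glass = simulate_glass_curve(
            cantilever,
            dataclasses.replace(protocol, seed=int(rng.integers(0, 2**31 - 1))),
        )
        tag = f"kc{kc:g}".replace(".", "p")
        cio.write_thermal_trace(out / f"thermal_{tag}.tsv", trace)
        cio.write_force_curve(out / f"glass_{tag}.tsv", glass)
        thermal = thermal_spring_constant(trace)
        cal = glass_sensitivity(glass, thermal=thermal)
        cio.write_calibration(out / f"calibration_{tag}.json", cal)
        calibrations[kc] = f"calibration_{tag}.json"

    entries: list[tuple[str, str]] = []
    for group in groups:
        cantilever, spec = ensemble_spec_for(
            group, seed=int(rng.integers(0, 2**31 - 1)), n_particles=n_particles
        )
        for i, curve in enumerate(simulate_ensemble(cantilever, spec, protocol)):
            curve.metadata["calibration"] = calibrations[cantilever.stiffness_kc]
            name = f"{group}_{i:03d}.tsv"
            cio.write_force_curve(out / name, curve)
            entries.append((name, group))
    manifest = out / "manifest.tsv"
    cio.write_manifest(manifest, entries)
    return manifest
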