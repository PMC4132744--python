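"""Core force-curve container.

Unit conventions used throughout the package: lengths in nm, forces in nN.
With these units a stiffness in N/m is numerically identical to a slope in
nN/nm, so cantilever and particle spring constants can be compared directly
to fitted force–distance slopes without conversion factors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

__all__ = ["ForceCurve"]

MIN_CURVE_SAMPLES = 50


@dataclass
class ForceCurve:
    """One nano-indentation experiment: force versus piezo extension.

    Parameters
    ----------
    z : ndarray
        Piezo extension in nm, strictly monotone, increasing toward the
        sample (larger z = deeper approach).
    force : ndarray
        Cantilever force in nN, same length as ``z``.
    metadata : dict
        Free-form key/value metadata: group label, probe id, calibration
        reference, and for synthetic curves the ground-truth parameters
        under ``true_*`` keys.
    """

    z: np.ndarray
    force: np.ndarray
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        if self.z.ndim != 1 or self.force.ndim != 1:
            raise ValueError("z and force must be 1-D arrays")
        if self.z.shape != self.force.shape:
            raise ValueError(
                f"z and force lengths differ: {self.z.size} vs {self.force.size}"
            )
        if self.z.size < MIN_CURVE_SAMPLES:
            raise ValueError(
                f"force curve needs >= {MIN_CURVE_SAMPLES} samples, got {self.z.size}"
            )
        dz = np.diff(self.z)
        if not (np.all(dz > 0) or np.all(dz < 0)):
            raise ValueError("z must be strictly monotone")
        if not (np.all(np.isfinite(self.z)) and np.all(np.isfinite(self.force))):
            raise ValueError("z and force must be finite")

    @property
    def n_samples(self) -> int:
        return int(self.z.size)

    @property
    def sample_spacing(self) -> float:
        """Median |dz| in nm."""
        return float(np.median(np.abs(np.diff(self.z))))

    def ascending(self) -> "ForceCurve":
        """Return a copy ordered by increasing z (approach direction)."""
        if self.z[1] > self.z[0]:
            return ForceCurve(self.z.copy(), self.force.copy(), dict(self.metadata))
        return ForceCurve(self.z[::-1].copy(), self.force[::-1].copy(), dict(self.metadata))

    def with_force(self, force: np.ndarray) -> "ForceCurve":
        """Copy of this curve with a replaced force channel (same z, metadata)."""
        return ForceCurve(self.z.copy(), np.asarray(force, dtype=float), dict(self.metadata))
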