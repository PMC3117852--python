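"""Parametric Ramachandran model.

Backbone phi/psi preferences are represented as a small set of Gaussian
basins per residue class (general / glycine / proline), loaded from a
versioned data file.  The model does three jobs: draw basin-restricted
(phi, psi) samples for loop perturbation, clamp small moves back into the
allowed basins, and provide a finite -log-probability score used as the
``rama`` term of the scorefunction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

import numpy as np

from .geometry import wrap_angle

_RAMA_FLOOR = 1e-8  # probability floor keeping the score finite everywhere


def _angdiff(a: float, b: float) -> float:
    """Periodic difference a-b in degrees, in (-180, 180]."""
    return wrap_angle(a - b)


@dataclass(frozen=True)
class Basin:
    phi: float
    psi: float
    sigma_phi: float
    sigma_psi: float
    weight: float

    def z2(self, phi: float, psi: float) -> float:
        """Squared Mahalanobis distance from the basin center."""
        return (_angdiff(phi, self.phi) / self.sigma_phi) ** 2 + (
            _angdiff(psi, self.psi) / self.sigma_psi
        ) ** 2

    def density(self, phi: float, psi: float) -> float:
        return self.weight * float(np.exp(-0.5 * self.z2(phi, psi)))


class RamachandranModel:
    """Three residue classes of Gaussian phi/psi basins."""

    def __init__(self, data: dict | None = None):
        if data is None:
            text = (
                resources.files("anchorloop") / "data" / "rama.json"
            ).read_text()
            data = json.loads(text)
        self.version = data.get("version", 0)
        self.trunc = float(data.get("trunc_sigma", 2.5))
        self.classes: dict[str, list[Basin]] = {}
        for cls, basins in data["classes"].items():
            self.classes[cls] = [
                Basin(b["phi"], b["psi"], b["sigma_phi"], b["sigma_psi"], b["weight"])
                for b in basins
            ]

    @staticmethod
    def residue_class(aa_type: str) -> str:
        if aa_type == "GLY":
            return "glycine"
        if aa_type == "PRO":
            return "proline"
        return "general"

    def basins(self, aa_type: str) -> list[Basin]:
        return self.classes[self.residue_class(aa_type)]

    # -- sampling ---------------------------------------------------------
    def sample(self, aa_type: str, rng: np.random.Generator) -> tuple[float, float]:
        """Draw (phi, psi) from the class basins, truncated so that every
        sample lies inside an allowed basin."""
        basins = self.basins(aa_type)
        weights = np.array([b.weight for b in basins])
        b = basins[rng.choice(len(basins), p=weights / weights.sum())]
        while True:
            dphi = rng.normal(0.0, b.sigma_phi)
            dpsi = rng.normal(0.0, b.sigma_psi)
            if (dphi / b.sigma_phi) ** 2 + (dpsi / b.sigma_psi) ** 2 <= self.trunc**2:
                return wrap_angle(b.phi + dphi), wrap_angle(b.psi + dpsi)

    # -- membership / clamping -------------------------------------------
    def in_basin(self, aa_type: str, phi: float, psi: float) -> bool:
        return any(b.z2(phi, psi) <= self.trunc**2 for b in self.basins(aa_type))

    def clamp(self, aa_type: str, phi: float, psi: float) -> tuple[float, float]:
        """Project (phi, psi) onto the boundary of the nearest basin if it
        fell outside all basins; otherwise return it unchanged."""
        if self.in_basin(aa_type, phi, psi):
            return phi, psi
        basins = self.basins(aa_type)
        nearest = min(basins, key=lambda b: b.z2(phi, psi))
        z = np.sqrt(nearest.z2(phi, psi))
        f = self.trunc / z
        return (
            wrap_angle(nearest.phi + _angdiff(phi, nearest.phi) * f),
            wrap_angle(nearest.psi + _angdiff(psi, nearest.psi) * f),
        )

    # -- scoring ----------------------------------------------------------
    def score(self, aa_type: str, phi: float, psi: float) -> float:
        """-log of the (floored) basin mixture density; finite everywhere."""
        p = sum(b.density(phi, psi) for b in self.basins(aa_type))
        return float(-np.log(p + _RAMA_FLOOR))


_DEFAULT: RamachandranModel | None = None


def default_model() -> RamachandranModel:
    global _DEFAULT
    if _DEFAULT is None:
        _DEFAULT = RamachandranModel()
    return _DEFAULT
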