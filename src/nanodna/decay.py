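"""Radionuclide electron-emission spectra and per-decay cascade sampling.

A decay spectrum is a line table (energy in eV, electrons per decay).  Two
sampling modes are offered:

* ``poisson_lines`` (default) -- each line independently emits a
  Poisson-distributed number of electrons with mean equal to its yield.
  Cascade correlations from atomic rearrangement are deliberately not
  modelled.
* ``fixed_cascade`` -- each line emits ``floor(yield)`` electrons plus one
  more with probability ``frac(yield)``; useful for deterministic tests.

Emission directions are isotropic.  Photon lines are outside the damage
model and should not appear in the table; spectra are user-supplied CSVs
(this package asserts no physical I-125 or Br-77 spectrum as correct).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from nanodna.geometry import DNAModel, MoietyKey, moiety_centroid


@dataclass(frozen=True)
class SpectrumLine:
    energy_ev: float
    electron_yield: float         # electrons per decay; may exceed 1

    def __post_init__(self):
        if self.energy_ev <= 0:
            raise ValueError(f"line energy must be > 0 eV, got {self.energy_ev}")
        if self.electron_yield < 0:
            raise ValueError(f"line yield must be >= 0, got {self.electron_yield}")


@dataclass
class DecaySpectrum:
    nuclide: str
    lines: list[SpectrumLine]
    sampling_mode: str = "poisson_lines"

    def __post_init__(self):
        if self.sampling_mode not in ("poisson_lines", "fixed_cascade"):
            raise ValueError(f"unknown sampling mode {self.sampling_mode!r}")
        self.lines = sorted(self.lines, key=lambda l: l.energy_ev)

    @property
    def mean_electrons_per_decay(self) -> float:
        return sum(l.electron_yield for l in self.lines)

    @property
    def max_energy_ev(self) -> float:
        return max(l.energy_ev for l in self.lines) if self.lines else 0.0


def read_spectrum(path, nuclide: str | None = None,
                  sampling_mode: str = "poisson_lines") -> DecaySpectrum:
    """Read a spectrum CSV with header ``energy_ev,yield``."""
    df = pd.read_csv(path, comment="#")
    if not {"energy_ev", "yield"} <= set(df.columns):
        raise ValueError("spectrum CSV must have columns energy_ev,yield")
    if len(df) == 0:
        raise ValueError(f"spectrum file {path} has no data rows")
    lines = []
    for i, row in df.iterrows():
        try:
            lines.append(SpectrumLine(float(row["energy_ev"]), float(row["yield"])))
        except ValueError as exc:
            raise ValueError(f"bad spectrum line at data row {i + 1}: {exc}") from None
    name = nuclide if nuclide is not None else str(path)
    return DecaySpectrum(nuclide=name, lines=lines, sampling_mode=sampling_mode)


def write_spectrum(spectrum: DecaySpectrum, path) -> None:
    df = pd.DataFrame(
        {"energy_ev": [l.energy_ev for l in spectrum.lines],
         "yield": [l.electron_yield for l in spectrum.lines]}
    )
    df.to_csv(path, index=False)


def isotropic_directions(n: int, rng: np.random.Generator) -> np.ndarray:
    """n unit vectors uniform on the sphere."""
    z = rng.uniform(-1.0, 1.0, size=n)
    phi = rng.uniform(0.0, 2.0 * math.pi, size=n)
    s = np.sqrt(1.0 - z ** 2)
    return np.column_stack([s * np.cos(phi), s * np.sin(phi), z])


def sample_decay(spectrum: DecaySpectrum, rng: np.random.Generator
                 ) -> list[tuple[float, np.ndarray]]:
    """Sample one decay: a list of (energy_ev, unit direction) electrons."""
    if not spectrum.lines:
        raise ValueError("cannot sample from an empty spectrum")
    energies: list[float] = []
    for line in spectrum.lines:
        if spectrum.sampling_mode == "poisson_lines":
            k = int(rng.poisson(line.electron_yield))
        else:
            k = int(math.floor(line.electron_yield))
            frac = line.electron_yield - k
            if frac > 0 and rng.random() < frac:
                k += 1
        energies.extend([line.energy_ev] * k)
    dirs = isotropic_directions(len(energies), rng)
    return [(e, d) for e, d in zip(energies, dirs)]


@dataclass
class SourcePlacement:
    """Where the decaying atom sits relative to the DNA model.

    ``at_bp`` anchors the source at the labeled-strand sugar-phosphate
    centroid of a base pair (covalent labeling); ``at_distance`` puts it at
    a radial stand-off from the bounding-cylinder surface at mid-height.
    """

    mode: str                                 # "at_bp" | "at_distance"
    bp_index: int = 21
    distance_nm: float = 0.0
    direction: tuple[float, float, float] = (1.0, 0.0, 0.0)

    def __post_init__(self):
        if self.mode not in ("at_bp", "at_distance"):
            raise ValueError(f"unknown placement mode {self.mode!r}")
        if self.mode == "at_distance" and self.distance_nm < 0:
            raise ValueError("distance_nm must be >= 0")


def place_source(placement: SourcePlacement, model: DNAModel) -> np.ndarray:
    """Resolve a placement to a 3-vector in nm."""
    if placement.mode == "at_bp":
        if not 1 <= placement.bp_index <= model.n_bp:
            raise ValueError(
                f"bp_index {placement.bp_index} out of range 1..{model.n_bp}")
        key = MoietyKey(placement.bp_index, "labeled", "sugar_phosphate")
        return moiety_centroid(model, key)
    cyl = model.bounding_cylinder
    d = np.asarray(placement.direction, dtype=float)
    d[2] = 0.0  # radial stand-off perpendicular to the helix axis
    n = np.linalg.norm(d)
    if n == 0:
        raise ValueError("at_distance direction must have a radial component")
    d /= n
    r = cyl.diameter / 2.0 + placement.distance_nm
    z_mid = cyl.z0 + cyl.height / 2.0
    return np.array([r * d[0], r * d[1], z_mid])
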