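"""Simplified event-by-event electron transport in liquid water.

The engine alternates exponential free flight (total inverse mean free
path), interaction-channel sampling proportional to the channel cross
sections, and energy loss:

* ``elastic`` -- direction change only, screened-Rutherford angular law;
* ``ionization`` -- binary-encounter-style energy transfer with a single
  effective binding energy ``B``: the secondary energy ``W`` is drawn from
  ``f(W) ~ 1/(W+B)^2`` on ``[0, (E-B)/2]``; ``B`` is deposited locally and
  the secondary is transported in turn (it inherits the primary's
  track_id);
* ``excitation`` -- a fixed mean excitation energy deposited locally;
* electrons below the cutoff energy deposit their remaining energy locally
  as ``subcutoff_absorption`` and stop.

Default cross-section tables are packaged CSV data with a BEB-shaped
ionization/excitation law and a screened-Rutherford elastic law; they are a
deliberately simplified, swappable stand-in for full dielectric-response
track-structure physics, adequate for studying the damage-scoring chain.
The medium is infinite homogeneous water; the DNA volumes do not perturb
transport.  An import path for externally generated event streams is
provided for interoperability with full track-structure codes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

#: molecules per nm^3 for liquid water at 1 g/cm^3
WATER_NUMBER_DENSITY_NM3 = 33.3679

EVENT_KINDS = ("ionization", "excitation", "subcutoff_absorption")

#: end of the physical stage, s
PHYSICAL_STAGE_TIME_S = 1e-15


@dataclass(frozen=True)
class DepositionEvent:
    """One energy deposition of the physical stage."""

    position: np.ndarray          # (3,) nm
    energy_ev: float
    kind: str                     # ionization | excitation | subcutoff_absorption
    track_id: int                 # primary lineage; secondaries inherit it
    time_s: float = PHYSICAL_STAGE_TIME_S

    def __post_init__(self):
        if self.energy_ev <= 0:
            raise ValueError(f"event energy must be > 0, got {self.energy_ev}")
        if self.kind not in EVENT_KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}")


@dataclass
class MediumModel:
    """Liquid-water medium with per-channel cross-section tables.

    Cross sections are nm^2 per molecule on an energy grid in eV; the grid
    must cover ``[cutoff_energy, E_max]``.
    """

    energy_grid_ev: np.ndarray
    sigma_elastic: np.ndarray
    sigma_ionization: np.ndarray
    sigma_excitation: np.ndarray
    cutoff_energy_ev: float = 10.0
    binding_energy_ev: float = 13.0       # effective ionization binding energy
    excitation_loss_ev: float = 8.0       # mean excitation energy, deposited locally
    screening_coeff: float = 16.5         # eta = screening_coeff / E[eV]
    density_g_cm3: float = 1.0
    number_density_nm3: float = WATER_NUMBER_DENSITY_NM3

    def __post_init__(self):
        for name in ("sigma_elastic", "sigma_ionization", "sigma_excitation"):
            if np.any(getattr(self, name) < 0):
                raise ValueError(f"{name} contains negative values")

    @classmethod
    def default(cls, cutoff_energy_ev: float = 10.0) -> "MediumModel":
        """Packaged simplified water tables."""
        with resources.files("nanodna.data").joinpath("xs_water.csv").open() as fh:
            df = pd.read_csv(fh, comment="#")
        return cls.from_frame(df, cutoff_energy_ev=cutoff_energy_ev)

    @classmethod
    def from_csv(cls, path, **kwargs) -> "MediumModel":
        return cls.from_frame(pd.read_csv(path, comment="#"), **kwargs)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, **kwargs) -> "MediumModel":
        return cls(
            energy_grid_ev=df["energy_ev"].to_numpy(dtype=float),
            sigma_elastic=df["sigma_elastic"].to_numpy(dtype=float),
            sigma_ionization=df["sigma_ionization"].to_numpy(dtype=float),
            sigma_excitation=df["sigma_excitation"].to_numpy(dtype=float),
            **kwargs,
        )

    @property
    def e_max_ev(self) -> float:
        return float(self.energy_grid_ev[-1])

    def cross_sections(self, energy_ev: float) -> tuple[float, float, float]:
        """(elastic, ionization, excitation) at one energy, nm^2."""
        e = self.energy_grid_ev
        i = int(np.searchsorted(e, energy_ev))
        if i <= 0:
            return (float(self.sigma_elastic[0]),
                    float(self.sigma_ionization[0]),
                    float(self.sigma_excitation[0]))
        if i >= len(e):
            return (float(self.sigma_elastic[-1]),
                    float(self.sigma_ionization[-1]),
                    float(self.sigma_excitation[-1]))
        f = (energy_ev - e[i - 1]) / (e[i] - e[i - 1])
        return (
            float(self.sigma_elastic[i - 1] + f * (self.sigma_elastic[i] - self.sigma_elastic[i - 1])),
            float(self.sigma_ionization[i - 1] + f * (self.sigma_ionization[i] - self.sigma_ionization[i - 1])),
            float(self.sigma_excitation[i - 1] + f * (self.sigma_excitation[i] - self.sigma_excitation[i - 1])),
        )

    def mean_free_path_nm(self, energy_ev: float) -> float:
        s = sum(self.cross_sections(energy_ev))
        return math.inf if s == 0.0 else 1.0 / (self.number_density_nm3 * s)

    # --- analytic moments of the sampling laws (used by consistency checks)

    def secondary_energy_max(self, energy_ev: float) -> float:
        return max(0.0, (energy_ev - self.binding_energy_ev) / 2.0)

    def mean_secondary_energy(self, energy_ev: float) -> float:
        """<W> of the 1/(W+B)^2 law on [0, W_max]."""
        b = self.binding_energy_ev
        wmax = self.secondary_energy_max(energy_ev)
        if wmax <= 0:
            return 0.0
        norm = 1.0 / b - 1.0 / (wmax + b)
        return (math.log((wmax + b) / b) - wmax / (wmax + b)) / norm

    def stopping_power_ev_nm(self, energy_ev: float) -> float:
        """Mean energy loss per unit path from the same tables, eV/nm."""
        _, sig_ion, sig_exc = self.cross_sections(energy_ev)
        loss_ion = self.binding_energy_ev + self.mean_secondary_energy(energy_ev)
        return self.number_density_nm3 * (
            sig_ion * loss_ion + sig_exc * self.excitation_loss_ev)


def _sample_secondary_energy(energy_ev, medium, rng) -> float:
    b = medium.binding_energy_ev
    wmax = medium.secondary_energy_max(energy_ev)
    if wmax <= 0:
        return 0.0
    u = rng.random()
    q = 1.0 / b - u * (1.0 / b - 1.0 / (wmax + b))
    return 1.0 / q - b


def _scatter(direction, cos_theta, phi):
    """Rotate a unit vector by polar angle (cos_theta) and azimuth phi."""
    dx, dy, dz = float(direction[0]), float(direction[1]), float(direction[2])
    # orthonormal frame around d (manual cross products: hot path)
    if abs(dz) < 0.99:
        ux, uy, uz = dy, -dx, 0.0
    else:
        ux, uy, uz = 0.0, dz, -dy
    un = math.sqrt(ux * ux + uy * uy + uz * uz)
    ux, uy, uz = ux / un, uy / un, uz / un
    vx = dy * uz - dz * uy
    vy = dz * ux - dx * uz
    vz = dx * uy - dy * ux
    sin_theta = math.sqrt(max(0.0, 1.0 - cos_theta ** 2))
    a, b = sin_theta * math.cos(phi), sin_theta * math.sin(phi)
    ox = cos_theta * dx + a * ux + b * vx
    oy = cos_theta * dy + a * uy + b * vy
    oz = cos_theta * dz + a * uz + b * vz
    n = math.sqrt(ox * ox + oy * oy + oz * oz)
    return np.array([ox / n, oy / n, oz / n])


def _elastic_cos_theta(energy_ev, medium, rng) -> float:
    """Screened-Rutherford polar angle: cos = 1 - 2*eta*mu/(1+eta-mu)."""
    eta = medium.screening_coeff / energy_ev
    mu = rng.random()
    return 1.0 - 2.0 * eta * mu / (1.0 + eta - mu)


def transport_electron(
    energy_ev: float,
    origin,
    direction,
    medium: MediumModel,
    rng: np.random.Generator,
    track_id: int = 0,
    stats: dict | None = None,
) -> list[DepositionEvent]:
    """Transport one electron and its secondaries; return all depositions.

    ``stats``, if given, is filled with ``primary_path_nm`` (path length of
    the primary electron including elastic legs) and ``n_interactions``.
    """
    if energy_ev <= 0:
        raise ValueError(f"energy must be > 0, got {energy_ev}")
    if energy_ev > medium.e_max_ev:
        raise ValueError(
            f"energy {energy_ev} eV above table range (E_max = "
            f"{medium.e_max_ev:g} eV)")

    origin = np.asarray(origin, dtype=float)
    direction = np.asarray(direction, dtype=float)
    direction = direction / np.linalg.norm(direction)

    events: list[DepositionEvent] = []
    if stats is not None:
        stats.setdefault("primary_path_nm", 0.0)
        stats.setdefault("n_interactions", 0)

    # LIFO stack of (energy, position, direction, generation)
    stack = [(energy_ev, origin.copy(), direction.copy(), 0)]
    while stack:
        e, pos, d, gen = stack.pop()
        if e < medium.cutoff_energy_ev:
            events.append(DepositionEvent(pos.copy(), e, "subcutoff_absorption",
                                          track_id))
            continue
        while True:
            sig_el, sig_ion, sig_exc = medium.cross_sections(e)
            tot = sig_el + sig_ion + sig_exc
            if tot <= 0.0:
                events.append(DepositionEvent(pos.copy(), e,
                                              "subcutoff_absorption", track_id))
                break
            step = rng.exponential(1.0 / (medium.number_density_nm3 * tot))
            pos = pos + step * d
            if stats is not None and gen == 0:
                stats["primary_path_nm"] += step
                stats["n_interactions"] += 1
            u = rng.random() * tot
            channel = 0 if u < sig_el else (1 if u < sig_el + sig_ion else 2)
            if channel == 0:  # elastic
                cos_t = _elastic_cos_theta(e, medium, rng)
                d = _scatter(d, cos_t, rng.uniform(0.0, 2.0 * math.pi))
                continue
            if channel == 1:  # ionization
                if e <= medium.binding_energy_ev:
                    # table tail below threshold: treat as local absorption
                    events.append(DepositionEvent(pos.copy(), e,
                                                  "subcutoff_absorption", track_id))
                    break
                w = _sample_secondary_energy(e, medium, rng)
                events.append(DepositionEvent(pos.copy(),
                                              medium.binding_energy_ev,
                                              "ionization", track_id))
                if w > 0:
                    if w >= medium.cutoff_energy_ev:
                        z = rng.uniform(-1.0, 1.0)
                        phi = rng.uniform(0.0, 2.0 * math.pi)
                        s = math.sqrt(1.0 - z * z)
                        sdir = np.array([s * math.cos(phi), s * math.sin(phi), z])
                        stack.append((w, pos.copy(), sdir, gen + 1))
                    else:
                        events.append(DepositionEvent(pos.copy(), w,
                                                      "subcutoff_absorption",
                                                      track_id))
                e -= medium.binding_energy_ev + w
            else:  # excitation
                loss = min(medium.excitation_loss_ev, e)
                events.append(DepositionEvent(pos.copy(), loss, "excitation",
                                              track_id))
                e -= loss
            if e < medium.cutoff_energy_ev:
                if e > 0:
                    events.append(DepositionEvent(pos.copy(), e,
                                                  "subcutoff_absorption",
                                                  track_id))
                break
    return events


# ---------------------------------------------------------------------------
# event-stream I/O (interchange with external track-structure codes)

_STREAM_COLUMNS = ["x_nm", "y_nm", "z_nm", "energy_ev", "kind", "track_id"]


def write_event_stream(events: list[DepositionEvent], path) -> None:
    """Write events as CSV (or HDF5 if the suffix is .h5/.hdf5)."""
    df = pd.DataFrame(
        {
            "x_nm": [e.position[0] for e in events],
            "y_nm": [e.position[1] for e in events],
            "z_nm": [e.position[2] for e in events],
            "energy_ev": [e.energy_ev for e in events],
            "kind": [e.kind for e in events],
            "track_id": [e.track_id for e in events],
        }
    )
    if str(path).endswith((".h5", ".hdf5")):
        import h5py

        with h5py.File(path, "w") as fh:
            for col in _STREAM_COLUMNS:
                data = df[col].to_numpy()
                if col == "kind":
                    data = data.astype("S24")
                fh.create_dataset(col, data=data)
    else:
        # %.17g round-trips float64 exactly
        df.to_csv(path, index=False, float_format="%.17g")


def read_event_stream(path) -> list[DepositionEvent]:
    """Read a deposition-event stream written by :func:`write_event_stream`."""
    if str(path).endswith((".h5", ".hdf5")):
        import h5py

        with h5py.File(path, "r") as fh:
            df = pd.DataFrame({
                col: (fh[col][:].astype(str) if col == "kind" else fh[col][:])
                for col in _STREAM_COLUMNS
            })
    else:
        df = pd.read_csv(path, comment="#", float_precision="round_trip")
    missing = set(_STREAM_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"event stream missing columns {sorted(missing)}")
    events = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        if row.kind not in EVENT_KINDS:
            raise ValueError(f"unknown event kind {row.kind!r} at data row {i}")
        if row.energy_ev <= 0:
            raise ValueError(f"non-positive energy at data row {i}")
        events.append(DepositionEvent(
            position=np.array([row.x_nm, row.y_nm, row.z_nm], dtype=float),
            energy_ev=float(row.energy_ev),
            kind=str(row.kind),
            track_id=int(row.track_id),
        ))
    return events
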