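"""Water-radiolysis species generation, Brownian diffusion, and DNA reactions.

Radical species (hydroxyl radical OH, hydrogen radical H, hydrogen peroxide
H2O2) are spawned at physical-stage deposition sites with configurable
per-event-kind branching yields, then diffused by step-by-step Brownian
dynamics on a geometric time schedule from 1 ps to 1 us (fine steps early,
coarser later).  After each step a species that lies within the reaction
radius of a matching DNA moiety reacts and is removed; per-moiety reaction
radii follow the standard hydroxyl-radical values (Adenine 0.372, Cytosine
0.366, Guanine 0.553, Thymine 0.384, Sugar 0.108 nm).

Simplifications, by design: no radical-radical recombination, no
homogeneous-chemistry network, and scavenging is an on/off switch handled
upstream (disabling the chemistry stage emulates a DMSO environment).
Branching yields are configuration placeholders, not measured G-values.
Only Sugar-channel reactions produce strand breaks downstream; base
reactions are tallied but never converted into breaks.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from nanodna.geometry import DNAModel, MoietyKey
from nanodna.transport import EVENT_KINDS, DepositionEvent

SPECIES = ("OH", "H", "H2O2")

#: diffusion coefficients, nm^2/ns (i.e. 1e-9 m^2/s)
DEFAULT_DIFFUSION_NM2_NS = {"OH": 2.8, "H": 7.0, "H2O2": 2.3}

#: reaction radii for the hydroxyl radical, nm
OH_REACTION_RADII_NM = {
    "Adenine": 0.372,
    "Cytosine": 0.366,
    "Guanine": 0.553,
    "Thymine": 0.384,
    "Sugar": 0.108,
}

REACTION_TARGETS = ("Adenine", "Cytosine", "Guanine", "Thymine", "Sugar")

#: start of the chemical stage, s
CHEMICAL_STAGE_START_S = 1e-12
CHEMICAL_STAGE_END_S = 1e-6

#: species yields per deposition-event kind (configuration placeholders)
DEFAULT_BRANCHING = {
    "ionization": {"OH": 1.0, "H": 0.1, "H2O2": 0.05},
    "excitation": {"OH": 0.3},
}


@dataclass
class SpeciesState:
    """One diffusing chemical species."""

    species: str
    position: np.ndarray          # (3,) nm
    birth_time_s: float
    diffusion_coefficient: float  # nm^2/ns
    origin_track_id: int

    def __post_init__(self):
        if self.species not in SPECIES:
            raise ValueError(f"unknown species {self.species!r}")
        if self.diffusion_coefficient <= 0:
            raise ValueError("diffusion coefficient must be > 0")


@dataclass(frozen=True)
class ReactionChannel:
    species: str
    target: str                   # Adenine | Cytosine | Guanine | Thymine | Sugar
    reaction_radius_nm: float

    def __post_init__(self):
        if self.target not in REACTION_TARGETS:
            raise ValueError(f"unknown reaction target {self.target!r}")
        if self.reaction_radius_nm <= 0:
            raise ValueError("reaction radius must be > 0")


@dataclass(frozen=True)
class ReactionEvent:
    species: str
    moiety_key: MoietyKey
    time_s: float
    origin_track_id: int


def default_channels(h_radius_scale: float = 1.0,
                     include_h: bool = True) -> list[ReactionChannel]:
    """OH channels at the standard radii; H channels reuse the OH radii
    scaled by ``h_radius_scale`` (H radii are not separately established --
    flagged at runtime).  H2O2 gets no channel and never reacts."""
    channels = [ReactionChannel("OH", t, r) for t, r in OH_REACTION_RADII_NM.items()]
    if include_h:
        warnings.warn(
            "H-radical reaction radii are not separately established; reusing "
            f"the OH radii scaled by {h_radius_scale}", stacklevel=2)
        channels += [ReactionChannel("H", t, r * h_radius_scale)
                     for t, r in OH_REACTION_RADII_NM.items()]
    return channels


def read_channels(path) -> list[ReactionChannel]:
    """Channels CSV: species,target,reaction_radius_nm."""
    df = pd.read_csv(path, comment="#")
    return [ReactionChannel(str(r.species), str(r.target),
                            float(r.reaction_radius_nm))
            for r in df.itertuples(index=False)]


def write_channels(channels: list[ReactionChannel], path) -> None:
    pd.DataFrame(
        {"species": [c.species for c in channels],
         "target": [c.target for c in channels],
         "reaction_radius_nm": [c.reaction_radius_nm for c in channels]}
    ).to_csv(path, index=False)


def generate_species(
    events: list[DepositionEvent],
    branching: dict[str, dict[str, float]] | None = None,
    rng: np.random.Generator | None = None,
    diffusion: dict[str, float] | None = None,
    thermalization_jitter_nm: float = 0.0,
) -> list[SpeciesState]:
    """Spawn radiolysis species at deposition sites.

    ``branching`` maps event kind -> {species: yield}; fractional yields
    are Bernoulli probabilities on top of the integer part.  Species are
    born at the parent event position (optionally jittered isotropically by
    a Gaussian thermalization displacement) at the chemical-stage start.
    """
    if branching is None:
        branching = DEFAULT_BRANCHING
    if rng is None:
        rng = np.random.default_rng()
    if diffusion is None:
        diffusion = DEFAULT_DIFFUSION_NM2_NS
    unknown = set(branching) - set(EVENT_KINDS)
    if unknown:
        raise ValueError(f"branching table has unknown event kind(s): {sorted(unknown)}")
    for kind, table in branching.items():
        bad = set(table) - set(SPECIES)
        if bad:
            raise ValueError(f"branching[{kind!r}] has unknown species {sorted(bad)}")

    out: list[SpeciesState] = []
    for ev in events:
        table = branching.get(ev.kind)
        if not table:
            continue
        for sp, y in table.items():
            k = int(math.floor(y))
            frac = y - k
            if frac > 0 and rng.random() < frac:
                k += 1
            for _ in range(k):
                pos = ev.position.astype(float).copy()
                if thermalization_jitter_nm > 0:
                    pos = pos + rng.normal(0.0, thermalization_jitter_nm, size=3)
                out.append(SpeciesState(
                    species=sp,
                    position=pos,
                    birth_time_s=CHEMICAL_STAGE_START_S,
                    diffusion_coefficient=diffusion[sp],
                    origin_track_id=ev.track_id,
                ))
    return out


def geometric_time_schedule(t_start: float = CHEMICAL_STAGE_START_S,
                            t_end: float = CHEMICAL_STAGE_END_S,
                            n_steps: int = 100) -> np.ndarray:
    """Log-spaced absolute times from t_start to t_end (n_steps intervals)."""
    return np.geomspace(t_start, t_end, n_steps + 1)


def _reactive_atom_trees(model: DNAModel, targets: set[str]):
    """KD-trees of atom centres per reaction target present in the model.

    Trees are cached on the model instance; targets are a small fixed set.
    """
    cache = getattr(model, "_reactive_tree_cache", None)
    if cache is None:
        cache = {}
        model._reactive_tree_cache = cache
    key = frozenset(targets)
    if key in cache:
        return cache[key]
    groups: dict[str, list[int]] = {t: [] for t in targets}
    for j, a in enumerate(model.atoms):
        if a.moiety == "sugar_phosphate":
            if "Sugar" in targets:
                groups["Sugar"].append(j)
        elif a.moiety == "base" and a.base in targets:
            groups[a.base].append(j)
    trees = {}
    for t, idxs in groups.items():
        if idxs:
            pts = np.array([model.atoms[j].position for j in idxs])
            trees[t] = (cKDTree(pts), np.array(idxs))
    cache[key] = trees
    return trees


def diffuse_and_react(
    species: list[SpeciesState],
    model: DNAModel,
    channels: list[ReactionChannel],
    rng: np.random.Generator,
    t_end: float = CHEMICAL_STAGE_END_S,
    time_schedule: np.ndarray | None = None,
    n_steps: int = 100,
    survivor_positions: list | None = None,
) -> tuple[list[ReactionEvent], int]:
    """Brownian dynamics of all species against the DNA targets.

    Per step each species takes an isotropic Gaussian displacement with
    per-axis sigma = sqrt(2 D dt); proximity to a matching moiety (checked
    at birth and after every step) within the channel's reaction radius
    records a ReactionEvent and removes the species.  Among simultaneously
    matching moieties the smallest centre distance wins.  Returns the
    reactions and the number of species surviving to t_end; if
    ``survivor_positions`` is a list, each survivor's final (species,
    position) is appended to it (diffusion diagnostics).
    """
    if model.kind != "high_res":
        raise ValueError("the chemistry stage requires the atomic (high_res) model")
    if time_schedule is None:
        time_schedule = geometric_time_schedule(t_end=t_end, n_steps=n_steps)
    time_schedule = np.asarray(time_schedule, dtype=float)
    if np.any(np.diff(time_schedule) <= 0):
        raise ValueError("time schedule must be strictly increasing (dt > 0)")

    reactions: list[ReactionEvent] = []
    surviving = 0

    by_species: dict[str, list[SpeciesState]] = {}
    for s in species:
        by_species.setdefault(s.species, []).append(s)

    chan_by_species: dict[str, list[ReactionChannel]] = {}
    for c in channels:
        chan_by_species.setdefault(c.species, []).append(c)

    for sp, members in by_species.items():
        chans = chan_by_species.get(sp, [])
        if not chans:
            surviving += len(members)   # no channel: drift to t_end, dropped
            if survivor_positions is not None:
                p = np.array([m.position for m in members], dtype=float)
                for k in range(len(time_schedule) - 1):
                    dt_ns = (time_schedule[k + 1] - time_schedule[k]) * 1e9
                    p += rng.normal(0.0, math.sqrt(2.0 * members[0].diffusion_coefficient * dt_ns),
                                    size=p.shape)
                survivor_positions.extend((sp, row.copy()) for row in p)
            continue
        trees = _reactive_atom_trees(model, {c.target for c in chans})
        radii = {c.target: c.reaction_radius_nm for c in chans}
        pos = np.array([m.position for m in members], dtype=float)
        track = np.array([m.origin_track_id for m in members])
        alive = np.ones(len(members), dtype=bool)
        d_coeff = members[0].diffusion_coefficient

        cyl = model.bounding_cylinder
        margin = max(radii.values())
        r2_cut = (cyl.diameter / 2.0 + margin) ** 2
        z_lo, z_hi = cyl.z0 - margin, cyl.z0 + cyl.height + margin

        def check(t_now):
            live = np.flatnonzero(alive)
            if live.size == 0:
                return
            # cheap cull: only walkers near the target cylinder can react
            p = pos[live]
            near = ((p[:, 0] ** 2 + p[:, 1] ** 2 <= r2_cut)
                    & (p[:, 2] >= z_lo) & (p[:, 2] <= z_hi))
            live = live[near]
            if live.size == 0:
                return
            best_d = np.full(live.size, np.inf)
            best_atom = np.full(live.size, -1)
            for target, (tree, idxs) in trees.items():
                rr = radii.get(target)
                if rr is None:
                    continue
                dist, nn = tree.query(pos[live])
                better = (dist <= rr) & (dist < best_d)
                best_d = np.where(better, dist, best_d)
                best_atom = np.where(better, idxs[nn], best_atom)
            hit = best_atom >= 0
            for li, aj in zip(live[hit], best_atom[hit]):
                reactions.append(ReactionEvent(
                    species=sp,
                    moiety_key=model.atoms[int(aj)].key,
                    time_s=float(t_now),
                    origin_track_id=int(track[li]),
                ))
                alive[li] = False

        check(time_schedule[0])
        for k in range(len(time_schedule) - 1):
            if not alive.any():
                break
            dt_ns = (time_schedule[k + 1] - time_schedule[k]) * 1e9
            sigma = math.sqrt(2.0 * d_coeff * dt_ns)
            live = np.flatnonzero(alive)
            pos[live] += rng.normal(0.0, sigma, size=(live.size, 3))
            check(time_schedule[k + 1])
        surviving += int(alive.sum())
        if survivor_positions is not None:
            survivor_positions.extend(
                (sp, pos[i].copy()) for i in np.flatnonzero(alive))

    return reactions, surviving
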