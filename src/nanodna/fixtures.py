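"""Deterministic synthetic fixtures for testing every pipeline stage.

Generators produce, from a seed: deposition-event clouds, reaction sets at
chosen moieties, and synthetic decay-spectrum line tables.  All outputs use
the package's standard file formats, so any stage can be exercised without
running the stages upstream of it.  Spectra produced here are synthetic and
deliberately non-physical; they are test inputs, not nuclear data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from nanodna.chemistry import CHEMICAL_STAGE_START_S, ReactionEvent
from nanodna.decay import DecaySpectrum, SpectrumLine, write_spectrum
from nanodna.geometry import MoietyKey
from nanodna.transport import DepositionEvent, write_event_stream


@dataclass
class SyntheticFixtureSpec:
    """Parameters of one synthetic fixture; fully deterministic given seed."""

    kind: str                       # event_cloud | reaction_set | spectrum
    params: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if self.kind not in ("event_cloud", "reaction_set", "spectrum"):
            raise ValueError(f"unknown fixture kind {self.kind!r}")


def event_cloud(
    n: int,
    center=(0.0, 0.0, 0.0),
    sigma_nm: float = 1.0,
    energy_ev: float = 12.0,
    kind: str = "ionization",
    n_tracks: int = 1,
    seed: int = 0,
    uniform_halfwidth_nm: float | None = None,
) -> list[DepositionEvent]:
    """Gaussian (or uniform-box) cloud of identical-energy events."""
    rng = np.random.default_rng(seed)
    center = np.asarray(center, dtype=float)
    if uniform_halfwidth_nm is not None:
        pos = center + rng.uniform(-uniform_halfwidth_nm, uniform_halfwidth_nm,
                                   size=(n, 3))
    else:
        pos = center + rng.normal(0.0, sigma_nm, size=(n, 3))
    tracks = rng.integers(0, n_tracks, size=n)
    return [DepositionEvent(pos[i], energy_ev, kind, int(tracks[i]))
            for i in range(n)]


def reaction_set(
    moieties: list[tuple[int, str]],
    species: str = "OH",
    time_s: float = CHEMICAL_STAGE_START_S,
    track_id: int = 0,
) -> list[ReactionEvent]:
    """Sugar-channel reactions at the given (bp_index, strand) locations."""
    return [
        ReactionEvent(species, MoietyKey(bp, strand, "sugar_phosphate"),
                      time_s, track_id)
        for bp, strand in moieties
    ]


def synthetic_spectrum(
    lines: list[tuple[float, float]] | None = None,
    nuclide: str = "synthetic",
    sampling_mode: str = "poisson_lines",
) -> DecaySpectrum:
    """Three-line synthetic Auger-like test spectrum (default lines:
    100 eV x 3.0, 500 eV x 2.0, 2000 eV x 0.5 electrons/decay)."""
    if lines is None:
        lines = [(100.0, 3.0), (500.0, 2.0), (2000.0, 0.5)]
    return DecaySpectrum(nuclide=nuclide,
                         lines=[SpectrumLine(e, y) for e, y in lines],
                         sampling_mode=sampling_mode)


def write_reaction_set(reactions: list[ReactionEvent], path) -> None:
    pd.DataFrame({
        "species": [r.species for r in reactions],
        "bp_index": [r.moiety_key.bp_index for r in reactions],
        "strand": [r.moiety_key.strand for r in reactions],
        "moiety": [r.moiety_key.moiety for r in reactions],
        "time_s": [r.time_s for r in reactions],
        "track_id": [r.origin_track_id for r in reactions],
    }).to_csv(path, index=False)


def read_reaction_set(path) -> list[ReactionEvent]:
    df = pd.read_csv(path, comment="#")
    return [
        ReactionEvent(str(r.species),
                      MoietyKey(int(r.bp_index), str(r.strand), str(r.moiety)),
                      float(r.time_s), int(r.track_id))
        for r in df.itertuples(index=False)
    ]


def make_fixture(spec: SyntheticFixtureSpec, outdir) -> list[Path]:
    """Materialize a fixture spec as files in the standard formats."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if spec.kind == "event_cloud":
        events = event_cloud(seed=spec.seed, **spec.params)
        path = outdir / "events.csv"
        write_event_stream(events, path)
        return [path]
    if spec.kind == "reaction_set":
        reactions = reaction_set(**spec.params)
        path = outdir / "reactions.csv"
        write_reaction_set(reactions, path)
        return [path]
    spectrum = synthetic_spectrum(**spec.params)
    path = outdir / "spectrum.csv"
    write_spectrum(spectrum, path)
    return [path]
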