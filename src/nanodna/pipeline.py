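"""Scenario orchestration: decay -> transport -> chemistry -> scoring.

A scenario couples one DNA target model, one decay spectrum, a source
placement, the transport medium, the chemistry stage (which can be disabled
to emulate a DMSO free-radical-scavenger environment), and the scoring
configuration.  ``run_scenario`` executes ``n_decays`` independent decays
with a fixed seed and returns a :class:`~nanodna.scoring.DamageTally`;
given an output directory it also writes the tally JSON, per-BP profile
CSV, a breaks CSV, and a run manifest with every resolved parameter.

Per-BP profiles are reported against the relative position
``rel_bp = bp_index - source_bp``, where ``source_bp`` is the labeled base
pair (covalent source) or the base-pair slab nearest the source otherwise.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from nanodna import chemistry as chem
from nanodna import geometry, scoring
from nanodna.decay import DecaySpectrum, SourcePlacement, SpectrumLine, place_source, read_spectrum, sample_decay
from nanodna.scoring import DamageTally, ScoringConfig, classify_dsb
from nanodna.transport import MediumModel, transport_electron

logger = logging.getLogger("nanodna")


@dataclass
class ModelSpec:
    kind: str = "high_res"
    n_bp: int = 41
    rise: float = 0.34
    twist: float = 36.0
    bounding_diameter: float = 2.4
    bounding_height: float | None = 14.3
    outer_diameter: float = 2.3           # simple model only
    inner_diameter: float = 1.0           # simple model only

    def build(self) -> geometry.DNAModel:
        if self.kind == "high_res":
            return geometry.build_high_res_bdna(
                self.n_bp, self.rise, self.twist,
                bounding_diameter=self.bounding_diameter,
                bounding_height=self.bounding_height,
            )
        return geometry.build_simple_bdna(
            self.n_bp, self.rise, self.twist,
            outer_diameter=self.outer_diameter,
            inner_diameter=self.inner_diameter,
            bounding_height=self.bounding_height,
        )


@dataclass
class ChemistryConfig:
    enabled: bool = True                   # False = DMSO (scavenger) mode
    branching: dict = field(default_factory=lambda: {
        k: dict(v) for k, v in chem.DEFAULT_BRANCHING.items()})
    channels_path: str | None = None       # None = packaged defaults
    include_h_channels: bool = True
    h_radius_scale: float = 1.0
    diffusion: dict = field(default_factory=lambda: dict(chem.DEFAULT_DIFFUSION_NM2_NS))
    t_end_s: float = chem.CHEMICAL_STAGE_END_S
    n_steps: int = 100

    def resolve_channels(self) -> list[chem.ReactionChannel]:
        if self.channels_path:
            return chem.read_channels(self.channels_path)
        return chem.default_channels(self.h_radius_scale, self.include_h_channels)


@dataclass
class PhysicsConfig:
    cutoff_energy_ev: float = 10.0
    xs_table_path: str | None = None       # None = packaged table

    def resolve_medium(self) -> MediumModel:
        if self.xs_table_path:
            return MediumModel.from_csv(self.xs_table_path,
                                        cutoff_energy_ev=self.cutoff_energy_ev)
        return MediumModel.default(cutoff_energy_ev=self.cutoff_energy_ev)


@dataclass
class ScenarioConfig:
    model: ModelSpec = field(default_factory=ModelSpec)
    spectrum_path: str | None = None
    spectrum: DecaySpectrum | None = None  # programmatic alternative to a path
    placement: SourcePlacement = field(default_factory=SourcePlacement)
    physics: PhysicsConfig = field(default_factory=PhysicsConfig)
    chemistry: ChemistryConfig = field(default_factory=ChemistryConfig)
    scoring: ScoringConfig = field(default_factory=ScoringConfig)
    n_decays: int = 100
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "ScenarioConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw, base_dir=Path(path).parent)

    @classmethod
    def from_dict(cls, raw: dict, base_dir: Path | None = None) -> "ScenarioConfig":
        def _resolve(p):
            if p is None or base_dir is None:
                return p
            q = Path(p)
            return str(q if q.is_absolute() else base_dir / q)

        known = {"model", "spectrum_path", "placement", "physics", "chemistry",
                 "scoring", "n_decays", "seed"}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown scenario config key(s): {sorted(unknown)}")
        cfg = cls(
            model=ModelSpec(**raw.get("model", {})),
            spectrum_path=_resolve(raw.get("spectrum_path")),
            placement=SourcePlacement(**{
                **{"mode": "at_bp"}, **raw.get("placement", {})}),
            physics=PhysicsConfig(**{
                **raw.get("physics", {}),
                "xs_table_path": _resolve(raw.get("physics", {}).get("xs_table_path")),
            }),
            chemistry=ChemistryConfig(**{
                **raw.get("chemistry", {}),
                "channels_path": _resolve(raw.get("chemistry", {}).get("channels_path")),
            }),
            scoring=ScoringConfig(**raw.get("scoring", {})),
            n_decays=int(raw.get("n_decays", 100)),
            seed=int(raw.get("seed", 0)),
        )
        for p in (cfg.spectrum_path, cfg.physics.xs_table_path,
                  cfg.chemistry.channels_path):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"referenced file does not exist: {p}")
        return cfg

    def resolve_spectrum(self) -> DecaySpectrum:
        if self.spectrum is not None:
            return self.spectrum
        if self.spectrum_path is None:
            raise ValueError("scenario needs spectrum_path or an inline spectrum")
        return read_spectrum(self.spectrum_path)

    def manifest(self) -> dict:
        from nanodna import __version__

        def _clean(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: _clean(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, dict):
                return {k: _clean(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [_clean(v) for v in obj]
            return obj

        spectrum = self.resolve_spectrum()
        return {
            "nanodna_version": __version__,
            "seed": self.seed,
            "n_decays": self.n_decays,
            "model": _clean(self.model),
            "placement": _clean(self.placement),
            "physics": _clean(self.physics),
            "chemistry": _clean(self.chemistry),
            "scoring": _clean(self.scoring),
            "spectrum": {
                "nuclide": spectrum.nuclide,
                "sampling_mode": spectrum.sampling_mode,
                "mean_electrons_per_decay": spectrum.mean_electrons_per_decay,
                "n_lines": len(spectrum.lines),
            },
        }


def run_scenario(cfg: ScenarioConfig, outdir: str | Path | None = None
                 ) -> DamageTally:
    """Execute a scenario: per decay, sample the cascade, transport every
    electron, run the (optional) chemistry stage, score and classify breaks,
    and accumulate the tally."""
    model = cfg.model.build()
    spectrum = cfg.resolve_spectrum()
    medium = cfg.physics.resolve_medium()
    if spectrum.max_energy_ev > medium.e_max_ev:
        raise ValueError(
            f"spectrum line at {spectrum.max_energy_ev:g} eV exceeds the "
            f"transport table range (E_max = {medium.e_max_ev:g} eV)")
    source = place_source(cfg.placement, model)
    if cfg.placement.mode == "at_bp":
        source_bp = cfg.placement.bp_index
    else:
        source_bp = model.source_bp_from_z(float(source[2]))

    chem_enabled = cfg.chemistry.enabled and model.kind == "high_res"
    channels = cfg.chemistry.resolve_channels() if chem_enabled else []

    tally = DamageTally(model.n_bp, cfg.scoring, source_bp=source_bp)
    all_breaks: list[scoring.StrandBreak] = []
    seeds = np.random.SeedSequence(cfg.seed).spawn(cfg.n_decays)
    logger.info("scenario start: %d decays, seed %d, model %s, source %s",
                cfg.n_decays, cfg.seed, model.kind, cfg.placement.mode)

    for decay_index in range(cfg.n_decays):
        rng = np.random.default_rng(seeds[decay_index])
        stage = "decay sampling"
        try:
            cascade = sample_decay(spectrum, rng)
            stage = "transport"
            events = []
            for track_id, (energy, direction) in enumerate(cascade):
                events.extend(transport_electron(
                    energy, source, direction, medium, rng, track_id=track_id))
            stage = "hit location"
            if events:
                hits = geometry.locate_hits(
                    np.array([e.position for e in events]), model)
            else:
                hits = []
            direct_energy: dict = {}
            indirect_energy: dict = {}
            bbox_ev = 0.0
            for ev, hit in zip(events, hits):
                if hit.region == "outside":
                    continue
                bbox_ev += ev.energy_ev
                table = direct_energy if hit.region == "target" else indirect_energy
                table[hit.key] = table.get(hit.key, 0.0) + ev.energy_ev

            stage = "scoring"
            if model.kind == "simple":
                breaks = scoring.score_simple_model(events, model, cfg.scoring,
                                                    decay_index)
            else:
                breaks = scoring.score_direct_breaks(events, model, cfg.scoring,
                                                     decay_index, hits=hits)
                if chem_enabled:
                    stage = "chemistry"
                    species = chem.generate_species(
                        events, cfg.chemistry.branching, rng,
                        diffusion=cfg.chemistry.diffusion)
                    reactions, _ = chem.diffuse_and_react(
                        species, model, channels, rng,
                        t_end=cfg.chemistry.t_end_s,
                        n_steps=cfg.chemistry.n_steps)
                    stage = "scoring"
                    breaks = breaks + scoring.score_chemical_breaks(
                        reactions, decay_index)
            dsbs, residual = classify_dsb(breaks, cfg.scoring.d_dsb)
            tally.add_decay(residual, dsbs, direct_energy, indirect_energy, bbox_ev)
            all_breaks.extend(breaks)
        except Exception as exc:
            raise RuntimeError(
                f"scenario failed in stage '{stage}' at decay {decay_index}: {exc}"
            ) from exc

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        tally.to_json(outdir / "tally.json")
        profile_frame(tally).to_csv(outdir / "profiles.csv", index=False)
        _breaks_frame(all_breaks).to_csv(outdir / "breaks.csv", index=False)
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(cfg.manifest(), fh, indent=2)
    return tally


def _breaks_frame(breaks: list[scoring.StrandBreak]) -> pd.DataFrame:
    return pd.DataFrame({
        "decay_index": [b.decay_index for b in breaks],
        "bp_index": [b.bp_index for b in breaks],
        "strand": [b.strand for b in breaks],
        "mechanism": [b.mechanism for b in breaks],
        "track_ids": [";".join(map(str, sorted(b.track_ids))) for b in breaks],
    })


def profile_frame(tally: DamageTally) -> pd.DataFrame:
    """Long-format per-BP profiles: rel_bp,strand,moiety,quantity,value."""
    src = tally.source_bp or 0
    rows = []
    e_dir = tally.energy_direct_sum_ev / max(tally.n_decays, 1)
    e_ind = tally.energy_indirect_sum_ev / max(tally.n_decays, 1)
    ssb = tally.ssb_probability_per_bp()
    for bp in range(1, tally.n_bp + 1):
        rel = bp - src
        for si, strand in enumerate(geometry.STRANDS):
            for mi, moiety in enumerate(geometry.MOIETIES):
                rows.append((rel, strand, moiety, "energy_direct_ev",
                             e_dir[bp - 1, si, mi]))
                rows.append((rel, strand, moiety, "energy_indirect_ev",
                             e_ind[bp - 1, si, mi]))
            rows.append((rel, strand, "sugar_phosphate", "ssb_probability",
                         ssb[bp - 1, si]))
    return pd.DataFrame(rows, columns=["rel_bp", "strand", "moiety",
                                       "quantity", "value"])


# ---------------------------------------------------------------------------
# profile comparison


@dataclass
class ComparisonResult:
    """Summary of |percent difference| between a simulated and a reference
    per-BP profile, over positions with a nonzero reference value."""

    per_position: pd.DataFrame     # rel_bp, sim, ref, percent_diff
    mean_abs_percent_diff: float
    sd_abs_percent_diff: float
    n_positions: int
    n_zero_reference: int

    def __str__(self):
        return (f"mean |diff| = {self.mean_abs_percent_diff:.1f} +/- "
                f"{self.sd_abs_percent_diff:.1f}% over {self.n_positions} "
                f"positions ({self.n_zero_reference} zero-reference excluded)")


def compare_profiles(sim: pd.DataFrame, ref: pd.DataFrame) -> ComparisonResult:
    """Compare per-BP profiles given as frames with columns rel_bp,value.

    Percent difference is 100*|sim - ref|/ref at each overlapping position
    with ref > 0; the summary is the mean and SD of those values.
    """
    sim = sim[["rel_bp", "value"]].rename(columns={"value": "sim"})
    ref = ref[["rel_bp", "value"]].rename(columns={"value": "ref"})
    merged = sim.merge(ref, on="rel_bp", how="inner")
    if len(merged) == 0:
        raise ValueError("profiles have no overlapping rel_bp positions")
    zero = merged["ref"] == 0
    used = merged[~zero].copy()
    used["percent_diff"] = 100.0 * (used["sim"] - used["ref"]).abs() / used["ref"]
    mean = float(used["percent_diff"].mean()) if len(used) else float("nan")
    sd = float(used["percent_diff"].std(ddof=0)) if len(used) else float("nan")
    return ComparisonResult(
        per_position=used,
        mean_abs_percent_diff=mean,
        sd_abs_percent_diff=sd,
        n_positions=len(used),
        n_zero_reference=int(zero.sum()),
    )


def read_reference_profile(path) -> pd.DataFrame:
    """Reference profile CSV: rel_bp,value."""
    df = pd.read_csv(path, comment="#")
    if not {"rel_bp", "value"} <= set(df.columns):
        raise ValueError("reference profile CSV must have columns rel_bp,value")
    return df


# ---------------------------------------------------------------------------
# yield decomposition report


def _round_half_away(x: float) -> int:
    return int(math.floor(abs(x) + 0.5)) * (1 if x >= 0 else -1)


def table3_report(tally: DamageTally) -> dict:
    """Per-decay SSB/DSB yields with integer percentage decompositions.

    SSB percentages are relative to the SSB total, DSB category percentages
    to the DSB total; ``dsb_chemical_pct`` aggregates the two categories
    with chemical involvement (physical+chemical and chemical+chemical).
    """
    ssb_tot, dsb_tot = tally.ssb_total, tally.dsb_total

    def pct(x, tot):
        return _round_half_away(100.0 * x / tot) if tot > 0 else 0

    dsb = {c: tally.dsb(c) for c in scoring.DSB_CATEGORIES}
    return {
        "n_decays": tally.n_decays,
        "energy_bbox_kev_per_decay": tally.energy_bbox_kev_per_decay,
        "ssb_total_per_decay": ssb_tot,
        "ssb_p_per_decay": tally.ssb_p,
        "ssb_p_pct": pct(tally.ssb_p, ssb_tot),
        "ssb_c_per_decay": tally.ssb_c,
        "ssb_c_pct": pct(tally.ssb_c, ssb_tot),
        "dsb_total_per_decay": dsb_tot,
        "dsb_corr_per_decay": dsb["corr_physical"],
        "dsb_corr_pct": pct(dsb["corr_physical"], dsb_tot),
        "dsb_uncorr_pp_per_decay": dsb["uncorr_pp"],
        "dsb_uncorr_pp_pct": pct(dsb["uncorr_pp"], dsb_tot),
        "dsb_uncorr_pc_per_decay": dsb["uncorr_pc"],
        "dsb_uncorr_pc_pct": pct(dsb["uncorr_pc"], dsb_tot),
        "dsb_uncorr_cc_per_decay": dsb["uncorr_cc"],
        "dsb_uncorr_cc_pct": pct(dsb["uncorr_cc"], dsb_tot),
        "dsb_chemical_pct": pct(dsb["uncorr_pc"] + dsb["uncorr_cc"], dsb_tot),
    }


def format_table3(report: dict) -> str:
    lines = [
        f"decays                       {report['n_decays']}",
        f"energy in bounding box       {report['energy_bbox_kev_per_decay']:.4g} keV/decay",
        f"SSB_total/decay              {report['ssb_total_per_decay']:.4g}",
        f"SSB_p/decay                  {report['ssb_p_per_decay']:.4g} ({report['ssb_p_pct']}%)",
        f"SSB_c/decay                  {report['ssb_c_per_decay']:.4g} ({report['ssb_c_pct']}%)",
        f"DSB_total/decay              {report['dsb_total_per_decay']:.4g}",
        f"DSB_corr/decay               {report['dsb_corr_per_decay']:.4g} ({report['dsb_corr_pct']}%)",
        f"DSB_uncorr,(p+p)/decay       {report['dsb_uncorr_pp_per_decay']:.4g} ({report['dsb_uncorr_pp_pct']}%)",
        f"DSB_uncorr,(p+c)/decay       {report['dsb_uncorr_pc_per_decay']:.4g} ({report['dsb_uncorr_pc_pct']}%)",
        f"DSB_uncorr,(c+c)/decay       {report['dsb_uncorr_cc_per_decay']:.4g} ({report['dsb_uncorr_cc_pct']}%)",
    ]
    return "\n".join(lines)


def plot_profile(tally: DamageTally, quantity: str = "ssb_probability",
                 strand: str = "labeled", ax=None):
    """Minimal per-BP profile plot (matplotlib axes returned)."""
    import matplotlib.pyplot as plt

    df = profile_frame(tally)
    sel = df[(df["quantity"] == quantity) & (df["strand"] == strand)
             & (df["moiety"] == "sugar_phosphate")]
    if ax is None:
        _, ax = plt.subplots()
    ax.bar(sel["rel_bp"], sel["value"], width=0.8)
    ax.set_xlabel("base pair relative to source")
    ax.set_ylabel(quantity)
    return ax
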