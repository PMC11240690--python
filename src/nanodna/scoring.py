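"""Strand-break scoring, DSB classification, and per-decay damage tallies.

Break rules
-----------
A *physical* break occurs on a sugar-phosphate moiety whose accumulated
direct energy deposition within its atomic volumes reaches the direct
threshold (default 10 eV, inclusive) in one decay.  A *chemical* break
occurs on a sugar-phosphate moiety with at least one Sugar-channel radical
reaction in that decay.  At most one break is scored per moiety per decay;
base-moiety hits never produce strand breaks.  The semi-cylindrical simple
model scores breaks from per-segment accumulated energy against a higher
threshold (default 17.5 eV) that stands in for both physical and chemical
action; the chemistry stage does not apply to it.

DSB classification
------------------
Breaks on opposite strands within ``d_dsb`` base pairs pair into DSBs by
maximum-cardinality matching; among maximum matchings the smallest total
base-pair separation wins, ties resolved toward lower base-pair indices.
Each break joins at most one DSB; unpaired breaks are the residual SSBs.
Categories: ``corr_physical`` (both physical, sharing a primary track),
``uncorr_pp`` (both physical, independent tracks), ``uncorr_pc`` (one
physical + one chemical), ``uncorr_cc`` (both chemical).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from nanodna.geometry import DNAModel, HitResult, MoietyKey, STRANDS, MOIETIES, locate_hits
from nanodna.transport import DepositionEvent
from nanodna.chemistry import ReactionEvent

DSB_CATEGORIES = ("corr_physical", "uncorr_pp", "uncorr_pc", "uncorr_cc")


@dataclass(frozen=True)
class StrandBreak:
    bp_index: int
    strand: str
    mechanism: str                # "physical" | "chemical"
    track_ids: frozenset = frozenset()
    decay_index: int = 0

    def __post_init__(self):
        if self.mechanism not in ("physical", "chemical"):
            raise ValueError(f"unknown mechanism {self.mechanism!r}")


@dataclass(frozen=True)
class DSBRecord:
    bp_pair: tuple[int, int]
    category: str
    separation: int
    breaks: tuple[StrandBreak, StrandBreak] = ()

    def __post_init__(self):
        if self.category not in DSB_CATEGORIES:
            raise ValueError(f"unknown DSB category {self.category!r}")


@dataclass
class ScoringConfig:
    direct_threshold_ev: float = 10.0
    simple_model_threshold_ev: float = 17.5
    d_dsb: int = 10
    accumulation: str = "per_moiety_per_decay"   # or "per_event"

    def __post_init__(self):
        if self.direct_threshold_ev <= 0 or self.simple_model_threshold_ev <= 0:
            raise ValueError("thresholds must be > 0")
        if self.d_dsb < 1:
            raise ValueError("d_dsb must be >= 1")
        if self.accumulation not in ("per_moiety_per_decay", "per_event"):
            raise ValueError(f"unknown accumulation mode {self.accumulation!r}")


def score_direct_breaks(
    events: list[DepositionEvent],
    model: DNAModel,
    cfg: ScoringConfig,
    decay_index: int = 0,
    hits: list[HitResult] | None = None,
) -> list[StrandBreak]:
    """Physical breaks from direct energy deposition in backbone volumes.

    ``hits`` may carry pre-computed :func:`locate_hits` results for the
    same event list to avoid re-locating.
    """
    if hits is None:
        if not events:
            return []
        hits = locate_hits(np.array([e.position for e in events]), model)
    acc: dict[MoietyKey, float] = {}
    tracks: dict[MoietyKey, set] = {}
    broken: set[MoietyKey] = set()
    for ev, hit in zip(events, hits):
        if hit.region != "target" or hit.key.moiety != "sugar_phosphate":
            continue
        if cfg.accumulation == "per_event":
            if ev.energy_ev >= cfg.direct_threshold_ev:
                broken.add(hit.key)
                tracks.setdefault(hit.key, set()).add(ev.track_id)
        else:
            acc[hit.key] = acc.get(hit.key, 0.0) + ev.energy_ev
            tracks.setdefault(hit.key, set()).add(ev.track_id)
    if cfg.accumulation == "per_moiety_per_decay":
        broken = {k for k, e in acc.items() if e >= cfg.direct_threshold_ev}
    return [
        StrandBreak(k.bp_index, k.strand, "physical",
                    frozenset(tracks.get(k, set())), decay_index)
        for k in sorted(broken)
    ]


def score_chemical_breaks(
    reactions: list[ReactionEvent],
    decay_index: int = 0,
) -> list[StrandBreak]:
    """Chemical breaks: one per moiety with >= 1 Sugar-channel reaction."""
    tracks: dict[MoietyKey, set] = {}
    for r in reactions:
        if r.moiety_key.moiety == "sugar_phosphate":
            tracks.setdefault(r.moiety_key, set()).add(r.origin_track_id)
    return [
        StrandBreak(k.bp_index, k.strand, "chemical", frozenset(t), decay_index)
        for k, t in sorted(tracks.items())
    ]


def score_simple_model(
    events: list[DepositionEvent],
    model: DNAModel,
    cfg: ScoringConfig,
    decay_index: int = 0,
) -> list[StrandBreak]:
    """Per-segment accumulated-energy breaks for the semi-cylindrical model."""
    if model.kind != "simple":
        raise ValueError("score_simple_model requires a simple (semi-cylindrical) model")
    if not events:
        return []
    hits = locate_hits(np.array([e.position for e in events]), model)
    acc: dict[MoietyKey, float] = {}
    tracks: dict[MoietyKey, set] = {}
    for ev, hit in zip(events, hits):
        if hit.region != "target":
            continue
        acc[hit.key] = acc.get(hit.key, 0.0) + ev.energy_ev
        tracks.setdefault(hit.key, set()).add(ev.track_id)
    return [
        StrandBreak(k.bp_index, k.strand, "physical", frozenset(tracks[k]), decay_index)
        for k in sorted(acc)
        if acc[k] >= cfg.simple_model_threshold_ev
    ]


# ---------------------------------------------------------------------------
# DSB classification


def _categorize(a: StrandBreak, b: StrandBreak) -> str:
    mechs = {a.mechanism, b.mechanism}
    if mechs == {"physical"}:
        if a.track_ids & b.track_ids:
            return "corr_physical"
        return "uncorr_pp"
    if mechs == {"chemical"}:
        return "uncorr_cc"
    return "uncorr_pc"


def _pair_signature(a: StrandBreak, b: StrandBreak) -> tuple:
    """Strand-order-independent identity of a candidate DSB pair, used as
    the deterministic tie-break among equal-separation matchings."""
    lab, nonlab = (a, b) if a.strand == STRANDS[0] else (b, a)
    return (lab.bp_index, nonlab.bp_index, lab.mechanism, nonlab.mechanism)


def classify_dsb(
    breaks: list[StrandBreak],
    d_dsb: int,
) -> tuple[list[DSBRecord], list[StrandBreak]]:
    """Pair one decay's breaks into DSBs; return (DSBs, residual SSBs).

    Exact search over bipartite matchings between the two strands,
    selecting maximum cardinality, then minimum total separation, then the
    lexicographically lowest pairing (by base-pair indices, labeled strand
    first, then mechanisms).
    """
    left = sorted([b for b in breaks if b.strand == STRANDS[0]],
                  key=lambda b: (b.bp_index, b.mechanism))
    right = sorted([b for b in breaks if b.strand == STRANDS[1]],
                   key=lambda b: (b.bp_index, b.mechanism))
    if len(left) > len(right):
        small, large, swapped = right, left, True
    else:
        small, large, swapped = left, right, False

    compat = [
        [j for j, lb in enumerate(large) if abs(sb.bp_index - lb.bp_index) <= d_dsb]
        for sb in small
    ]

    best: dict = {"key": None, "pairs": []}

    def dfs(i: int, used: int, pairs: list[tuple[int, int]], sep: int,
            remaining_possible: int):
        if best["key"] is not None and len(pairs) + remaining_possible < -best["key"][0]:
            return  # cannot reach the best cardinality
        if i == len(small):
            key = (-len(pairs), sep,
                   tuple(sorted(_pair_signature(small[a], large[b])
                                for a, b in pairs)))
            if best["key"] is None or key < best["key"]:
                best["key"] = key
                best["pairs"] = list(pairs)
            return
        # try pairing small[i]
        for j in compat[i]:
            if not (used >> j) & 1:
                pairs.append((i, j))
                dfs(i + 1, used | (1 << j), pairs,
                    sep + abs(small[i].bp_index - large[j].bp_index),
                    remaining_possible - 1)
                pairs.pop()
        # leave small[i] unpaired
        dfs(i + 1, used, pairs, sep, remaining_possible - 1)

    dfs(0, 0, [], 0, len(small))

    matched_small = {a for a, _ in best["pairs"]}
    matched_large = {b for _, b in best["pairs"]}
    records = []
    for a, b in sorted(best["pairs"],
                       key=lambda p: (small[p[0]].bp_index, large[p[1]].bp_index)):
        sb, lb = small[a], large[b]
        first, second = (lb, sb) if swapped else (sb, lb)
        records.append(DSBRecord(
            bp_pair=(first.bp_index, second.bp_index),
            category=_categorize(sb, lb),
            separation=abs(sb.bp_index - lb.bp_index),
            breaks=(first, second),
        ))
    residual = ([b for i, b in enumerate(small) if i not in matched_small]
                + [b for j, b in enumerate(large) if j not in matched_large])
    residual.sort(key=lambda b: (b.bp_index, b.strand, b.mechanism))
    return records, residual


# ---------------------------------------------------------------------------
# tallies


@dataclass
class DamageTally:
    """Running per-decay damage accumulator.

    Yields are stored as sums and reported as per-decay means.  Residual
    SSBs (breaks not consumed by a DSB) define the SSB yields, split by
    mechanism; DSB yields are split over the four categories.  Per-BP
    energy profiles separate direct hits (inside atoms) from
    physical-indirect hits (inside the bounding cylinder only, attributed
    to the nearest moiety), per strand and moiety.
    """

    n_bp: int
    config: ScoringConfig = field(default_factory=ScoringConfig)
    source_bp: int | None = None
    n_decays: int = 0
    ssb_p_sum: int = 0
    ssb_c_sum: int = 0
    dsb_sums: dict = field(default_factory=lambda: {c: 0 for c in DSB_CATEGORIES})
    energy_bbox_sum_ev: float = 0.0
    # [bp, strand, moiety] with strand/moiety in STRANDS/MOIETIES order
    energy_direct_sum_ev: np.ndarray = None
    energy_indirect_sum_ev: np.ndarray = None
    ssb_count: np.ndarray = None          # [bp, strand], backbone breaks

    def __post_init__(self):
        if self.energy_direct_sum_ev is None:
            self.energy_direct_sum_ev = np.zeros((self.n_bp, 2, 2))
        if self.energy_indirect_sum_ev is None:
            self.energy_indirect_sum_ev = np.zeros((self.n_bp, 2, 2))
        if self.ssb_count is None:
            self.ssb_count = np.zeros((self.n_bp, 2), dtype=int)

    @classmethod
    def from_yields(
        cls,
        ssb_p: float,
        ssb_c: float,
        dsb: dict[str, float] | None = None,
        energy_bbox_kev_per_decay: float = 0.0,
        n_bp: int = 41,
        n_decays: int = 1,
    ) -> "DamageTally":
        """Tally holding given per-decay yields (e.g. a published row) so
        that decomposition reports can be recomputed from them."""
        out = cls(n_bp)
        out.n_decays = n_decays
        out.ssb_p_sum = ssb_p * n_decays
        out.ssb_c_sum = ssb_c * n_decays
        if dsb:
            unknown = set(dsb) - set(DSB_CATEGORIES)
            if unknown:
                raise ValueError(f"unknown DSB categories {sorted(unknown)}")
            for c, v in dsb.items():
                out.dsb_sums[c] = v * n_decays
        out.energy_bbox_sum_ev = energy_bbox_kev_per_decay * 1000.0 * n_decays
        return out

    # --- per-decay means

    @property
    def ssb_p(self) -> float:
        return self.ssb_p_sum / self.n_decays if self.n_decays else 0.0

    @property
    def ssb_c(self) -> float:
        return self.ssb_c_sum / self.n_decays if self.n_decays else 0.0

    @property
    def ssb_total(self) -> float:
        return self.ssb_p + self.ssb_c

    def dsb(self, category: str) -> float:
        return self.dsb_sums[category] / self.n_decays if self.n_decays else 0.0

    @property
    def dsb_total(self) -> float:
        return sum(self.dsb_sums.values()) / self.n_decays if self.n_decays else 0.0

    @property
    def energy_bbox_kev_per_decay(self) -> float:
        return self.energy_bbox_sum_ev / 1000.0 / self.n_decays if self.n_decays else 0.0

    def ssb_probability_per_bp(self) -> np.ndarray:
        """[bp, strand] mean SSBs per decay at each backbone location."""
        if self.n_decays == 0:
            return np.zeros_like(self.ssb_count, dtype=float)
        return self.ssb_count / self.n_decays

    # --- accumulation

    def add_decay(
        self,
        residual_ssbs: list[StrandBreak],
        dsbs: list[DSBRecord],
        direct_energy: dict[MoietyKey, float] | None = None,
        indirect_energy: dict[MoietyKey, float] | None = None,
        energy_bbox_ev: float = 0.0,
    ) -> "DamageTally":
        self.n_decays += 1
        strand_idx = {s: i for i, s in enumerate(STRANDS)}
        moiety_idx = {m: i for i, m in enumerate(MOIETIES)}
        for b in residual_ssbs:
            if b.mechanism == "physical":
                self.ssb_p_sum += 1
            else:
                self.ssb_c_sum += 1
            self.ssb_count[b.bp_index - 1, strand_idx[b.strand]] += 1
        for d in dsbs:
            self.dsb_sums[d.category] += 1
        for table, store in ((direct_energy, self.energy_direct_sum_ev),
                             (indirect_energy, self.energy_indirect_sum_ev)):
            if table:
                for key, e in table.items():
                    store[key.bp_index - 1, strand_idx[key.strand],
                          moiety_idx[key.moiety]] += e
        self.energy_bbox_sum_ev += energy_bbox_ev
        return self

    def merge(self, other: "DamageTally") -> "DamageTally":
        """Combine two tallies accumulated under identical conditions."""
        if self.n_bp != other.n_bp or self.config != other.config \
                or self.source_bp != other.source_bp:
            raise ValueError("cannot merge tallies with mismatched configuration")
        out = DamageTally(self.n_bp, self.config, self.source_bp)
        out.n_decays = self.n_decays + other.n_decays
        out.ssb_p_sum = self.ssb_p_sum + other.ssb_p_sum
        out.ssb_c_sum = self.ssb_c_sum + other.ssb_c_sum
        out.dsb_sums = {c: self.dsb_sums[c] + other.dsb_sums[c]
                        for c in DSB_CATEGORIES}
        out.energy_bbox_sum_ev = self.energy_bbox_sum_ev + other.energy_bbox_sum_ev
        out.energy_direct_sum_ev = self.energy_direct_sum_ev + other.energy_direct_sum_ev
        out.energy_indirect_sum_ev = self.energy_indirect_sum_ev + other.energy_indirect_sum_ev
        out.ssb_count = self.ssb_count + other.ssb_count
        return out

    # --- serialization

    def to_dict(self) -> dict:
        return {
            "n_decays": self.n_decays,
            "n_bp": self.n_bp,
            "source_bp": self.source_bp,
            "ssb_p_per_decay": self.ssb_p,
            "ssb_c_per_decay": self.ssb_c,
            "ssb_total_per_decay": self.ssb_total,
            "dsb_per_decay": {c: self.dsb(c) for c in DSB_CATEGORIES},
            "dsb_total_per_decay": self.dsb_total,
            "energy_bbox_kev_per_decay": self.energy_bbox_kev_per_decay,
            "config": {
                "direct_threshold_ev": self.config.direct_threshold_ev,
                "simple_model_threshold_ev": self.config.simple_model_threshold_ev,
                "d_dsb": self.config.d_dsb,
                "accumulation": self.config.accumulation,
            },
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)
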