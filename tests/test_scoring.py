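"""Break scoring rules, DSB classification (vs an exhaustive oracle), and
tally accumulation."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nanodna.chemistry import ReactionEvent
from nanodna.geometry import MoietyKey, STRANDS
from nanodna.scoring import (
    DSB_CATEGORIES,
    DamageTally,
    ScoringConfig,
    StrandBreak,
    classify_dsb,
    score_chemical_breaks,
    score_direct_breaks,
    score_simple_model,
)
from nanodna.transport import DepositionEvent


def _ev(pos, energy, track=0, kind="ionization"):
    return DepositionEvent(np.asarray(pos, float), energy, kind, track)


def _atom(model, moiety, bp=3, strand="labeled"):
    return next(a for a in model.atoms
                if a.moiety == moiety and a.bp_index == bp and a.strand == strand)


class TestDirectBreaks:
    def test_single_event_over_threshold_breaks_backbone(self, model41):
        a = _atom(model41, "sugar_phosphate")
        breaks = score_direct_breaks([_ev(a.position, 12.0)], model41,
                                     ScoringConfig())
        assert len(breaks) == 1
        assert breaks[0].bp_index == 3
        assert breaks[0].mechanism == "physical"

    def test_subthreshold_events_accumulate_within_moiety(self, model41):
        a = _atom(model41, "sugar_phosphate")
        events = [_ev(a.position, 6.0), _ev(a.position, 5.0)]
        assert len(score_direct_breaks(events, model41, ScoringConfig())) == 1
        # split across two different moieties: no break
        b = _atom(model41, "sugar_phosphate", bp=10, strand="nonlabeled")
        events = [_ev(a.position, 6.0), _ev(b.position, 5.0)]
        assert score_direct_breaks(events, model41, ScoringConfig()) == []

    def test_base_hits_never_break_strands(self, model41):
        a = _atom(model41, "base")
        assert score_direct_breaks([_ev(a.position, 15.0)], model41,
                                   ScoringConfig()) == []

    def test_per_event_mode_ignores_accumulation(self, model41):
        a = _atom(model41, "sugar_phosphate")
        cfg = ScoringConfig(accumulation="per_event")
        assert score_direct_breaks([_ev(a.position, 6.0), _ev(a.position, 5.0)],
                                   model41, cfg) == []
        assert len(score_direct_breaks([_ev(a.position, 12.0)], model41, cfg)) == 1

    def test_break_count_nonincreasing_in_threshold(self, model41, rng):
        events = [_ev(rng.normal(0, 1.0, 3) + [0, 0, 7], rng.uniform(2, 15),
                      track=int(rng.integers(3)))
                  for _ in range(300)]
        counts = [len(score_direct_breaks(
            events, model41, ScoringConfig(direct_threshold_ev=t)))
            for t in (5.0, 10.0, 20.0)]
        assert counts[0] >= counts[1] >= counts[2]

    def test_track_ids_are_unioned(self, model41):
        a = _atom(model41, "sugar_phosphate")
        events = [_ev(a.position, 6.0, track=1), _ev(a.position, 6.0, track=2)]
        (brk,) = score_direct_breaks(events, model41, ScoringConfig())
        assert brk.track_ids == frozenset({1, 2})


class TestChemicalBreaks:
    def test_sugar_reaction_breaks_once_per_moiety(self):
        key = MoietyKey(7, "labeled", "sugar_phosphate")
        r = ReactionEvent("OH", key, 1e-9, 0)
        assert len(score_chemical_breaks([r])) == 1
        assert len(score_chemical_breaks([r, r, r])) == 1

    def test_base_reaction_is_not_a_break(self):
        r = ReactionEvent("OH", MoietyKey(7, "labeled", "base"), 1e-9, 0)
        assert score_chemical_breaks([r]) == []


class TestSimpleModel:
    def _seg_point(self, model, bp, z_frac=0.5):
        # mid-arc point of the labeled-strand segment of this bp
        seg = next(s for s in model.segments
                   if s.bp_index == bp and s.strand == "labeled")
        import math
        mid = math.radians(seg.phase_angle + 90.0)
        r = 0.5 * (seg.inner_radius + seg.outer_radius)
        return [r * math.cos(mid), r * math.sin(mid), seg.z_center]

    def test_threshold_is_inclusive(self, simple42):
        p = self._seg_point(simple42, 1)
        cfg = ScoringConfig()
        assert len(score_simple_model([_ev(p, 17.5)], simple42, cfg)) == 1
        assert score_simple_model([_ev(p, 17.4)], simple42, cfg) == []

    def test_energy_does_not_accumulate_across_segments(self, simple42):
        cfg = ScoringConfig()
        events = [_ev(self._seg_point(simple42, 1), 10.0),
                  _ev(self._seg_point(simple42, 2), 7.5)]
        assert score_simple_model(events, simple42, cfg) == []

    def test_high_res_model_rejected(self, model41):
        with pytest.raises(ValueError, match="simple"):
            score_simple_model([], model41, ScoringConfig())


# ---------------------------------------------------------------------------
# DSB classification


def _brk(bp, strand, mech, tracks=()):
    return StrandBreak(bp, strand, mech, frozenset(tracks))


def oracle_classify(breaks, d_dsb):
    """Independent exhaustive enumeration of all bipartite matchings with
    the same preference rule (max cardinality, min total separation, lowest
    pairing signature)."""
    left = [b for b in breaks if b.strand == STRANDS[0]]
    right = [b for b in breaks if b.strand == STRANDS[1]]
    best = None
    k_max = min(len(left), len(right))
    for k in range(k_max, -1, -1):
        for lsub in itertools.combinations(range(len(left)), k):
            for rperm in itertools.permutations(range(len(right)), k):
                pairs = list(zip(lsub, rperm))
                if any(abs(left[i].bp_index - right[j].bp_index) > d_dsb
                       for i, j in pairs):
                    continue
                sep = sum(abs(left[i].bp_index - right[j].bp_index)
                          for i, j in pairs)
                sig = tuple(sorted(
                    (left[i].bp_index, right[j].bp_index,
                     left[i].mechanism, right[j].mechanism) for i, j in pairs))
                key = (-k, sep, sig)
                if best is None or key < best[0]:
                    best = (key, pairs)
        if best is not None and -best[0][0] == k:
            break  # no larger matching exists; smaller k cannot beat it
    pairs = best[1] if best else []

    def cat(a, b):
        m = {a.mechanism, b.mechanism}
        if m == {"physical"}:
            return "corr_physical" if a.track_ids & b.track_ids else "uncorr_pp"
        if m == {"chemical"}:
            return "uncorr_cc"
        return "uncorr_pc"

    cats = sorted(cat(left[i], right[j]) for i, j in pairs)
    n_residual = len(breaks) - 2 * len(pairs)
    return len(pairs), cats, n_residual


def _break_set(draw):
    n = draw(st.integers(0, 12))
    moieties = draw(st.lists(
        st.tuples(st.integers(1, 41), st.sampled_from(STRANDS),
                  st.sampled_from(["physical", "chemical"])),
        min_size=n, max_size=n, unique=True))
    return [
        _brk(bp, strand, mech,
             draw(st.sets(st.integers(0, 3), max_size=2)))
        for bp, strand, mech in moieties
    ]


break_sets = st.composite(_break_set)()


class TestClassifyDSB:
    def test_physical_plus_chemical_pair(self):
        breaks = [_brk(5, "labeled", "physical", {1}),
                  _brk(8, "nonlabeled", "chemical", {1})]
        dsbs, residual = classify_dsb(breaks, 10)
        assert len(dsbs) == 1
        assert dsbs[0].category == "uncorr_pc"
        assert dsbs[0].separation == 3
        assert residual == []

    def test_same_strand_breaks_never_pair(self):
        breaks = [_brk(5, "labeled", "physical"), _brk(8, "labeled", "physical")]
        dsbs, residual = classify_dsb(breaks, 10)
        assert dsbs == []
        assert len(residual) == 2

    def test_shared_track_marks_correlated(self):
        breaks = [_brk(5, "labeled", "physical", {3}),
                  _brk(6, "nonlabeled", "physical", {3, 4})]
        dsbs, _ = classify_dsb(breaks, 10)
        assert dsbs[0].category == "corr_physical"

    def test_distance_gate_excludes_far_pairs(self):
        breaks = [_brk(5, "labeled", "physical"), _brk(20, "nonlabeled", "physical")]
        assert classify_dsb(breaks, 10)[0] == []

    @settings(max_examples=250, derandomize=True, deadline=None)
    @given(breaks=break_sets, d_dsb=st.sampled_from([3, 5, 10]))
    def test_matches_exhaustive_oracle(self, breaks, d_dsb):
        """The classifier equals brute-force enumeration over all pairings
        for any break set of one decay (count, categories, residual)."""
        dsbs, residual = classify_dsb(breaks, d_dsb)
        n, cats, n_res = oracle_classify(breaks, d_dsb)
        assert len(dsbs) == n
        assert sorted(d.category for d in dsbs) == cats
        assert len(residual) == n_res

    @settings(max_examples=150, derandomize=True, deadline=None)
    @given(breaks=break_sets)
    def test_dsb_monotone_and_ssb_antimonotone_in_distance(self, breaks):
        """Shrinking d_DSB can only turn DSBs back into SSBs."""
        counts = {d: classify_dsb(breaks, d) for d in (3, 5, 10)}
        assert len(counts[3][0]) <= len(counts[5][0]) <= len(counts[10][0])
        assert len(counts[3][1]) >= len(counts[5][1]) >= len(counts[10][1])

    @settings(max_examples=150, derandomize=True, deadline=None)
    @given(breaks=break_sets, d_dsb=st.sampled_from([3, 5, 10]))
    def test_break_conservation(self, breaks, d_dsb):
        dsbs, residual = classify_dsb(breaks, d_dsb)
        assert 2 * len(dsbs) + len(residual) == len(breaks)


class TestDamageTally:
    def test_zero_decays_all_zero(self):
        t = DamageTally(41)
        assert t.ssb_total == 0.0
        assert t.dsb_total == 0.0
        assert t.energy_bbox_kev_per_decay == 0.0

    def test_constant_input_yield_is_exact(self):
        t = DamageTally(41)
        for i in range(100):
            t.add_decay([_brk(5, "labeled", "physical"),
                         _brk(30, "labeled", "chemical")], [])
        assert t.ssb_p == 1.0
        assert t.ssb_c == 1.0
        assert t.ssb_total == 2.0

    def test_merge_equals_concatenated_run(self, rng):
        def random_run(t, n, seed):
            r = np.random.default_rng(seed)
            for _ in range(n):
                bps = r.choice(41, size=3, replace=False) + 1
                breaks = [_brk(int(bps[0]), "labeled", "physical", {0}),
                          _brk(int(bps[1]), "nonlabeled", "chemical"),
                          _brk(int(bps[2]), "labeled", "chemical")]
                dsbs, residual = classify_dsb(breaks, 10)
                t.add_decay(residual, dsbs, energy_bbox_ev=float(r.uniform(0, 100)))
            return t

        t1 = random_run(DamageTally(41), 40, seed=1)
        t2 = random_run(DamageTally(41), 60, seed=2)
        merged = t1.merge(t2)
        combined = random_run(random_run(DamageTally(41), 40, seed=1), 60, seed=2)
        assert merged.n_decays == combined.n_decays == 100
        assert merged.ssb_p == combined.ssb_p
        assert merged.ssb_c == combined.ssb_c
        assert merged.dsb_sums == combined.dsb_sums
        assert merged.energy_bbox_sum_ev == pytest.approx(combined.energy_bbox_sum_ev)
        np.testing.assert_array_equal(merged.ssb_count, combined.ssb_count)

    def test_merge_rejects_config_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            DamageTally(41).merge(DamageTally(41, ScoringConfig(d_dsb=3)))

    def test_dsb_category_yields(self):
        t = DamageTally(41)
        breaks = [_brk(5, "labeled", "physical", {1}),
                  _brk(6, "nonlabeled", "physical", {1})]
        dsbs, residual = classify_dsb(breaks, 10)
        t.add_decay(residual, dsbs)
        assert t.dsb("corr_physical") == 1.0
        assert t.dsb_total == 1.0
        assert sum(t.dsb(c) for c in DSB_CATEGORIES) == t.dsb_total
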