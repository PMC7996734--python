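"""Folding-space enumeration, k-best hishape classes and filters."""

import numpy as np
import pytest

from alikin import (
    Alignment,
    CovarianceParams,
    FoldingSpaceConfig,
    SecondaryStructure,
    brute_force_hishapes,
    enumerate_structures,
    kbest_hishapes,
    parse_dotbracket,
)
from alikin.folding_space import allowed_pairs, apply_x_filter, external_components
from alikin.energy import ConsensusEnergyEvaluator


def cfg_toy(toy, lam0, **kw):
    kw.setdefault("backend", toy)
    kw.setdefault("params", lam0)
    return FoldingSpaceConfig(**kw)


class TestEnumerate:
    def test_all_a_only_open_chain(self, toy, lam0):
        aln = Alignment.from_rows(["AAAAAAA"])
        out = list(enumerate_structures(aln, cfg_toy(toy, lam0)))
        assert len(out) == 1 and out[0][0].is_open_chain

    def test_matches_subset_oracle(self, hairpin_aln, toy, lam0):
        """Structure set equals a direct power-set filter over candidate pairs."""
        import itertools
        from alikin.hishape import decompose_helices

        cfg = cfg_toy(toy, lam0)
        got = {s.pairs for s, _ in enumerate_structures(hairpin_aln, cfg)}
        cand = allowed_pairs(hairpin_aln, cfg)
        expected = set()
        for r in range(len(cand) + 1):
            for combo in itertools.combinations(cand, r):
                try:
                    s = SecondaryStructure.make(hairpin_aln.L, combo, min_hairpin=3)
                except Exception:
                    continue
                if all(h.length >= 2 for h in decompose_helices(s)):
                    expected.add(s.pairs)
        assert got == expected
        assert frozenset({(1, 9), (2, 8), (3, 7)}) in got

    def test_no_lonely_pairs_and_min_hairpin(self, hairpin_aln, toy, lam0):
        from alikin.hishape import decompose_helices
        for s, _ in enumerate_structures(hairpin_aln, cfg_toy(toy, lam0)):
            for h in decompose_helices(s):
                assert h.length >= 2
            for i, j in s.pairs:
                inner = [p for p in s.pairs if i < p[0] and p[1] < j]
                if not inner:
                    assert j - i - 1 >= 3

    def test_threshold_boundary(self, toy, lam0):
        # pair (1,9) valid in 1 of 2 rows
        aln = Alignment.from_rows(["GGGAAACCC", "AGGAAACCA"])
        at_05 = allowed_pairs(aln, cfg_toy(toy, lam0, bp_threshold=0.5))
        at_06 = allowed_pairs(aln, cfg_toy(toy, lam0, bp_threshold=0.6))
        assert (1, 9) in at_05 and (1, 9) not in at_06

    def test_threshold_monotonicity(self, toy, lam0):
        aln = Alignment.from_rows(["GGGAAACCC", "GCGAAACGC", "AGGAAACCA"])
        sets = []
        for thr in (0.3, 0.5, 0.8):
            structs = {s.dotbracket() for s, _ in enumerate_structures(aln, cfg_toy(toy, lam0, bp_threshold=thr))}
            sets.append(structs)
        assert sets[2] <= sets[1] <= sets[0]

    def test_energy_band(self, hairpin_aln, toy, lam0):
        full = list(enumerate_structures(hairpin_aln, cfg_toy(toy, lam0)))
        emin = min(e.total for _, e in full)
        banded = list(enumerate_structures(hairpin_aln, cfg_toy(toy, lam0, energy_band=1.0)))
        assert {s.dotbracket() for s, _ in banded} == {
            s.dotbracket() for s, e in full if e.total <= emin + 1.0
        }


class TestKBest:
    def test_all_a_single_class(self, toy, lam0):
        aln = Alignment.from_rows(["AAAAAAA"])
        out = kbest_hishapes(aln, cfg_toy(toy, lam0, k=5))
        assert len(out) == 1
        assert out[0].hishape.render() == "[_]" and out[0].energy.total == 0.0

    def test_hairpin_rank1(self, hairpin_aln, toy, lam0):
        out = kbest_hishapes(hairpin_aln, cfg_toy(toy, lam0, k=2))
        assert out[0].hishape.render() == "[5]"
        assert out[0].hishrep.dotbracket() == "(((...)))"
        assert out[0].energy.total == pytest.approx(-1.0)

    def test_matches_brute_force(self, hairpin_aln, toy, lam0):
        cfg = cfg_toy(toy, lam0, k=6)
        got = kbest_hishapes(hairpin_aln, cfg)
        exp = brute_force_hishapes(hairpin_aln, cfg)
        assert [(c.hishape.render(), round(c.energy.total, 9), c.hishrep.dotbracket()) for c in got] == [
            (c.hishape.render(), round(c.energy.total, 9), c.hishrep.dotbracket()) for c in exp
        ]

    def test_bistable_two_leading_classes(self, toy):
        # compensatory two-row alignment with two mutually exclusive hairpins
        aln = Alignment.from_rows(["GGGGAAACCCCAAAGGG", "GGGGAAACCCCAAAGGG"])
        out = kbest_hishapes(aln, cfg_toy(toy, CovarianceParams(lam=-1.0), k=3))
        names = [c.hishape.render() for c in out]
        # 4-stack hairpin beats 3-stack hairpin
        assert out[0].hishrep.dotbracket() == "((((...))))......"
        assert out[0].energy.total < out[1].energy.total
        assert len(set(names)) == len(names)

    def test_ranks_and_monotone_energies(self, hairpin_aln, toy, lam0):
        out = kbest_hishapes(hairpin_aln, cfg_toy(toy, lam0, k=10))
        assert [c.rank for c in out] == list(range(1, len(out) + 1))
        energies = [c.energy.total for c in out]
        assert energies == sorted(energies)
        for c in out:
            from alikin import abstract
            assert abstract(c.hishrep, "h").render() == c.hishape.render()

    def test_determinism(self, hairpin_aln, toy, lam0):
        cfg = cfg_toy(toy, lam0, k=5)
        a = [(c.hishape.render(), c.hishrep.dotbracket()) for c in kbest_hishapes(hairpin_aln, cfg)]
        b = [(c.hishape.render(), c.hishrep.dotbracket()) for c in kbest_hishapes(hairpin_aln, cfg)]
        assert a == b


class TestXFilter:
    def test_positive_component_removed(self, toy, lam0):
        aln = Alignment.from_rows(["GGAAACCAAAGGGAAACCC"])
        ev = ConsensusEnergyEvaluator(aln, toy, lam0)
        weak = parse_dotbracket("((...))............")       # +1.0 component
        s_strong = SecondaryStructure.make(19, [(11, 19), (12, 18), (13, 17)])
        stream = [(weak, ev.evaluate(weak)), (s_strong, ev.evaluate(s_strong))]
        kept = [s for s, _ in apply_x_filter(iter(stream), 0.0, ev)]
        assert weak not in kept  # +1.0 > 0 removed
        assert s_strong in kept  # -1.0 <= 0 retained

    def test_open_chain_retained(self, toy, lam0):
        aln = Alignment.from_rows(["AAAA"])
        ev = ConsensusEnergyEvaluator(aln, toy, lam0)
        oc = SecondaryStructure(length=4, pairs=frozenset())
        kept = list(apply_x_filter(iter([(oc, ev.evaluate(oc))]), 0.0, ev))
        assert len(kept) == 1

    def test_boundary_zero_retained(self, toy):
        # component with exactly 0.0 pseudo energy is retained at e=0
        aln = Alignment.from_rows(["GGGAAACCC"])
        params = CovarianceParams(lam=1.0, phi=0.0)  # no penalty, V=0 for M=1
        ev = ConsensusEnergyEvaluator(aln, toy, params)
        s = parse_dotbracket("(((...)))")
        e = ev.total(s)
        kept = list(apply_x_filter(iter([(s, ev.evaluate(s))]), e, ev))
        assert len(kept) == 1

    def test_external_components_split(self):
        s = parse_dotbracket("((...))..((...))")
        comps = external_components(s)
        assert len(comps) == 2
        assert {frozenset(c.pairs) for c in comps} == {
            frozenset({(1, 7), (2, 6)}),
            frozenset({(10, 16), (11, 15)}),
        }

    def test_kbest_with_x_filter_drops_positive_classes(self, hairpin_aln, toy, lam0):
        cfg = cfg_toy(toy, lam0, k=10, x_filter=0.0)
        out = kbest_hishapes(hairpin_aln, cfg)
        for c in out:
            if not c.hishrep.is_open_chain:
                assert c.energy.total <= 0.0
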