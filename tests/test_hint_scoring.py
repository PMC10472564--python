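"""Intron evidence scoring: IBA arithmetic, IMC counting, classification."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from exonweave import fixtures
from exonweave.formats import (
    IDENTICAL,
    MISMATCH,
    SUBSTITUTION,
    AlignmentChain,
    Junction,
)
from exonweave.hint_scoring import (
    ScoringConfig,
    classify_evidence,
    compute_imc,
    score_iba,
)


def make_junction(left, right, left_ev=(), right_ev=()):
    return Junction((1000, 1100), tuple(left), tuple(right), tuple(left_ev), tuple(right_ev))


class TestScoreIba:
    def test_perfect_conservation_scores_one(self):
        j = make_junction([IDENTICAL] * 20, [IDENTICAL] * 20)
        assert score_iba(j) == 1.0

    def test_all_mismatch_scores_zero(self):
        j = make_junction([MISMATCH] * 20, [MISMATCH] * 20)
        assert score_iba(j) == 0.0

    def test_decay_weighted_mean_hand_computed(self):
        # left (identical, mismatch) with q=0.8: (1 + 0) / 1.8; right perfect
        cfg = ScoringConfig(window=2, decay=0.8)
        j = make_junction([IDENTICAL, MISMATCH], [IDENTICAL, IDENTICAL])
        assert score_iba(j, cfg) == pytest.approx((1 / 1.8 + 1.0) / 2, abs=1e-4)
        assert score_iba(j, cfg) == pytest.approx(0.7778, abs=1e-4)

    def test_event_penalty_is_multiplicative(self):
        cfg = ScoringConfig(window=2, decay=0.8, event_penalty=0.5)
        j = make_junction([IDENTICAL, MISMATCH], [IDENTICAL, IDENTICAL], left_ev=(0,))
        assert score_iba(j, cfg) == pytest.approx(0.3889, abs=1e-4)

    def test_event_outside_window_not_penalized(self):
        cfg = ScoringConfig(window=2)
        j = make_junction([IDENTICAL] * 5, [IDENTICAL] * 5, left_ev=(4,))
        assert score_iba(j, cfg) == 1.0

    def test_empty_side_scores_zero(self):
        j = make_junction([], [IDENTICAL] * 10)
        assert score_iba(j) == 0.5

    def test_unknown_column_class_rejected(self):
        with pytest.raises(ValueError, match="unknown column class"):
            score_iba(make_junction(["weird"], [IDENTICAL]))

    @given(
        cols=st.lists(st.sampled_from([IDENTICAL, SUBSTITUTION, MISMATCH]), min_size=1, max_size=20),
        flip=st.integers(min_value=0, max_value=19),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_upgrading_mismatch_never_decreases_iba(self, cols, flip):
        flip = flip % len(cols)
        before = score_iba(make_junction(cols, cols))
        upgraded = list(cols)
        upgraded[flip] = IDENTICAL
        after = score_iba(make_junction(upgraded, upgraded))
        assert after >= before - 1e-12
        assert 0.0 <= before <= 1.0 and 0.0 <= after <= 1.0

    @pytest.mark.parametrize("cls,expect", [(IDENTICAL, 1.0), (MISMATCH, 0.0), (SUBSTITUTION, 0.5)])
    def test_decay_invariant_for_uniform_columns(self, cls, expect):
        j = make_junction([cls] * 10, [cls] * 10)
        for q in (0.2, 0.5, 0.8, 0.99, 1.0):
            assert score_iba(j, ScoringConfig(decay=q)) == pytest.approx(expect)


def chain(pid, introns, seq="s1", strand="+"):
    blocks = []
    pos = 100
    for a, b in introns:
        blocks.append((pos, a))
        pos = b
    blocks.append((pos, pos + 60))
    return AlignmentChain(protein_id=pid, seq_id=seq, strand=strand, blocks=blocks)


class TestComputeImc:
    def test_counts_distinct_proteins(self):
        chains = [chain(p, [(1000, 1100)]) for p in ("p1", "p2", "p3")]
        imc, prots = compute_imc(chains)[("s1", "+", (1000, 1100))]
        assert imc == 3 and prots == {"p1", "p2", "p3"}

    def test_same_protein_twice_counts_once(self):
        chains = [chain("p1", [(1000, 1100)]), chain("p1", [(1000, 1100)])]
        assert compute_imc(chains)[("s1", "+", (1000, 1100))][0] == 1

    def test_opposite_strands_are_distinct_keys(self):
        chains = [chain("p1", [(1000, 1100)]), chain("p2", [(1000, 1100)], strand="-")]
        m = compute_imc(chains)
        assert ("s1", "+", (1000, 1100)) in m and ("s1", "-", (1000, 1100)) in m

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            chains = []
            for i in range(rng.integers(1, 12)):
                pid = f"p{rng.integers(1, 5)}"
                s = int(rng.integers(0, 3))
                introns = sorted(
                    {(int(a) * 100, int(a) * 100 + 80) for a in rng.integers(1, 6, size=rng.integers(1, 4))}
                )
                chains.append(chain(pid, introns, seq=f"s{s}", strand="+-"[rng.integers(2)]))
            got = {k: v[0] for k, v in compute_imc(chains).items()}
            # oracle: brute-force double loop over (protein, intron) pairs
            expected = {}
            for key in got:
                prots = set()
                for c in chains:
                    for iv in c.intron_intervals:
                        if (c.seq_id, c.strand, iv) == key:
                            prots.add(c.protein_id)
                expected[key] = len(prots)
            assert got == expected


class TestClassifyEvidence:
    def _single(self, left, right, imc_proteins=("p1",), events=()):
        chains = []
        for p in imc_proteins:
            c = AlignmentChain(
                protein_id=p,
                seq_id="s1",
                strand="+",
                blocks=[(900, 1000), (1100, 1160)],
                junctions=[make_junction(left, right, *((events, ()) if events else ((), ())))],
            )
            chains.append(c)
        return classify_evidence(chains)

    def test_high_iba_alone_suffices(self):
        ev, _ = self._single([IDENTICAL] * 15, [IDENTICAL] * 15)
        assert ev[0].confidence == "high" and ev[0].imc == 1

    def test_low_iba_low_imc_discarded(self):
        ev, hints = self._single([MISMATCH] * 15, [MISMATCH] * 15)
        assert ev[0].confidence == "discarded"
        assert not any(h.feature == "intron" for h in hints)

    def test_imc_rescues_weak_iba(self):
        ev, _ = self._single([MISMATCH] * 15, [MISMATCH] * 15, imc_proteins=("p1", "p2", "p3"))
        assert ev[0].confidence == "high"  # imc 3 >= 2

    def test_intermediate_iba_is_low_confidence(self):
        cfg = ScoringConfig()
        # uniform substitution columns -> iba = substitution_credit = 0.5? no:
        # mix to land between keep (0.1) and high (0.25)
        left = [MISMATCH] * 15
        right = [IDENTICAL, MISMATCH] + [MISMATCH] * 13
        ev, hints = self._single(left, right)
        assert cfg.iba_min_keep <= ev[0].iba < cfg.iba_min_high
        assert ev[0].confidence == "low"
        (ih,) = [h for h in hints if h.feature == "intron"]
        assert ih.source_tag == "P" and ih.mult == 1

    def test_partition_exhaustive_and_exclusive(self, tiny_fixture):
        ev, _ = classify_evidence(tiny_fixture.chains)
        keys = [(e.seq_id, e.strand, e.interval) for e in ev]
        assert len(keys) == len(set(keys))
        assert all(e.confidence in ("discarded", "low", "high") for e in ev)

    def test_perfect_recovery_on_clean_fixture(self, clean_fixture):
        ev, _ = classify_evidence(clean_fixture.chains)
        planted = {
            (m.seq_id, m.strand, iv) for m in clean_fixture.truth for iv in m.introns
        }
        found_high = {
            (e.seq_id, e.strand, e.interval) for e in ev if e.confidence == "high"
        }
        assert found_high == planted  # all planted high, no false intron

    def test_cdspart_shrunk_nine_bp(self):
        c = AlignmentChain(
            protein_id="p1", seq_id="s1", strand="+", blocks=[(1000, 1100)], junctions=[]
        )
        _, hints = classify_evidence([c])
        (cp,) = [h for h in hints if h.feature == "CDSpart"]
        assert (cp.start, cp.end) == (1009, 1091)
        assert cp.source_tag == "P"

    def test_tiny_block_cdspart_floors_at_one_bp(self):
        c = AlignmentChain(
            protein_id="p1", seq_id="s1", strand="+", blocks=[(1000, 1012)], junctions=[]
        )
        _, hints = classify_evidence([c])
        (cp,) = [h for h in hints if h.feature == "CDSpart"]
        assert cp.end - cp.start == 1

    def test_terminal_hints_only_with_protein_coverage(self):
        covered = AlignmentChain(
            protein_id="p1", seq_id="s1", strand="+", blocks=[(1000, 1090)],
            junctions=[], protein_start=0, protein_end=29, protein_length=29,
        )
        partial = AlignmentChain(
            protein_id="p2", seq_id="s1", strand="+", blocks=[(2000, 2090)],
            junctions=[], protein_start=3, protein_end=20, protein_length=29,
        )
        _, hints = classify_evidence([covered, partial])
        feats = {(h.feature, h.start, h.end) for h in hints}
        assert ("start", 1000, 1003) in feats and ("stop", 1087, 1090) in feats
        assert not any(h.feature in ("start", "stop") and h.start >= 2000 for h in hints)

    def test_minus_strand_terminal_hints_swap_ends(self):
        c = AlignmentChain(
            protein_id="p1", seq_id="s1", strand="-", blocks=[(1000, 1090)],
            junctions=[], protein_start=0, protein_end=29, protein_length=29,
        )
        _, hints = classify_evidence([c])
        feats = {(h.feature, h.start, h.end) for h in hints}
        assert ("start", 1087, 1090) in feats and ("stop", 1000, 1003) in feats
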