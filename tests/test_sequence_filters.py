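"""Per-sequence filters: length, deduplication, terminal-X trimming,
consensus-"change" filtering, and the iterative overlap filter."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from phylocurate.errors import AlignmentShapeError, EmptyInputError
from phylocurate.io import AlignedSequence
from phylocurate.seqfilters import (
    FilterThresholds,
    change_percent,
    consensus_sequence,
    dedup_identical,
    filter_by_change,
    filter_min_length,
    filter_min_overlap,
    trim_terminal_x,
)

from conftest import AA20, mk_aln, random_aligned_rows


class TestThresholds:
    def test_defaults_are_the_published_values(self):
        thr = FilterThresholds()
        assert (thr.min_seq_len, thr.x_window, thr.max_change) == (100, 20, 75.0)
        assert (thr.min_overlap, thr.min_nongap_col, thr.min_aln_len) == (20, 4, 50)
        assert (thr.min_taxa, thr.collapse_support) == (35, 50.0)

    def test_validation(self):
        with pytest.raises(ValueError):
            FilterThresholds(min_seq_len=-1)
        with pytest.raises(ValueError):
            FilterThresholds(max_change=101)
        with pytest.raises(ValueError):
            FilterThresholds(change_denominator="both")


class TestMinLength:
    def test_strictly_shorter_than_threshold_removed(self):
        # 99 residues (with interleaved gaps) removed, exactly 100 kept.
        aln = mk_aln(
            "og",
            [
                ("tA", "1", "A" * 99 + "-" * 21),
                ("tB", "2", "C" * 100 + "-" * 20),
                ("tC", "3", "-" * 120),
            ],
        )
        out, rep = filter_min_length(aln, 100)
        assert [m.taxon_id for m in out.members] == ["tB"]
        assert {(r[1], r[3]) for r in rep.removed_sequences} == {
            ("tA", "min_length"),
            ("tC", "min_length"),
        }

    def test_x_counts_toward_length(self):
        aln = mk_aln("og", [("tA", "1", "X" * 50 + "A" * 50 + "-" * 10)])
        out, _ = filter_min_length(aln, 100)
        assert len(out) == 1


class TestDedup:
    def test_same_taxon_identical_after_gap_stripping(self):
        aln = mk_aln(
            "og",
            [("tA", "1", "AC-DE"), ("tA", "2", "ACDE-"), ("tB", "3", "AC-DE")],
        )
        out, rep = dedup_identical(aln)
        assert [m.seq_id for m in out.members] == ["1", "3"]
        assert rep.removed_sequences == [("og", "tA", "2", "duplicate_of:1")]

    def test_cross_taxon_identity_kept_by_default_removed_globally(self):
        aln = mk_aln("og", [("tA", "1", "ACDE"), ("tB", "2", "ACDE")])
        out, _ = dedup_identical(aln)
        assert len(out) == 2
        out_global, _ = dedup_identical(aln, within_taxon=False)
        assert [m.taxon_id for m in out_global.members] == ["tA"]

    def test_three_way_duplicates_leave_exactly_one_and_idempotent(self):
        aln = mk_aln(
            "og",
            [("tA", "1", "ACDE-"), ("tA", "2", "-ACDE"), ("tA", "3", "AC-DE")],
        )
        out, rep = dedup_identical(aln)
        assert [m.seq_id for m in out.members] == ["1"]
        again, rep2 = dedup_identical(out)
        assert again == out and rep2.is_empty()

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_matches_all_pairs_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        # few taxa / short rows so duplicates actually happen
        rows = []
        for i in range(rng.integers(1, 7)):
            chars = "".join(
                "-" if rng.random() < 0.4 else AA20[rng.integers(0, 3)]
                for _ in range(6)
            )
            rows.append((f"t{rng.integers(0, 3)}", f"s{i}", chars))
        aln = mk_aln("og", rows)
        out, _ = dedup_identical(aln)
        # oracle: keep member i iff no earlier member j of same taxon with
        # identical gap-stripped residues
        expect = []
        for i, m in enumerate(aln.members):
            dup = any(
                n.taxon_id == m.taxon_id
                and n.residues.replace("-", "") == m.residues.replace("-", "")
                for n in aln.members[:i]
            )
            if not dup:
                expect.append(m.seq_id)
        assert [m.seq_id for m in out.members] == expect


def oracle_trim(residues: str, window: int) -> str:
    """Independent re-statement of the terminal-X rule: scan the first and
    last `window` residues, take the innermost X, mask through the end;
    repeat until no X remains in either terminal window (fixpoint)."""
    while True:
        res_idx = [i for i, c in enumerate(residues) if c != "-"]
        out = list(residues)
        front = [k for k in range(min(window, len(res_idx))) if residues[res_idx[k]] == "X"]
        if front:
            for k in range(max(front) + 1):
                out[res_idx[k]] = "-"
        back = [
            k
            for k in range(max(0, len(res_idx) - window), len(res_idx))
            if residues[res_idx[k]] == "X"
        ]
        if back:
            for k in range(min(back), len(res_idx)):
                out[res_idx[k]] = "-"
        new = "".join(out)
        if new == residues:
            return new
        residues = new


class TestTrimTerminalX:
    def test_leading_x_masked(self):
        seq = AlignedSequence("tA", "1", "XAAAAAAAAAAAAAAAAAAAAAAAA")
        out, segs = trim_terminal_x(seq)
        assert out.residues == "-" + "A" * 24
        assert segs == [(0, 1)]

    def test_x_outside_window_untouched(self):
        residues = "A" * 20 + "X" + "A" * 179
        seq = AlignedSequence("tA", "1", residues)  # X is residue 21
        out, segs = trim_terminal_x(seq, 20)
        assert out.residues == residues and segs == []

    def test_innermost_x_governs(self):
        # X at residue positions 3 and 15 (1-based): mask residues 1-15.
        chars = list("A" * 40)
        chars[2] = "X"
        chars[14] = "X"
        seq = AlignedSequence("tA", "1", "".join(chars))
        out, segs = trim_terminal_x(seq, 20)
        assert out.residues == "-" * 15 + "A" * 25
        assert segs == [(0, 15)]

    def test_window_counts_residues_not_columns(self):
        # 19 gaps then X: X is residue 1, well inside the window.
        seq = AlignedSequence("tA", "1", "-" * 19 + "X" + "A" * 30)
        out, segs = trim_terminal_x(seq, 20)
        assert out.residues == "-" * 20 + "A" * 30
        assert segs == [(19, 20)]

    def test_both_ends_masked_independently(self):
        seq = AlignedSequence("tA", "1", "XA" + "C" * 40 + "AX")
        out, segs = trim_terminal_x(seq, 20)
        assert out.residues == "-A" + "C" * 40 + "A-"
        assert len(segs) == 2

    def test_exhaustive_x_placements_match_oracle(self):
        # All 1- and 2-X placements on 30-residue strings, with and without
        # interleaved gaps.
        base = "A" * 30
        for i in range(30):
            for j in range(i, 30):
                chars = list(base)
                chars[i] = "X"
                chars[j] = "X"
                for gapped in (False, True):
                    s = "".join(
                        c + ("-" if gapped and k % 3 == 0 else "")
                        for k, c in enumerate(chars)
                    )
                    seq = AlignedSequence("tA", "1", s)
                    out, _ = trim_terminal_x(seq, 20)
                    assert out.residues == oracle_trim(s, 20), (i, j, gapped)

    def test_idempotent(self, rng):
        for _ in range(50):
            chars = [
                "-" if rng.random() < 0.2 else ("X" if rng.random() < 0.1 else "A")
                for _ in range(60)
            ]
            seq = AlignedSequence("tA", "1", "".join(chars))
            once, _ = trim_terminal_x(seq)
            twice, segs = trim_terminal_x(once)
            assert twice.residues == once.residues and segs == []


class TestConsensus:
    def test_plurality_gap_and_tie(self):
        aln = mk_aln(
            "og",
            [("tA", "1", "A-A"), ("tB", "2", "A-A"), ("tC", "3", "A-C"), ("tD", "4", "--C")],
        )
        # col0: A,A,A,- -> A; col1: all gaps -> -; col2: {A,A,C,C} tie -> A
        assert consensus_sequence(aln) == "A-A"

    def test_x_is_eligible(self):
        aln = mk_aln("og", [("tA", "1", "X"), ("tB", "2", "X"), ("tC", "3", "Y")])
        assert consensus_sequence(aln) == "X"

    def test_empty_alignment_rejected(self):
        with pytest.raises(EmptyInputError):
            consensus_sequence(mk_aln("og", []))


class TestChangePercent:
    def test_forced_arithmetic(self):
        cons = "A" * 10
        assert change_percent(AlignedSequence("t", "1", "A" * 10), cons) == 0.0
        assert change_percent(AlignedSequence("t", "1", "C" * 10), cons) == 100.0
        assert change_percent(AlignedSequence("t", "1", "CCCAAAAAAA"), cons) == 30.0

    def test_all_gap_sequence_scores_zero(self):
        assert change_percent(AlignedSequence("t", "1", "----"), "ACDE") == 0.0

    def test_gap_positions_excluded_from_seq_denominator(self):
        # 5 residues, 1 mismatch -> 20% regardless of surrounding gaps
        assert change_percent(AlignedSequence("t", "1", "--CAAAA---"), "AAAAAAAAAA") == 20.0

    def test_alignment_denominator_variant(self):
        value = change_percent(
            AlignedSequence("t", "1", "--CAAAA---"), "AAAAAAAAAA", denominator="alignment"
        )
        assert value == 10.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(AlignmentShapeError):
            change_percent(AlignedSequence("t", "1", "ACD"), "AC")

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_invariant_under_joint_column_permutation(self, seed):
        rng = np.random.default_rng(seed)
        n = 30
        seq_chars = ["-" if rng.random() < 0.3 else AA20[rng.integers(0, 20)] for _ in range(n)]
        cons_chars = [AA20[rng.integers(0, 20)] for _ in range(n)]
        perm = rng.permutation(n)
        a = change_percent(AlignedSequence("t", "1", "".join(seq_chars)), "".join(cons_chars))
        b = change_percent(
            AlignedSequence("t", "1", "".join(seq_chars[i] for i in perm)),
            "".join(cons_chars[i] for i in perm),
        )
        assert a == pytest.approx(b)


class TestFilterByChange:
    def test_threshold_is_strict(self):
        # tB differs from the consensus at 3 of its 4 residues = exactly 75.
        rows = [("t%d" % i, str(i), "AAAA") for i in range(6)]
        rows.append(("tB", "9", "ACCC"))
        aln = mk_aln("og", rows)
        out, rep = filter_by_change(aln, 75.0)
        assert len(out) == 7 and rep.is_empty()

    def test_outlier_removed_with_value_in_reason(self):
        rng = np.random.default_rng(7)
        clean = "".join(AA20[rng.integers(0, 20)] for _ in range(100))
        rows = [(f"t{i}", str(i), clean) for i in range(9)]
        outlier = "".join(AA20[(AA20.index(c) + 1) % 20] for c in clean)  # 100% change
        rows.append(("tZ", "z", outlier))
        aln = mk_aln("og", rows)
        out, rep = filter_by_change(aln, 75.0)
        assert [m.taxon_id for m in out.members] == [f"t{i}" for i in range(9)]
        (og, tax, sid, reason), = rep.removed_sequences
        assert tax == "tZ" and reason.startswith("change:")
        assert float(reason.split(":")[1]) > 75.0

    def test_identical_alignment_untouched(self):
        aln = mk_aln("og", [(f"t{i}", str(i), "ACDEF") for i in range(5)])
        out, rep = filter_by_change(aln)
        assert out == aln and rep.is_empty()

    def test_consensus_from_input_not_recomputed(self):
        # Two opposite outliers: both judged against the ORIGINAL consensus,
        # so both go in one pass.
        rows = [(f"t{i}", str(i), "AAAAAAAA") for i in range(6)]
        rows += [("tX", "x", "CCCCCCCC"), ("tY", "y", "DDDDDDDD")]
        out, rep = filter_by_change(mk_aln("og", rows), 75.0)
        assert len(rep.removed_sequences) == 2


def oracle_overlap_filter(rows: list[str], min_overlap: int) -> list[int]:
    """Explicit simulation of the deletion loop with full recomputation.

    Returns surviving row indices. Independent of the numpy implementation:
    pure-python column counting.
    """
    alive = list(range(len(rows)))
    if len(alive) <= 1:
        return alive

    def ov(a, b):
        return sum(
            1 for x, y in zip(rows[a], rows[b]) if x != "-" and y != "-"
        )

    def nongap(a):
        return sum(1 for c in rows[a] if c != "-")

    while len(alive) > 1:
        failing = [
            i for i in alive
            if any(ov(i, j) < min_overlap for j in alive if j != i)
        ]
        if not failing:
            break
        victim = None
        for i in failing:  # fewest residues; tie -> latest input position
            if (
                victim is None
                or nongap(i) < nongap(victim)
                or (nongap(i) == nongap(victim) and i > victim)
            ):
                victim = i
        alive.remove(victim)
    return alive


class TestMinOverlap:
    def test_overlap_of_exactly_threshold_is_enough(self):
        rows = [("tA", "1", "A" * 20 + "-" * 20), ("tB", "2", "-" * 0 + "C" * 20 + "-" * 20)]
        aln = mk_aln("og", [("tA", "1", "A" * 20 + "-" * 20), ("tB", "2", "C" * 20 + "-" * 20)])
        out, rep = filter_min_overlap(aln, 20)
        assert len(out) == 2 and rep.is_empty()

    def test_nineteen_columns_fails_shorter_deleted_survivor_kept(self):
        aln = mk_aln(
            "og",
            [
                ("tA", "1", "A" * 25 + "-" * 15),  # 25 residues
                ("tB", "2", "-" * 21 + "C" * 19),  # 19 residues, overlap 4...
            ],
        )
        # overlap = columns 21..24 -> 4 < 20: shorter member (tB) deleted,
        # survivor has no partner left and is kept.
        out, rep = filter_min_overlap(aln, 20)
        assert [m.taxon_id for m in out.members] == ["tA"]
        assert rep.removed_sequences == [("og", "tB", "2", "min_overlap")]

    def test_single_member_untouched(self):
        aln = mk_aln("og", [("tA", "1", "A-A")])
        out, rep = filter_min_overlap(aln, 20)
        assert out == aln and rep.is_empty()

    def test_satisfied_alignment_is_fixpoint(self, rng):
        aln = mk_aln("og", random_aligned_rows(rng, 6, 60, gap_prob=0.1))
        out, rep = filter_min_overlap(aln, 20)
        assert out == aln and rep.is_empty()

    def test_tie_breaks_to_latest_input_position(self):
        # Two disjoint equal-length members: both fail, the later one goes
        # first; the survivor is then kept.
        aln = mk_aln("og", [("tA", "1", "A" * 10 + "-" * 10), ("tB", "2", "-" * 10 + "C" * 10)])
        out, rep = filter_min_overlap(aln, 5)
        assert [m.taxon_id for m in out.members] == ["tA"]

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 9))
        cols = int(rng.integers(10, 61))
        rows = random_aligned_rows(rng, n, cols, gap_prob=float(rng.uniform(0.2, 0.8)))
        min_overlap = int(rng.integers(1, 25))
        aln = mk_aln("og", rows)
        out, _ = filter_min_overlap(aln, min_overlap)
        expect = oracle_overlap_filter([r[2] for r in rows], min_overlap)
        assert [m.seq_id for m in out.members] == [rows[i][1] for i in expect]

    def test_idempotent(self, rng):
        for _ in range(20):
            rows = random_aligned_rows(rng, 6, 40, gap_prob=0.5)
            out, _ = filter_min_overlap(mk_aln("og", rows), 10)
            again, rep = filter_min_overlap(out, 10)
            assert again == out and rep.is_empty()
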