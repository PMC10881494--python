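import itertools

import numpy as np
import pytest

from dolphyn.core_io import PeptideKind, ProteinRecord, ValidationError
from dolphyn.design import (
    EpitopeWindow,
    compression_ratio,
    coverage,
    design_library,
    dolphyn_select,
    dolphyn_stitch,
    epitope_records,
    group_shared_epitopes,
    library_stats,
    pepsyn_tile,
    split_stitched,
    tile_library,
)
from dolphyn.synthetic import _random_seq


def prot(seq, pid="p"):
    return ProteinRecord(id=pid, seq=seq)


class TestPepsynTile:
    @pytest.mark.parametrize("L,starts", [
        (56, [0]),
        (84, [0, 28]),
        (100, [0, 28, 44]),   # C-terminal rule: last tile overlaps 40 aa
        (112, [0, 28, 56]),
        (57, [0, 1]),
    ])
    def test_start_layout(self, L, starts):
        tiles = pepsyn_tile(prot("A" * L))
        assert [t.start for t in tiles] == starts
        assert all(len(t.seq) == 56 for t in tiles)
        assert tiles[-1].start + 56 == L

    def test_tiles_cover_every_residue(self):
        rng = np.random.default_rng(0)
        for L in (56, 70, 84, 101, 163, 200):
            p = prot(_random_seq(rng, L))
            covered = set()
            for t in pepsyn_tile(p):
                assert t.seq == p.seq[t.start : t.start + 56]
                covered.update(range(t.start, t.start + 56))
            assert covered == set(range(L))

    def test_no_duplicate_tiles(self):
        for L in range(56, 200):
            starts = [t.start for t in pepsyn_tile(prot("A" * L, "p"))]
            assert len(starts) == len(set(starts))

    def test_short_protein_single_short_tile(self):
        tiles = pepsyn_tile(prot("MKT" * 10))  # 30 aa
        assert len(tiles) == 1
        assert tiles[0].seq == "MKT" * 10
        assert tiles[0].kind is PeptideKind.TILE


def windows_from(probs_by_start, protein):
    return [
        EpitopeWindow(protein.id, s, protein.seq[s : s + 15], p)
        for s, p in probs_by_start.items()
    ]


class TestDolphynSelect:
    def _probs(self, L, assignments, default=0.1):
        probs = [default] * (L - 14)
        for start, p in assignments.items():
            probs[start] = p
        return probs

    def test_greedy_trace(self, prob_by_start):
        p = prot(_random_seq(np.random.default_rng(2), 40))
        model = prob_by_start(self._probs(40, {0: 0.9, 5: 0.8, 20: 0.7}))
        sel = dolphyn_select(p, model)
        assert [(w.start, w.prob) for w in sel] == [(0, 0.9), (20, 0.7)]

    def test_all_below_threshold_empty(self, prob_by_start):
        p = prot("A" * 30)
        assert dolphyn_select(p, prob_by_start([0.5] * 16)) == []  # strict >

    def test_tie_prefers_smaller_start(self, prob_by_start):
        p = prot(_random_seq(np.random.default_rng(3), 40))
        model = prob_by_start(self._probs(40, {3: 0.8, 0: 0.8}))
        sel = dolphyn_select(p, model)
        assert [w.start for w in sel] == [0]

    def test_nonoverlap_invariant_random(self, prob_by_start):
        rng = np.random.default_rng(9)
        for _ in range(30):
            L = int(rng.integers(15, 120))
            p = prot(_random_seq(rng, L))
            sel = dolphyn_select(p, prob_by_start(rng.random(L - 14)))
            for a, b in itertools.combinations(sel, 2):
                assert abs(a.start - b.start) >= 15
            assert all(w.prob > 0.5 for w in sel)
            assert [w.prob for w in sel] == sorted((w.prob for w in sel), reverse=True)
            for w in sel:
                assert w.seq == p.seq[w.start : w.start + 15]

    def test_greedy_equals_brute_force_on_short_proteins(self, prob_by_start):
        """Exhaustive oracle: greedy = lexicographically best non-overlapping set."""
        rng = np.random.default_rng(17)
        grid = np.array([0.0, 0.3, 0.6, 0.9])
        for trial in range(40):
            L = int(rng.integers(15, 61))
            n_win = L - 14
            probs = grid[rng.integers(0, len(grid), n_win)]
            p = prot(_random_seq(rng, L), f"p{trial}")
            got = [(w.start, w.prob) for w in dolphyn_select(p, prob_by_start(probs))]
            best = brute_force_select(probs, threshold=0.5)
            assert got == best

    def test_short_protein_empty(self, prob_by_start):
        assert dolphyn_select(prot("A" * 14), None) == []

    def test_skip_noncanonical_windows(self, prob_by_start):
        seq = "K" * 15 + "X" + "K" * 15  # windows 1..15 contain the X
        p = ProteinRecord("p", seq)
        n_clean = 2  # only windows at starts 0 and 16 avoid the X
        sel = dolphyn_select(p, prob_by_start([0.9] * n_clean), skip_noncanonical=True)
        assert [w.start for w in sel] == [0, 16]


def brute_force_select(probs, threshold=0.5):
    """Enumerate every non-overlapping subset of windows above threshold and
    return the one whose descending (prob, -start) profile is lexicographically
    largest — the definition greedy selection is meant to realize."""
    cand = [(s, p) for s, p in enumerate(probs) if p > threshold]

    def compatible(subset, s):
        return all(abs(s - t) >= 15 for t, _ in subset)

    best = []
    stack = [([], 0)]
    all_subsets = []
    n = len(cand)

    def rec(idx, subset):
        all_subsets.append(list(subset))
        for i in range(idx, n):
            s, p = cand[i]
            if compatible(subset, s):
                subset.append((s, p))
                rec(i + 1, subset)
                subset.pop()

    rec(0, [])

    def key(subset):
        return sorted(((p, -s) for s, p in subset), reverse=True)

    best = max(all_subsets, key=key) if all_subsets else []
    return [(s, p) for p, negs in key(best) for s in [-negs]]


class TestDolphynStitch:
    def _windows(self, n, pid="p"):
        # descending probabilities, starts spaced by 15
        return [EpitopeWindow(pid, 15 * i, "ACDEFGHIKLMNPQR", (100 - i) / 100)
                for i in range(n)]

    @pytest.mark.parametrize("n,expected", [(0, 0), (1, 0), (2, 0), (3, 1),
                                            (4, 1), (5, 1), (6, 2), (8, 2), (9, 3)])
    def test_peptide_count_floor_n_over_3(self, n, expected):
        assert len(dolphyn_stitch(self._windows(n))) == expected

    def test_rank_interleaving_n6(self):
        ws = self._windows(6)
        peps = dolphyn_stitch(ws)
        assert [w.prob for w in peps[0].members] == [ws[0].prob, ws[2].prob, ws[4].prob]
        assert [w.prob for w in peps[1].members] == [ws[1].prob, ws[3].prob, ws[5].prob]

    def test_n5_uses_top3_only(self):
        ws = self._windows(5)
        (pep,) = dolphyn_stitch(ws)
        assert [w.prob for w in pep.members] == [w.prob for w in ws[:3]]

    def test_sequence_layout_and_split(self):
        ws = [EpitopeWindow("p", 0, "A" * 15, 0.9),
              EpitopeWindow("p", 15, "C" * 15, 0.8),
              EpitopeWindow("p", 30, "E" * 15, 0.7)]
        (pep,) = dolphyn_stitch(ws)
        assert pep.seq == "A" * 15 + "GGGGS" + "C" * 15 + "GGGGS" + "E" * 15
        assert len(pep.seq) == 55
        assert split_stitched(pep.seq) == ("A" * 15, "C" * 15, "E" * 15)


class TestGrouping:
    def _sel(self, pid, seqs, base_prob=0.9):
        return [EpitopeWindow(pid, 15 * i, s, base_prob - i / 100)
                for i, s in enumerate(seqs)]

    def test_identical_proteins_one_group(self):
        seqs = ["A" * 15, "C" * 15, "E" * 15]
        groups = group_shared_epitopes({"p1": self._sel("p1", seqs),
                                        "p2": self._sel("p2", seqs)})
        assert len(groups) == 1
        assert groups[0].protein_ids == ("p1", "p2")

    def test_partial_sharing_stays_separate(self):
        g = group_shared_epitopes({
            "p1": self._sel("p1", ["A" * 15, "C" * 15, "E" * 15]),
            "p2": self._sel("p2", ["A" * 15, "C" * 15, "F" * 15]),
        })
        assert len(g) == 2
        # but the flat epitope library deduplicates the shared 15-mers
        records = epitope_records({
            "p1": self._sel("p1", ["A" * 15, "C" * 15, "E" * 15]),
            "p2": self._sel("p2", ["A" * 15, "C" * 15, "F" * 15]),
        })
        assert len(records) == 4
        shared = [r for r in records if r.seq == "A" * 15]
        assert shared[0].source_protein_ids == ("p1", "p2")

    def test_no_sharing_groups_equal_proteins(self):
        g = group_shared_epitopes({
            "p1": self._sel("p1", ["A" * 15]),
            "p2": self._sel("p2", ["C" * 15]),
        })
        assert len(g) == 2


class TestLibraryStats:
    def test_pilot_coverage_arithmetic(self):
        assert coverage(23745, 56, 750776) == pytest.approx(1.77, abs=0.005)
        assert coverage(5266, 45, 750776) == pytest.approx(0.32, abs=0.005)
        assert compression_ratio(5266, 23745) == pytest.approx(0.22, abs=0.005)

    def test_stats_from_records(self):
        rng = np.random.default_rng(1)
        proteins = [prot(_random_seq(rng, 100), f"p{i}") for i in range(3)]
        tiles, stats = tile_library(proteins)
        assert stats.n_tiles == 9
        assert stats.total_aa == 300
        assert stats.coverage == pytest.approx(9 * 56 / 300)
        assert stats.n_proteins_skipped == 0


class TestDesignLibrary:
    def test_end_to_end_with_trained_model(self, small_model):
        from dolphyn.synthetic import FixtureSpec, make_proteome

        proteins, truth = make_proteome(FixtureSpec(seed=2, n_proteins=8))
        peptides, stats, groups = design_library(proteins, small_model)
        assert peptides, "separable fixture should yield stitched peptides"
        for pep in peptides:
            assert len(pep.seq) == 55
            assert pep.kind is PeptideKind.STITCHED
            a, b, c = split_stitched(pep.seq)
            src = {p.id: p.seq for p in proteins}
            joined = "|".join(src[pid] for pid in pep.source_protein_ids)
            for member in (a, b, c):
                assert member in joined

    def test_threshold_monotonicity(self, small_model):
        from dolphyn.synthetic import FixtureSpec, make_proteome

        proteins, _ = make_proteome(FixtureSpec(seed=3, n_proteins=6))
        sizes = []
        for thr in (0.3, 0.5, 0.7, 0.9):
            peptides, _, _ = design_library(proteins, small_model, threshold=thr)
            sizes.append(len(peptides))
        assert sizes == sorted(sizes, reverse=True)
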