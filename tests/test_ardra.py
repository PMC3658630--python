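"""Tests for in-silico ARDRA: amplicon finding, digestion, gel model,
Dice/UPGMA clustering and OTU assignment."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ardrapipe import (assign_otus, dice_similarity, digest,
                       distance_matrix_from_patterns, find_amplicon,
                       to_band_pattern, upgma)
from ardrapipe.ardra import (AmpliconNotFoundError, DistanceMatrix,
                             FragmentSet, PrimerPair, reverse_complement)

dna = st.text(alphabet="ACGT", min_size=1, max_size=300)


class TestFindAmplicon:
    def test_absent_primers_raise(self):
        with pytest.raises(AmpliconNotFoundError):
            find_amplicon("ACGT" * 50, PrimerPair("TTTTTT", "CCCCCC"))

    def test_degenerate_forward_matching(self):
        # M = A or C: "ACM" must match ACA and ACC but never ACG
        primers = PrimerPair(forward="ACM", reverse="GGG")
        rev_site = reverse_complement("GGG")  # CCC
        for hit in ("ACA", "ACC"):
            amp = find_amplicon("TT" + hit + "TTTT" + rev_site + "TT", primers)
            assert amp.startswith(hit)
        with pytest.raises(AmpliconNotFoundError):
            find_amplicon("TT" + "ACG" + "TTTT" + rev_site + "TT", primers)

    def test_constructed_offsets(self):
        """Forward site at offset 10, reverse site ending at 460 ->
        an amplicon of length 450 starting at offset 10."""
        rng = np.random.default_rng(0)
        bases = np.array(list("ACGT"))
        primers = PrimerPair(forward="AGAGTTTGAT", reverse="TACGGCTACC")
        rev_site = reverse_complement(primers.reverse)
        seq = list("T" * 600)
        # keep the random filler free of accidental primer hits
        seq = list("".join(rng.choice(["T", "G"], size=600)))
        seq[10:20] = primers.forward
        seq[450:460] = rev_site
        amp = find_amplicon("".join(seq), primers)
        assert len(amp) == 450
        assert amp.startswith(primers.forward)
        assert amp.endswith(rev_site)

    def test_reverse_site_before_forward_rejected(self):
        primers = PrimerPair(forward="AAAAAA", reverse="CCCCCC")
        rev_site = reverse_complement(primers.reverse)  # GGGGGG
        seq = "TT" + rev_site + "TTTT" + primers.forward + "TT"
        with pytest.raises(AmpliconNotFoundError, match="before"):
            find_amplicon(seq, primers)

    def test_leftmost_forward_match_wins(self):
        primers = PrimerPair(forward="AAAA", reverse="CCCC")
        seq = "T" + "AAAA" + "TT" + "AAAA" + "TTT" + "GGGG" + "T"
        amp = find_amplicon(seq, primers)
        assert len(amp) == len(seq) - 2  # from offset 1 to the site end


class TestDigest:
    def test_no_site_single_fragment(self):
        frag = digest("ATATATAT")
        assert frag.fragment_lengths == (8,)

    @pytest.mark.parametrize("seq, expected", [
        ("AAGGCCTT", (4, 4)),          # one GG^CC cut
        ("GGCCGGCC", (2, 4, 2)),       # sites at 0 and 4
        ("GGCC", (2, 2)),
        ("AGGCCGGCCT", (3, 4, 3)),
    ])
    def test_haeiii_hand_examples(self, seq, expected):
        assert digest(seq).fragment_lengths == expected

    def test_overlapping_sites_all_counted(self):
        # "AAA" occurs at 0 and 1 in "AAAA": cuts after offset 1 -> 1 and 2
        frag = digest("AAAA", recognition_site="AAA", cut_offset=1)
        assert frag.fragment_lengths == (1, 1, 2)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            digest("")

    @given(seq=dna, offset=st.integers(0, 4))
    @settings(max_examples=200, deadline=None)
    def test_length_conservation(self, seq, offset):
        frag = digest(seq, "GGCC", offset)
        assert sum(frag.fragment_lengths) == len(seq)
        assert all(l >= 1 for l in frag.fragment_lengths)


class TestBandPattern:
    def test_everything_below_detection_floor(self, pattern_factory):
        assert pattern_factory([10, 30, 59]).bands == frozenset()

    def test_identical_lengths_comigrate(self, pattern_factory):
        assert len(pattern_factory([100, 100, 300]).bands) == 2

    def test_log_tolerance_controls_comigration(self, pattern_factory):
        # delta log10(102/100) ~ 0.0086: one band at 0.01, two at 0.005
        assert len(pattern_factory([100, 102], tol=0.01).bands) == 1
        assert len(pattern_factory([100, 102], tol=0.005).bands) == 2

    def test_identical_fragments_give_identical_patterns(self, pattern_factory):
        assert pattern_factory([80, 200, 350]) == pattern_factory([350, 80, 200])


class TestDice:
    def test_identical_patterns(self, pattern_factory):
        p = pattern_factory([100, 200, 400])
        assert dice_similarity(p, p) == 1.0

    def test_disjoint_patterns(self, pattern_factory):
        assert dice_similarity(pattern_factory([100, 200]),
                               pattern_factory([400, 800])) == 0.0

    def test_partial_overlap_hand_value(self, pattern_factory):
        # {100, 200, 400} vs {200, 400, 800}: 2*2/(3+3)
        p1 = pattern_factory([100, 200, 400])
        p2 = pattern_factory([200, 400, 800])
        assert dice_similarity(p1, p2) == pytest.approx(2 / 3)

    def test_both_empty_warns_and_returns_one(self, pattern_factory):
        e1, e2 = pattern_factory([10]), pattern_factory([20])
        with pytest.warns(UserWarning, match="empty"):
            assert dice_similarity(e1, e2) == 1.0

def test_dice_bounds_and_symmetry_property(pattern_factory):
    rng = np.random.default_rng(42)
    for _ in range(200):
        l1 = rng.integers(60, 2000, size=rng.integers(1, 8)).tolist()
        l2 = rng.integers(60, 2000, size=rng.integers(1, 8)).tolist()
        p1, p2 = pattern_factory(l1), pattern_factory(l2)
        s = dice_similarity(p1, p2)
        assert 0.0 <= s <= 1.0
        assert s == dice_similarity(p2, p1)
        assert dice_similarity(p1, p1) == 1.0


def brute_force_average_linkage(labels, matrix):
    """Definitional UPGMA oracle: at every step recompute the mean of all
    original pairwise distances across each cluster pair."""
    idx = {lab: i for i, lab in enumerate(labels)}
    clusters = {lab: [lab] for lab in labels}
    merges = []
    while len(clusters) > 1:
        keys = sorted(clusters)
        best = None
        for a, b in itertools.combinations(keys, 2):
            d = np.mean([matrix[idx[x], idx[y]]
                         for x in clusters[a] for y in clusters[b]])
            cand = (d, a, b)
            if best is None or cand < best:
                best = cand
        d, a, b = best
        merges.append((frozenset(clusters[a]) | frozenset(clusters[b]), d / 2))
        clusters[min(a, b)] = clusters.pop(a) + clusters.pop(b)
    return merges


def tree_merges(dendrogram):
    """(leaf set, height) for every internal node of a dendrogram."""
    out = []

    def walk(node):
        if not node.is_leaf:
            out.append((frozenset(node.leaves()), node.height))
            for c in node.children:
                walk(c)

    walk(dendrogram.root)
    return sorted(out, key=lambda t: (t[1], sorted(t[0])))


def random_distance_matrix(rng, n):
    v = rng.random((n, n))
    v = (v + v.T) / 2
    np.fill_diagonal(v, 0.0)
    labels = tuple(f"L{i}" for i in range(n))
    return DistanceMatrix(labels=labels, values=v)


class TestUPGMA:
    def test_two_leaves_join_at_half_distance(self):
        dm = DistanceMatrix(labels=("A", "B"),
                            values=np.array([[0, 0.4], [0.4, 0]]))
        tree = upgma(dm)
        assert tree.root.height == pytest.approx(0.2)
        assert sorted(tree.leaves()) == ["A", "B"]

    def test_three_leaf_hand_example(self):
        # d(A,B)=0.2, d(A,C)=d(B,C)=0.6: (A,B) join at 0.1, C at 0.3
        v = np.array([[0, 0.2, 0.6], [0.2, 0, 0.6], [0.6, 0.6, 0]])
        tree = upgma(DistanceMatrix(labels=("A", "B", "C"), values=v))
        merges = tree_merges(tree)
        assert merges[0] == (frozenset({"A", "B"}), pytest.approx(0.1))
        assert merges[1][0] == frozenset({"A", "B", "C"})
        assert merges[1][1] == pytest.approx(0.3)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            n = int(rng.integers(3, 7))
            dm = random_distance_matrix(rng, n)
            tree = upgma(dm)
            oracle = brute_force_average_linkage(dm.labels, dm.values)
            got = tree_merges(tree)
            want = sorted(oracle, key=lambda t: (t[1], sorted(t[0])))
            for (gs, gh), (ws, wh) in zip(got, want):
                assert gs == ws
                assert gh == pytest.approx(wh)

    def test_ultrametricity(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            dm = random_distance_matrix(rng, 8)
            tree = upgma(dm)

            def depths(node, acc):
                if node.is_leaf:
                    return [acc]
                return [d for c in node.children
                        for d in depths(c, acc + node.height - c.height)]

            d = depths(tree.root, 0.0)
            assert max(d) - min(d) < 1e-9

    def test_invalid_input_rejected(self):
        with pytest.raises(ValueError):
            DistanceMatrix(labels=("A", "B"),
                           values=np.array([[0, 1], [0.5, 0]]))
        with pytest.raises(ValueError):
            DistanceMatrix(labels=("A", "B"),
                           values=np.array([[0, -0.2], [-0.2, 0]]))


class TestAssignOTUs:
    def test_identical_patterns_one_otu(self, pattern_factory):
        pats = {f"c{i}": pattern_factory([100, 250]) for i in range(5)}
        assert assign_otus(pats).n_otus == 1

    def test_disjoint_patterns_one_otu_each(self, pattern_factory):
        pats = {f"c{i}": pattern_factory([100 * (i + 1) + 60]) for i in range(5)}
        assert assign_otus(pats).n_otus == 5

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="no band patterns"):
            assign_otus({})

    def test_exact_mode_matches_pattern_identity(self, pattern_factory):
        pats = {
            "a1": pattern_factory([100, 200]),
            "a2": pattern_factory([200, 100]),
            "b1": pattern_factory([100, 300]),
        }
        res = assign_otus(pats, mode="exact")
        assert res.assignments["a1"] == res.assignments["a2"]
        assert res.assignments["a1"] != res.assignments["b1"]

    def test_cut_mode_matches_brute_force_oracle(self, pattern_factory):
        rng = np.random.default_rng(3)
        for trial in range(10):
            pats = {
                f"c{i:02d}": pattern_factory(
                    rng.integers(60, 1500, size=rng.integers(2, 6)).tolist())
                for i in range(12)
            }
            threshold = 0.9
            res = assign_otus(pats, mode="cut", threshold=threshold)
            dm = distance_matrix_from_patterns(pats)
            merges = brute_force_average_linkage(dm.labels, dm.values)
            # oracle clusters: replay merges whose height <= cut height
            cut_h = (1 - threshold) / 2
            groups = {lab: frozenset([lab]) for lab in dm.labels}
            for members, h in merges:
                if h <= cut_h + 1e-12:
                    for m in members:
                        groups[m] = members
            oracle_parts = {frozenset(g) for g in groups.values()}
            got_parts = {frozenset(m) for m in res.otus().values()}
            assert got_parts == oracle_parts

    def test_lower_threshold_never_increases_otus(self, pattern_factory):
        rng = np.random.default_rng(4)
        pats = {
            f"c{i:02d}": pattern_factory(
                rng.integers(60, 1500, size=rng.integers(2, 6)).tolist())
            for i in range(15)
        }
        counts = [assign_otus(pats, mode="cut", threshold=t).n_otus
                  for t in (1.0, 0.95, 0.9, 0.8, 0.6, 0.4, 0.2, 0.0)]
        assert counts == sorted(counts, reverse=True)


def test_ground_truth_recovery(sequenced_community):
    """With taxa divergent enough for distinct band patterns, exact-pattern
    OTUs equal the taxa observed in a sampled library."""
    from ardrapipe import sample_clone_library

    taxon_patterns = {}
    for t in sequenced_community.taxa:
        amp = find_amplicon(t.ref_sequence)
        taxon_patterns[t.taxon_id] = to_band_pattern(digest(amp))
    # precondition of the check: the fixture's taxa are all distinguishable
    assert len({p.bands for p in taxon_patterns.values()}) == len(taxon_patterns)

    lib = sample_clone_library(sequenced_community, 80, "F1", "IB", seed=9)
    pats = {cid: taxon_patterns[taxon] for cid, taxon, _ in lib.clones}
    observed_taxa = {taxon for _, taxon, _ in lib.clones}
    assert assign_otus(pats).n_otus == len(observed_taxa)
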