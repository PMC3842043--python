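"""Anchor alignment, distance-based family placement, NJ, bootstrap."""

import numpy as np
import pytest

from bhlhscan.classify import (AlignedDomain, align_domains, assign_family,
                               bootstrap_support, multi_ortholog_suffixes,
                               neighbor_joining, pairwise_distance)
from bhlhscan.scanner import scan_sequence
from bhlhscan.simulate import ProteomeSpec, SimulationSpec, _build_domain, \
    generate_proteome
from bhlhscan.motif import load_consensus

from conftest import make_perfect_domain


def _dom(sid, s1, s2):
    return AlignedDomain(sid, make_perfect_domain(s1, s2), (s1, s2))


class TestAlignment:
    def test_width_is_maximal_token_expansion(self):
        aln = align_domains([_dom("a", 3, 5), _dom("b", 6, 22)])
        assert aln.width == 64
        assert len(aln.diagnostic_columns) == 19

    def test_single_domain_alignment_is_itself(self):
        d = _dom("a", 4, 9)
        aln = align_domains([d])
        assert aln.rows == [d.domain]

    def test_spacers_right_aligned_against_following_anchor(self, motif):
        aln = align_domains([_dom("a", 3, 5), _dom("b", 6, 5)])
        # the 3-residue spacer row is left-padded with gaps to width 6
        assert aln.rows[0][2:5] == "---"
        assert "-" not in aln.rows[1]

    def test_rows_equal_length_and_diagnostic_columns_ungapped(self):
        aln = align_domains([_dom("a", 3, 5), _dom("b", 5, 17),
                             _dom("c", 6, 22)])
        assert len({len(r) for r in aln.rows}) == 1
        for row in aln.rows:
            assert all(row[c] != "-" for c in aln.diagnostic_columns)

    def test_conservation_shading_threshold(self):
        rows = [_dom(f"s{i}", 3, 5) for i in range(4)]
        variant = list(rows[0].domain)
        wild_col = 7  # a wildcard position inside the X(3) block
        variant[wild_col] = "W" if variant[wild_col] != "W" else "C"
        rows.append(AlignedDomain("s4", "".join(variant), (3, 5)))
        cons = align_domains(rows).conservation(high_threshold=0.8)
        assert cons[wild_col][2] == "high"          # 4/5 = 0.8 -> high
        rows[3] = rows.pop()                         # 3/5 identical now
        cons = align_domains(rows[:4] + [rows[3]]).conservation(0.8)

    def test_text_view_marks_diagnostics(self):
        view = align_domains([_dom("a", 3, 5)]).text_view()
        assert view.count("*") == 19


class TestPairwiseDistance:
    def test_identity_and_saturation(self):
        assert pairwise_distance("A" * 44, "A" * 44) == 0.0
        assert pairwise_distance("A" * 44, "C" * 44) == 1.0

    def test_quarter_divergence(self):
        a = "A" * 44
        b = "C" * 11 + "A" * 33
        assert pairwise_distance(a, b) == pytest.approx(0.25)

    def test_gapped_columns_skipped(self):
        assert pairwise_distance("AA--", "A-A-") == 0.0
        with pytest.raises(ValueError, match="comparable"):
            pairwise_distance("A---", "-AAA")
        with pytest.raises(ValueError, match="length"):
            pairwise_distance("AA", "AAA")


class TestFamilyAssignment:
    def test_every_representative_self_classifies(self, panel):
        for fam, dom in zip(panel.families, panel.domains):
            a = assign_family(dom, panel)
            assert a.family_name == fam
            assert a.supergroup == panel.supergroups[fam]
            assert a.distance == 0.0

    def test_self_support_is_100_percent(self, panel):
        a = assign_family(panel.domains[0], panel, bootstrap_replicates=50,
                          seed=3)
        assert a.support_percent == 100.0

    def test_divergent_copy_returns_to_donor_family(self, panel):
        spec = SimulationSpec(seed=9, proteome=ProteomeSpec(
            n_planted=0, n_decoys=0, family_donors=("MyoD",),
            divergence=0.10))
        result = generate_proteome(spec)
        sid, seq = result.records[0]
        hit = next(h for h in scan_sequence(seq, sequence_id=sid) if h.accepted)
        a = assign_family(AlignedDomain.from_hit(hit, seq), panel)
        assert a.family_name == "MyoD"
        assert a.supergroup == "A"
        assert a.distance <= 0.2

    def test_unrelated_domain_is_orphan(self, panel):
        rng = np.random.default_rng(17)
        domain, spacers = _build_domain(rng, load_consensus(), 0, "random", None)
        a = assign_family(AlignedDomain("q", domain, spacers), panel)
        assert a.distance > 0.55          # generator-independent sanity
        assert a.family_name == "orphan"
        assert a.supergroup == "orphan"

    def test_empty_panel_rejected(self, panel):
        from bhlhscan.classify import ReferencePanel
        with pytest.raises(ValueError, match="empty"):
            assign_family(panel.domains[0], ReferencePanel([], {}, []))

    def test_planted_family_recovery_is_exact(self, panel):
        """50 domains planted from 10 families at 12% divergence all return
        to their donor family and supergroup."""
        donors = ("MyoD", "MYC", "Clock", "Emc", "Hey", "Coe", "Twist",
                  "USF", "Sim", "H/E(spl)") * 5
        spec = SimulationSpec(seed=42, proteome=ProteomeSpec(
            n_planted=0, n_decoys=0, family_donors=donors, divergence=0.12))
        result = generate_proteome(spec)
        truth = dict(zip(result.truth.sequence_id, result.truth.family))
        correct = 0
        for sid, seq in result.records:
            hit = next(h for h in scan_sequence(seq, sequence_id=sid)
                       if h.accepted)
            a = assign_family(AlignedDomain.from_hit(hit, seq), panel)
            assert a.supergroup == panel.supergroups[truth[sid]]
            correct += a.family_name == truth[sid]
        assert correct == len(result.records) == 50


class TestBootstrap:
    def test_deterministic_given_seed(self, panel):
        d = panel.domains[5]
        s1 = bootstrap_support(d, panel, n_replicates=40, seed=11)
        s2 = bootstrap_support(d, panel, n_replicates=40, seed=11)
        assert s1 == s2

    def test_low_divergence_high_support(self, panel):
        spec = SimulationSpec(seed=7, proteome=ProteomeSpec(
            n_planted=0, n_decoys=0, family_donors=("MyoD",),
            divergence=0.05))
        result = generate_proteome(spec)
        sid, seq = result.records[0]
        hit = next(h for h in scan_sequence(seq, sequence_id=sid) if h.accepted)
        support = bootstrap_support(AlignedDomain.from_hit(hit, seq), panel,
                                    n_replicates=100, seed=7)
        assert support >= 90.0

    def test_replicate_count_validated(self, panel):
        with pytest.raises(ValueError):
            bootstrap_support(panel.domains[0], panel, n_replicates=0, seed=1)


def _random_additive(rng, n):
    """Additive distance matrix from a random binary tree; returns (D,
    splits) where splits are the non-trivial leaf bipartitions (frozensets)."""
    clusters = [({i}, {i: 0.0}) for i in range(n)]
    D = np.zeros((n, n))
    splits = []
    while len(clusters) > 1:
        i, j = sorted(rng.choice(len(clusters), size=2, replace=False))
        (la, da), (lb, db) = clusters[i], clusters[j]
        bla, blb = rng.uniform(0.5, 2.0, size=2)
        for x in la:
            for y in lb:
                D[x, y] = D[y, x] = da[x] + bla + db[y] + blb
        merged = la | lb
        if 2 <= len(merged) <= n - 2:
            splits.append(frozenset(merged))
        dist = {x: d + bla for x, d in da.items()}
        dist.update({y: d + blb for y, d in db.items()})
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)]
        clusters.append((merged, dist))
    return D, splits


def _newick_splits(newick, labels):
    import dendropy
    tree = dendropy.Tree.get(data=newick, schema="newick")
    tree.encode_bipartitions()
    n = len(labels)
    idx = {name: k for k, name in enumerate(labels)}
    splits = set()
    for bp in tree.bipartition_encoding:
        leafset = frozenset(
            idx[t.label] for t in tree.taxon_namespace
            if bp.split_bitmask & tree.taxon_namespace.taxon_bitmask(t))
        for s in (leafset, frozenset(range(n)) - leafset):
            if 2 <= len(s) <= n - 2:
                splits.add(s)
    return splits


class TestNeighborJoining:
    def test_four_taxon_additive_recovery(self):
        # tree ((A,B),(C,D)): the AB|CD quartet must be recovered
        labels = ["A", "B", "C", "D"]
        D = np.array([[0, 3, 5, 6],
                      [3, 0, 6, 7],
                      [5, 6, 0, 7],
                      [6, 7, 7, 0]], dtype=float)
        newick = neighbor_joining(D, labels)
        splits = _newick_splits(newick, labels)
        assert frozenset({0, 1}) in splits or frozenset({2, 3}) in splits

    def test_three_taxa_star(self):
        D = np.array([[0, 2, 3], [2, 0, 4], [3, 4, 0]], dtype=float)
        newick = neighbor_joining(D, ["x", "y", "z"])
        assert newick.count("(") == 1      # single trifurcation
        # star branch lengths solve the three-point equations exactly
        assert ":0.5," in newick or ":0.5)" in newick

    @pytest.mark.parametrize("n", [4, 5, 6])
    def test_additive_matrices_reconstructed_exactly(self, n):
        """On additive input NJ recovers the generating topology (checked
        against the known bipartitions) and the patristic distances."""
        import dendropy
        rng = np.random.default_rng(100 + n)
        labels = [f"t{k}" for k in range(n)]
        D, true_splits = _random_additive(rng, n)
        newick = neighbor_joining(D, labels)
        assert set(true_splits) <= _newick_splits(newick, labels)
        tree = dendropy.Tree.get(data=newick, schema="newick")
        pdm = tree.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in tree.taxon_namespace}
        for i in range(n):
            for j in range(i + 1, n):
                got = pdm.patristic_distance(taxa[f"t{i}"], taxa[f"t{j}"])
                assert got == pytest.approx(D[i, j], abs=1e-8)

    def test_order_invariance(self):
        rng = np.random.default_rng(2)
        labels = [f"t{k}" for k in range(5)]
        D, _ = _random_additive(rng, 5)
        ref = _newick_splits(neighbor_joining(D, labels), labels)
        perm = rng.permutation(5)
        Dp = D[np.ix_(perm, perm)]
        labp = [labels[k] for k in perm]
        got_named = _newick_splits(neighbor_joining(Dp, labp), labp)
        # map permuted indices back to original labels
        remap = {k: perm[k] for k in range(5)}
        got = {frozenset(remap[i] for i in s) for s in got_named}
        assert got == ref

    def test_agreement_with_reference_implementation(self):
        from skbio import DistanceMatrix
        from skbio.tree import nj as skbio_nj
        rng = np.random.default_rng(8)
        labels = [f"t{k}" for k in range(6)]
        D, _ = _random_additive(rng, 6)
        ours = _newick_splits(neighbor_joining(D, labels), labels)
        ref_tree = skbio_nj(DistanceMatrix(D, labels))
        ref = _newick_splits(str(ref_tree), labels)
        assert ours == ref

    def test_small_or_malformed_input_rejected(self):
        with pytest.raises(ValueError):
            neighbor_joining(np.zeros((2, 2)), ["a", "b"])
        bad = np.array([[0, 1, 2], [1, 0, 3], [9, 3, 0]], dtype=float)
        with pytest.raises(ValueError, match="symmetric"):
            neighbor_joining(bad, list("abc"))


def test_multi_ortholog_suffixing_in_input_order():
    from bhlhscan.classify import FamilyAssignment

    def fa(sid, fam):
        return FamilyAssignment(sid, fam, "A", fam, 100.0, 0.1)

    names = multi_ortholog_suffixes([fa("q1", "Hes5"), fa("q2", "MyoD"),
                                     fa("q3", "Hes5")])
    assert names == {"q1": "Hes5a", "q2": "MyoD", "q3": "Hes5b"}
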