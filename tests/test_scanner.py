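"""Motif scanner: placements, mismatch counting, segmentation, binding."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bhlhscan import bruteforce
from bhlhscan.motif import load_consensus
from bhlhscan.scanner import (count_mismatches, diagnose_binding, hits_table,
                              scan_proteome, scan_sequence, segment_hit)
from bhlhscan.simulate import ProteomeSpec, SimulationSpec, generate_proteome

from conftest import PERFECT_DOMAIN, make_perfect_domain


def _mutate(seq: str, positions, residue="G") -> str:
    out = list(seq)
    for p in positions:
        out[p] = residue
    return "".join(out)


class TestScanSequence:
    def test_perfect_minimal_domain(self):
        hits = scan_sequence(PERFECT_DOMAIN)
        assert len(hits) == 1
        h = hits[0]
        assert (h.start, h.end) == (0, 44)
        assert h.spacer_lengths == (3, 5)
        assert h.mismatch_count == 0
        assert h.accepted
        assert all(h.site_matches)

    def test_ten_mismatches_rejected(self, motif):
        # diagnostic sites 1,2,4,5,7,9,10,12,14,15 (1-based ranks) -> G
        offsets = motif.diagnostic_offsets(3, 5)
        ranks = [0, 1, 3, 4, 6, 8, 9, 11, 13, 14]
        seq = _mutate(PERFECT_DOMAIN, [offsets[r] for r in ranks])
        hits = scan_sequence(seq)
        best = min(h.mismatch_count for h in hits)
        assert best == 10
        assert not any(h.accepted for h in hits)

    def test_too_short_and_empty_sequences(self):
        assert scan_sequence("GGGG") == []
        assert scan_sequence("") == []

    @pytest.mark.parametrize("n_bad,expected", [(8, True), (9, True), (10, False)])
    def test_acceptance_boundary(self, motif, n_bad, expected):
        offsets = motif.diagnostic_offsets(3, 5)
        seq = _mutate(PERFECT_DOMAIN, [offsets[r] for r in range(n_bad)])
        assert bruteforce.min_mismatches(seq) == n_bad
        hits = scan_sequence(seq)
        assert any(h.accepted for h in hits) is expected

    def test_ambiguity_codes_always_mismatch(self, motif):
        offsets = motif.diagnostic_offsets(3, 5)
        for letter in "BZXU*":
            seq = _mutate(PERFECT_DOMAIN, [offsets[0]], residue=letter)
            assert min(h.mismatch_count for h in scan_sequence(seq)) == 1

    def test_embedded_domain_found_at_correct_span(self):
        seq = "M" * 30 + make_perfect_domain(4, 12) + "W" * 25
        accepted = [h for h in scan_sequence(seq) if h.accepted]
        assert len(accepted) == 1
        h = accepted[0]
        assert (h.start, h.end) == (30, 30 + 36 + 4 + 12)
        assert h.spacer_lengths == (4, 12)
        assert h.mismatch_count == 0

    @settings(derandomize=True, deadline=None, max_examples=40)
    @given(st.text(alphabet="ACDEFGHIKLMNPQRSTVWYXBZ", min_size=44, max_size=80),
           st.integers(0, 2**31 - 1))
    def test_oracle_equivalence_on_short_sequences(self, seq, _):
        """The vectorised scanner's best mismatch count equals exhaustive
        enumeration over every (start, spacer1, loop) placement."""
        hits = scan_sequence(seq)
        oracle = bruteforce.min_mismatches(seq)
        assert min(h.mismatch_count for h in hits) == oracle

    def test_mutation_monotonicity(self, motif):
        """Mutating a matching diagnostic residue never decreases the
        mismatch count of that placement."""
        rng = np.random.default_rng(5)
        seq = ("".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=20))
               + make_perfect_domain(5, 9)
               + "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=20)))
        h = min(scan_sequence(seq), key=lambda h: h.mismatch_count)
        s1, s2 = h.spacer_lengths
        offsets = motif.diagnostic_offsets(s1, s2)
        for rank, matched in enumerate(h.site_matches):
            if not matched:
                continue
            mutated = _mutate(seq, [h.start + offsets[rank]])
            new = bruteforce.placement_mismatches(mutated, h.start, s1, s2)
            assert new >= h.mismatch_count

    def test_overlap_suppression_keeps_distinct_domains(self):
        two = make_perfect_domain(3, 5) + "PG" * 6 + make_perfect_domain(6, 22)
        accepted = [h for h in scan_sequence(two) if h.accepted]
        assert len(accepted) == 2
        assert accepted[0].spacer_lengths == (3, 5)
        assert accepted[1].spacer_lengths == (6, 22)


class TestCountMismatches:
    def test_explicit_placements(self, motif):
        perfect = {i: sorted(motif.tokens[i].allowed_residues)[0]
                   for i in motif.diagnostic_indices}
        assert count_mismatches(perfect) == 0

        alpha_idx = next(i for i in motif.diagnostic_indices
                         if motif.tokens[i].allowed_residues == frozenset("ILV"))
        one_off = {**perfect, alpha_idx: "M"}   # M not in {I, L, V}
        assert count_mismatches(one_off) == 1

        all_g = {i: "G" for i in motif.diagnostic_indices}
        assert count_mismatches(all_g) == 19

    def test_incomplete_placement_rejected(self, motif):
        with pytest.raises(ValueError, match="cover"):
            count_mismatches({motif.diagnostic_indices[0]: "K"})


class TestSegmentation:
    def test_minimal_domain_region_lengths(self):
        h = scan_sequence(PERFECT_DOMAIN)[0]
        regions = segment_hit(h)
        lengths = {name: b - a for name, (a, b) in regions.items()}
        assert lengths == {"basic": 12, "helix1": 9, "loop": 5, "helix2": 18}

    @pytest.mark.parametrize("s1,s2", [(3, 5), (4, 13), (6, 22)])
    def test_regions_tile_the_hit_exactly(self, s1, s2):
        h = next(h for h in scan_sequence(make_perfect_domain(s1, s2))
                 if h.accepted)
        regions = segment_hit(h)
        assert regions["loop"][1] - regions["loop"][0] == s2
        spans = sorted(regions.values())
        assert spans[0][0] == h.start and spans[-1][1] == h.end
        for (_, end), (start, _) in zip(spans, spans[1:]):
            assert end == start


class TestBindingDiagnosis:
    def test_perfect_hit_binds_ebox(self):
        h = scan_sequence(PERFECT_DOMAIN)[0]
        assert h.glu9_present and h.arg12_present
        assert diagnose_binding(h) == "E-box-binder"

    def test_glutamate_loss_abolishes_binding(self, motif):
        glu_pos = motif.token_offsets(3, 5)[motif.glu_token]
        seq = _mutate(PERFECT_DOMAIN, [glu_pos], residue="Q")
        h = min(scan_sequence(seq), key=lambda h: h.mismatch_count)
        assert h.accepted and not h.glu9_present
        assert diagnose_binding(h) == "non-binder"

    def test_arginine_loss_abolishes_binding(self, motif):
        arg_pos = motif.token_offsets(3, 5)[motif.arg_token]
        seq = _mutate(PERFECT_DOMAIN, [arg_pos])
        h = min(scan_sequence(seq), key=lambda h: h.mismatch_count)
        assert h.accepted and h.glu9_present and not h.arg12_present
        assert diagnose_binding(h) == "non-binder"

    def test_basic_region_loss_abolishes_binding(self, motif):
        # all three basic-region K/R sites gone -> group-D-like non-binder
        offsets = motif.token_offsets(3, 5)
        seq = _mutate(PERFECT_DOMAIN,
                      [offsets[i] for i in motif.basic_plus_tokens])
        h = min(scan_sequence(seq), key=lambda h: h.mismatch_count)
        assert h.accepted and h.glu9_present and h.arg12_present
        assert diagnose_binding(h) == "non-binder"


class TestScanProteome:
    def test_planted_proteome_recovery(self, tmp_path):
        spec = SimulationSpec(seed=1, proteome=ProteomeSpec(
            n_planted=3, n_decoys=5))
        result = generate_proteome(spec)
        fasta = tmp_path / "proteome.fasta"
        result.write_fasta(fasta)
        table, hits = scan_proteome(fasta)
        assert len(table) == 3
        assert set(table["sequence_id"]) == {"planted_001", "planted_002",
                                             "planted_003"}
        assert table["accepted"].all()

    def test_empty_fasta(self, tmp_path):
        fasta = tmp_path / "empty.fasta"
        fasta.write_text("")
        table, hits = scan_proteome(fasta)
        assert len(table) == 0 and hits == []

    def test_duplicate_identifier_rejected(self, tmp_path):
        fasta = tmp_path / "dup.fasta"
        fasta.write_text(f">a\n{PERFECT_DOMAIN}\n>a\n{PERFECT_DOMAIN}\n")
        with pytest.raises(ValueError, match="'a'"):
            scan_proteome(fasta)

    def test_same_sequence_twice_under_different_ids(self, tmp_path):
        fasta = tmp_path / "two.fasta"
        fasta.write_text(f">a\n{PERFECT_DOMAIN}\n>b\n{PERFECT_DOMAIN}\n")
        table, hits = scan_proteome(fasta)
        assert len(hits) == 2
        a, b = hits
        assert (a.start, a.end, a.mismatch_count) == (b.start, b.end,
                                                      b.mismatch_count)

    def test_report_coordinates_one_based(self):
        table = hits_table(scan_sequence(PERFECT_DOMAIN))
        row = table.iloc[0]
        assert (row["start1"], row["end1"]) == (1, 44)
        assert row["basic"] == "1-12" and row["helix2"] == "27-44"
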