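"""Exhaustive reference scanner.

A deliberately plain enumeration of every (start, spacer1, loop) placement of
the consensus on a sequence.  The synthetic-data generator certifies every
planted domain against this module rather than the production scanner, so a
bug in the vectorised scanner and a bug in the generator cannot cancel; the
test suite uses it as the independent oracle for scanner equivalence.
"""

from __future__ import annotations

from .motif import ConsensusMotif, load_consensus

__all__ = ["enumerate_placements", "min_mismatches", "best_placement"]


def placement_mismatches(seq: str, start: int, spacer1: int, loop_length: int,
                         motif: ConsensusMotif | None = None) -> int:
    """Diagnostic-site mismatch count of one concrete placement."""
    motif = motif or load_consensus()
    offsets = motif.diagnostic_offsets(spacer1, loop_length)
    mism = 0
    for tok_index, off in zip(motif.diagnostic_indices, offsets):
        if not motif.tokens[tok_index].matches(seq[start + off]):
            mism += 1
    return mism


def enumerate_placements(seq: str, motif: ConsensusMotif | None = None) -> list:
    """All placements as ``(start, spacer1, loop_length, mismatches, length)``."""
    motif = motif or load_consensus()
    seq = seq.upper()
    (s1_lo, s1_hi), (s2_lo, s2_hi) = motif.spacer_ranges
    out = []
    for s1 in range(s1_lo, s1_hi + 1):
        for s2 in range(s2_lo, s2_hi + 1):
            length = motif.match_length(s1, s2)
            sites = [(motif.tokens[i].allowed_residues, off)
                     for i, off in zip(motif.diagnostic_indices,
                                       motif.diagnostic_offsets(s1, s2))]
            for start in range(len(seq) - length + 1):
                mism = sum(1 for allowed, off in sites
                           if seq[start + off] not in allowed)
                out.append((start, s1, s2, mism, length))
    return out


def min_mismatches(seq: str, motif: ConsensusMotif | None = None):
    """Smallest mismatch count over every placement, or ``None`` if the
    sequence is shorter than the minimal match length."""
    placements = enumerate_placements(seq, motif)
    if not placements:
        return None
    return min(p[3] for p in placements)


def best_placement(seq: str, motif: ConsensusMotif | None = None):
    """Best placement under the production tie-break order
    (mismatches, length, spacer1, start), or ``None``."""
    placements = enumerate_placements(seq, motif)
    if not placements:
        return None
    return min(placements, key=lambda p: (p[3], p[4], p[1], p[0]))
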