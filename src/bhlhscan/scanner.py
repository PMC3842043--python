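"""Motif scanner: best-placement matching of the degenerate bHLH consensus.

For every window start the scanner considers both spacer lengths (basic-region
spacer 3-6, loop 5-22), keeps the best placement under the tie-break order
(mismatch count, total match length, smaller first spacer, leftmost start),
suppresses placements overlapping a better one by more than half their span,
and flags placements with at most ``max_mismatches`` (default 9) diagnostic
mismatches as accepted putative bHLH domains.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO

from .motif import ConsensusMotif, load_consensus

__all__ = [
    "MotifHit",
    "scan_sequence",
    "count_mismatches",
    "segment_hit",
    "diagnose_binding",
    "scan_proteome",
    "hits_table",
    "MISMATCH_THRESHOLD",
]

#: A placement is a putative bHLH domain at no more than this many of the 19
#: diagnostic sites mismatched.
MISMATCH_THRESHOLD = 9

E_BOX_BINDER = "E-box-binder"
NON_BINDER = "non-binder"

_SCORE_MISM = 1 << 20   # mismatches dominate ...
_SCORE_LEN = 1 << 6     # ... then total length ...
_BIG = np.iinfo(np.int64).max


@dataclass(frozen=True)
class MotifHit:
    """One placement of the consensus on a protein sequence.

    Coordinates are 0-based half-open; human-readable reports are emitted
    1-based inclusive by :func:`hits_table`.
    """

    sequence_id: str
    start: int
    end: int
    spacer_lengths: tuple          # (basic spacer in 3..6, loop length in 5..22)
    site_matches: tuple            # 19 booleans over the diagnostic tokens
    mismatch_count: int
    accepted: bool
    regions: dict                  # {basic, helix1, loop, helix2} -> (start, end)
    glu9_present: bool
    arg12_present: bool
    binding_class: str

    @property
    def length(self) -> int:
        return self.end - self.start


def _site_lookup(motif: ConsensusMotif) -> list:
    """Per diagnostic token a 256-entry boolean membership table."""
    tables = []
    for i in motif.diagnostic_indices:
        table = np.zeros(256, dtype=bool)
        for res in motif.tokens[i].allowed_residues:
            table[ord(res)] = True
        tables.append(table)
    return tables


def _candidate_placements(seq: str, motif: ConsensusMotif):
    """Best placement per start: list of (start, s1, s2, mismatches, length)."""
    L = len(seq)
    if L < motif.min_length:
        return [], None
    codes = np.frombuffer(seq.encode("ascii", errors="replace"), dtype=np.uint8)
    match = [table[codes] for table in _site_lookup(motif)]  # 19 x L booleans

    best_score = np.full(L, _BIG, dtype=np.int64)
    best_combo = np.full(L, -1, dtype=np.int64)
    combos = []
    (s1_lo, s1_hi), (s2_lo, s2_hi) = motif.spacer_ranges
    for s1 in range(s1_lo, s1_hi + 1):
        for s2 in range(s2_lo, s2_hi + 1):
            length = motif.match_length(s1, s2)
            n = L - length + 1
            if n <= 0:
                continue
            mism = np.zeros(n, dtype=np.int64)
            for m, off in zip(match, motif.diagnostic_offsets(s1, s2)):
                mism += ~m[off:off + n]
            score = mism * _SCORE_MISM + length * _SCORE_LEN + s1
            idx = len(combos)
            combos.append((s1, s2, length))
            better = score < best_score[:n]
            best_score[:n][better] = score[better]
            best_combo[:n][better] = idx

    out = []
    for start in np.nonzero(best_combo >= 0)[0]:
        s1, s2, length = combos[best_combo[start]]
        mism = int(best_score[start]) // _SCORE_MISM
        out.append((int(start), s1, s2, mism, length))
    return out, match


def _suppress_overlaps(candidates: list) -> list:
    """Drop placements overlapping a better-ranked one by >50% of their span."""
    ranked = sorted(candidates, key=lambda c: (c[3], c[4], c[1], c[0]))
    kept = []
    for start, s1, s2, mism, length in ranked:
        end = start + length
        ok = True
        for ks, ke in kept:
            overlap = min(end, ke) - max(start, ks)
            if overlap > 0.5 * length:
                ok = False
                break
        if ok:
            kept.append((start, end))
        else:
            continue
    kept_spans = set(kept)
    return [c for c in candidates if (c[0], c[0] + c[4]) in kept_spans]


def _build_hit(seq: str, sequence_id: str, start: int, s1: int, s2: int,
               motif: ConsensusMotif, max_mismatches: int) -> MotifHit:
    site_matches = tuple(
        motif.tokens[i].matches(seq[start + off])
        for i, off in zip(motif.diagnostic_indices,
                          motif.diagnostic_offsets(s1, s2))
    )
    mism = len(site_matches) - sum(site_matches)
    regions = {
        name: (start + a, start + b)
        for name, (a, b) in motif.region_intervals(s1, s2).items()
    }
    glu = site_matches[motif.diagnostic_position(motif.glu_token)]
    arg = site_matches[motif.diagnostic_position(motif.arg_token)]
    basic_ok = any(site_matches[motif.diagnostic_position(i)]
                   for i in motif.basic_plus_tokens)
    return MotifHit(
        sequence_id=sequence_id,
        start=start,
        end=start + motif.match_length(s1, s2),
        spacer_lengths=(s1, s2),
        site_matches=site_matches,
        mismatch_count=mism,
        accepted=mism <= max_mismatches,
        regions=regions,
        glu9_present=glu,
        arg12_present=arg,
        binding_class=E_BOX_BINDER if (glu and arg and basic_ok) else NON_BINDER,
    )


def scan_sequence(seq: str, motif: ConsensusMotif | None = None, *,
                  sequence_id: str = "query",
                  max_mismatches: int = MISMATCH_THRESHOLD) -> list:
    """Scan one amino-acid sequence; return surviving hits sorted by start.

    Every hit carries its mismatch count and ``accepted`` flag, so rejected
    best placements remain reportable.  An empty or too-short sequence yields
    an empty list.
    """
    motif = motif or load_consensus()
    seq = seq.upper()
    candidates, _ = _candidate_placements(seq, motif)
    kept = _suppress_overlaps(candidates)
    hits = [_build_hit(seq, sequence_id, start, s1, s2, motif, max_mismatches)
            for start, s1, s2, mism, length in kept]
    return sorted(hits, key=lambda h: h.start)


def count_mismatches(placement: Mapping, motif: ConsensusMotif | None = None) -> int:
    """Mismatch count of an explicit token->residue assignment.

    ``placement`` maps every diagnostic token index of the motif to the
    residue aligned to it; non-diagnostic entries are ignored.
    """
    motif = motif or load_consensus()
    missing = [i for i in motif.diagnostic_indices if i not in placement]
    if missing:
        raise ValueError(f"placement does not cover diagnostic tokens {missing}")
    return sum(
        0 if motif.tokens[i].matches(placement[i].upper()) else 1
        for i in motif.diagnostic_indices
    )


def segment_hit(hit: MotifHit, motif: ConsensusMotif | None = None) -> dict:
    """Basic/helix1/loop/helix2 intervals of a hit (absolute coordinates)."""
    motif = motif or load_consensus()
    s1, s2 = hit.spacer_lengths
    return {name: (hit.start + a, hit.start + b)
            for name, (a, b) in motif.region_intervals(s1, s2).items()}


def diagnose_binding(hit: MotifHit) -> str:
    """E-box binder iff the Glu and Arg anchors match and at least one
    basic-region K/R site is present; otherwise a group-D-like non-binder."""
    return hit.binding_class


def _region_str(interval: tuple) -> str:
    a, b = interval
    return f"{a + 1}-{b}"       # 1-based inclusive for reports


def hits_table(hits: list) -> pd.DataFrame:
    """Human-readable hit table (1-based inclusive coordinates)."""
    rows = [
        {
            "sequence_id": h.sequence_id,
            "start1": h.start + 1,
            "end1": h.end,
            "mismatches": h.mismatch_count,
            "accepted": h.accepted,
            "spacer1": h.spacer_lengths[0],
            "loop_len": h.spacer_lengths[1],
            "basic": _region_str(h.regions["basic"]),
            "helix1": _region_str(h.regions["helix1"]),
            "loop": _region_str(h.regions["loop"]),
            "helix2": _region_str(h.regions["helix2"]),
            "binding_class": h.binding_class,
        }
        for h in hits
    ]
    columns = ["sequence_id", "start1", "end1", "mismatches", "accepted",
               "spacer1", "loop_len", "basic", "helix1", "loop", "helix2",
               "binding_class"]
    return pd.DataFrame(rows, columns=columns)


def scan_proteome(fasta_path, motif: ConsensusMotif | None = None, *,
                  max_mismatches: int = MISMATCH_THRESHOLD,
                  include_rejected: bool = False):
    """Scan a multi-record FASTA; returns (table, hits).

    The table holds one row per accepted hit (all best placements when
    ``include_rejected``), ordered by (sequence_id, start).  Duplicated FASTA
    identifiers raise a ``ValueError`` naming the record.
    """
    motif = motif or load_consensus()
    seen = set()
    all_hits = []
    for record in SeqIO.parse(str(fasta_path), "fasta"):
        if record.id in seen:
            raise ValueError(f"duplicated FASTA identifier: {record.id!r}")
        seen.add(record.id)
        hits = scan_sequence(str(record.seq), motif, sequence_id=record.id,
                             max_mismatches=max_mismatches)
        if not include_rejected:
            hits = [h for h in hits if h.accepted]
        all_hits.extend(hits)
    all_hits.sort(key=lambda h: (h.sequence_id, h.start))
    return hits_table(all_hits), all_hits
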