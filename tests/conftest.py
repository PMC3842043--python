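"""Shared fixtures and helpers for the test suite."""

from __future__ import annotations

import pytest

from bhlhscan.classify import build_reference_panel
from bhlhscan.motif import load_consensus
from bhlhscan.reference_data import load_family_registry

#: The worked example: every wildcard/spacer residue is A, conserved sites
#: take K/E/R/I/N/F/L/V/A/Y, spacers at their minima (3, 5) -> one perfect
#: 44-residue match.
PERFECT_DOMAIN = "KRAAAEKARAAAINAAFAALKAAAAARAAKAAVLAAAVAYIAAL"


def make_perfect_domain(s1: int = 3, s2: int = 5, motif=None) -> str:
    """A zero-mismatch domain with the given spacer lengths: wildcards and
    spacers are filled with A, every diagnostic site takes its first allowed
    residue (alphabetically)."""
    motif = motif or load_consensus()
    parts = []
    for i, tok in enumerate(motif.tokens):
        if tok.kind == "spacer":
            parts.append("A" * (s1 if i == motif.spacer_indices[0] else s2))
        elif tok.is_diagnostic:
            parts.append(sorted(tok.allowed_residues)[0])
        else:
            parts.append("A")
    return "".join(parts)


@pytest.fixture(scope="session")
def motif():
    return load_consensus()


@pytest.fixture(scope="session")
def registry():
    return load_family_registry()


@pytest.fixture(scope="session")
def panel(registry):
    return build_reference_panel(registry)
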