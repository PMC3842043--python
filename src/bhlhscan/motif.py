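"""Degenerate consensus motif for the basic helix-loop-helix (bHLH) domain.

The bHLH domain is recognised here by a predictive degenerate pattern over
amino-acid residue classes::

    ++ X(3-6) E + X R X(3) aN X(2) F X(2) L + X(5-22) + X(2) K X(2) dL X(2) A d X Y a X(2) L

where ``+`` = K/R, ``a`` = I/L/V, ``F`` (Phi) = F/I/L, ``d`` (delta) = I/V/T,
the capital letters E, R, N, L, K, A and Y stand for themselves, ``X`` is any
residue and the two parenthesised runs are variable-length spacers (the gap
between the two basic-region anchors, and the loop between the helices).

The pattern contains exactly 19 conserved ("diagnostic") sites - the fixed
and class tokens.  A candidate placement is scored by the number of
diagnostic sites whose residue falls outside the allowed set; placements with
at most nine mismatches are treated as putative bHLH domains.

With the first spacer at its maximum length (6), the fixed glutamate and
arginine anchors sit at domain positions 9 and 12 - the Glu-9/Arg-12 pair
that contacts the CANNTG E-box.  Downstream code therefore keys DNA-binding
diagnosis on those fixed tokens rather than on absolute coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

__all__ = [
    "MotifToken",
    "ConsensusMotif",
    "load_consensus",
    "AMINO_ACIDS",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

KIND_FIXED = "fixed"
KIND_CLASS = "class"
KIND_WILDCARD = "wildcard"
KIND_SPACER = "spacer"

# Residue classes of the degenerate pattern.
BASIC = frozenset("KR")      # '+'
ALPHA = frozenset("ILV")     # alpha
PHI = frozenset("FIL")       # Phi
DELTA = frozenset("IVT")     # delta


@dataclass(frozen=True)
class MotifToken:
    """One position (or spacer) of the degenerate consensus.

    ``kind`` is one of ``fixed``/``class``/``wildcard``/``spacer``;
    ``allowed_residues`` is empty for wildcards and spacers;
    ``length_range`` is ``(1, 1)`` except for spacers.
    """

    kind: str
    allowed_residues: frozenset = frozenset()
    length_range: tuple = (1, 1)
    label: str = "X"

    def __post_init__(self):
        if self.kind == KIND_FIXED and len(self.allowed_residues) != 1:
            raise ValueError("fixed tokens have exactly one allowed residue")
        if self.kind == KIND_CLASS and not 2 <= len(self.allowed_residues) <= 3:
            raise ValueError("class tokens have 2-3 allowed residues")
        if self.kind in (KIND_WILDCARD, KIND_SPACER) and self.allowed_residues:
            raise ValueError("wildcard/spacer tokens carry no residue set")
        lo, hi = self.length_range
        if self.kind != KIND_SPACER and (lo, hi) != (1, 1):
            raise ValueError("only spacers are variable-length")
        if lo < 1 or hi < lo:
            raise ValueError(f"bad length range {self.length_range}")

    @property
    def is_diagnostic(self) -> bool:
        return self.kind in (KIND_FIXED, KIND_CLASS)

    def matches(self, residue: str) -> bool:
        """True if ``residue`` satisfies this (diagnostic) token.

        Non-standard letters (B, Z, X, U, ``*`` ...) never satisfy a
        diagnostic token: ambiguity codes in translated input always count
        as mismatches.
        """
        if not self.is_diagnostic:
            return True
        return residue in self.allowed_residues


def _fixed(residue: str) -> MotifToken:
    return MotifToken(KIND_FIXED, frozenset(residue), label=residue)


def _cls(residues: frozenset, label: str) -> MotifToken:
    return MotifToken(KIND_CLASS, residues, label=label)


def _x() -> MotifToken:
    return MotifToken(KIND_WILDCARD)


def _spacer(lo: int, hi: int) -> MotifToken:
    return MotifToken(KIND_SPACER, length_range=(lo, hi), label=f"X({lo}-{hi})")


@dataclass(frozen=True)
class ConsensusMotif:
    """The canonical degenerate bHLH pattern, token by token."""

    tokens: tuple
    diagnostic_indices: tuple = field(default=())

    def __post_init__(self):
        if not self.diagnostic_indices:
            object.__setattr__(
                self,
                "diagnostic_indices",
                tuple(i for i, t in enumerate(self.tokens) if t.is_diagnostic),
            )

    # ---- structural bookkeeping -------------------------------------------------

    @property
    def spacer_indices(self) -> tuple:
        return tuple(i for i, t in enumerate(self.tokens) if t.kind == KIND_SPACER)

    @property
    def spacer_ranges(self) -> tuple:
        return tuple(self.tokens[i].length_range for i in self.spacer_indices)

    @property
    def min_length(self) -> int:
        return sum(t.length_range[0] for t in self.tokens)

    @property
    def max_length(self) -> int:
        return sum(t.length_range[1] for t in self.tokens)

    def match_length(self, spacer1: int, loop_length: int) -> int:
        fixed = sum(1 for t in self.tokens if t.kind != KIND_SPACER)
        return fixed + spacer1 + loop_length

    def token_offsets(self, spacer1: int, loop_length: int) -> list:
        """Start offset of every token for a concrete spacer assignment."""
        lengths = {self.spacer_indices[0]: spacer1, self.spacer_indices[1]: loop_length}
        offsets, pos = [], 0
        for i, tok in enumerate(self.tokens):
            offsets.append(pos)
            pos += lengths.get(i, 1)
        return offsets

    def diagnostic_offsets(self, spacer1: int, loop_length: int) -> list:
        offs = self.token_offsets(spacer1, loop_length)
        return [offs[i] for i in self.diagnostic_indices]

    def region_token_spans(self) -> dict:
        """Token-index spans of the four structural regions.

        basic = leading basics through the X(3) block after the arginine
        anchor; helix1 = the a N ... L + run; loop = the X(5-22) spacer;
        helix2 = the remainder through the final leucine.
        """
        return {
            "basic": (0, _HELIX1_FIRST),
            "helix1": (_HELIX1_FIRST, _LOOP_INDEX),
            "loop": (_LOOP_INDEX, _LOOP_INDEX + 1),
            "helix2": (_LOOP_INDEX + 1, len(self.tokens)),
        }

    def region_intervals(self, spacer1: int, loop_length: int) -> dict:
        """Residue-coordinate intervals (relative to the match start) of the
        basic / helix1 / loop / helix2 regions; they tile the match exactly."""
        offs = self.token_offsets(spacer1, loop_length)
        offs.append(self.match_length(spacer1, loop_length))
        return {
            name: (offs[a], offs[b])
            for name, (a, b) in self.region_token_spans().items()
        }

    # indices of the tokens the binding diagnosis keys on
    @property
    def glu_token(self) -> int:
        return _GLU_INDEX

    @property
    def arg_token(self) -> int:
        return _ARG_INDEX

    @property
    def basic_plus_tokens(self) -> tuple:
        return _BASIC_PLUS

    def diagnostic_position(self, token_index: int) -> int:
        """Rank (0-18) of a diagnostic token among the 19 diagnostic sites."""
        return self.diagnostic_indices.index(token_index)


# Token list transcribing the printed pattern left to right.
_TOKENS = (
    _cls(BASIC, "+"),        # 0
    _cls(BASIC, "+"),        # 1
    _spacer(3, 6),           # 2   basic-region spacer
    _fixed("E"),             # 3   Glu-9 anchor
    _cls(BASIC, "+"),        # 4
    _x(),                    # 5
    _fixed("R"),             # 6   Arg-12 anchor
    _x(), _x(), _x(),        # 7-9
    _cls(ALPHA, "a"),        # 10
    _fixed("N"),             # 11
    _x(), _x(),              # 12-13
    _cls(PHI, "F"),          # 14
    _x(), _x(),              # 15-16
    _fixed("L"),             # 17
    _cls(BASIC, "+"),        # 18
    _spacer(5, 22),          # 19  loop
    _cls(BASIC, "+"),        # 20
    _x(), _x(),              # 21-22
    _fixed("K"),             # 23
    _x(), _x(),              # 24-25
    _cls(DELTA, "d"),        # 26
    _fixed("L"),             # 27
    _x(), _x(),              # 28-29
    _fixed("A"),             # 30
    _cls(DELTA, "d"),        # 31
    _x(),                    # 32
    _fixed("Y"),             # 33
    _cls(ALPHA, "a"),        # 34
    _x(), _x(),              # 35-36
    _fixed("L"),             # 37
)

_GLU_INDEX = 3
_ARG_INDEX = 6
_BASIC_PLUS = (0, 1, 4)
_HELIX1_FIRST = 10   # the alpha token opening helix 1
_LOOP_INDEX = 19     # the X(5-22) spacer


@lru_cache(maxsize=1)
def load_consensus() -> ConsensusMotif:
    """Return the canonical degenerate bHLH consensus motif."""
    return ConsensusMotif(tokens=_TOKENS)
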