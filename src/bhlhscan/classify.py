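"""Family and supergroup assignment of accepted bHLH domains.

Accepted domains are aligned by anchoring their 19 diagnostic consensus
tokens to shared columns; the two variable spacers are right-aligned against
the anchor that follows them and left-padded with gaps.  Family placement is
distance-based: the query joins the family of the nearest registry
representative (normalised p-distance over mutually ungapped columns) unless
that distance exceeds the orphan threshold, and assignment stability is
scored by column-bootstrap resampling.  A small deterministic
neighbor-joining routine provides desk-scale tree placement; full Bayesian or
maximum-likelihood inference is outside this package's scope, so bootstrap
proportions here are not comparable to published posterior/ML support
values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .motif import ConsensusMotif, load_consensus
from .scanner import MotifHit, scan_sequence

__all__ = [
    "DomainAlignment",
    "FamilyAssignment",
    "ReferencePanel",
    "align_domains",
    "pairwise_distance",
    "build_reference_panel",
    "assign_family",
    "bootstrap_support",
    "neighbor_joining",
    "DEFAULT_ORPHAN_THRESHOLD",
]

#: Beyond ~55% divergence over the domain, family identity in this
#: classification scheme is not credible; such queries become orphans.
DEFAULT_ORPHAN_THRESHOLD = 0.55

GAP = "-"


@dataclass(frozen=True)
class AlignedDomain:
    """Input record for the anchor alignment."""

    sequence_id: str
    domain: str                 # the matched span, ungapped
    spacer_lengths: tuple       # (basic spacer, loop length)

    @classmethod
    def from_hit(cls, hit: MotifHit, sequence: str) -> "AlignedDomain":
        return cls(hit.sequence_id, sequence[hit.start:hit.end], hit.spacer_lengths)


@dataclass
class DomainAlignment:
    """Anchor alignment of bHLH domains.

    All rows share one width; ``diagnostic_columns`` marks the 19 anchor
    columns and ``region_columns`` the basic/helix1/loop/helix2 intervals.
    """

    ids: list
    rows: list
    diagnostic_columns: tuple
    region_columns: dict
    spacer_maxima: tuple

    @property
    def width(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def matrix(self) -> np.ndarray:
        return np.array([list(r) for r in self.rows], dtype="U1")

    def conservation(self, high_threshold: float = 0.8) -> list:
        """Per column: (modal residue, fraction of rows carrying it, flag).

        Columns where the modal non-gap residue covers at least
        ``high_threshold`` of the rows are flagged ``"high"``.
        """
        mat = self.matrix()
        out = []
        n = len(self.rows)
        for col in mat.T:
            residues, counts = np.unique(col[col != GAP], return_counts=True)
            if residues.size == 0:
                out.append((GAP, 0.0, "low"))
                continue
            top = int(np.argmax(counts))
            frac = counts[top] / n
            out.append((str(residues[top]), float(frac),
                        "high" if frac >= high_threshold else "low"))
        return out

    def to_fasta(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for sid, row in zip(self.ids, self.rows):
                fh.write(f">{sid}\n{row}\n")

    def text_view(self, high_threshold: float = 0.8) -> str:
        """Plain-text conservation report: region ruler, asterisks over the
        diagnostic columns, shading line marking highly conserved columns."""
        ruler = [" "] * self.width
        for name, (a, b) in self.region_columns.items():
            mark = {"basic": "b", "helix1": "1", "loop": "l", "helix2": "2"}[name]
            for i in range(a, b):
                ruler[i] = mark
        stars = [" "] * self.width
        for c in self.diagnostic_columns:
            stars[c] = "*"
        cons = self.conservation(high_threshold)
        shade = "".join("#" if flag == "high" else " " for _, _, flag in cons)
        name_w = max((len(i) for i in self.ids), default=0) + 2
        lines = ["".ljust(name_w) + "".join(ruler),
                 "".ljust(name_w) + "".join(stars)]
        lines += [sid.ljust(name_w) + row for sid, row in zip(self.ids, self.rows)]
        lines.append("conserved".ljust(name_w) + shade)
        return "\n".join(lines) + "\n"


def _layout(motif: ConsensusMotif, s1_max: int, s2_max: int):
    """Column offsets of every token when spacers are padded to the maxima."""
    sp1, sp2 = motif.spacer_indices
    lengths = {sp1: s1_max, sp2: s2_max}
    offsets, pos = [], 0
    for i in range(len(motif.tokens)):
        offsets.append(pos)
        pos += lengths.get(i, 1)
    return offsets, pos


def _gapped_row(domain: str, spacers: tuple, s1_max: int, s2_max: int,
                motif: ConsensusMotif) -> str:
    s1, s2 = spacers
    offs = motif.token_offsets(s1, s2)
    sp1, sp2 = motif.spacer_indices
    head = domain[:offs[sp1]]
    spacer1 = domain[offs[sp1]:offs[sp1] + s1]
    mid = domain[offs[sp1] + s1:offs[sp2]]
    loop = domain[offs[sp2]:offs[sp2] + s2]
    tail = domain[offs[sp2] + s2:]
    return (head + GAP * (s1_max - s1) + spacer1 + mid
            + GAP * (s2_max - s2) + loop + tail)


def align_domains(items, motif: ConsensusMotif | None = None) -> DomainAlignment:
    """Anchor-align domains (``AlignedDomain`` records or (id, domain,
    spacer_lengths) tuples); spacers are right-aligned against the anchor
    following them."""
    motif = motif or load_consensus()
    records = [i if isinstance(i, AlignedDomain) else AlignedDomain(*i) for i in items]
    if not records:
        raise ValueError("nothing to align")
    s1_max = max(r.spacer_lengths[0] for r in records)
    s2_max = max(r.spacer_lengths[1] for r in records)
    offsets, width = _layout(motif, s1_max, s2_max)
    rows = [_gapped_row(r.domain, r.spacer_lengths, s1_max, s2_max, motif)
            for r in records]
    assert all(len(r) == width for r in rows)
    diag_cols = tuple(offsets[i] for i in motif.diagnostic_indices)
    offsets_ext = offsets + [width]
    region_cols = {name: (offsets_ext[a], offsets_ext[b])
                   for name, (a, b) in motif.region_token_spans().items()}
    return DomainAlignment(
        ids=[r.sequence_id for r in records],
        rows=rows,
        diagnostic_columns=diag_cols,
        region_columns=region_cols,
        spacer_maxima=(s1_max, s2_max),
    )


def pairwise_distance(a: str, b: str) -> float:
    """Normalised dissimilarity in [0, 1] between two equal-length gapped
    rows: 1 - identical/compared, skipping columns gapped in either row."""
    if len(a) != len(b):
        raise ValueError("gapped domains differ in length")
    compared = identical = 0
    for x, y in zip(a, b):
        if x == GAP or y == GAP:
            continue
        compared += 1
        if x == y:
            identical += 1
    if compared == 0:
        raise ValueError("no comparable (mutually ungapped) columns")
    return 1.0 - identical / compared


@dataclass(frozen=True)
class FamilyAssignment:
    sequence_id: str
    family_name: str             # a registry family or "orphan"
    supergroup: str
    nearest_reference: str
    support_percent: float
    distance: float


@dataclass
class ReferencePanel:
    """Registry representatives with their scanned spacer assignments."""

    families: list
    supergroups: dict
    domains: list                # AlignedDomain per family, registry order

    def __len__(self):
        return len(self.families)


def build_reference_panel(registry) -> ReferencePanel:
    """Scan every registry representative and keep its best accepted hit.

    Registry self-consistency: every representative must itself pass the
    scanner; a representative without an accepted hit is an error.
    """
    families, domains, supergroups = [], [], {}
    for rec in registry:
        hits = [h for h in scan_sequence(rec.representative_domain,
                                         sequence_id=rec.family_name) if h.accepted]
        if not hits:
            raise ValueError(
                f"registry representative for {rec.family_name!r} does not "
                f"pass the motif scanner")
        best = min(hits, key=lambda h: (h.mismatch_count, h.length, h.start))
        families.append(rec.family_name)
        supergroups[rec.family_name] = rec.supergroup
        domains.append(AlignedDomain.from_hit(best, rec.representative_domain))
    return ReferencePanel(families, supergroups, domains)


def _panel_alignment(query: AlignedDomain, panel: ReferencePanel,
                     motif: ConsensusMotif | None = None):
    aln = align_domains([query] + list(panel.domains), motif)
    return aln.rows[0], aln.rows[1:]


def assign_family(query, panel_or_registry,
                  orphan_threshold: float = DEFAULT_ORPHAN_THRESHOLD, *,
                  bootstrap_replicates: int = 0, seed: int = 0,
                  motif: ConsensusMotif | None = None) -> FamilyAssignment:
    """Assign a domain to the family of its nearest representative.

    ``query`` is an ``AlignedDomain`` (or (id, domain, spacers) tuple).
    Queries farther than ``orphan_threshold`` from every representative are
    orphans.  With ``bootstrap_replicates`` > 0 a column-bootstrap support
    percentage is computed (otherwise reported as NaN).
    """
    panel = (panel_or_registry if isinstance(panel_or_registry, ReferencePanel)
             else build_reference_panel(panel_or_registry))
    if len(panel) == 0:
        raise ValueError("empty reference panel")
    if not isinstance(query, AlignedDomain):
        query = AlignedDomain(*query)
    qrow, refrows = _panel_alignment(query, panel, motif)
    dists = [pairwise_distance(qrow, r) for r in refrows]
    nearest_idx = int(np.argmin(dists))    # ties -> first in registry order
    nearest = panel.families[nearest_idx]
    distance = float(dists[nearest_idx])
    if distance <= orphan_threshold:
        family, group = nearest, panel.supergroups[nearest]
    else:
        family, group = "orphan", "orphan"
    support = float("nan")
    if bootstrap_replicates > 0:
        support = bootstrap_support(query, panel, bootstrap_replicates, seed,
                                    motif=motif)
    return FamilyAssignment(query.sequence_id, family, group, nearest,
                            support, distance)


def bootstrap_support(query, panel: ReferencePanel, n_replicates: int = 100,
                      seed: int = 0, *, motif: ConsensusMotif | None = None) -> float:
    """Percentage of column-resampled replicates whose nearest reference
    belongs to the same family as on the full alignment."""
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if not isinstance(query, AlignedDomain):
        query = AlignedDomain(*query)
    qrow, refrows = _panel_alignment(query, panel, motif)
    q = np.array(list(qrow), dtype="U1")
    refs = np.array([list(r) for r in refrows], dtype="U1")
    comparable = (refs != GAP) & (q != GAP)[None, :]      # n_ref x width
    equal = comparable & (refs == q[None, :])
    full = 1.0 - equal.sum(1) / np.maximum(comparable.sum(1), 1)
    full = np.where(comparable.sum(1) == 0, np.inf, full)
    original = panel.families[int(np.argmin(full))]

    rng = np.random.default_rng(seed)
    width = q.size
    same = 0
    for _ in range(n_replicates):
        cols = rng.integers(0, width, size=width)
        comp = comparable[:, cols].sum(1)
        eq = equal[:, cols].sum(1)
        with np.errstate(invalid="ignore"):
            dist = np.where(comp == 0, np.inf, 1.0 - eq / np.maximum(comp, 1))
        if panel.families[int(np.argmin(dist))] == original:
            same += 1
    return 100.0 * same / n_replicates


def neighbor_joining(dist_matrix, labels) -> str:
    """Neighbor joining on a symmetric distance matrix; returns newick.

    Agglomeration is the standard Saitou-Nei scheme with deterministic
    tie-breaking: among minimal-Q pairs the lowest (i, j) index pair is
    joined.  Consistent on additive matrices.
    """
    D = np.asarray(dist_matrix, dtype=float)
    n = D.shape[0]
    if D.shape != (n, n):
        raise ValueError("distance matrix must be square")
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    if not np.allclose(D, D.T) or not np.allclose(np.diag(D), 0.0):
        raise ValueError("distance matrix must be symmetric with zero diagonal")
    if len(labels) != n:
        raise ValueError("labels do not match matrix size")

    nodes = [str(l) for l in labels]          # newick fragment per active node
    D = D.copy()
    active = list(range(n))

    def fmt(x: float) -> str:
        return f"{max(x, 0.0):.12g}"

    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(1)
        best = None
        for i in range(m):
            for j in range(i + 1, m):
                qv = (m - 2) * sub[i, j] - r[i] - r[j]
                if best is None or qv < best[0] - 1e-12:
                    best = (qv, i, j)
        _, i, j = best
        dij = sub[i, j]
        li = dij / 2 + (r[i] - r[j]) / (2 * (m - 2))
        lj = dij - li
        ai, aj = active[i], active[j]
        new_frag = f"({nodes[ai]}:{fmt(li)},{nodes[aj]}:{fmt(lj)})"
        # distances from the new node to the remaining ones
        new_row = np.zeros(D.shape[0] + 1)
        for k_pos, ak in enumerate(active):
            if k_pos in (i, j):
                continue
            new_row[ak] = (sub[i, k_pos] + sub[j, k_pos] - dij) / 2
        D = np.pad(D, ((0, 1), (0, 1)))
        D[-1, :-1] = new_row[:-1]
        D[:-1, -1] = new_row[:-1]
        nodes.append(new_frag)
        active = [a for p, a in enumerate(active) if p not in (i, j)] + [D.shape[0] - 1]

    # resolve the final three nodes as a star
    a, b, c = active
    la = (D[a, b] + D[a, c] - D[b, c]) / 2
    lb = (D[a, b] + D[b, c] - D[a, c]) / 2
    lc = (D[a, c] + D[b, c] - D[a, b]) / 2
    return f"({nodes[a]}:{fmt(la)},{nodes[b]}:{fmt(lb)},{nodes[c]}:{fmt(lc)});"


def multi_ortholog_suffixes(assignments) -> dict:
    """Suffix queries mapping to one family with "a", "b", "c" ... in input
    order; returns {sequence_id: display_name}."""
    by_family = {}
    for a in assignments:
        by_family.setdefault(a.family_name, []).append(a.sequence_id)
    out = {}
    for family, ids in by_family.items():
        if family == "orphan" or len(ids) == 1:
            for sid in ids:
                out[sid] = family if family != "orphan" else f"orphan:{sid}"
            continue
        for k, sid in enumerate(ids):
            suffix = ""
            n = k
            while True:
                suffix = chr(ord("a") + n % 26) + suffix
                n = n // 26 - 1
                if n < 0:
                    break
            out[sid] = f"{family}{suffix}"
    return out
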