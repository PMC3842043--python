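"""Synthetic inputs with known ground truth.

Every input the pipeline consumes can be generated here: proteomes with
bHLH domains planted at scheduled mismatch counts (plus certified decoys),
annotation sets with terms planted at stated fold enrichments, and
interaction networks with planted hubs and family modules.  A single integer
seed drives all randomness through per-stream ``numpy`` generators, so an
identical spec and seed reproduce byte-identical output files.

Planted domains are certified before emission by re-scanning with the
exhaustive reference scanner (:mod:`bhlhscan.bruteforce`), never with the
production scanner, so a generator bug and a scanner bug cannot cancel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import bruteforce
from .classify import AlignedDomain, ReferencePanel, align_domains, \
    build_reference_panel, pairwise_distance
from .motif import AMINO_ACIDS, ConsensusMotif, load_consensus
from .reference_data import load_family_registry

__all__ = [
    "ProteomeSpec",
    "AnnotationSpec",
    "NetworkSpec",
    "SimulationSpec",
    "ProteomeResult",
    "AnnotationResult",
    "NetworkResult",
    "generate_proteome",
    "generate_annotations",
    "generate_network",
]

_MAX_TRIES = 100
_DECOY_MIN_MISMATCHES = 12


@dataclass(frozen=True)
class ProteomeSpec:
    """Planted-domain proteome layout.

    ``mismatch_schedule`` fixes the per-domain diagnostic-site violation
    count (0..19).  Domains scheduled at <= 9 mismatches are embedded in
    random flanks; domains scheduled at >= 10 are emitted as bare
    minimal-spacer matches, because in longer random context a competing
    placement would almost surely score below a high scheduled count and the
    schedule could never be certified.  ``family_donors`` plants additional
    domains derived from registry representatives at the stated per-site
    divergence.
    """

    n_planted: int = 3
    n_decoys: int = 5
    mismatch_schedule: tuple | None = None      # default: all zeros
    spacer_policy: str = "random"               # "random" | "minimal"
    flank_length: tuple = (5, 40)
    decoy_length: tuple = (60, 160)
    family_donors: tuple | None = None
    divergence: float = 0.10
    background_frequencies: dict | None = None  # default: uniform over 20 aa

    def schedule(self) -> tuple:
        if self.mismatch_schedule is not None:
            sched = tuple(int(m) for m in self.mismatch_schedule)
        else:
            sched = (0,) * self.n_planted
        if any(not 0 <= m <= 19 for m in sched):
            raise ValueError("mismatch schedule values must lie in 0..19")
        return sched


@dataclass(frozen=True)
class AnnotationSpec:
    """Planted-enrichment annotation layout.

    ``planted_terms`` is a tuple of (term_size K, fold) pairs; the planted
    overlap with the sample is round(fold * n * K / N) genes.  Fold-1 terms
    are drawn hypergeometrically and serve as nulls.
    """

    background_size: int = 1000
    sample_size: int = 20
    planted_terms: tuple = ((20, 10.0),)
    n_null_terms: int = 5
    null_term_size: int = 20


@dataclass(frozen=True)
class NetworkSpec:
    """Planted-hub network layout.

    Hubs are wired into family cliques of ``module_size`` plus random spokes
    to non-hub nodes so that each hub has at least five distinct partners at
    confidence >= 0.15, while every non-hub stays at degree <= 4 after
    filtering.  ``noise_nodes`` designates a block wired only with
    sub-threshold confidences, contributing nothing after filtering.
    """

    n_nodes: int = 40
    n_hubs: int = 6
    hub_degree: tuple = (5, 8)
    module_size: int = 3
    n_background_edges: int = 10
    noise_nodes: int = 4
    noise_edges: int = 6


@dataclass(frozen=True)
class SimulationSpec:
    seed: int = 0
    proteome: ProteomeSpec = field(default_factory=ProteomeSpec)
    annotations: AnnotationSpec = field(default_factory=AnnotationSpec)
    network: NetworkSpec = field(default_factory=NetworkSpec)


# --------------------------------------------------------------------------
# proteomes


def _write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


@dataclass
class ProteomeResult:
    records: list                 # (sequence_id, sequence)
    truth: pd.DataFrame

    def write_fasta(self, path) -> None:
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            for sid, seq in self.records:
                fh.write(f">{sid}\n")
                for i in range(0, len(seq), 60):
                    fh.write(seq[i:i + 60] + "\n")

    def write_truth(self, path) -> None:
        _write_tsv(self.truth, path)


def _draw_background(rng, length: int, freqs: dict | None) -> str:
    if freqs is None:
        idx = rng.integers(0, len(AMINO_ACIDS), size=length)
        return "".join(AMINO_ACIDS[i] for i in idx)
    residues = sorted(freqs)
    probs = np.array([freqs[r] for r in residues], dtype=float)
    probs = probs / probs.sum()
    return "".join(rng.choice(residues, size=length, p=probs))


def _build_domain(rng, motif: ConsensusMotif, mismatches: int,
                  spacer_policy: str, freqs: dict | None):
    """Token-by-token construction with exactly ``mismatches`` diagnostic
    violations; returns (domain, (s1, s2))."""
    (s1_lo, s1_hi), (s2_lo, s2_hi) = motif.spacer_ranges
    if spacer_policy == "minimal":
        s1, s2 = s1_lo, s2_lo
    elif spacer_policy == "random":
        s1 = int(rng.integers(s1_lo, s1_hi + 1))
        s2 = int(rng.integers(s2_lo, s2_hi + 1))
    else:
        raise ValueError(f"unknown spacer policy {spacer_policy!r}")
    violate = set(rng.choice(len(motif.diagnostic_indices),
                             size=mismatches, replace=False).tolist())
    parts = []
    diag_rank = 0
    for i, tok in enumerate(motif.tokens):
        if tok.kind == "spacer":
            length = s1 if i == motif.spacer_indices[0] else s2
            parts.append(_draw_background(rng, length, freqs))
        elif tok.is_diagnostic:
            if diag_rank in violate:
                forbidden = sorted(set(AMINO_ACIDS) - tok.allowed_residues)
                parts.append(forbidden[int(rng.integers(0, len(forbidden)))])
            else:
                allowed = sorted(tok.allowed_residues)
                parts.append(allowed[int(rng.integers(0, len(allowed)))])
            diag_rank += 1
        else:
            parts.append(_draw_background(rng, 1, freqs))
    return "".join(parts), (s1, s2)


def _certify_planted(seq: str, span: tuple, mismatches: int,
                     motif: ConsensusMotif) -> bool:
    best = bruteforce.best_placement(seq, motif)
    if best is None:
        return False
    start, s1, s2, mism, length = best
    return mism == mismatches and (start, start + length) == span


def _mutate_domain(rng, domain: str, divergence: float) -> str:
    out = []
    for res in domain:
        if rng.random() < divergence:
            alternatives = AMINO_ACIDS.replace(res, "")
            out.append(alternatives[int(rng.integers(0, len(alternatives)))])
        else:
            out.append(res)
    return "".join(out)


def generate_proteome(spec: SimulationSpec,
                      motif: ConsensusMotif | None = None,
                      registry=None) -> ProteomeResult:
    """Emit planted-domain proteins, family-derived domains and certified
    decoys, plus a truth table of every planted record."""
    motif = motif or load_consensus()
    ps = spec.proteome
    rng = np.random.default_rng([spec.seed, 1])
    freqs = ps.background_frequencies
    records, truth_rows = [], []

    for idx, m in enumerate(ps.schedule(), start=1):
        sid = f"planted_{idx:03d}"
        bare = m >= 10
        for _ in range(_MAX_TRIES):
            policy = "minimal" if bare else ps.spacer_policy
            domain, (s1, s2) = _build_domain(rng, motif, m, policy, freqs)
            if bare:
                left = right = ""
            else:
                lo, hi = ps.flank_length
                left = _draw_background(rng, int(rng.integers(lo, hi + 1)), freqs)
                right = _draw_background(rng, int(rng.integers(lo, hi + 1)), freqs)
            seq = left + domain + right
            span = (len(left), len(left) + len(domain))
            if _certify_planted(seq, span, m, motif):
                break
        else:
            raise RuntimeError(f"could not certify planted domain {sid} "
                               f"({m} mismatches) in {_MAX_TRIES} tries")
        records.append((sid, seq))
        truth_rows.append((sid, "planted", "", span[0], span[1], s1, s2, m, m <= 9))

    if ps.family_donors:
        panel = build_reference_panel(registry if registry is not None
                                      else load_family_registry())
        by_family = {f: d for f, d in zip(panel.families, panel.domains)}
        for idx, family in enumerate(ps.family_donors, start=1):
            if family not in by_family:
                raise ValueError(f"unknown donor family {family!r}")
            donor = by_family[family]
            sid = f"fam_{idx:03d}_{family.replace('/', '_')}"
            for _ in range(_MAX_TRIES):
                domain = _mutate_domain(rng, donor.domain, ps.divergence)
                lo, hi = ps.flank_length
                left = _draw_background(rng, int(rng.integers(lo, hi + 1)), freqs)
                right = _draw_background(rng, int(rng.integers(lo, hi + 1)), freqs)
                seq = left + domain + right
                span = (len(left), len(left) + len(domain))
                best = bruteforce.best_placement(seq, motif)
                if best is None or best[3] > 9:
                    continue
                if (best[0], best[0] + best[4]) != span:
                    continue
                if _donor_is_nearest(domain, donor, family, panel, motif):
                    break
            else:
                raise RuntimeError(f"could not certify family-derived domain "
                                   f"{sid} in {_MAX_TRIES} tries")
            records.append((sid, seq))
            truth_rows.append((sid, "family", family, span[0], span[1],
                               donor.spacer_lengths[0], donor.spacer_lengths[1],
                               best[3], True))

    for idx in range(1, ps.n_decoys + 1):
        sid = f"decoy_{idx:03d}"
        lo, hi = ps.decoy_length
        for _ in range(_MAX_TRIES):
            seq = _draw_background(rng, int(rng.integers(lo, hi + 1)), freqs)
            worst = bruteforce.min_mismatches(seq, motif)
            if worst is None or worst >= _DECOY_MIN_MISMATCHES:
                break
        else:
            raise RuntimeError(f"could not certify decoy {sid} "
                               f"(best placement < {_DECOY_MIN_MISMATCHES} "
                               f"mismatches) in {_MAX_TRIES} tries")
        records.append((sid, seq))
        truth_rows.append((sid, "decoy", "", -1, -1, 0, 0,
                           worst if worst is not None else -1, False))

    truth = pd.DataFrame(
        truth_rows,
        columns=["sequence_id", "kind", "family", "start", "end",
                 "spacer1", "loop_len", "mismatches", "accepted"])
    return ProteomeResult(records=records, truth=truth)


def _donor_is_nearest(domain: str, donor: AlignedDomain, family: str,
                      panel: ReferencePanel, motif, margin: float = 0.05) -> bool:
    """Planting guarantee: the mutated domain is nearer its donor than any
    other representative, with a distance margin."""
    query = AlignedDomain("q", domain, donor.spacer_lengths)
    aln = align_domains([query] + list(panel.domains), motif)
    qrow, refrows = aln.rows[0], aln.rows[1:]
    donor_dist, other = None, np.inf
    for fam, row in zip(panel.families, refrows):
        d = pairwise_distance(qrow, row)
        if fam == family:
            donor_dist = d
        else:
            other = min(other, d)
    return donor_dist is not None and donor_dist + margin < other


# --------------------------------------------------------------------------
# annotations


@dataclass
class AnnotationResult:
    pairs: list                   # (gene, term)
    term_meta: pd.DataFrame       # term, source, category
    sample: list
    background: list
    truth: pd.DataFrame

    def write_annotations(self, path) -> None:
        _write_tsv(pd.DataFrame(self.pairs, columns=["gene", "term"]), path)

    def write_term_meta(self, path) -> None:
        _write_tsv(self.term_meta, path)

    def write_sample(self, path) -> None:
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            fh.writelines(g + "\n" for g in self.sample)

    def write_truth(self, path) -> None:
        _write_tsv(self.truth, path)


def generate_annotations(spec: SimulationSpec) -> AnnotationResult:
    """Plant term enrichments at stated folds over a finite background."""
    an = spec.annotations
    rng = np.random.default_rng([spec.seed, 2])
    N, n = an.background_size, an.sample_size
    if n > N:
        raise ValueError("sample larger than background")
    genes = [f"g{i:05d}" for i in range(N)]
    sample_idx = np.sort(rng.choice(N, size=n, replace=False))
    sample = [genes[i] for i in sample_idx]
    sample_set = set(sample)
    non_sample = [g for g in genes if g not in sample_set]

    pairs, meta_rows, truth_rows = [], [], []

    for t, (K, fold) in enumerate(an.planted_terms, start=1):
        if fold < 1:
            raise ValueError("fold enrichments must be >= 1")
        if K > N:
            raise ValueError("term size exceeds background")
        term = f"planted_t{t:02d}"
        k = int(round(fold * n * K / N))
        k = min(k, n, K)
        in_sample = rng.choice(n, size=k, replace=False)
        members = [sample[i] for i in sorted(in_sample)]
        rest = rng.choice(len(non_sample), size=K - k, replace=False)
        members += [non_sample[i] for i in sorted(rest)]
        pairs += [(g, term) for g in members]
        meta_rows.append((term, "GO", "BP"))
        truth_rows.append((term, "planted", fold, k, K, n, N))

    for t in range(1, an.n_null_terms + 1):
        term = f"null_t{t:02d}"
        K = an.null_term_size
        members_idx = rng.choice(N, size=K, replace=False)
        members = [genes[i] for i in sorted(members_idx)]
        pairs += [(g, term) for g in members]
        meta_rows.append((term, "GO", "BP"))
        k = len(set(members) & set(sample))
        truth_rows.append((term, "null", 1.0, k, K, n, N))

    pairs.sort()
    meta = pd.DataFrame(meta_rows, columns=["term", "source", "category"])
    truth = pd.DataFrame(
        truth_rows, columns=["term", "kind", "fold", "k", "K", "n", "N"])
    return AnnotationResult(pairs=pairs, term_meta=meta, sample=sample,
                            background=genes, truth=truth)


# --------------------------------------------------------------------------
# networks


@dataclass
class NetworkResult:
    edges: list                   # (a, b, confidence)
    labels: dict                  # node -> family
    truth_hubs: list
    truth_modules: list           # (family, sorted member list)

    def write_edges(self, path) -> None:
        df = pd.DataFrame(self.edges, columns=["node_a", "node_b", "confidence"])
        df["confidence"] = df["confidence"].map(lambda c: f"{c:.4f}")
        _write_tsv(df, path)

    def write_labels(self, path) -> None:
        rows = sorted(self.labels.items())
        _write_tsv(pd.DataFrame(rows, columns=["protein", "family"]), path)

    def write_truth(self, path) -> None:
        rows = [("hub", h, "") for h in self.truth_hubs]
        rows += [("module", fam, ";".join(nodes))
                 for fam, nodes in self.truth_modules]
        _write_tsv(pd.DataFrame(rows, columns=["kind", "id", "members"]), path)


def generate_network(spec: SimulationSpec) -> NetworkResult:
    """Wire planted hubs (degree >= 5 at confidence >= 0.15) into family
    cliques plus spokes, keep every non-hub at post-filter degree <= 4, and
    optionally add a sub-threshold noise block."""
    ns = spec.network
    rng = np.random.default_rng([spec.seed, 3])
    if ns.n_hubs > ns.n_nodes:
        raise ValueError("more hubs than nodes")
    nodes = [f"p{i:03d}" for i in range(ns.n_nodes)]
    hubs = nodes[:ns.n_hubs]
    non_hubs = nodes[ns.n_hubs:]
    noise = set(non_hubs[len(non_hubs) - ns.noise_nodes:]) if ns.noise_nodes else set()
    spoke_pool = [v for v in non_hubs if v not in noise]

    lo, hi = ns.hub_degree
    capacity = {v: 4 for v in spoke_pool}
    edges, labels = [], {}
    seen = set()

    def add_edge(a, b, conf):
        key = (min(a, b), max(a, b))
        if key in seen:
            return False
        seen.add(key)
        edges.append((key[0], key[1], conf))
        return True

    # family cliques over the hubs
    modules = []
    fam_names = []
    for i in range(0, len(hubs), ns.module_size):
        group = hubs[i:i + ns.module_size]
        fam = f"fam{chr(ord('A') + len(fam_names))}"
        fam_names.append(fam)
        for h in group:
            labels[h] = fam
        for x in range(len(group)):
            for y in range(x + 1, len(group)):
                add_edge(group[x], group[y],
                         round(float(rng.uniform(0.5, 1.0)), 4))
        if len(group) >= 2:
            modules.append((fam, sorted(group)))

    degree = {v: 0 for v in nodes}
    for a, b, _ in edges:
        degree[a] += 1
        degree[b] += 1

    # spokes from each hub to capacity-limited non-hub partners
    for h in hubs:
        target = int(rng.integers(lo, hi + 1))
        needed = max(target - degree[h], 0)
        candidates = [v for v in spoke_pool if capacity[v] > 0]
        if len(candidates) < needed:
            raise ValueError("hub degree constraints unsatisfiable: "
                             "not enough non-hub capacity")
        picks = rng.choice(len(candidates), size=needed, replace=False)
        for p in sorted(picks):
            v = candidates[p]
            if add_edge(h, v, round(float(rng.uniform(0.15, 1.0)), 4)):
                capacity[v] -= 1
                degree[h] += 1
                degree[v] += 1
        if degree[h] < 5:
            raise ValueError("hub degree constraints unsatisfiable")

    # sparse background among non-hub, non-noise nodes
    for _ in range(ns.n_background_edges):
        avail = [v for v in spoke_pool if capacity[v] > 0]
        if len(avail) < 2:
            break
        i, j = rng.choice(len(avail), size=2, replace=False)
        a, b = avail[i], avail[j]
        if add_edge(a, b, round(float(rng.uniform(0.15, 1.0)), 4)):
            capacity[a] -= 1
            capacity[b] -= 1
            degree[a] += 1
            degree[b] += 1

    # noise block: only sub-threshold confidences
    noise_list = sorted(noise)
    for _ in range(ns.noise_edges):
        if len(noise_list) < 2:
            break
        i, j = rng.choice(len(noise_list), size=2, replace=False)
        add_edge(noise_list[i], noise_list[j],
                 round(float(rng.uniform(0.01, 0.14)), 4))

    truth_hubs = sorted(hubs)
    return NetworkResult(edges=edges, labels=labels, truth_hubs=truth_hubs,
                         truth_modules=sorted(modules))
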