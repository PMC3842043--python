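"""Hypergeometric term/pathway enrichment with Benjamini-Hochberg control.

Over-representation of annotation terms in a gene list is scored with the
upper hypergeometric tail P(X >= k) for k of n sampled genes hitting a term
of size K in a background of N genes.  Raw P values are corrected with the
Benjamini-Hochberg step-up procedure pooled across every tested term of
every source (KEGG, PANTHER, Reactome, GO ...): only that pooling reproduces
the published pathway table's corrected column.  Annotations are used as
given - no GO-graph ancestor propagation is performed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TermRecord",
    "AnnotationSet",
    "EnrichmentResult",
    "hypergeom_tail",
    "bh_correct",
    "enrich",
    "coherence",
    "frequency_summary",
    "results_table",
    "DEFAULT_BACKGROUND_SIZE",
]

logger = logging.getLogger(__name__)

#: The published analyses never state their annotation backgrounds; a
#: vertebrate-genome-scale default is used when none is supplied.
DEFAULT_BACKGROUND_SIZE = 20000

CATEGORIES = ("BP", "MF", "CC", "pathway")


@dataclass(frozen=True)
class TermRecord:
    term_id: str
    source: str                  # GO / KEGG / PANTHER / Reactome
    category: str                # BP / MF / CC / pathway
    genes: frozenset


@dataclass
class AnnotationSet:
    """A term -> gene-set map over a finite background of size N."""

    background_size: int
    terms: dict = field(default_factory=dict)
    background_genes: frozenset | None = None   # optional explicit universe

    def __post_init__(self):
        union = set()
        for t in self.terms.values():
            union |= t.genes
        if self.background_genes is not None:
            extra = union - self.background_genes
            if extra:
                raise ValueError(
                    f"{len(extra)} annotated genes outside the background, "
                    f"e.g. {sorted(extra)[:3]}")
            if self.background_size < len(self.background_genes):
                raise ValueError("background_size smaller than the gene universe")
        if self.background_size < len(union):
            raise ValueError("background_size smaller than the union of term sets")

    def annotated_genes(self) -> frozenset:
        out = set()
        for t in self.terms.values():
            out |= t.genes
        return frozenset(out)

    @classmethod
    def from_gene_term_tsv(cls, path, background_size: int,
                           term_meta_path=None) -> "AnnotationSet":
        """Two-column TSV ``gene<TAB>term`` plus an optional metadata TSV
        ``term<TAB>source<TAB>category``."""
        pairs = pd.read_csv(path, sep="\t", header=0, dtype=str)
        gene_col, term_col = pairs.columns[:2]
        meta = {}
        if term_meta_path is not None:
            mdf = pd.read_csv(term_meta_path, sep="\t", dtype=str)
            for _, row in mdf.iterrows():
                meta[row.iloc[0]] = (row.iloc[1], row.iloc[2])
        terms = {}
        for term, sub in pairs.groupby(term_col, sort=True):
            source, category = meta.get(term, ("GO", "BP"))
            terms[term] = TermRecord(term, source, category,
                                     frozenset(sub[gene_col]))
        return cls(background_size=background_size, terms=terms)

    @classmethod
    def from_gmt(cls, path, background_size: int, source: str = "GO",
                 category: str = "BP") -> "AnnotationSet":
        """GMT: one term per line, ``term<TAB>description<TAB>member...``."""
        terms = {}
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                fieldv = line.rstrip("\n").split("\t")
                if len(fieldv) < 3 or not fieldv[0]:
                    continue
                terms[fieldv[0]] = TermRecord(fieldv[0], source, category,
                                              frozenset(g for g in fieldv[2:] if g))
        return cls(background_size=background_size, terms=terms)


@dataclass(frozen=True)
class EnrichmentResult:
    term_id: str
    source: str
    category: str
    sample_hits: int             # k
    term_size: int               # K
    sample_size: int             # n
    raw_p: float
    corrected_p: float
    coherence_percent: float


def hypergeom_tail(k: int, K: int, n: int, N: int) -> float:
    """Upper tail P(X >= k) for X ~ Hypergeometric(N, K, n)."""
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"invalid urn: K={K}, n={n}, N={N}")
    if not (0 <= k <= min(n, K)):
        raise ValueError(f"invalid hit count k={k} for K={K}, n={n}")
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))


def bh_correct(pvals) -> list:
    """Benjamini-Hochberg step-up adjusted P values, in input order."""
    p = np.asarray(list(pvals), dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return list(multipletests(p, method="fdr_bh")[1])


def coherence(k: int, annotated_group_size: int) -> float:
    """Percentage of the group's annotated genes covered by the term."""
    if annotated_group_size < 1:
        raise ValueError("annotated_group_size must be >= 1")
    if k > annotated_group_size:
        raise ValueError("hits exceed the annotated group size")
    return round(100.0 * k / annotated_group_size, 1)


def enrich(sample, annotations: AnnotationSet, *,
           retrieval_p: float | None = None) -> list:
    """Score every term hit by the sample; one result per term with k >= 1.

    Sample genes outside the known background universe are excluded with a
    warning.  Corrected P values are BH-pooled across all tested terms of
    all sources; results are sorted by (raw_p, source, term_id).  With
    ``retrieval_p`` set, only terms with raw P <= cutoff are retained
    (applied after correction, so the BH pool is unchanged).
    """
    sample = list(dict.fromkeys(sample))      # de-dup, keep order
    if annotations.background_genes is not None:
        outside = [g for g in sample if g not in annotations.background_genes]
        if outside:
            warnings.warn(f"{len(outside)} sample gene(s) outside the "
                          f"background were excluded", stacklevel=2)
            logger.info("excluded sample genes: %s", outside)
            sample = [g for g in sample if g in annotations.background_genes]
    n = len(sample)
    N = annotations.background_size
    if n > N:
        raise ValueError("sample larger than the background")
    sample_set = set(sample)
    annotated = annotations.annotated_genes()
    annotated_in_sample = sum(1 for g in sample if g in annotated)
    rows = []
    for term in annotations.terms.values():
        k = len(sample_set & term.genes)
        if k == 0:
            continue
        K = len(term.genes)
        rows.append((term, k, K, hypergeom_tail(k, K, n, N)))
    if not rows:
        return []
    adj = bh_correct([r[3] for r in rows])
    results = [
        EnrichmentResult(
            term_id=term.term_id, source=term.source, category=term.category,
            sample_hits=k, term_size=K, sample_size=n, raw_p=p,
            corrected_p=q,
            coherence_percent=coherence(k, max(annotated_in_sample, 1)),
        )
        for (term, k, K, p), q in zip(rows, adj)
    ]
    results.sort(key=lambda r: (r.raw_p, r.source, r.term_id))
    if retrieval_p is not None:
        results = [r for r in results if r.raw_p <= retrieval_p]
    return results


def results_table(results) -> pd.DataFrame:
    columns = ["term", "source", "category", "k", "K", "n", "raw_p",
               "corrected_p", "coherence"]
    rows = [[r.term_id, r.source, r.category, r.sample_hits, r.term_size,
             r.sample_size, r.raw_p, r.corrected_p, r.coherence_percent]
            for r in results]
    return pd.DataFrame(rows, columns=columns)


def frequency_summary(results_by_group: dict) -> pd.DataFrame:
    """Cross-group term frequencies.

    ``results_by_group`` maps a group label to its ``EnrichmentResult`` list
    (or a DataFrame with term/category columns).  Returns one row per term
    with the number of groups it appears in; ``attrs["category_totals"]``
    carries per-category row totals.
    """
    counts, categories = {}, {}
    for group, results in results_by_group.items():
        if isinstance(results, pd.DataFrame):
            items = [(r["term_id"], r["category"]) for _, r in results.iterrows()]
        else:
            items = [(r.term_id, r.category) for r in results]
        for term, category in items:
            counts[term] = counts.get(term, 0) + 1
            categories[term] = category
    df = pd.DataFrame(
        [(t, categories[t], c) for t, c in counts.items()],
        columns=["term", "category", "group_count"],
    ).sort_values(["group_count", "term"], ascending=[False, True],
                  kind="stable").reset_index(drop=True)
    totals = {}
    for group, results in results_by_group.items():
        if isinstance(results, pd.DataFrame):
            cats = list(results["category"])
        else:
            cats = [r.category for r in results]
        for c in cats:
            totals[c] = totals.get(c, 0) + 1
    df.attrs["category_totals"] = totals
    return df
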