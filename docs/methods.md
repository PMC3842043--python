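# Methods

## Domain model and scanner

The scanner matches a degenerate consensus for the bHLH domain: 38 tokens of
which 19 are conserved ("diagnostic") fixed-residue or residue-class sites,
17 are fixed-width wildcards, and 2 are variable-length spacers — the
basic-region gap X(3–6) and the inter-helix loop X(5–22). Total match
length therefore ranges from 44 to 64 residues. A placement's score is its
number of diagnostic sites whose residue falls outside the allowed set;
letters outside the 20 canonical amino acids (B, Z, X, U, `*`) are legal
input but always count as mismatches, since translated EST or ab-initio
protein sets contain ambiguity codes. A placement with at most 9 mismatches
is an accepted putative domain. The survey literature states the rule both
as "no more than 9 mismatches" and as hits having "more than 10 conserved
amino acids" (which would imply ≤ 8); we implement ≤ 9 and expose the
threshold (`max_mismatches` / `mismatch_threshold`) so the stricter reading
is one flag away.

For every window start the scanner evaluates all 4 × 18 spacer combinations
and keeps the best placement under the tie-break order **(mismatch count,
total match length, smaller basic spacer, leftmost start)** — the sources
never specify how competing spacer expansions are resolved, so this order
was fixed once: it prefers the most parsimonious (shortest) realisation of
an equally good match. Placements overlapping a better-ranked hit by more
than half their own span are suppressed, which yields one hit per domain
while leaving genuine multi-domain proteins representable. The
implementation is vectorised (per-token boolean membership tables, shifted
sums per spacer combination); a deliberately naive exhaustive scanner
(`bhlhscan.bruteforce`) is kept as the certification oracle and test
reference, and the test suite checks exact agreement of the two on random
sequences up to 80 residues.

Region segmentation follows the token structure: basic = the leading
residues through the X(3) block after the arginine anchor (length 9 + s1),
helix 1 = the `aN…L+` run (9), loop = the second spacer (s2), helix 2 = the
remainder (18); the four intervals tile the match exactly. DNA-binding
diagnosis keys on tokens, not absolute positions: with the basic spacer at
its maximum the fixed glutamate and arginine fall at domain positions 9 and
12, so a hit is an E-box binder iff the E token matches, the R token
matches, and at least one of the three basic-region K/R sites is intact;
otherwise it is a group-D-like non-binder.

## Family classification

Accepted domains are aligned by anchoring the 19 diagnostic tokens to
shared columns; spacer residues are right-aligned against the anchor that
follows them and left-padded with gaps (alignment width = 36 + max s1 + max
s2, at most 64). Distance is the normalised p-distance over mutually
ungapped columns. A query joins the family of its nearest registry
representative unless that distance exceeds the **orphan threshold, default
0.55**: beyond roughly 55% divergence across a ~50-residue domain, family
identity under this scheme is not credible. The threshold is exposed in the
configuration. Assignment stability is scored by bootstrap-resampling
alignment columns (default 100 replicates, seeded) and reporting the
percentage of replicates whose nearest representative is the same family.

Full Bayesian and maximum-likelihood tree inference is out of scope; a
deterministic neighbor-joining routine (minimal-Q pair, ties broken by the
lowest index pair) provides desk-scale tree context and is provably
consistent on additive matrices — the tests verify exact reconstruction of
random additive 4–6-taxon matrices and agreement with an independent NJ
implementation. Bootstrap proportions from this distance pipeline are
**not** comparable to published ML bootstrap or Bayesian posterior values;
the packaged catalog stores those published support markers verbatim
(including the `n/m` / `n/m*` non-monophyly markers) without attempting to
reproduce them.

The packaged 45-family registry carries the family names, supergroups A–F
and DNA-box labels of the standard classification (groups A/B bind E-box
variants, C the ACGTG/GCGTG core, E the N-box, D and F lack a basic region).
Two families (Mist, Delilah) have no catalog entries, so registry and
catalog are separate files. The registry's representative domain sequences
are a synthetic stand-in (file suffix `.synthetic.tsv`): 45 zero-mismatch
consensus realisations selected for mutual distance (minimum pairwise
p-distance 0.67), generated once with a fixed seed. Tests depend only on
their self-consistency (each passes the scanner; each self-classifies at
distance 0), never on specific residues. Supergroup membership was chosen
so that the per-group catalog row counts reproduce the published group
sizes (44/26/11/3/15/4 + 2 orphans as counted from the table itself; the
prose totals differ by two in group A and the fixture preserves the table
verbatim rather than resolving the discrepancy).

## Enrichment statistics

Over-representation uses the exact upper hypergeometric tail
P(X ≥ k | N, K, n) (scipy implementation; verified against exhaustive
enumeration for N ≤ 12). Raw P values are corrected with Benjamini–Hochberg
step-up adjustment **pooled across every tested term of every source** —
KEGG, PANTHER, Reactome and GO together — because only that pooling
reproduces the published 16-row pathway table's corrected column (the
rank-11 entry inherits rank-12's adjusted value through the step-up
minimum). Reproduction is exact to 1e-7 on eleven rows; the remaining five
are limited to ~3e-7 by the fact that the printed raw inputs are themselves
rounded to seven decimals, so the regression test asserts the propagation
bound 5e-7. The annotation background size N is a required input (default
20 000, a vertebrate-genome scale) since the published analyses never state
their backgrounds — their raw P values are therefore shipped as fixtures,
not recomputed. Coherence is 100·k divided by the number of annotated genes
in the group, one decimal. Annotations are used exactly as given: no GO-DAG
ancestor propagation. Retrieval keeps terms with raw P ≤ 0.5 (default);
significance reporting uses FDR ≤ 0.05.

## Networks

Edge confidences live in [0, 1]; STRING-style 0–1000 integer scores are
accepted only behind an explicit flag (`--string-scale`) — the scale is
never auto-detected, to avoid silently misreading a file. Duplicate edges
collapse to the maximum confidence, self-loops are dropped with a warning,
and edges below the confidence threshold (default 0.15) are removed. A hub
has at least 5 **distinct** neighbours (degree counts partners, not
multi-edges); a family module is a connected component with ≥ 2 members in
the subgraph induced by one family label. The published count of 68 hub
proteins depends on a live interaction database and is not an offline
target; the printed hub list ships as a labelling fixture only. The printed
"10 predicted functional partners" list contains nine names; the fixture
stores the nine as printed.

## Synthetic data: what it emulates, and what it does not

The generators produce every pipeline input with known truth, under one
integer seed (per-stream `numpy` generators; identical spec + seed gives
byte-identical files).

* **Proteomes** — planted domains are built token-by-token with exactly the
  scheduled number of diagnostic violations, embedded in random flanks
  (uniform residue background by default; a frequency table can be
  supplied), and certified before emission by the brute-force oracle, not
  the production scanner, so generator and scanner defects cannot cancel.
  Domains scheduled at ≥ 10 mismatches are emitted bare with minimal
  spacers: in longer random context some competing placement would almost
  surely score below a high scheduled count, making the schedule
  uncertifiable. Decoys are resampled until their best placement has ≥ 12
  mismatches. Family-derived domains mutate a registry representative at a
  fixed per-site rate (default 10%) with no indels, and are certified to
  remain nearest their donor with a 0.05 distance margin.
* **Annotations** — a planted term of size K at fold f overlaps the sample
  in round(f·nK/N) genes; fold-1 terms are drawn hypergeometrically and
  behave as exact nulls (verified by a KS check on the randomized
  probability integral transform over 200 seeds).
* **Networks** — hubs are wired into family cliques plus spokes at
  confidence ≥ 0.15 with every non-hub capped at post-filter degree 4, so
  the planted hub set is exactly the degree-≥ 5 set; an optional noise block
  carries only sub-threshold edges.

These benchmarks demonstrate correctness of the machinery — recovery of
planted truth, exact statistics, deterministic reports. They do not
demonstrate performance on real proteomes: real bHLH flanks are not uniform
random sequence, real families have correlated (phylogenetic) rather than
i.i.d. site divergence and contain indels, real annotation terms overlap
hierarchically, and real interaction networks are scale-free rather than
capacity-capped. Passing tests therefore certify the algorithmic contracts,
not field sensitivity/specificity.

## Numerical and engineering choices

* Coordinates are 0-based half-open internally, 1-based inclusive in
  reports.
* Scanner scores are packed into integers (mismatches ≫ length ≫ spacer), so
  best-placement selection is an exact integer argmin with no float ties.
* `hypergeom_tail` delegates to `scipy.stats.hypergeom.sf` (stable in log
  space); `bh_correct` delegates to `statsmodels.stats.multitest`.
* p-distance raises on zero comparable columns rather than guessing.
* NJ branch lengths are clamped at zero for display and printed at 12
  significant digits so additive inputs round-trip through newick.
* Pipeline reports are stamped with a 12-hex-digit SHA-256 hash of the
  serialised run configuration; `run.log` (timings, input hashes) is the
  only file that may differ between identical runs.
* Problem sizes used by the tests and the acceptance script (proteomes of a
  few dozen sequences, backgrounds of 500–4000 genes, 35–40-node networks,
  20-domain mismatch schedules) were chosen as the smallest sizes at which
  every planted structure is still unambiguous.

## Known limitations

* The scanner reports the best placement per start; a domain whose true
  spacer assignment loses the parsimony tie-break is still found, but its
  reported segmentation may shift by a residue or two.
* Distance-based placement cannot separate families whose representatives
  are closer to each other than the query divergence; with the synthetic
  registry (min pairwise distance 0.67) this needs > 30% divergence, but
  real families are far less separated.
* BH correction assumes the tested terms form the whole family of
  hypotheses; callers who test sources separately will not reproduce the
  pooled published column.
* No nucleotide input: six-frame translation and EST verification are out
  of scope.
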