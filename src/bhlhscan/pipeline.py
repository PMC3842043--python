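"""End-to-end survey runs: scan -> classify -> enrich -> network.

A run is driven by a :class:`RunConfig` (key=value file or keyword
arguments), writes its reports into one output directory, serialises the
config verbatim next to them, and stamps every report with the config hash.
Each stage is a pure function of its inputs, so any stage can be re-run from
the saved intermediates and reproduce the full-run output byte for byte
(``run.log`` carries timings and is the one non-deterministic file).
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
import sys
import time
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .classify import AlignedDomain, align_domains, assign_family, \
    build_reference_panel
from .enrich import AnnotationSet, enrich, results_table
from .network import find_hubs, load_network, write_hub_table, \
    write_module_table
from .reference_data import load_catalog_fixture, load_family_registry, \
    registry_index
from .scanner import scan_proteome

__all__ = ["RunConfig", "run_pipeline", "summarize_counts",
           "entries_in_supergroup"]

logger = logging.getLogger(__name__)

REPORT_FILES = ("catalog.tsv", "alignment.txt", "enrichment_by_group.tsv",
                "pathways.tsv", "hubs.tsv", "modules.tsv")


@dataclass
class RunConfig:
    """All inputs and thresholds of one pipeline run."""

    fasta: str | None = None
    registry: str | None = None          # None -> packaged registry
    annotations: str | None = None       # gene<TAB>term TSV
    term_meta: str | None = None
    edges: str | None = None
    node_labels: str | None = None
    outdir: str = "bhlh_run"
    mismatch_threshold: int = 9
    orphan_threshold: float = 0.55
    bootstrap_replicates: int = 100
    seed: int = 0
    background_size: int = 20000
    retrieval_p: float = 0.5
    fdr_cutoff: float = 0.05
    min_confidence: float = 0.15
    string_scale: bool = False
    hub_threshold: int = 5

    def to_text(self) -> str:
        lines = []
        for f in dataclasses.fields(self):
            value = getattr(self, f.name)
            lines.append(f"{f.name}={'' if value is None else value}")
        return "\n".join(lines) + "\n"

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.to_text().encode()).hexdigest()[:12]

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        values = {}
        types = {f.name: f for f in dataclasses.fields(cls)}
        with open(path, encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                if "=" not in line:
                    raise ValueError(f"line {lineno}: expected key=value")
                key, _, raw = line.partition("=")
                key, raw = key.strip(), raw.strip()
                if key not in types:
                    raise ValueError(f"line {lineno}: unknown key {key!r}")
                values[key] = _coerce(raw, types[key].type)
        return cls(**values)


def _coerce(raw: str, annotation):
    if raw == "":
        return None if "None" in str(annotation) or "str" in str(annotation) else raw
    ann = str(annotation)
    if "bool" in ann:
        return raw.lower() in ("1", "true", "yes")
    if "int" in ann:
        return int(raw)
    if "float" in ann:
        return float(raw)
    return raw


def _write_report(df: pd.DataFrame, path: Path, config_hash: str) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(f"# config_hash={config_hash}\n")
        df.to_csv(fh, sep="\t", index=False, lineterminator="\n")


def read_report(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


# --------------------------------------------------------------------------
# stages


def stage_scan_classify(config: RunConfig):
    """Scan the FASTA and assign every accepted domain to a family.

    Returns (catalog DataFrame, accepted hits, sequences by id).
    """
    from Bio import SeqIO

    table, hits = scan_proteome(config.fasta,
                                max_mismatches=config.mismatch_threshold)
    sequences = {r.id: str(r.seq) for r in SeqIO.parse(str(config.fasta), "fasta")}
    registry = load_family_registry(config.registry)
    panel = build_reference_panel(registry)
    rows = []
    for h in hits:
        dom = AlignedDomain.from_hit(h, sequences[h.sequence_id])
        a = assign_family(dom, panel, config.orphan_threshold,
                          bootstrap_replicates=config.bootstrap_replicates,
                          seed=config.seed)
        rows.append((h.sequence_id, a.family_name, a.supergroup,
                     round(a.distance, 4), round(a.support_percent, 1),
                     h.start + 1, h.end, h.mismatch_count, h.binding_class))
    catalog = pd.DataFrame(
        rows, columns=["sequence_id", "family", "supergroup", "distance",
                       "support", "start1", "end1", "mismatches",
                       "binding_class"])
    return catalog, hits, sequences


def stage_alignment(hits, sequences) -> str:
    domains = [AlignedDomain.from_hit(h, sequences[h.sequence_id]) for h in hits]
    return align_domains(domains).text_view()


def stage_enrichment(config: RunConfig, catalog: pd.DataFrame):
    """Per-supergroup and pooled enrichment over the accepted sequence ids."""
    annotations = AnnotationSet.from_gene_term_tsv(
        config.annotations, background_size=config.background_size,
        term_meta_path=config.term_meta)
    group_frames = []
    for group in sorted(catalog["supergroup"].unique()):
        sample = list(catalog.loc[catalog["supergroup"] == group, "sequence_id"])
        results = enrich(sample, annotations)
        df = results_table(results)
        df.insert(0, "group", group)
        group_frames.append(df)
    by_group = (pd.concat(group_frames, ignore_index=True) if group_frames
                else pd.DataFrame())
    pooled = enrich(list(catalog["sequence_id"]), annotations,
                    retrieval_p=config.retrieval_p)
    return by_group, results_table(pooled)


def stage_network(config: RunConfig, catalog: pd.DataFrame | None):
    net = load_network(config.edges, config.min_confidence,
                       string_scale=config.string_scale,
                       hub_threshold=config.hub_threshold)
    if config.node_labels:
        labels_df = pd.read_csv(config.node_labels, sep="\t", dtype=str)
        labels = dict(zip(labels_df.iloc[:, 0], labels_df.iloc[:, 1]))
    elif catalog is not None and len(catalog):
        labels = dict(zip(catalog["sequence_id"], catalog["family"]))
    else:
        labels = {}
    net.set_labels(labels)
    return net


# --------------------------------------------------------------------------


def run_pipeline(config: RunConfig) -> dict:
    """Run every configured stage; returns {report name: path}.

    Stages without inputs (or without accepted domains upstream) are skipped
    with a logged notice but still emit an empty, hash-stamped report so a
    run always yields the same set of files.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash
    (outdir / "config.txt").write_text(config.to_text(), encoding="utf-8")

    log_lines = []
    handler = logging.StreamHandler(sys.stderr)
    logger.addHandler(handler)

    def log(msg):
        logger.info(msg)
        log_lines.append(msg)

    def timed(name, fn, *args):
        t0 = time.perf_counter()
        try:
            result = fn(*args)
        except Exception as exc:
            log(f"stage {name}: FAILED: {exc}")
            _write_log()
            raise
        log(f"stage {name}: done in {time.perf_counter() - t0:.2f}s")
        return result

    def _write_log():
        (outdir / "run.log").write_text("\n".join(log_lines) + "\n",
                                        encoding="utf-8")

    log(f"config hash {chash}")
    for name in ("fasta", "annotations", "edges"):
        p = getattr(config, name)
        if p:
            digest = hashlib.sha256(Path(p).read_bytes()).hexdigest()[:12]
            log(f"input {name}={p} sha256:{digest}")

    catalog = pd.DataFrame(columns=["sequence_id", "family", "supergroup",
                                    "distance", "support", "start1", "end1",
                                    "mismatches", "binding_class"])
    hits, sequences = [], {}
    if config.fasta:
        catalog, hits, sequences = timed(
            "scan+classify", stage_scan_classify, config)
        log(f"accepted domains: {len(catalog)}")
    else:
        log("stage scan+classify: skipped (no FASTA input)")
    _write_report(catalog, outdir / "catalog.tsv", chash)

    if hits:
        view = timed("alignment", stage_alignment, hits, sequences)
        (outdir / "alignment.txt").write_text(
            f"# config_hash={chash}\n" + view, encoding="utf-8")
    else:
        log("stage alignment: skipped (no accepted domains)")
        (outdir / "alignment.txt").write_text(
            f"# config_hash={chash}\n", encoding="utf-8")

    empty_enrich = pd.DataFrame(columns=["group", "term", "source", "category",
                                         "k", "K", "n", "raw_p", "corrected_p",
                                         "coherence"])
    if config.annotations and len(catalog):
        by_group, pooled = timed("enrichment", stage_enrichment, config, catalog)
        _write_report(by_group if len(by_group) else empty_enrich,
                      outdir / "enrichment_by_group.tsv", chash)
        _write_report(pooled, outdir / "pathways.tsv", chash)
    else:
        log("stage enrichment: skipped (no annotations or no accepted domains)")
        _write_report(empty_enrich, outdir / "enrichment_by_group.tsv", chash)
        _write_report(empty_enrich.drop(columns=["group"]),
                      outdir / "pathways.tsv", chash)

    if config.edges:
        net = timed("network", stage_network, config,
                    catalog if len(catalog) else None)
        hubs_path, modules_path = outdir / "hubs.tsv", outdir / "modules.tsv"
        write_hub_table(net, hubs_path)
        write_module_table(net, modules_path)
        # stamp the network reports like the others
        for p in (hubs_path, modules_path):
            body = p.read_text(encoding="utf-8")
            p.write_text(f"# config_hash={chash}\n" + body, encoding="utf-8")
        log(f"hubs: {len(find_hubs(net))}")
    else:
        log("stage network: skipped (no edge list)")
        for name, cols in (("hubs.tsv", ["protein", "degree"]),
                           ("modules.tsv", ["family", "size", "members"])):
            _write_report(pd.DataFrame(columns=cols), outdir / name, chash)

    _write_log()
    logger.removeHandler(handler)
    return {name: outdir / name for name in REPORT_FILES} | {
        "run.log": outdir / "run.log", "config.txt": outdir / "config.txt"}


# --------------------------------------------------------------------------
# survey summaries


def summarize_counts(catalog, registry=None) -> dict:
    """Totals, per-family and per-supergroup counts for a survey catalog.

    ``catalog`` is a list of ``CatalogEntry`` (or a DataFrame with a
    ``family`` column); supergroups are looked up in the family registry.
    Families named "Orphan"/"orphan" are counted as orphans.
    """
    if isinstance(catalog, pd.DataFrame):
        families = list(catalog["family"])
    else:
        families = [e.family_name for e in catalog]
    index = registry_index(load_family_registry() if registry is None
                           else registry)
    fam_counts, group_counts = {}, {}
    orphans = 0
    for fam in families:
        fam_counts[fam] = fam_counts.get(fam, 0) + 1
        if fam.lower() == "orphan":
            orphans += 1
            group = "orphan"
        elif fam in index:
            group = index[fam].supergroup
        else:
            group = "unknown"
        group_counts[group] = group_counts.get(group, 0) + 1
    distinct = len({f for f in families if f.lower() != "orphan"})
    return {
        "total": len(families),
        "per_family": dict(sorted(fam_counts.items())),
        "per_supergroup": dict(sorted(group_counts.items())),
        "orphans": orphans,
        "distinct_families": distinct,
    }


def entries_in_supergroup(entries, supergroup: str, registry=None) -> list:
    """Catalog entries whose family belongs to the given supergroup."""
    index = registry_index(load_family_registry() if registry is None
                           else registry)
    if supergroup == "orphan":
        return [e for e in entries if e.family_name.lower() == "orphan"]
    return [e for e in entries
            if e.family_name in index
            and index[e.family_name].supergroup == supergroup]


def load_survey_catalog():
    """Convenience: the packaged survey catalog fixture."""
    return load_catalog_fixture()
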