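"""Reference assets: family registry, survey catalog, and packaged tables.

Three kinds of data live here.

* The 45-family registry (supergroups A-F, DNA-box labels, one representative
  bHLH domain per family).  The packaged representative sequences are a
  synthetic stand-in generated from the consensus (see
  ``data/family_registry.synthetic.tsv``): their exact residues are a data
  asset, not a contract - each simply has to pass the motif scanner itself.
* The survey catalog of the 105 Xenopus tropicalis bHLH proteins with family,
  human ortholog, phylogenetic support markers and accessions, transcribed
  verbatim from the published survey table.
* Machine-readable transcriptions of the published per-supergroup GO
  enrichment table, the pathway-enrichment table, the hub-protein list, and
  the reannotated-accession list, used as regression fixtures and labelling
  demos.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .motif import load_consensus  # noqa: F401  (re-export: consensus lives with the reference data)

__all__ = [
    "FamilyRecord",
    "CatalogEntry",
    "RegistryParseError",
    "CatalogValidationError",
    "SUPERGROUPS",
    "DNA_BOXES",
    "SUPPORT_VALUE",
    "SUPPORT_NM",
    "SUPPORT_NM_STAR",
    "load_consensus",
    "load_family_registry",
    "write_family_registry",
    "load_catalog_fixture",
    "write_catalog",
    "load_go_enrichment_fixture",
    "go_annotation_rows",
    "load_pathway_fixture",
    "load_hub_fixture",
    "load_partner_fixture",
    "load_reannotation_fixture",
]

SUPERGROUPS = ("A", "B", "C", "D", "E", "F", "orphan")

#: Core DNA-binding-site vocabularies per supergroup (empty for the
#: basic-region-less groups D and F).
DNA_BOXES = {
    "A": {"CACCTG", "CAGCTG"},
    "B": {"CACGTG", "CATGTTG"},
    "C": {"ACGTG", "GCGTG"},
    "D": {""},
    "E": {"CACGCG", "CACGAG"},
    "F": {""},
}

# Phylogenetic-support markers of the survey table, stored as an enumeration
# rather than coerced to numbers.
SUPPORT_VALUE = "value"        # a plain bootstrap / posterior percentage
SUPPORT_NM = "n/m"             # support below 50%
SUPPORT_NM_STAR = "n/m*"       # monophyletic only with >=2 orthologs


class RegistryParseError(ValueError):
    """Malformed family-registry file."""


class CatalogValidationError(ValueError):
    """Malformed or inconsistent survey-catalog fixture."""


@dataclass(frozen=True)
class FamilyRecord:
    family_name: str
    supergroup: str
    dna_box: str
    representative_domain: str


@dataclass(frozen=True)
class CatalogEntry:
    family_name: str
    gene_name: str
    human_ortholog: str
    mle_bootstrap: str           # percentage string, "n/m" or "n/m*"
    bi_posterior: str
    protein_accession: str
    contig_accession: str

    @staticmethod
    def support_kind(value: str) -> str:
        if value == "n/m":
            return SUPPORT_NM
        if value == "n/m*":
            return SUPPORT_NM_STAR
        return SUPPORT_VALUE


def _data_path(name: str):
    return resources.files("bhlhscan").joinpath("data", name)


_REGISTRY_COLUMNS = ["family", "supergroup", "dna_box", "representative_domain"]


def load_family_registry(path=None) -> list:
    """Load the family registry TSV; the packaged registry has 45 records
    covering every supergroup A-F."""
    path = path if path is not None else _data_path("family_registry.synthetic.tsv")
    records = []
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is None or [h.strip() for h in header] != _REGISTRY_COLUMNS:
            raise RegistryParseError(
                f"line 1: expected header {_REGISTRY_COLUMNS}, got {header}")
        seen = set()
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != 4:
                raise RegistryParseError(f"line {lineno}: expected 4 columns, got {len(row)}")
            family, group, box, domain = (c.strip() for c in row)
            if not family:
                raise RegistryParseError(f"line {lineno}: empty family name")
            if family in seen:
                raise RegistryParseError(f"line {lineno}: duplicate family {family!r}")
            seen.add(family)
            if group not in SUPERGROUPS:
                raise RegistryParseError(f"line {lineno}: unknown supergroup {group!r}")
            if group in DNA_BOXES and box not in DNA_BOXES[group]:
                raise RegistryParseError(
                    f"line {lineno}: dna_box {box!r} not allowed for group {group}")
            if not domain:
                raise RegistryParseError(f"line {lineno}: empty representative domain")
            records.append(FamilyRecord(family, group, box, domain))
    return records


def write_family_registry(records, path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_REGISTRY_COLUMNS)
        for r in records:
            writer.writerow([r.family_name, r.supergroup, r.dna_box,
                             r.representative_domain])


def registry_index(records) -> dict:
    return {r.family_name: r for r in records}


_CATALOG_COLUMNS = ["family", "gene", "human_ortholog", "mle_bootstrap",
                    "bi_posterior", "protein_accession", "contig_accession"]


def load_catalog_fixture(path=None) -> list:
    """Load the 105-protein survey catalog (verbatim transcription)."""
    path = path if path is not None else _data_path("xt_bhlh_catalog.tsv")
    entries = []
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is None or [h.strip() for h in header] != _CATALOG_COLUMNS:
            raise CatalogValidationError(
                f"line 1: expected header {_CATALOG_COLUMNS}, got {header}")
        seen = set()
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != 7:
                raise CatalogValidationError(
                    f"line {lineno}: expected 7 columns, got {len(row)}")
            entry = CatalogEntry(*(c.strip() for c in row))
            key = (entry.family_name, entry.gene_name)
            if key in seen:
                raise CatalogValidationError(f"line {lineno}: duplicate entry {key}")
            seen.add(key)
            entries.append(entry)
    return entries


def write_catalog(entries, path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_CATALOG_COLUMNS)
        for e in entries:
            writer.writerow([e.family_name, e.gene_name, e.human_ortholog,
                             e.mle_bootstrap, e.bi_posterior,
                             e.protein_accession, e.contig_accession])


def load_go_enrichment_fixture(path=None) -> pd.DataFrame:
    """Per-supergroup GO/KEGG enrichment table.

    Groups without significant annotations (D, F, orphan) appear with
    ``term_id == "None"``; :func:`go_annotation_rows` filters them out.
    The ``group_gene_count`` column is stored verbatim even where it is
    inconsistent with the group sizes, and is not used by computation.
    """
    path = path if path is not None else _data_path("go_enrichment_by_group.tsv")
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    df["coherence_percent"] = pd.to_numeric(df["coherence_percent"], errors="coerce")
    df["p_value"] = pd.to_numeric(df["p_value"], errors="coerce")
    return df


def go_annotation_rows(df: pd.DataFrame) -> pd.DataFrame:
    """The enriched-annotation rows of the GO table (term rows only)."""
    return df[df["term_id"] != "None"].reset_index(drop=True)


def load_pathway_fixture(path=None) -> pd.DataFrame:
    """Pathway-enrichment table: 16 rows with raw and corrected P values."""
    path = path if path is not None else _data_path("pathway_enrichment.tsv")
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("sample_hits", "background_hits"):
        df[col] = df[col].astype(int)
    for col in ("raw_p", "corrected_p"):
        df[col] = df[col].astype(float)
    return df


def load_hub_fixture(path=None) -> list:
    """The 68 published hub-protein names (labelling demos only: the count
    depends on the live interaction database and is not an offline target)."""
    path = path if path is not None else _data_path("hub_proteins.tsv")
    df = pd.read_csv(path, sep="\t", dtype=str)
    return df["protein"].tolist()


def load_partner_fixture(path=None) -> list:
    """Predicted functional partners as printed (nine names)."""
    path = path if path is not None else _data_path("predicted_partners.tsv")
    df = pd.read_csv(path, sep="\t", dtype=str)
    return df["protein"].tolist()


def load_reannotation_fixture(path=None) -> pd.DataFrame:
    """The printed list of reannotated protein accessions, kept as printed
    (one accession appears twice and is flagged as a duplicate)."""
    path = path if path is not None else _data_path("reannotated_accessions.tsv")
    return pd.read_csv(path, sep="\t")
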