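"""Marker-gene capability profiling of annotated genome bins.

Given per-genome feature tables (locus id, gene symbol, product string,
optional % identity) — e.g. Prokka/PGAP output flattened to TSV or GFF3 —
this module screens them against curated marker catalogs and produces
per-genome capability verdicts:

* reductive dehalogenase inventory (catalytic rdhA, membrane anchor rdhB,
  hypothetical dehalogenases, haloacid dehalogenase),
* CRISPR-Cas system presence,
* corrinoid (vitamin B12) biosynthesis completeness, split into the
  upstream ring-synthesis module M00924 and the downstream module M00122,
  plus the btuF salvage transporter,
* hydrogenase complex repertoire (Hyp, Hyc, Hym, Vhu, Ech, Hup),
* hydrogenotrophic methanogenesis completeness (module M00567), and
* extracellular (mtrCAB + c-type cytochrome) and intracellular
  (ABC transport + NADPH-dependent reductase) Cr(VI)-reduction machinery.

Presence is decided from annotation text only: no homology search, no
identity threshold (identity is carried as metadata).  All verdicts are
deterministic and order-independent, and monotone under record addition.
Catalogs are YAML data under ``becath/catalogs`` and can be edited
without code changes.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml

__all__ = [
    "GeneRecord",
    "PathwayBlock",
    "MarkerCatalog",
    "CapabilityReport",
    "AnnotationParseError",
    "load_catalog",
    "load_catalogs",
    "parse_annotation",
    "write_feature_tsv",
    "classify_dehalogenases",
    "detect_crispr_cas",
    "pathway_completeness",
    "detect_hydrogenase_complexes",
    "methanogenesis_completeness",
    "cobalamin_verdict",
    "cr_reduction_verdict",
    "profile_genome",
    "normalize_product",
]

DEHALOGENASE_CLASSES = (
    "catalytic_rdhA",
    "anchor_rdhB",
    "hypothetical_dehalogenase",
    "haloacid_dehalogenase",
)

_PUNCT = re.compile(r"[-–—_/,;:()\[\]*]+")
_WS = re.compile(r"\s+")


def normalize_product(text: str) -> str:
    """Lowercase, strip markup/punctuation, collapse whitespace."""
    return _WS.sub(" ", _PUNCT.sub(" ", text.lower())).strip()


class AnnotationParseError(ValueError):
    """Malformed annotation input; carries the offending line number."""


@dataclass(frozen=True)
class GeneRecord:
    """One annotated feature (CDS) of a genome bin."""

    locus_id: str
    gene_symbol: str = ""
    product: str = ""
    percent_identity: float | None = None
    ortholog_group: str | None = None

    def __post_init__(self) -> None:
        if self.percent_identity is not None and not (0 <= self.percent_identity <= 100):
            raise ValueError(
                f"{self.locus_id}: percent_identity must be in [0, 100], "
                f"got {self.percent_identity}"
            )

    @property
    def symbol_norm(self) -> str:
        return self.gene_symbol.strip().lower()

    @property
    def product_norm(self) -> str:
        return normalize_product(self.product)


@dataclass(frozen=True)
class PathwayBlock:
    """One pathway step; present iff any alternative symbol prefix hits."""

    name: str
    alternatives: tuple[str, ...]


@dataclass
class MarkerCatalog:
    """A curated marker definition loaded from YAML.

    ``raw`` keeps the full YAML mapping so detector-specific keys
    (class precedence lists, cytochrome keywords, ...) stay available.
    """

    name: str
    required_symbols: frozenset[str] = frozenset()
    keyword_patterns: frozenset[str] = frozenset()
    blocks: tuple[PathwayBlock, ...] = ()
    logic: str = "ALL"
    raw: dict = field(default_factory=dict)

    @classmethod
    def from_mapping(cls, doc: Mapping) -> "MarkerCatalog":
        blocks = tuple(
            PathwayBlock(b["name"], tuple(s.lower() for s in b["alternatives"]))
            for b in doc.get("blocks", [])
        )
        return cls(
            name=doc["name"],
            required_symbols=frozenset(s.lower() for s in doc.get("required_symbols", [])),
            keyword_patterns=frozenset(
                normalize_product(k) for k in doc.get("keyword_patterns", [])
            ),
            blocks=blocks,
            logic=doc.get("logic", "ALL"),
            raw=dict(doc),
        )


def _catalog_dir() -> Path:
    return Path(str(resources.files("becath").joinpath("catalogs")))


def load_catalog(name: str, catalog_dir: str | Path | None = None) -> MarkerCatalog:
    """Load one catalog by stem name (e.g. ``"m00567"``)."""
    directory = Path(catalog_dir) if catalog_dir else _catalog_dir()
    path = directory / f"{name}.yaml"
    with open(path) as fh:
        return MarkerCatalog.from_mapping(yaml.safe_load(fh))


def load_catalogs(catalog_dir: str | Path | None = None) -> dict[str, MarkerCatalog]:
    """Load every shipped (or user-supplied) catalog, keyed by stem."""
    directory = Path(catalog_dir) if catalog_dir else _catalog_dir()
    catalogs = {}
    for path in sorted(directory.glob("*.yaml")):
        with open(path) as fh:
            catalogs[path.stem] = MarkerCatalog.from_mapping(yaml.safe_load(fh))
    if not catalogs:
        raise FileNotFoundError(f"no catalog YAML files in {directory}")
    return catalogs


# ---------------------------------------------------------------------------
# Parsing

def _parse_feature_tsv(path: Path) -> list[GeneRecord]:
    records: list[GeneRecord] = []
    seen: set[str] = set()
    first_data_line = True
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if first_data_line:
                first_data_line = False
                if parts[0].strip().lower() in {"locus_id", "locus", "accession"}:
                    continue
            if len(parts) < 3:
                raise AnnotationParseError(
                    f"{path}:{lineno}: expected >=3 tab-separated fields, got {len(parts)}"
                )
            locus = parts[0].strip()
            if not locus:
                raise AnnotationParseError(f"{path}:{lineno}: empty locus_id")
            if locus in seen:
                raise AnnotationParseError(f"{path}:{lineno}: duplicate locus_id {locus!r}")
            seen.add(locus)
            identity: float | None = None
            if len(parts) > 3 and parts[3].strip() not in {"", "nd", "na", "-"}:
                try:
                    identity = float(parts[3])
                except ValueError as exc:
                    raise AnnotationParseError(
                        f"{path}:{lineno}: bad identity {parts[3]!r}"
                    ) from exc
            og = parts[4].strip() or None if len(parts) > 4 else None
            try:
                records.append(
                    GeneRecord(locus, parts[1].strip().lower(), parts[2].strip(),
                               identity, og)
                )
            except ValueError as exc:
                raise AnnotationParseError(f"{path}:{lineno}: {exc}") from exc
    return records


def _parse_gff3(path: Path) -> list[GeneRecord]:
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    records: list[GeneRecord] = []
    seen: set[str] = set()
    for feat in db.features_of_type("CDS"):
        locus = (feat.attributes.get("locus_tag") or feat.attributes.get("ID") or [feat.id])[0]
        if locus in seen:
            raise AnnotationParseError(f"{path}: duplicate locus_id {locus!r}")
        seen.add(locus)
        gene = (feat.attributes.get("gene") or [""])[0]
        product = (feat.attributes.get("product") or [""])[0]
        records.append(GeneRecord(locus, gene.strip().lower(), product.strip()))
    return records


def parse_annotation(path: str | Path, dialect: str = "feature_tsv") -> list[GeneRecord]:
    """Parse an annotation file into GeneRecords.

    ``dialect`` is ``"feature_tsv"`` (columns locus_id, gene, product,
    [identity, [ortholog_group]]) or ``"gff3"`` (CDS features with
    ``gene=``/``product=`` attributes).  Gene symbols are lowercased;
    duplicate locus ids raise.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "feature_tsv":
        return _parse_feature_tsv(path)
    if dialect == "gff3":
        return _parse_gff3(path)
    raise ValueError(f"unknown annotation dialect {dialect!r}")


def write_feature_tsv(records: Iterable[GeneRecord], path: str | Path) -> None:
    """Write records in the 5-column feature TSV dialect (round-trippable)."""
    with open(path, "w") as fh:
        fh.write("locus_id\tgene\tproduct\tidentity\tortholog_group\n")
        for r in records:
            ident = "" if r.percent_identity is None else f"{r.percent_identity:g}"
            fh.write(f"{r.locus_id}\t{r.gene_symbol}\t{r.product}\t{ident}\t"
                     f"{r.ortholog_group or ''}\n")


# ---------------------------------------------------------------------------
# Detectors

def _symbol_hits(record: GeneRecord, symbols: Iterable[str]) -> bool:
    return record.symbol_norm in set(symbols)


def _symbol_prefix_hits(record: GeneRecord, prefixes: Iterable[str]) -> bool:
    s = record.symbol_norm
    return bool(s) and any(s.startswith(p) for p in prefixes)


def _keyword_hits(record: GeneRecord, keywords: Iterable[str]) -> bool:
    p = record.product_norm
    return bool(p) and any(k in p for k in keywords)


def classify_dehalogenases(
    records: Sequence[GeneRecord], catalog: MarkerCatalog | None = None
) -> dict[str, int]:
    """Count dehalogenase genes by class.

    Each record is assigned to at most one class, trying the catalog's
    classes in precedence order (anchor rdhB > haloacid > catalytic rdhA >
    hypothetical); an exact gene-symbol match or a product keyword match
    qualifies.  Non-dehalogenase records are ignored.
    """
    catalog = catalog or load_catalog("dehalogenase")
    classes = catalog.raw["classes"]
    counts = {c["class"]: 0 for c in classes}
    for record in records:
        for cls in classes:
            keywords = [normalize_product(k) for k in cls.get("keywords", [])]
            if _symbol_hits(record, cls.get("symbols", [])) or _keyword_hits(record, keywords):
                counts[cls["class"]] += 1
                break
    counts["total"] = sum(counts.values())
    return counts


def detect_crispr_cas(
    records: Sequence[GeneRecord], catalog: MarkerCatalog | None = None
) -> dict:
    """CRISPR-Cas presence verdict.

    Present iff >=1 record's symbol belongs to the cas family or its
    product mentions a CRISPR-associated protein.  Regulators (LexA
    family) are listed as auxiliary evidence, never sufficient alone.
    """
    catalog = catalog or load_catalog("crispr")
    prefixes = [s.lower() for s in catalog.raw.get("core_symbol_prefixes", [])]
    core_kw = [normalize_product(k) for k in catalog.raw.get("core_keywords", [])]
    aux_kw = [normalize_product(k) for k in catalog.raw.get("auxiliary_keywords", [])]
    hits, auxiliary = [], []
    for record in records:
        if _symbol_prefix_hits(record, prefixes) or _keyword_hits(record, core_kw):
            hits.append(record.locus_id)
        elif _keyword_hits(record, aux_kw):
            auxiliary.append(record.locus_id)
    return {"present": bool(hits), "gene_hits": sorted(hits),
            "auxiliary_hits": sorted(auxiliary)}


def pathway_completeness(
    records: Sequence[GeneRecord], catalog: MarkerCatalog
) -> float:
    """Fraction of catalog blocks with at least one alternative present.

    A block alternative hits on a gene-symbol prefix (so any subunit of a
    multi-gene operon, e.g. mcrA/mcrB/mcrG, satisfies the mcr block).
    """
    if not catalog.blocks:
        raise ValueError(f"catalog {catalog.name!r} defines no pathway blocks")
    hit = 0
    for block in catalog.blocks:
        if any(_symbol_prefix_hits(r, block.alternatives) for r in records):
            hit += 1
    return hit / len(catalog.blocks)


def detect_hydrogenase_complexes(
    records: Sequence[GeneRecord], catalog: MarkerCatalog | None = None
) -> set[str]:
    """Set of hydrogenase complexes with >=1 gene present (symbol prefix)."""
    catalog = catalog or load_catalog("hydrogenase")
    complexes = catalog.raw["complexes"]
    found = set()
    for name, prefixes in complexes.items():
        if any(_symbol_prefix_hits(r, [p.lower() for p in prefixes]) for r in records):
            found.add(name)
    return found


def methanogenesis_completeness(
    records: Sequence[GeneRecord], catalog: MarkerCatalog | None = None
) -> float:
    """Completeness of the CO2->CH4 module M00567 (0-1)."""
    return pathway_completeness(records, catalog or load_catalog("m00567"))


def cobalamin_verdict(
    records: Sequence[GeneRecord],
    upstream: MarkerCatalog | None = None,
    downstream: MarkerCatalog | None = None,
) -> dict:
    """Corrinoid biosynthesis split verdict: upstream ring synthesis
    (M00924), downstream cobalamin assembly (M00122), btuF salvage."""
    upstream = upstream or load_catalog("m00924")
    downstream = downstream or load_catalog("m00122")
    transport = [s.lower() for s in downstream.raw.get("transport_symbols", [])]
    return {
        "upstream_M00924_completeness": pathway_completeness(records, upstream),
        "downstream_M00122_completeness": pathway_completeness(records, downstream),
        "btuF_transport": any(_symbol_prefix_hits(r, transport) for r in records),
    }


def cr_reduction_verdict(
    records: Sequence[GeneRecord], catalog: MarkerCatalog | None = None
) -> dict:
    """Extracellular / intracellular Cr(VI)-reduction capability.

    extracellular: complete mtrCAB conduit (mtrA and mtrB and mtrC) plus
    >=1 c-type cytochrome.  intracellular: ABC transport system (>=1
    ATP-dependent component and >=1 permease) plus an NADPH-dependent
    F420/FMN reductase (npdG).  Evidence lists the matched locus ids.
    """
    catalog = catalog or load_catalog("cr_reduction")
    extra = catalog.raw["extracellular"]
    intra = catalog.raw["intracellular"]

    mtr_needed = [s.lower() for s in extra["required_symbols"]]
    cyt_kw = [normalize_product(k) for k in extra["cytochrome_keywords"]]
    atp_kw = [normalize_product(k) for k in intra["atp_dependent_keywords"]]
    perm_kw = [normalize_product(k) for k in intra["permease_keywords"]]
    red_sym = [s.lower() for s in intra.get("reductase_symbols", [])]
    red_kw = [normalize_product(k) for k in intra.get("reductase_keywords", [])]

    mtr_hits = {s: [] for s in mtr_needed}
    cytochromes, atp_dependent, permeases, reductases = [], [], [], []
    for r in records:
        for s in mtr_needed:
            if r.symbol_norm == s:
                mtr_hits[s].append(r.locus_id)
        if _keyword_hits(r, cyt_kw):
            cytochromes.append(r.locus_id)
        if _keyword_hits(r, atp_kw) and not _keyword_hits(r, perm_kw):
            atp_dependent.append(r.locus_id)
        if _keyword_hits(r, perm_kw):
            permeases.append(r.locus_id)
        if _symbol_hits(r, red_sym) or _keyword_hits(r, red_kw):
            reductases.append(r.locus_id)

    extracellular = all(mtr_hits[s] for s in mtr_needed) and bool(cytochromes)
    intracellular = bool(atp_dependent) and bool(permeases) and bool(reductases)
    return {
        "extracellular": extracellular,
        "intracellular": intracellular,
        "evidence": {
            "mtrCAB": {s: sorted(v) for s, v in mtr_hits.items()},
            "c_type_cytochromes": sorted(cytochromes),
            "abc_atp_dependent": sorted(atp_dependent),
            "abc_permeases": sorted(permeases),
            "nadph_reductases": sorted(reductases),
        },
    }


@dataclass
class CapabilityReport:
    """Per-genome capability verdicts; JSON-serializable and deterministic."""

    genome_id: str
    dehalogenase_inventory: dict[str, int]
    crispr: dict
    cobalamin: dict
    methanogenesis_M00567_completeness: float
    hydrogenase_complexes: list[str]
    cr_reduction: dict

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, **kwargs)

    @classmethod
    def from_json(cls, text: str) -> "CapabilityReport":
        return cls(**json.loads(text))


def profile_genome(
    records: Sequence[GeneRecord],
    catalogs: Mapping[str, MarkerCatalog] | None = None,
    genome_id: str = "genome",
) -> CapabilityReport:
    """Run every detector and assemble a CapabilityReport.

    The report is a pure function of the record *set*: reordering or
    duplicating input never changes verdicts (dehalogenase counts count
    records, so duplicates there are the caller's responsibility —
    locus-id uniqueness is enforced at parse time).
    """
    catalogs = catalogs or load_catalogs()
    return CapabilityReport(
        genome_id=genome_id,
        dehalogenase_inventory=classify_dehalogenases(records, catalogs.get("dehalogenase")),
        crispr=detect_crispr_cas(records, catalogs.get("crispr")),
        cobalamin=cobalamin_verdict(records, catalogs.get("m00924"), catalogs.get("m00122")),
        methanogenesis_M00567_completeness=methanogenesis_completeness(
            records, catalogs.get("m00567")
        ),
        hydrogenase_complexes=sorted(
            detect_hydrogenase_complexes(records, catalogs.get("hydrogenase"))
        ),
        cr_reduction=cr_reduction_verdict(records, catalogs.get("cr_reduction")),
    )
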