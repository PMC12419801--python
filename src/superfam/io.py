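"""Readers and writers for every external representation the pipeline touches.

Conventions enforced here and assumed everywhere downstream:

* genomic coordinates are 1-based, inclusive (the GFF3 convention);
* amino-acid coordinates are 1-based, inclusive (the HMMER convention);
* tables are plain TSV with a header row;
* networks round-trip through GraphML or a TSV edge list without losing
  isolated nodes or edge weights.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

from .errors import FormatError, ValidationError

logger = logging.getLogger("superfam")

GENE_TSV_COLUMNS = [
    "genome_id",
    "contig_id",
    "gene_id",
    "start",
    "end",
    "strand",
    "product_id",
]

DOMAIN_TSV_COLUMNS = [
    "product_id",
    "domain_name",
    "aa_start",
    "aa_end",
    "score",
    "source",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneRecord:
    """One protein-coding gene on a contig; coordinates 1-based inclusive."""

    genome_id: str
    contig_id: str
    gene_id: str
    start: int
    end: int
    strand: str
    product_id: str

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValidationError(
                f"gene {self.gene_id!r}: start must be >= 1, got {self.start}"
            )
        if self.end < self.start:
            raise ValidationError(
                f"gene {self.gene_id!r}: end ({self.end}) < start ({self.start})"
            )
        if self.strand not in ("+", "-"):
            raise ValidationError(
                f"gene {self.gene_id!r}: strand must be '+' or '-', got {self.strand!r}"
            )


@dataclass(frozen=True)
class DomainHit:
    """One domain model hit on a protein product (envelope coordinates)."""

    product_id: str
    domain_name: str
    aa_start: int
    aa_end: int
    score: float
    source: str = "-"

    def __post_init__(self) -> None:
        if self.aa_start < 1:
            raise ValidationError(
                f"hit {self.domain_name!r} on {self.product_id!r}: "
                f"aa_start must be >= 1, got {self.aa_start}"
            )
        if self.aa_end < self.aa_start:
            raise ValidationError(
                f"hit {self.domain_name!r} on {self.product_id!r}: "
                f"aa_end ({self.aa_end}) < aa_start ({self.aa_start})"
            )


@dataclass(frozen=True)
class FunctionalLabelMap:
    """Domain-name → biochemical-function category map over a declared vocabulary.

    Unmapped domains are permitted and treated as unlabeled downstream.
    """

    vocabulary: tuple[str, ...]
    mapping: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        vocab = set(self.vocabulary)
        if len(vocab) != len(self.vocabulary):
            raise ValidationError("duplicate category in vocabulary")
        for domain, category in self.mapping.items():
            if category not in vocab:
                raise ValidationError(
                    f"domain {domain!r} mapped to undeclared category {category!r}"
                )

    def category_of(self, domain: str) -> str | None:
        return self.mapping.get(domain)


# ---------------------------------------------------------------------------
# gene tables
# ---------------------------------------------------------------------------

def read_gene_table(path: str | Path, dialect: str = "tsv",
                    genome_id: str | None = None) -> list[GeneRecord]:
    """Read gene records from a flat TSV or a GFF3 file.

    TSV columns: genome_id, contig_id, gene_id, start, end, strand, product_id.
    GFF3: CDS features with an ``ID`` attribute; ``protein_id`` (falling back
    to ``ID``) supplies the product, a ``genome_id`` attribute (falling back to
    the ``genome_id`` argument, then the file stem) supplies the genome.
    Records come back sorted by (genome_id, contig_id, start).
    """
    path = Path(path)
    if dialect == "tsv":
        records = _read_gene_tsv(path)
    elif dialect == "gff3":
        records = _read_gene_gff3(path, genome_id=genome_id)
    else:
        raise ValueError(f"unknown gene-table dialect {dialect!r}")
    _check_unique_gene_ids(records)
    return sorted(records, key=lambda r: (r.genome_id, r.contig_id, r.start, r.gene_id))


def _read_gene_tsv(path: Path) -> list[GeneRecord]:
    frame = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in GENE_TSV_COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    records = []
    for idx, row in frame.iterrows():
        try:
            records.append(GeneRecord(
                genome_id=row["genome_id"],
                contig_id=row["contig_id"],
                gene_id=row["gene_id"],
                start=int(row["start"]),
                end=int(row["end"]),
                strand=row["strand"],
                product_id=row["product_id"],
            ))
        except (ValidationError, ValueError) as exc:
            # +2: header line plus 1-based numbering
            raise ValidationError(f"{path}, line {idx + 2}: {exc}") from exc
    return records


def _read_gene_gff3(path: Path, genome_id: str | None = None) -> list[GeneRecord]:
    import gffutils

    default_genome = genome_id if genome_id is not None else path.stem
    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    records = []
    for feat in db.features_of_type("CDS"):
        attrs = feat.attributes
        if "ID" not in attrs:
            raise FormatError(f"{path}: CDS at {feat.seqid}:{feat.start} lacks ID attribute")
        gid = attrs["ID"][0]
        product = attrs.get("protein_id", [gid])[0]
        gnm = attrs.get("genome_id", [default_genome])[0]
        try:
            records.append(GeneRecord(
                genome_id=gnm,
                contig_id=feat.seqid,
                gene_id=gid,
                start=feat.start,
                end=feat.end,
                strand=feat.strand,
                product_id=product,
            ))
        except ValidationError as exc:
            raise ValidationError(f"{path}: CDS {gid!r}: {exc}") from exc
    return records


def _check_unique_gene_ids(records: Sequence[GeneRecord]) -> None:
    seen: set[tuple[str, str]] = set()
    for rec in records:
        key = (rec.genome_id, rec.gene_id)
        if key in seen:
            raise ValidationError(f"duplicate gene id {key} in dataset")
        seen.add(key)


def write_gene_table(records: Iterable[GeneRecord], path: str | Path,
                     dialect: str = "tsv") -> None:
    path = Path(path)
    records = list(records)
    if dialect == "tsv":
        frame = pd.DataFrame(
            [(r.genome_id, r.contig_id, r.gene_id, r.start, r.end, r.strand,
              r.product_id) for r in records],
            columns=GENE_TSV_COLUMNS,
        )
        frame.to_csv(path, sep="\t", index=False)
    elif dialect == "gff3":
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for r in records:
                attrs = (f"ID={r.gene_id};protein_id={r.product_id};"
                         f"genome_id={r.genome_id}")
                fh.write("\t".join([
                    r.contig_id, "superfam", "CDS", str(r.start), str(r.end),
                    ".", r.strand, "0", attrs,
                ]) + "\n")
    else:
        raise ValueError(f"unknown gene-table dialect {dialect!r}")


# ---------------------------------------------------------------------------
# domain hits
# ---------------------------------------------------------------------------

def read_domain_hits(path: str | Path, dialect: str = "tsv") -> list[DomainHit]:
    """Read per-domain hits from a flat TSV or an HMMER3 ``domtblout`` table.

    The domtblout dialect follows hmmscan orientation: target name = domain
    model, query name = protein product; envelope coordinates (columns 20-21)
    are used, per-domain bit score is column 14.
    """
    path = Path(path)
    if dialect == "tsv":
        return _read_domain_tsv(path)
    if dialect == "domtblout":
        return _read_domtblout(path)
    raise ValueError(f"unknown domain-hit dialect {dialect!r}")


def _read_domain_tsv(path: Path) -> list[DomainHit]:
    frame = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in DOMAIN_TSV_COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    hits = []
    for idx, row in frame.iterrows():
        try:
            hits.append(DomainHit(
                product_id=row["product_id"],
                domain_name=row["domain_name"],
                aa_start=int(row["aa_start"]),
                aa_end=int(row["aa_end"]),
                score=float(row["score"]),
                source=row["source"],
            ))
        except (ValidationError, ValueError) as exc:
            raise ValidationError(f"{path}, line {idx + 2}: {exc}") from exc
    return hits


def _read_domtblout(path: Path) -> list[DomainHit]:
    hits = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 22:
                raise FormatError(
                    f"{path}, line {lineno}: expected >= 22 whitespace-separated "
                    f"fields, got {len(fields)}"
                )
            try:
                hits.append(DomainHit(
                    product_id=fields[3],
                    domain_name=fields[0],
                    aa_start=int(fields[19]),
                    aa_end=int(fields[20]),
                    score=float(fields[13]),
                    source=fields[1],
                ))
            except (ValidationError, ValueError) as exc:
                raise ValidationError(f"{path}, line {lineno}: {exc}") from exc
    return hits


def write_domain_hits(hits: Iterable[DomainHit], path: str | Path,
                      dialect: str = "tsv") -> None:
    path = Path(path)
    hits = list(hits)
    if dialect == "tsv":
        frame = pd.DataFrame(
            [(h.product_id, h.domain_name, h.aa_start, h.aa_end, h.score,
              h.source) for h in hits],
            columns=DOMAIN_TSV_COLUMNS,
        )
        frame.to_csv(path, sep="\t", index=False)
    elif dialect == "domtblout":
        with open(path, "w") as fh:
            fh.write("# superfam domtblout (hmmscan orientation)\n")
            for h in hits:
                fields = [
                    h.domain_name, h.source, "0", h.product_id, "-", "0",
                    "0", "0", "0", "1", "1", "0", "0", repr(h.score), "0",
                    "0", "0", str(h.aa_start), str(h.aa_end),
                    str(h.aa_start), str(h.aa_end), "0.0", "-",
                ]
                fh.write(" ".join(fields) + "\n")
    else:
        raise ValueError(f"unknown domain-hit dialect {dialect!r}")


# ---------------------------------------------------------------------------
# functional-label YAML
# ---------------------------------------------------------------------------

def read_label_yaml(path: str | Path) -> FunctionalLabelMap:
    """Read a functional-label map: top-level ``categories`` and ``domains``."""
    path = Path(path)
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict) or "categories" not in data:
        raise FormatError(f"{path}: expected top-level 'categories' key")
    categories = data["categories"]
    domains = data.get("domains") or {}
    if not isinstance(categories, list):
        raise FormatError(f"{path}: 'categories' must be a list")
    if not isinstance(domains, dict):
        raise FormatError(f"{path}: 'domains' must be a mapping")
    try:
        return FunctionalLabelMap(vocabulary=tuple(categories), mapping=dict(domains))
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}") from exc


def write_label_yaml(labels: FunctionalLabelMap, path: str | Path) -> None:
    data = {
        "categories": list(labels.vocabulary),
        "domains": {k: labels.mapping[k] for k in sorted(labels.mapping)},
    }
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False, default_flow_style=False)


# ---------------------------------------------------------------------------
# sequences and family tables
# ---------------------------------------------------------------------------

def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    """Write ``sequence_id -> residues`` as FASTA (insertion order preserved)."""
    records = [
        _BioSeqRecord(Seq(res), id=seq_id, description="")
        for seq_id, res in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def read_family_table(path: str | Path) -> pd.DataFrame:
    """Read a sequence → family assignment TSV (sequence_id, family_id)."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in ("sequence_id", "family_id") if c not in frame.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    return frame


def write_family_table(assignments: Mapping[str, str], path: str | Path) -> None:
    frame = pd.DataFrame(
        sorted(assignments.items()), columns=["sequence_id", "family_id"]
    )
    frame.to_csv(path, sep="\t", index=False)


def read_comparison_table(path: str | Path) -> pd.DataFrame:
    """Read a profile-profile comparison TSV (query, target, p_value, e_value)."""
    frame = pd.read_csv(path, sep="\t")
    missing = [c for c in ("query_family", "target_family", "p_value", "e_value")
               if c not in frame.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    return frame


# ---------------------------------------------------------------------------
# networks
# ---------------------------------------------------------------------------

def write_network(graph: nx.Graph, path: str | Path, dialect: str = "graphml",
                  weight_attr: str = "weight") -> None:
    """Write a weighted undirected graph re-readably.

    The TSV edge-list dialect keeps isolated nodes as rows with empty target
    and weight fields so the round trip is lossless.
    """
    path = Path(path)
    for a, b, data in graph.edges(data=True):
        w = data.get(weight_attr, 1.0)
        if not math.isfinite(w) or w < 0:
            raise ValidationError(
                f"edge ({a!r}, {b!r}): weight must be finite and non-negative, got {w}"
            )
    if dialect == "graphml":
        nx.write_graphml(graph, str(path))
    elif dialect == "edgelist_tsv":
        with open(path, "w") as fh:
            fh.write(f"source\ttarget\t{weight_attr}\n")
            covered = set()
            for a, b, data in sorted(graph.edges(data=True),
                                     key=lambda e: (str(e[0]), str(e[1]))):
                fh.write(f"{a}\t{b}\t{data.get(weight_attr, 1.0):.12g}\n")
                covered.update((a, b))
            for node in sorted(set(graph.nodes) - covered, key=str):
                fh.write(f"{node}\t\t\n")
    else:
        raise ValueError(f"unknown network dialect {dialect!r}")


def read_network(path: str | Path, dialect: str = "graphml",
                 weight_attr: str = "weight") -> nx.Graph:
    path = Path(path)
    if dialect == "graphml":
        return nx.read_graphml(str(path))
    if dialect == "edgelist_tsv":
        graph = nx.Graph()
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            if len(header) < 3:
                raise FormatError(f"{path}: expected 3-column edge-list header")
            for lineno, line in enumerate(fh, start=2):
                parts = line.rstrip("\n").split("\t")
                if len(parts) != 3:
                    raise FormatError(f"{path}, line {lineno}: expected 3 columns")
                a, b, w = parts
                if b == "":
                    graph.add_node(a)
                else:
                    graph.add_edge(a, b, **{weight_attr: float(w)})
        return graph
    raise ValueError(f"unknown network dialect {dialect!r}")


# ---------------------------------------------------------------------------
# logging / config plumbing
# ---------------------------------------------------------------------------

def setup_logging(level: str = "INFO") -> None:
    """Configure stderr logging for the package (idempotent)."""
    root = logging.getLogger("superfam")
    root.setLevel(getattr(logging, level.upper()))
    if not root.handlers:
        handler = logging.StreamHandler()
        handler.setFormatter(
            logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s")
        )
        root.addHandler(handler)


def load_config(path: str | Path | None) -> dict:
    """Load a YAML run configuration; ``None`` yields an empty config."""
    if path is None:
        return {}
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if data is None:
        return {}
    if not isinstance(data, dict):
        raise FormatError(f"{path}: config must be a YAML mapping")
    return data
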