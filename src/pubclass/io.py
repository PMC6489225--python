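"""Readers, writers and record types for the gene-family pipeline.

Handles the gene catalog dialect ("chrNH:start–end" loci with digit-grouping
commas and blank EST cells), three domain-annotation dialects (InterProScan
TSV, HMMER3 ``hmmscan --domtblout``, and a minimal 5-column TSV), aligned
FASTA, newick, and Cq (quantification cycle) tables.

All genomic and residue coordinates are 1-based inclusive.
"""

from __future__ import annotations

import csv
import io as _stdio
import logging
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)


class ParseError(ValueError):
    """Input text does not conform to the declared dialect."""


class ValidationError(ValueError):
    """Parsed values violate a record invariant."""


class UsageError(ValueError):
    """Caller asked for an unknown format/option."""


# ---------------------------------------------------------------------------
# controlled domain vocabulary
# ---------------------------------------------------------------------------

DOMAIN_LABELS = frozenset({
    "U_BOX", "UFD2", "ARM", "HEAT", "ARM_LIKE", "CYCLOPHILIN",
    "PKC", "STK_N", "WD40", "TPR", "MIF4G", "DJ1", "OTHER",
})

#: Default accession/name -> controlled label map. Keys are matched
#: case-insensitively after stripping punctuation variants (e.g. "u-box").
DEFAULT_VOCAB: Mapping[str, str] = {
    # Pfam accessions
    "PF04564": "U_BOX",
    "PF04056": "UFD2",
    "PF00514": "ARM",
    "PF02985": "HEAT",
    "PF00160": "CYCLOPHILIN",
    "PF00069": "PKC",
    "PF00400": "WD40",
    "PF00515": "TPR",
    "PF02854": "MIF4G",
    "PF01965": "DJ1",
    # common free-text names
    "UBOX": "U_BOX",
    "U_BOX": "U_BOX",
    "UFD2": "UFD2",
    "ARM": "ARM",
    "ARMADILLO": "ARM",
    "HEAT": "HEAT",
    "ARM_LIKE": "ARM_LIKE",
    "ARMLIKE": "ARM_LIKE",
    "GKL": "ARM_LIKE",
    "CYCLOPHILIN": "CYCLOPHILIN",
    "PRO_ISOMERASE": "CYCLOPHILIN",
    "PKC": "PKC",
    "PKINASE": "PKC",
    "STK_N": "STK_N",
    "STKN": "STK_N",
    "WD40": "WD40",
    "TPR": "TPR",
    "TRP": "TPR",   # the literature sometimes transposes the repeat acronym
    "MIF4G": "MIF4G",
    "DJ1": "DJ1",
    "DJ_1": "DJ1",
}


def normalize_domain_label(raw: str, vocab: Optional[Mapping[str, str]] = None) -> str:
    """Map an accession or free-text domain name to a controlled label.

    Total function: unknown input maps to ``OTHER`` with a logged warning.
    Matching is case-insensitive and ignores ``-``/``.``/space variants.
    """
    table = DEFAULT_VOCAB if vocab is None else vocab
    if raw in DOMAIN_LABELS:
        return raw
    key = re.sub(r"[\s\.\-]", "_", raw.strip()).upper().replace("__", "_")
    for candidate in (raw.strip(), key, key.replace("_", "")):
        for k, v in table.items():
            if k.upper() == str(candidate).upper():
                return v
    logger.warning("unmapped domain label %r -> OTHER", raw)
    return "OTHER"


# ---------------------------------------------------------------------------
# record types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DomainHit:
    """A located domain on a protein (residue coordinates, 1-based inclusive)."""

    label: str
    start_aa: int
    end_aa: int
    source_accession: Optional[str] = None
    score: Optional[float] = None

    def __post_init__(self):
        if self.label not in DOMAIN_LABELS:
            raise ValidationError(f"unknown domain label {self.label!r}")
        if not (1 <= self.start_aa <= self.end_aa):
            raise ValidationError(
                f"bad hit coordinates [{self.start_aa},{self.end_aa}] for {self.label}")

    @property
    def midpoint(self) -> float:
        return (self.start_aa + self.end_aa) / 2.0


@dataclass
class ProteinRecord:
    """A protein with length and an ordered set of located domain hits."""

    id: str
    length_aa: int
    domains: tuple[DomainHit, ...] = ()
    species: str = ""

    def __post_init__(self):
        if self.length_aa < 1:
            raise ValidationError(f"{self.id}: length must be >= 1")
        for h in self.domains:
            if h.end_aa > self.length_aa:
                raise ValidationError(
                    f"{self.id}: hit {h.label} [{h.start_aa},{h.end_aa}] exceeds "
                    f"protein length {self.length_aa}")
        self.domains = tuple(sorted(self.domains, key=lambda h: (h.start_aa, h.end_aa)))

    def hits(self, label: str) -> tuple[DomainHit, ...]:
        return tuple(h for h in self.domains if h.label == label)

    def has(self, *labels: str) -> bool:
        present = {h.label for h in self.domains}
        return any(l in present for l in labels)


@dataclass(frozen=True)
class CatalogEntry:
    """One gene-catalog row: symbol, locus and EST library counts."""

    name: str
    gene_id: str
    chromosome: str
    start_bp: int
    end_bp: int
    class_label: Optional[str] = None
    est_counts: tuple[int, int, int, int] = (0, 0, 0, 0)  # abiotic, biotic, generative, vegetative

    def __post_init__(self):
        if self.start_bp > self.end_bp:
            raise ValidationError(f"{self.name}: start_bp > end_bp")
        if any(c < 0 for c in self.est_counts):
            raise ValidationError(f"{self.name}: negative EST count")


EST_CATEGORIES = ("abiotic", "biotic", "generative", "vegetative")

_LOCUS_RE = re.compile(r"^(?P<chrom>\S+?):(?P<start>[\d,]+)\s*[–-]\s*(?P<end>[\d,]+)$")


def parse_locus(text: str) -> tuple[str, int, int]:
    """Split "chr7H:625630612–625,636,687" into (chromosome, start, end).

    Accepts both en-dash and hyphen separators and digit-grouping commas.
    """
    m = _LOCUS_RE.match(text.strip())
    if not m:
        raise ParseError(f"malformed locus string {text!r}")
    start = int(m.group("start").replace(",", ""))
    end = int(m.group("end").replace(",", ""))
    return m.group("chrom"), start, end


def read_gene_catalog(path, dialect: str = "table1_tsv") -> list[CatalogEntry]:
    """Parse a gene catalog TSV (columns: class, name, gene_id, locus, 4 EST cells).

    Blank EST cells are read as zero. Duplicate gene names are rejected.
    """
    if dialect != "table1_tsv":
        raise UsageError(f"unknown catalog dialect {dialect!r}")
    entries: list[CatalogEntry] = []
    seen: set[str] = set()
    with open(path, newline="", encoding="utf-8") as fh:
        rows = [r for r in csv.reader(fh, delimiter="\t")
                if r and not r[0].startswith("#")]
    header = [c.strip().lower() for c in rows[0]]
    if "name" not in header or "locus" not in header:
        raise UsageError("catalog header must contain 'name' and 'locus' columns")
    idx = {c: header.index(c) for c in header}
    est_idx = [idx[c] for c in EST_CATEGORIES if c in idx]
    for rowno, row in enumerate(rows[1:], start=2):
        def cell(i):
            return row[i].strip() if i < len(row) else ""
        name = cell(idx["name"])
        if name in seen:
            raise ValidationError(f"duplicate gene name {name!r} (row {rowno})")
        seen.add(name)
        try:
            chrom, start, end = parse_locus(cell(idx["locus"]))
        except ParseError as e:
            raise ParseError(f"row {rowno} ({name or 'unnamed'}): {e}") from e
        ests = tuple(int(cell(i)) if cell(i) else 0 for i in est_idx)
        ests = tuple(list(ests) + [0] * (4 - len(ests)))
        entries.append(CatalogEntry(
            name=name,
            gene_id=cell(idx["gene_id"]) if "gene_id" in idx else "",
            chromosome=chrom, start_bp=start, end_bp=end,
            class_label=cell(idx["class"]) or None if "class" in idx else None,
            est_counts=ests,
        ))
    return entries


def write_gene_catalog(entries: Iterable[CatalogEntry], path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["class", "name", "gene_id", "locus", *EST_CATEGORIES])
        for e in entries:
            w.writerow([e.class_label or "", e.name, e.gene_id,
                        f"{e.chromosome}:{e.start_bp}-{e.end_bp}",
                        *e.est_counts])


def load_barley_catalog() -> list[CatalogEntry]:
    """The packaged 67-gene barley PUB catalog.

    Transcribed from the published table of named HvPUB genes. Locus strings,
    gene IDs and class labels are exact; where the source print leaves the
    assignment of partially blank EST cells to the four library categories
    ambiguous, counts were placed left-to-right (abiotic, biotic, generative,
    vegetative) as a best-effort reconstruction.
    """
    ref = resources.files("pubclass").joinpath("data/barley_table1.tsv")
    with resources.as_file(ref) as p:
        return read_gene_catalog(p)


# ---------------------------------------------------------------------------
# domain annotations
# ---------------------------------------------------------------------------

def _merge_same_label(hits: list[DomainHit]) -> list[DomainHit]:
    """Merge overlapping (or touching) hits of the same label into their union."""
    out: list[DomainHit] = []
    for h in sorted(hits, key=lambda h: (h.label, h.start_aa, h.end_aa)):
        if out and out[-1].label == h.label and h.start_aa <= out[-1].end_aa + 1:
            prev = out.pop()
            out.append(DomainHit(prev.label, prev.start_aa,
                                 max(prev.end_aa, h.end_aa),
                                 prev.source_accession, prev.score))
        else:
            out.append(h)
    return sorted(out, key=lambda h: (h.start_aa, h.end_aa))


def read_domain_annotations(path, format: str = "simple_tsv",
                            vocab: Optional[Mapping[str, str]] = None,
                            ) -> list[ProteinRecord]:
    """Parse per-protein domain annotations into ProteinRecord objects.

    Formats: ``simple_tsv`` (protein, length, label, start, end),
    ``interproscan_tsv`` (standard 14-column output), or
    ``hmmscan_domtblout`` (HMMER3 ``--domtblout``; alignment coordinates,
    i.e. the "ali from/to" columns, are used — not the envelope).

    Hits are grouped by protein, labels normalised to the controlled
    vocabulary, sorted by start, and same-label overlaps merged.
    """
    parsers = {
        "simple_tsv": _parse_simple_tsv,
        "interproscan_tsv": _parse_interproscan,
        "hmmscan_domtblout": _parse_domtblout,
    }
    if format not in parsers:
        raise UsageError(f"unknown annotation format {format!r}")
    raw = parsers[format](path, vocab)
    records = []
    for pid, (length, hits) in raw.items():
        try:
            records.append(ProteinRecord(id=pid, length_aa=length,
                                         domains=tuple(_merge_same_label(hits))))
        except ValidationError as e:
            raise ValidationError(f"protein {pid}: {e}") from e
    return records


def _parse_simple_tsv(path, vocab):
    out: dict[str, tuple[int, list[DomainHit]]] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) != 5:
                raise ParseError(f"simple_tsv rows need 5 fields, got {len(fields)}: {line!r}")
            pid, length, label, start, end = fields
            length = int(length)
            hit = DomainHit(normalize_domain_label(label, vocab), int(start), int(end),
                            source_accession=label)
            out.setdefault(pid, (length, []))[1].append(hit)
    return out


def _parse_interproscan(path, vocab):
    # columns: 0 protein, 1 md5, 2 length, 3 analysis, 4 signature acc,
    # 5 signature desc, 6 start, 7 stop, 8 score, ...
    out: dict[str, tuple[int, list[DomainHit]]] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9:
                raise ParseError(f"interproscan_tsv row has {len(f)} columns, need >= 9")
            pid, length, acc = f[0], int(f[2]), f[4]
            score = float(f[8]) if f[8] not in ("", "-") else None
            hit = DomainHit(normalize_domain_label(acc, vocab), int(f[6]), int(f[7]),
                            source_accession=acc, score=score)
            out.setdefault(pid, (length, []))[1].append(hit)
    return out


def _parse_domtblout(path, vocab):
    # hmmscan --domtblout: whitespace-separated, 22 fixed columns + description.
    # 0 target name, 1 target acc, 3 query (protein), 5 qlen, 13 dom score,
    # 17 ali from, 18 ali to (alignment coordinates; envelope cols 19-20 unused).
    out: dict[str, tuple[int, list[DomainHit]]] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.split()
            if len(f) < 22:
                raise ParseError(f"domtblout row has {len(f)} columns, need >= 22")
            target, target_acc, pid, qlen = f[0], f[1], f[3], int(f[5])
            acc = target_acc if target_acc != "-" else target
            label = normalize_domain_label(acc.split(".")[0], vocab)
            if label == "OTHER":
                label = normalize_domain_label(target, vocab)
            hit = DomainHit(label, int(f[17]), int(f[18]),
                            source_accession=acc, score=float(f[13]))
            out.setdefault(pid, (qlen, []))[1].append(hit)
    return out


def write_domain_annotations(records: Iterable[ProteinRecord], path) -> None:
    """Write records in the simple 5-column TSV dialect."""
    with open(path, "w", encoding="utf-8") as fh:
        for r in records:
            for h in r.domains:
                fh.write(f"{r.id}\t{r.length_aa}\t{h.label}\t{h.start_aa}\t{h.end_aa}\n")


# ---------------------------------------------------------------------------
# alignments and trees
# ---------------------------------------------------------------------------

def read_aligned_fasta(path) -> "Alignment":
    """Read an aligned FASTA into an Alignment; rows must be equal length."""
    from .phylo import Alignment
    ids, seqs = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        ids.append(rec.id)
        seqs.append(str(rec.seq).upper())
    if not ids:
        raise ParseError(f"no sequences in {path}")
    return Alignment(ids, seqs)


def write_aligned_fasta(aln: "Alignment", path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for i, s in zip(aln.ids, aln.seqs):
            fh.write(f">{i}\n{s}\n")


def write_newick(tree, path=None) -> str:
    """Serialise a PhyloTree (branch lengths; integer support as internal labels)."""
    text = tree.to_newick()
    if path is not None:
        Path(path).write_text(text + "\n", encoding="utf-8")
    return text


def read_newick(source):
    """Parse newick text or a file path into a dendropy Tree."""
    import dendropy
    text = source if ";" in str(source) else Path(source).read_text(encoding="utf-8")
    return dendropy.Tree.get(data=text, schema="newick")


# ---------------------------------------------------------------------------
# Cq tables
# ---------------------------------------------------------------------------

CQ_COLUMNS = ("gene", "condition", "bio_rep", "tech_rep", "cq")


@dataclass
class CqTable:
    """Raw quantification cycles: one row per (gene, condition, bio, tech) well."""

    data: pd.DataFrame
    reference_gene: str

    def __post_init__(self):
        missing = [c for c in CQ_COLUMNS if c not in self.data.columns]
        if missing:
            raise UsageError(f"Cq table missing required column(s) {missing}")
        df = self.data
        if (df["cq"] < 0).any():
            raise ValidationError("Cq values must be >= 0")
        groups = set(map(tuple, df[["condition", "bio_rep"]].drop_duplicates().values))
        ref_groups = set(map(tuple, df.loc[df["gene"] == self.reference_gene,
                                           ["condition", "bio_rep"]].drop_duplicates().values))
        if groups - ref_groups:
            raise ValidationError(
                f"reference gene {self.reference_gene!r} missing from "
                f"replicate group(s) {sorted(groups - ref_groups)}")

    @property
    def genes(self) -> list[str]:
        return sorted(self.data["gene"].unique())

    @property
    def conditions(self) -> list[str]:
        return sorted(self.data["condition"].unique())


def read_cq_table(path, reference_gene: str) -> CqTable:
    df = pd.read_csv(path, comment="#")
    return CqTable(df, reference_gene)


def write_cq_table(cq: CqTable, path, header_comment: str = "") -> None:
    with open(path, "w", encoding="utf-8") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        cq.data.to_csv(fh, index=False)
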