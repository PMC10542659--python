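"""Disease-variant association database: parsing, indexing, persistence.

The database holds one record per published disease association: a genomic
locus (chromosome + 1-based position), the associated alleles, the GWAS
p-value, the trait/disease name and the source database it came from.
Records are indexed by ``(chrom, pos)`` — the join key used when annotating
a VCF — and can be compiled once into a versioned on-disk store that loads
much faster than re-parsing the TSV.

p-values are kept twice: as a float (used for filtering and ordering) and as
the original text from the source file (echoed verbatim in reports, so
heterogeneous formats like ``2.00E−12`` and ``2E-170`` survive a round trip).
"""

from __future__ import annotations

import csv
import gzip
import json
import math
from dataclasses import dataclass
from typing import IO, Iterable

from .errors import (
    SchemaError,
    StoreIntegrityError,
    StoreVersionError,
    ValidationError,
)

STORE_FORMAT = "varhits-store"
STORE_VERSION = "1.0"

#: Logical field name -> default header name in the association TSV.
DEFAULT_SCHEMA = {
    "chrom": "chrom",
    "pos": "pos",
    "rsid": "rsid",
    "ref_allele": "ref",
    "alt_allele": "alt",
    "gene": "gene",
    "consequence": "consequence",
    "p_value": "p_value",
    "disease": "disease",
    "source_db": "source_db",
}

MANDATORY_FIELDS = ("chrom", "pos", "p_value", "disease", "source_db")

_ALLELE_CHARS = frozenset("ACGTN")


def normalize_chrom(name: str) -> str:
    """Canonicalize a chromosome name.

    Case-insensitive; strips a leading ``chr``; maps ``M`` to ``MT``.
    Unknown contigs are returned upper-cased unchanged — they are legal,
    they simply never match anything in a human database.

    >>> normalize_chrom("chr6")
    '6'
    >>> normalize_chrom("chrM")
    'MT'
    """
    if name is None or not name.strip():
        raise ValidationError("chromosome name is empty")
    canon = name.strip().upper()
    if canon.startswith("CHR"):
        canon = canon[3:]
    if canon == "M":
        canon = "MT"
    if not canon:
        raise ValidationError(f"chromosome name {name!r} is empty after normalization")
    return canon


def parse_p_value(text: str) -> float:
    """Parse a p-value string, tolerating the Unicode minus sign (U+2212).

    Raises ValueError if the text is not a number in (0, 1].
    """
    value = float(text.strip().replace("−", "-"))
    if not (0.0 < value <= 1.0) or math.isnan(value):
        raise ValueError(f"p-value {text!r} outside (0, 1]")
    return value


@dataclass(frozen=True)
class DiseaseVariantRecord:
    """One disease-association row: locus + alleles + p-value + provenance."""

    chrom: str
    pos: int
    rsid: str
    ref_allele: str
    alt_allele: str
    gene: str
    consequence: str
    p_value: float
    p_text: str
    disease: str
    source_db: str

    def __post_init__(self):
        if self.pos < 1:
            raise ValidationError(f"position must be >= 1, got {self.pos}")
        if not (0.0 < self.p_value <= 1.0):
            raise ValidationError(f"p-value must be in (0, 1], got {self.p_value}")
        if not self.disease:
            raise ValidationError("disease name is empty")
        if not self.source_db:
            raise ValidationError("source database name is empty")

    @property
    def key(self) -> tuple[str, int]:
        return (self.chrom, self.pos)

    def identity(self) -> tuple:
        """The full ten-field tuple used for exact-duplicate detection."""
        return (
            self.chrom, self.pos, self.rsid, self.ref_allele, self.alt_allele,
            self.gene, self.consequence, self.p_text, self.disease, self.source_db,
        )


@dataclass
class ParseSummary:
    """Outcome of one TSV parse: row accounting plus warning flags."""

    rows_read: int = 0
    records_parsed: int = 0
    rows_dropped: int = 0
    empty_input: bool = False


@dataclass
class DbMeta:
    build_tag: str = "GRCh38"
    source_name: str = ""
    record_count: int = 0
    created: str = ""
    dedup_count: int = 0

    def to_dict(self) -> dict:
        return {
            "build_tag": self.build_tag,
            "source_name": self.source_name,
            "record_count": self.record_count,
            "created": self.created,
            "dedup_count": self.dedup_count,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DbMeta":
        return cls(
            build_tag=d.get("build_tag", ""),
            source_name=d.get("source_name", ""),
            record_count=int(d.get("record_count", 0)),
            created=d.get("created", ""),
            dedup_count=int(d.get("dedup_count", 0)),
        )


class VariantDatabase:
    """Position-indexed collection of association records.

    Every record is reachable through the index at exactly its own
    ``(chrom, pos)`` key; lookups of absent loci return the empty list.
    """

    def __init__(self, records: list[DiseaseVariantRecord], meta: DbMeta):
        self.records = list(records)
        self.meta = meta
        self.meta.record_count = len(self.records)
        self._index: dict[tuple[str, int], list[DiseaseVariantRecord]] = {}
        for rec in self.records:
            self._index.setdefault(rec.key, []).append(rec)

    def lookup(self, chrom: str, pos: int) -> list[DiseaseVariantRecord]:
        """All records at exactly (chrom, pos), in stable insertion order."""
        return self._index.get((chrom, pos), [])

    def loci(self) -> list[tuple[str, int]]:
        return list(self._index.keys())

    def __len__(self) -> int:
        return len(self.records)

    def __eq__(self, other) -> bool:
        if not isinstance(other, VariantDatabase):
            return NotImplemented
        return (
            self.records == other.records
            and self.meta.to_dict() == other.meta.to_dict()
        )


def _normalize_allele(text: str) -> str:
    """Upper-case an allele; anything outside {A,C,G,T,N}+ becomes empty."""
    allele = (text or "").strip().upper()
    if allele and all(c in _ALLELE_CHARS for c in allele):
        return allele
    return ""


def parse_database_tsv(
    stream: IO[str], schema: dict | None = None
) -> tuple[list[DiseaseVariantRecord], ParseSummary]:
    """Parse an association TSV into records.

    ``schema`` maps the ten logical field names to header names; unmapped
    extra columns in the file are ignored. Rows with an unparseable position
    or p-value, or an empty disease/source field, are dropped and counted in
    the summary rather than aborting the parse.
    """
    schema = dict(DEFAULT_SCHEMA, **(schema or {}))
    reader = csv.reader(stream, delimiter="\t")
    try:
        header = next(reader)
    except StopIteration:
        summary = ParseSummary(empty_input=True)
        return [], summary

    positions = {name.strip(): i for i, name in enumerate(header)}
    missing = [
        schema[f] for f in MANDATORY_FIELDS if schema[f] not in positions
    ]
    if missing:
        raise SchemaError(missing)

    col = {
        logical: positions.get(header_name)
        for logical, header_name in schema.items()
    }

    def cell(row, logical):
        i = col[logical]
        if i is None or i >= len(row):
            return ""
        return row[i].strip()

    records: list[DiseaseVariantRecord] = []
    summary = ParseSummary()
    for row in reader:
        if not row or all(not c.strip() for c in row):
            continue
        summary.rows_read += 1
        try:
            chrom = normalize_chrom(cell(row, "chrom"))
            pos = int(cell(row, "pos"))
            if pos < 1:
                raise ValueError("position < 1")
            p_text = cell(row, "p_value")
            p_value = parse_p_value(p_text)
            rec = DiseaseVariantRecord(
                chrom=chrom,
                pos=pos,
                rsid=cell(row, "rsid"),
                ref_allele=_normalize_allele(cell(row, "ref_allele")),
                alt_allele=_normalize_allele(cell(row, "alt_allele")),
                gene=cell(row, "gene"),
                consequence=cell(row, "consequence"),
                p_value=p_value,
                p_text=p_text,
                disease=cell(row, "disease"),
                source_db=cell(row, "source_db"),
            )
        except (ValueError, ValidationError):
            summary.rows_dropped += 1
            continue
        records.append(rec)
        summary.records_parsed += 1
    if summary.rows_read == 0:
        summary.empty_input = True
    return records, summary


def write_database_tsv(records: Iterable[DiseaseVariantRecord], stream: IO[str]) -> int:
    """Write records in the default-schema TSV dialect; returns row count."""
    writer = csv.writer(stream, delimiter="\t", lineterminator="\n")
    writer.writerow(list(DEFAULT_SCHEMA.values()))
    n = 0
    for rec in records:
        writer.writerow(
            [
                rec.chrom, rec.pos, rec.rsid, rec.ref_allele, rec.alt_allele,
                rec.gene, rec.consequence, rec.p_text, rec.disease, rec.source_db,
            ]
        )
        n += 1
    return n


def build_index(
    records: list[DiseaseVariantRecord], meta: DbMeta | None = None
) -> VariantDatabase:
    """Deduplicate exact-duplicate records and build the position index.

    Records identical on all ten fields collapse to one (counted in
    ``meta.dedup_count``); near-duplicates — same locus, disease and source
    but a different p-value — are all kept, each becoming its own report row.
    """
    meta = meta if meta is not None else DbMeta()
    seen: set[tuple] = set()
    unique: list[DiseaseVariantRecord] = []
    dropped = 0
    for rec in records:
        ident = rec.identity()
        if ident in seen:
            dropped += 1
            continue
        seen.add(ident)
        unique.append(rec)
    meta.dedup_count = dropped
    return VariantDatabase(unique, meta)


def save_store(db: VariantDatabase, path) -> None:
    """Persist a database as a versioned, gzip-compressed store file."""
    payload = {
        "format": STORE_FORMAT,
        "version": STORE_VERSION,
        "meta": db.meta.to_dict(),
        "records": [list(rec.identity()) for rec in db.records],
    }
    text = json.dumps(payload, ensure_ascii=False, separators=(",", ":"))
    # GzipFile over an explicit fileobj with mtime=0: no filename or
    # timestamp in the gzip header, so identical databases give identical
    # bytes on disk.
    with open(path, "wb") as raw:
        with gzip.GzipFile(filename="", fileobj=raw, mode="wb", mtime=0) as gz:
            gz.write(text.encode("utf-8"))


def load_store(path) -> VariantDatabase:
    """Load a store written by :func:`save_store`.

    Raises StoreVersionError on a major-version mismatch and
    StoreIntegrityError on a truncated or corrupt file.
    """
    try:
        with gzip.open(path, "rt", encoding="utf-8") as fh:
            payload = json.load(fh)
    except (OSError, EOFError, json.JSONDecodeError, UnicodeDecodeError) as exc:
        raise StoreIntegrityError(f"store file {path!s} is unreadable: {exc}") from exc

    if not isinstance(payload, dict) or payload.get("format") != STORE_FORMAT:
        raise StoreIntegrityError(f"{path!s} is not a {STORE_FORMAT} file")
    version = str(payload.get("version", ""))
    if version.split(".")[0] != STORE_VERSION.split(".")[0]:
        raise StoreVersionError(
            f"store version {version} is incompatible with reader version {STORE_VERSION}"
        )
    try:
        meta = DbMeta.from_dict(payload["meta"])
        records = []
        for row in payload["records"]:
            (chrom, pos, rsid, ref_allele, alt_allele,
             gene, consequence, p_text, disease, source_db) = row
            records.append(
                DiseaseVariantRecord(
                    chrom=chrom,
                    pos=int(pos),
                    rsid=rsid,
                    ref_allele=ref_allele,
                    alt_allele=alt_allele,
                    gene=gene,
                    consequence=consequence,
                    p_value=parse_p_value(p_text),
                    p_text=p_text,
                    disease=disease,
                    source_db=source_db,
                )
            )
    except (KeyError, TypeError, ValueError, ValidationError) as exc:
        raise StoreIntegrityError(f"store file {path!s} is corrupt: {exc}") from exc

    if meta.record_count != len(records):
        raise StoreIntegrityError(
            f"store file {path!s}: meta claims {meta.record_count} records, "
            f"found {len(records)}"
        )
    return VariantDatabase(records, meta)
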