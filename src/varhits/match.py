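"""The core join: VCF variants x association database by (chrom, pos).

Each streamed variant is looked up at its exact locus; database records
whose association p-value falls strictly below the genome-wide significance
threshold (default 1.0e-7) become annotation hits. Alleles from both sides
are reported side by side ("Allele Variant" vs "Allele DB") for the user to
compare; an optional strict mode additionally requires them to agree.

The database is the in-memory side of the join; the VCF is streamed once,
so memory use is bounded by database size plus hit count, not VCF size.
"""

from __future__ import annotations

import time
from dataclasses import dataclass
from typing import Iterable

from .db import DiseaseVariantRecord, VariantDatabase
from .errors import ValidationError
from .vcf import VcfVariant, classify_structural

#: Conventional genome-wide significance bound used as the default cutoff.
GENOME_WIDE_SIGNIFICANCE = 1.0e-7

NO_MATCH_STATUS = "no matching variants"


@dataclass(frozen=True)
class MatchOptions:
    """Join options: significance cutoff and allele handling.

    p_threshold is an *exclusive* upper bound: a record at exactly the
    threshold is not a hit. allele_mode "report" joins on position only and
    shows both allele pairs; "strict" also requires VCF (REF, ALT) to equal
    the database (ref, alt) whenever the database supplies both.
    """

    p_threshold: float = GENOME_WIDE_SIGNIFICANCE
    allele_mode: str = "report"

    def __post_init__(self):
        if not (0.0 < self.p_threshold <= 1.0):
            raise ValidationError(
                f"p_threshold must be in (0, 1], got {self.p_threshold}"
            )
        if self.allele_mode not in ("report", "strict"):
            raise ValidationError(f"unknown allele_mode {self.allele_mode!r}")


@dataclass(frozen=True)
class AnnotationHit:
    """One VCF variant joined with one significant database record."""

    disease: str
    chrom: str
    pos: int
    gene: str
    rsid: str
    variant_type: str
    allele_variant: str
    allele_db: str
    p_value: float
    p_text: str
    source_db: str
    qual: str
    filter: str
    info: str


@dataclass
class RunSummary:
    variants_scanned: int = 0
    hits_found: int = 0
    elapsed_s: float = 0.0
    status: str = "ok"


def render_alleles(ref: str, alt: str) -> str:
    """Render an allele pair as "REF>ALT"; empty components become "?"."""
    return f"{ref or '?'}>{alt or '?'}"


def lookup(db: VariantDatabase, chrom: str, pos: int) -> list[DiseaseVariantRecord]:
    """All database records at exactly (chrom, pos); no threshold applied."""
    return db.lookup(chrom, pos)


def match_variant(
    v: VcfVariant, db: VariantDatabase, opts: MatchOptions | None = None
) -> list[AnnotationHit]:
    """Hits for one variant: records at its locus with p below the cutoff."""
    opts = opts or MatchOptions()
    hits: list[AnnotationHit] = []
    for rec in db.lookup(v.chrom, v.pos):
        if not rec.p_value < opts.p_threshold:
            continue
        if (
            opts.allele_mode == "strict"
            and rec.ref_allele
            and rec.alt_allele
            and (v.ref, v.alt) != (rec.ref_allele, rec.alt_allele)
        ):
            continue
        # The database's consequence string (e.g. "missense") wins; the
        # structural REF/ALT comparison only fills in when it is absent.
        variant_type = rec.consequence or classify_structural(v.ref, v.alt).value
        rsid = rec.rsid or (v.id if v.id != "." else "")
        hits.append(
            AnnotationHit(
                disease=rec.disease,
                chrom=v.chrom,
                pos=v.pos,
                gene=rec.gene,
                rsid=rsid,
                variant_type=variant_type,
                allele_variant=render_alleles(v.ref, v.alt),
                allele_db=render_alleles(rec.ref_allele, rec.alt_allele),
                p_value=rec.p_value,
                p_text=rec.p_text,
                source_db=rec.source_db,
                qual=v.qual,
                filter=v.filter,
                info=v.info,
            )
        )
    return hits


def annotate(
    variants: Iterable[VcfVariant],
    db: VariantDatabase,
    opts: MatchOptions | None = None,
) -> tuple[list[AnnotationHit], RunSummary]:
    """Join a variant stream against the database.

    Returns the deduplicated hit list and a run summary. Duplicate hits
    (identical on every output column, e.g. via a repeated input line) are
    collapsed. A zero-hit run is a success with an explicit
    "no matching variants" status so callers can inform the user.
    """
    opts = opts or MatchOptions()
    start = time.perf_counter()
    summary = RunSummary()
    hits: list[AnnotationHit] = []
    seen: set[AnnotationHit] = set()
    for v in variants:
        summary.variants_scanned += 1
        for hit in match_variant(v, db, opts):
            if hit in seen:
                continue
            seen.add(hit)
            hits.append(hit)
    summary.hits_found = len(hits)
    summary.elapsed_s = time.perf_counter() - start
    summary.status = "ok" if hits else NO_MATCH_STATUS
    return hits, summary
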