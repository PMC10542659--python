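"""Disease-grouped report assembly and the 13-column TSV writer.

Hits are grouped by disease; within a group rows run from the smallest to
the largest p-value, and groups themselves are ordered by their minimum
p-value ascending (ties broken alphabetically by disease name), so the most
strongly supported disease appears first. An alphabetical group order is
available as an alternative presentation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import IO

from .match import AnnotationHit

logger = logging.getLogger(__name__)

#: The fixed 13-column report header.
TSV_HEADER = (
    "Disease\tChr\tPosition\tGene\tVariant_id\tVariant_type\t"
    "Allele Variant\tAllele DB\tP-value\tDB\tQual\tFilter\tInfo"
)

SORT_MODES = ("pvalue", "alphabetical")


def _chrom_key(chrom: str) -> tuple[int, int, str]:
    """Numeric chromosomes first in natural order, then X, Y, MT, others."""
    if chrom.isdigit():
        return (0, int(chrom), "")
    special = {"X": 23, "Y": 24, "MT": 25}
    if chrom in special:
        return (0, special[chrom], "")
    return (1, 0, chrom)


def _hit_key(hit: AnnotationHit) -> tuple:
    """Total within-group order: p ascending, then positional/text fields."""
    return (
        hit.p_value,
        _chrom_key(hit.chrom),
        hit.pos,
        hit.rsid,
        hit.gene,
        hit.source_db,
        hit.allele_variant,
        hit.allele_db,
        hit.p_text,
        hit.variant_type,
        hit.qual,
        hit.filter,
        hit.info,
    )


@dataclass
class Report:
    """Ordered disease groups plus summary counts."""

    groups: list[tuple[str, list[AnnotationHit]]] = field(default_factory=list)

    @property
    def summary(self) -> dict:
        return {
            "diseases": len(self.groups),
            "hits": sum(len(hits) for _, hits in self.groups),
        }

    def all_hits(self) -> list[AnnotationHit]:
        return [hit for _, hits in self.groups for hit in hits]


def group_and_sort(hits: list[AnnotationHit], sort_mode: str = "pvalue") -> Report:
    """Group hits by disease and order everything deterministically.

    sort_mode "pvalue" (default) orders groups by their minimum p-value
    ascending with alphabetical tie-breaking; "alphabetical" orders groups
    by disease name alone.
    """
    if sort_mode not in SORT_MODES:
        raise ValueError(f"sort_mode must be one of {SORT_MODES}, got {sort_mode!r}")
    by_disease: dict[str, list[AnnotationHit]] = {}
    for hit in hits:
        by_disease.setdefault(hit.disease, []).append(hit)
    for disease in by_disease:
        by_disease[disease].sort(key=_hit_key)
    if sort_mode == "alphabetical":
        order = sorted(by_disease)
    else:
        order = sorted(
            by_disease, key=lambda d: (by_disease[d][0].p_value, d)
        )
    return Report(groups=[(d, by_disease[d]) for d in order])


def _cell(value: str) -> str:
    return value if value else "."


def write_tsv(report: Report, stream: IO[str]) -> int:
    """Write the report as the fixed 13-column TSV; returns data-row count.

    The disease name is repeated on every row of its group (no spanning
    cells), the p-value cell is the preserved original text, and missing
    optional values are printed as ".". An empty report yields a header-only
    file and logs an informational message.
    """
    stream.write(TSV_HEADER + "\n")
    n = 0
    for disease, hits in report.groups:
        for hit in hits:
            row = [
                disease,
                hit.chrom,
                str(hit.pos),
                _cell(hit.gene),
                _cell(hit.rsid),
                _cell(hit.variant_type),
                hit.allele_variant,
                hit.allele_db,
                hit.p_text,
                hit.source_db,
                _cell(hit.qual),
                _cell(hit.filter),
                _cell(hit.info),
            ]
            stream.write("\t".join(row) + "\n")
            n += 1
    if n == 0:
        logger.info("no matching variants were found in the database")
    return n


def read_tsv_matrix(stream: IO[str]) -> list[list[str]]:
    """Parse a report TSV back into its cell matrix (header included)."""
    return [line.rstrip("\n").split("\t") for line in stream if line.rstrip("\n")]
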