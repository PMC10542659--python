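"""Deterministic test inputs: worked-example fixture, simulator, oracle.

Three generators live here. ``table_fixture`` reproduces the small worked
example used throughout the documentation: a four-record association
database, a seven-line VCF (three lines landing on database loci, four on
unrelated loci) and the exact annotated TSV the pipeline must produce.
``simulate`` builds arbitrary-size synthetic VCF/database pairs with a
planted overlap fraction, for property and scaling tests.
``oracle_annotate`` is the independent verifier of the join: a literal
nested loop over every (variant, record) pair, with no index, against which
the indexed matcher is checked.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass

import numpy as np

from .db import DiseaseVariantRecord, parse_p_value
from .errors import SimSpecError
from .match import (
    GENOME_WIDE_SIGNIFICANCE,
    AnnotationHit,
    MatchOptions,
    render_alleles,
)
from .vcf import VcfVariant, read_vcf

# --------------------------------------------------------------------------
# Worked-example fixture
# --------------------------------------------------------------------------

_INFO_TREM2 = (
    "AC=14;AF=0.00218613;AN=6404;BaseQRankSum=0.155;"
    "ClippingRankSum=0.481;DP=111734"
)
_INFO_C8ORF38 = (
    "AC=3017;AF=0.471112;AN=6404;BaseQRankSum=0.223;"
    "ClippingRankSum=0;DP=106075"
)
_INFO_FGFR2 = (
    "AC=3227;AF=0.503904;AN=6404;BaseQRankSum=0.098;"
    "ClippingRankSum=-0.024;DP=95506"
)

# Note the mixed p-value spellings: Unicode minus in "2.00E−12" vs ASCII
# hyphen in "2E-170". Both must survive to the output verbatim.
_FIXTURE_DB_ROWS = [
    ("6", 41161514, "rs75932628", "C", "T", "TREM2", "missense",
     "2.00E−12", "Alzheimer’s disease", "GWASdb"),
    ("8", 95041772, "rs7818382", "C", "T", "C8orf38", "intron",
     "8.00E−08", "Alzheimer’s disease", "GWASdb"),
    ("10", 121577821, "rs2981579", "A", "G", "FGFR2", "intron",
     "2E-170", "Breast cancer", "GWASdb"),
    ("10", 121577821, "rs2981579", "A", "G", "FGFR2", "intron",
     "2.00E−10", "Nasopharyngeal carcinoma", "GWASdb"),
]

_FIXTURE_VCF_MATCHING = [
    ("6", 41161514, "rs75932628", "C", "T", "7296.45", "PASS", _INFO_TREM2),
    ("8", 95041772, "rs7818382", "C", "T", "1587730", "PASS", _INFO_C8ORF38),
    ("10", 121577821, "rs2981579", "A", "G", "1491780", "PASS", _INFO_FGFR2),
]

#: The classic four-line, five-column example file — none of these loci
#: appear in the fixture database.
_FIVE_COLUMN_ROWS = [
    ("3", 4700592, "rs6762644", "A", "G"),
    ("6", 149842694, "rs1125107", "T", "C"),
    ("16", 5225061, "rs2333967", "C", "T"),
    ("X", 83723541, "rs35161124", "A", "G"),
]


@dataclass
class TableFixture:
    records: list[DiseaseVariantRecord]
    vcf_text: str
    expected_tsv: str


def _fixture_records() -> list[DiseaseVariantRecord]:
    out = []
    for chrom, pos, rsid, ref, alt, gene, cons, p_text, disease, src in _FIXTURE_DB_ROWS:
        out.append(
            DiseaseVariantRecord(
                chrom=chrom, pos=pos, rsid=rsid, ref_allele=ref, alt_allele=alt,
                gene=gene, consequence=cons, p_value=parse_p_value(p_text),
                p_text=p_text, disease=disease, source_db=src,
            )
        )
    return out


def five_column_vcf() -> str:
    """The truncated five-column example VCF (header without a '#' prefix)."""
    lines = ["##fileformat=VCFv4.1", "CHROM\tPOS\tID\tREF\tALT"]
    for chrom, pos, rsid, ref, alt in _FIVE_COLUMN_ROWS:
        lines.append(f"{chrom}\t{pos}\t{rsid}\t{ref}\t{alt}")
    return "\n".join(lines) + "\n"


def table_fixture() -> TableFixture:
    """The worked-example fixture: database, VCF, and expected output TSV.

    The VCF has seven data lines: three at database loci (each carrying the
    QUAL/FILTER/INFO values echoed in the expected output) and the four
    five-column lines, which match nothing. Under default options the
    expected report has four rows — the shared locus 10:121577821 hits two
    diseases — grouped by disease with groups ordered by minimum p-value.
    """
    lines = ["##fileformat=VCFv4.1", "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO"]
    for chrom, pos, rsid, ref, alt, qual, filt, info in _FIXTURE_VCF_MATCHING:
        lines.append(f"{chrom}\t{pos}\t{rsid}\t{ref}\t{alt}\t{qual}\t{filt}\t{info}")
    for chrom, pos, rsid, ref, alt in _FIVE_COLUMN_ROWS:
        lines.append(f"{chrom}\t{pos}\t{rsid}\t{ref}\t{alt}")
    vcf_text = "\n".join(lines) + "\n"

    header = (
        "Disease\tChr\tPosition\tGene\tVariant_id\tVariant_type\t"
        "Allele Variant\tAllele DB\tP-value\tDB\tQual\tFilter\tInfo"
    )
    # Hand-applied join/filter/sort rules: all four database p-values are
    # below 1e-7; group minima order Breast cancer (2e-170) before
    # Alzheimer's (2e-12) before Nasopharyngeal carcinoma (2e-10).
    expected_rows = [
        ("Breast cancer\t10\t121577821\tFGFR2\trs2981579\tintron\t"
         f"A>G\tA>G\t2E-170\tGWASdb\t1491780\tPASS\t{_INFO_FGFR2}"),
        ("Alzheimer’s disease\t6\t41161514\tTREM2\trs75932628\tmissense\t"
         f"C>T\tC>T\t2.00E−12\tGWASdb\t7296.45\tPASS\t{_INFO_TREM2}"),
        ("Alzheimer’s disease\t8\t95041772\tC8orf38\trs7818382\tintron\t"
         f"C>T\tC>T\t8.00E−08\tGWASdb\t1587730\tPASS\t{_INFO_C8ORF38}"),
        ("Nasopharyngeal carcinoma\t10\t121577821\tFGFR2\trs2981579\tintron\t"
         f"A>G\tA>G\t2.00E−10\tGWASdb\t1491780\tPASS\t{_INFO_FGFR2}"),
    ]
    expected_tsv = header + "\n" + "\n".join(expected_rows) + "\n"
    return TableFixture(
        records=_fixture_records(), vcf_text=vcf_text, expected_tsv=expected_tsv
    )


# --------------------------------------------------------------------------
# Simulator
# --------------------------------------------------------------------------

_SIM_DISEASES = (
    "Type 2 diabetes", "Breast cancer", "Coronary artery disease",
    "Rheumatoid arthritis", "Schizophrenia", "Crohn's disease",
    "Alzheimer's disease", "Asthma",
)
_SIM_GENES = ("TCF7L2", "FTO", "APOE", "BRCA2", "IL23R", "PTPN22", "CDKN2A", "")
_SIM_CONSEQUENCES = ("missense", "intron", "synonymous", "3_prime_UTR", "")
_SIM_SOURCES = ("GWASdb", "GWAS Catalog", "GRASP", "GADCDC", "JohnsonOdonnell")
_BASES = ("A", "C", "G", "T")


@dataclass
class SimSpec:
    """Parameters of one synthetic VCF/database instance.

    overlap_fraction is the fraction of VCF lines planted exactly at
    database loci (drawn without replacement from the distinct loci);
    the remaining lines are placed at loci guaranteed absent from the
    database. p_significant_fraction of database records are forced below
    the significance threshold; the rest are drawn log-uniformly over the
    whole p range, so near-threshold values occur routinely.
    """

    n_db_records: int = 200
    n_vcf_lines: int = 1000
    overlap_fraction: float = 0.1
    p_significant_fraction: float = 0.5
    chrom_set: tuple[str, ...] = tuple(str(c) for c in range(1, 23)) + ("X", "Y")
    pos_range: tuple[int, int] = (1, 1_000_000)
    seed: int = 0

    def validate(self) -> None:
        if self.n_db_records < 0 or self.n_vcf_lines < 0:
            raise SimSpecError("record and line counts must be non-negative")
        for name in ("overlap_fraction", "p_significant_fraction"):
            value = getattr(self, name)
            if not (0.0 <= value <= 1.0):
                raise SimSpecError(f"{name} must be in [0, 1], got {value}")
        lo, hi = self.pos_range
        if lo < 1 or hi < lo:
            raise SimSpecError(f"pos_range {self.pos_range} is empty or invalid")
        if not self.chrom_set:
            raise SimSpecError("chrom_set must be non-empty")


@dataclass
class SimResult:
    records: list[DiseaseVariantRecord]
    vcf_text: str
    expected_hits: int | None


def _random_snv(rng) -> tuple[str, str]:
    ref = _BASES[rng.integers(4)]
    alt = _BASES[rng.integers(4)]
    while alt == ref:
        alt = _BASES[rng.integers(4)]
    return ref, alt


def simulate(spec: SimSpec, compute_expected: bool = True) -> SimResult:
    """Generate a deterministic synthetic database + VCF pair.

    Fully reproducible: the same spec yields byte-identical outputs. The
    expected hit count is measured by running the nested-loop oracle over
    the generated inputs, never inferred from construction arithmetic.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.pos_range

    records: list[DiseaseVariantRecord] = []
    n_sig = round(spec.p_significant_fraction * spec.n_db_records)
    sig_idx = set(
        rng.choice(spec.n_db_records, size=n_sig, replace=False).tolist()
    ) if spec.n_db_records else set()
    for i in range(spec.n_db_records):
        chrom = spec.chrom_set[rng.integers(len(spec.chrom_set))]
        pos = int(rng.integers(lo, hi + 1))
        ref, alt = _random_snv(rng)
        if i in sig_idx:
            log_p = rng.uniform(-15.0, math.log10(GENOME_WIDE_SIGNIFICANCE))
        else:
            log_p = rng.uniform(-15.0, 0.0)
        p_text = f"{10.0 ** log_p:.2E}"
        records.append(
            DiseaseVariantRecord(
                chrom=chrom,
                pos=pos,
                rsid=f"rs{int(rng.integers(10_000, 100_000_000))}",
                ref_allele=ref,
                alt_allele=alt,
                gene=_SIM_GENES[rng.integers(len(_SIM_GENES))],
                consequence=_SIM_CONSEQUENCES[rng.integers(len(_SIM_CONSEQUENCES))],
                p_value=parse_p_value(p_text),
                p_text=p_text,
                disease=_SIM_DISEASES[rng.integers(len(_SIM_DISEASES))],
                source_db=_SIM_SOURCES[rng.integers(len(_SIM_SOURCES))],
            )
        )

    db_loci = list(dict.fromkeys(rec.key for rec in records))
    db_loci_set = set(db_loci)
    n_overlap = round(spec.overlap_fraction * spec.n_vcf_lines)
    if n_overlap > len(db_loci):
        raise SimSpecError(
            f"overlap_fraction {spec.overlap_fraction} demands {n_overlap} "
            f"planted loci but the database has only {len(db_loci)} distinct"
        )
    planted = [
        db_loci[i]
        for i in (rng.choice(len(db_loci), size=n_overlap, replace=False).tolist()
                  if n_overlap else [])
    ]

    data_lines: list[str] = []
    for chrom, pos in planted:
        rec = next(r for r in records if r.key == (chrom, pos))
        if rng.random() < 0.5:
            ref, alt = rec.ref_allele, rec.alt_allele
        else:
            ref, alt = _random_snv(rng)
        data_lines.append(_sim_vcf_line(rng, chrom, pos, ref, alt))
    for _ in range(spec.n_vcf_lines - n_overlap):
        while True:
            chrom = spec.chrom_set[rng.integers(len(spec.chrom_set))]
            pos = int(rng.integers(lo, hi + 1))
            if (chrom, pos) not in db_loci_set:
                break
        ref, alt = _random_snv(rng)
        data_lines.append(_sim_vcf_line(rng, chrom, pos, ref, alt))
    order = rng.permutation(len(data_lines)) if data_lines else []
    lines = ["##fileformat=VCFv4.1", "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO"]
    lines.extend(data_lines[i] for i in order)
    vcf_text = "\n".join(lines) + "\n"

    expected = None
    if compute_expected:
        variants = list(read_vcf(io.StringIO(vcf_text)))
        expected = len(oracle_annotate(variants, records, MatchOptions()))
    return SimResult(records=records, vcf_text=vcf_text, expected_hits=expected)


def _sim_vcf_line(rng, chrom: str, pos: int, ref: str, alt: str) -> str:
    # ~10% multi-allelic lines so the split path is exercised.
    alts = alt
    if rng.random() < 0.1:
        extra = _BASES[rng.integers(4)]
        while extra in (ref, alt):
            extra = _BASES[rng.integers(4)]
        alts = f"{alt},{extra}"
    vid = f"rs{int(rng.integers(10_000, 100_000_000))}" if rng.random() < 0.7 else "."
    qual = f"{rng.uniform(10, 5000):.2f}" if rng.random() < 0.8 else "."
    filt = "PASS" if rng.random() < 0.8 else "q10"
    info = f"DP={int(rng.integers(1, 10_000))}" if rng.random() < 0.5 else "."
    return f"{chrom}\t{pos}\t{vid}\t{ref}\t{alts}\t{qual}\t{filt}\t{info}"


# --------------------------------------------------------------------------
# Brute-force oracle
# --------------------------------------------------------------------------

def _oracle_variant_type(ref: str, alt: str) -> str:
    # Independent re-statement of the structural classification rules.
    if len(ref) == 1 and len(alt) == 1 and ref != alt:
        return "SNP"
    if len(alt) > len(ref) and alt[: len(ref)] == ref:
        return "insertion"
    if len(ref) > len(alt) and ref[: len(alt)] == alt:
        return "deletion"
    return "complex"


def oracle_annotate(
    variants: list[VcfVariant],
    records: list[DiseaseVariantRecord],
    opts: MatchOptions | None = None,
) -> list[AnnotationHit]:
    """Reference join: literal nested loop over every (variant, record) pair.

    Applies the same predicates as the indexed matcher — exact (chrom, pos)
    equality, strict p < threshold, optional allele concordance — with no
    index and no shortcuts, then deduplicates on the full output tuple and
    returns the hits in a canonical sorted order.
    """
    opts = opts or MatchOptions()
    strict = opts.allele_mode == "strict"
    threshold = opts.p_threshold
    hits: set[AnnotationHit] = set()
    for v in variants:
        v_chrom, v_pos = v.chrom, v.pos
        for rec in records:
            if rec.chrom != v_chrom or rec.pos != v_pos:
                continue
            if not rec.p_value < threshold:
                continue
            if strict and rec.ref_allele and rec.alt_allele and (
                v.ref != rec.ref_allele or v.alt != rec.alt_allele
            ):
                continue
            vtype = rec.consequence or _oracle_variant_type(v.ref, v.alt)
            rsid = rec.rsid or (v.id if v.id != "." else "")
            hits.add(
                AnnotationHit(
                    disease=rec.disease,
                    chrom=v_chrom,
                    pos=v_pos,
                    gene=rec.gene,
                    rsid=rsid,
                    variant_type=vtype,
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
    return sorted(
        hits,
        key=lambda h: (
            h.disease, h.chrom, h.pos, h.rsid, h.p_text,
            h.allele_variant, h.allele_db, h.source_db,
        ),
    )
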