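"""Tiny builders shared across test modules."""

from varhits.db import DiseaseVariantRecord
from varhits.vcf import VcfVariant


def record(pos=1000, p_text="1e-9", **kw):
    defaults = dict(
        chrom="1", pos=pos, rsid="rs1", ref_allele="A", alt_allele="G",
        gene="GENE1", consequence="intron", p_value=float(p_text),
        p_text=p_text, disease="Testopathy", source_db="GWASdb",
    )
    defaults.update(kw)
    return DiseaseVariantRecord(**defaults)


def variant(chrom="1", pos=1000, ref="A", alt="G", **kw):
    return VcfVariant(chrom=chrom, pos=pos, id=kw.pop("id", "."), ref=ref,
                      alts=(alt,), **kw)


def hit_key(h):
    return (
        h.disease, h.chrom, h.pos, h.gene, h.rsid, h.variant_type,
        h.allele_variant, h.allele_db, h.p_text, h.source_db,
        h.qual, h.filter, h.info,
    )


def canonical(hits):
    """Sort a hit list into a canonical total order for multiset comparison."""
    return sorted(hits, key=hit_key)
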