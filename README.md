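# varhits

Find out which variants in a VCF file coincide with published
disease-associated variants — at scale, on the current reference genome.

Genome-wide association studies (GWAS) have catalogued hundreds of
thousands of variant–disease associations, but checking an individual's
millions of called variants against them through web interfaces is
impractical. `varhits` does the whole lookup locally: it compiles a
disease-association table (GWAS Catalog / GWASdb / GRASP-style TSV
exports) into a position-indexed store, streams a VCF of any size against
it, keeps the genome-wide-significant associations, and writes a
disease-grouped report. It is meant for bioinformaticians and clinical
researchers triaging variant callsets.

## The method

For a VCF variant $v$ at locus $(c, p)$ and an association database $D$ of
records $r = (c_r, p_r, \text{alleles}, P_r, \text{disease}, \dots)$, the
hit set is

$$H = \{(v, r) : c_v = c_r,\; p_v = p_r,\; P_r < \alpha\}, \qquad \alpha = 1.0 \times 10^{-7},$$

i.e. an exact point-wise join on (chromosome, 1-based position) with a
strict genome-wide-significance filter ($P = \alpha$ exactly is *not* a
hit). The database side is held in a hash index, the VCF side is streamed,
so memory is bounded by database size plus hit count and runtime is linear
in VCF length. Hits are grouped by disease; groups are ordered by their
minimum p-value ascending, rows within a group from smallest to largest p.
Alleles from both sides are printed next to each other (`Allele Variant`
vs `Allele DB`) rather than silently required to match; `--strict-alleles`
enforces concordance. Multi-allelic VCF lines are split into one candidate
per ALT allele before matching.

The output is a fixed 13-column TSV:

```
Disease  Chr  Position  Gene  Variant_id  Variant_type  Allele Variant  Allele DB  P-value  DB  Qual  Filter  Info
```

See `docs/methods.md` for the full model, parameters and limitations.

## Worked example

```sh
python examples/annotate_worked_example.py
```

annotates the built-in seven-line example VCF against a four-record
association database and prints:

```
Disease	Chr	Position	Gene	Variant_id	Variant_type	Allele Variant	Allele DB	P-value	DB	Qual	Filter	Info
Breast cancer	10	121577821	FGFR2	rs2981579	intron	A>G	A>G	2E-170	GWASdb	1491780	PASS	AC=3227;...
Alzheimer’s disease	6	41161514	TREM2	rs75932628	missense	C>T	C>T	2.00E−12	GWASdb	7296.45	PASS	AC=14;...
Alzheimer’s disease	8	95041772	C8orf38	rs7818382	intron	C>T	C>T	8.00E−08	GWASdb	1587730	PASS	AC=3017;...
Nasopharyngeal carcinoma	10	121577821	FGFR2	rs2981579	intron	A>G	A>G	2.00E−10	GWASdb	1491780	PASS	AC=3227;...

variants scanned: 7
hits found:       4
diseases:         3
```

(INFO cells truncated here for width; the file contains them verbatim.)
Three of the seven VCF lines land on database loci; the locus 10:121577821
carries associations to two diseases, hence 4 hits from 3 matching lines.
The four remaining lines match nothing. Breast cancer leads the report
because its smallest p-value (2E-170) beats every other group's. The
p-value cells are the database's original text, preserved exactly.

The same flow from the shell:

```sh
varhits compile-db --tsv associations.tsv --out assoc.store
varhits annotate --db assoc.store --out-dir out/ sample.vcf
# -> out/sample.hits.tsv, plus a per-file summary line
varhits simulate --seed 42 --db-records 200 --vcf-lines 1000 --overlap 0.1 --out-prefix sim
```

Other examples: `examples/compile_and_query_store.py` (store round-trip
and locus lookup) and `examples/simulate_and_verify.py` (synthetic data
vs. the exhaustive oracle).

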