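# Methods

## The procedure

`varhits` answers one question: which variants in a VCF file coincide with
published disease associations? The method is a point-wise join. A table of
GWAS associations — one row per (chromosome, position, alleles, p-value,
disease, source database) — is compiled once into a hash index keyed on
`(chrom, pos)`. Each VCF data line is then looked up at its exact
coordinate; every association found there whose p-value lies **strictly
below** the genome-wide significance bound (default `1.0e-7`) becomes one
annotation hit. Hits are grouped by disease and written as a fixed
13-column TSV: Disease, Chr, Position, Gene, Variant_id, Variant_type,
Allele Variant, Allele DB, P-value, DB, Qual, Filter, Info.

Assumptions the join makes:

* **Coordinates are comparable.** Both the VCF and the association table
  must come from the same genome build (we default to a `GRCh38` build tag,
  recorded as store metadata). No liftover is performed; mixing builds
  silently produces wrong matches, which is why the tag is stored and
  surfaced.
* **Position-only matching.** The default join key is `(chrom, pos)` alone.
  The report prints the VCF alleles and the database alleles side by side
  ("Allele Variant" vs "Allele DB") so a discordant pair is visible rather
  than hidden; `allele_mode="strict"` (CLI `--strict-alleles`) additionally
  drops hits whose alleles disagree whenever the database supplies both.
* **The threshold is exclusive.** A record with p exactly `1.0e-7` is not a
  hit. The comparison uses the parsed float; the report echoes the
  database's original p-value text (`2.00E−12`, `2E-170`, Unicode minus and
  all) so the output round-trips the source faithfully.

## Parameters that matter

| Parameter | Default | Meaning |
|---|---|---|
| `p_threshold` | `1.0e-7` | exclusive upper bound on the association p-value; in (0, 1] |
| `allele_mode` | `report` | `report` = position-only join, alleles shown; `strict` = alleles must agree |
| `sort_mode` | `pvalue` | disease groups ordered by minimum p ascending; `alphabetical` orders by name |
| `build_tag` | `GRCh38` | metadata only; no coordinate conversion is attempted |

Two report orderings exist because the two natural presentations genuinely
differ: ordering groups by their smallest p-value puts the most strongly
supported disease first (the default), while alphabetical ordering is
easier to scan for a known disease. Within a group rows always run from
smallest to largest p. All ordering is total (ties broken by chromosome,
position, rsID and the remaining text fields), so output bytes are a pure
function of the hit multiset regardless of input order.

## Input handling

The VCF reader is a streaming line parser: memory use is bounded by the
database plus the hit list, never by VCF length, which is what makes
100-million-line inputs feasible on a laptop. It accepts standard VCFv4.x
(plain or gzipped) and also the truncated five-column dialect
(CHROM POS ID REF ALT, header with or without the leading `#`) that worked
examples are often distributed in; missing QUAL/FILTER/INFO become `.`.
Multi-allelic ALT values are split into one candidate per allele before
matching, because the database stores single ref/alt pairs; duplicate hits
arising from the split (or from repeated input lines) are collapsed on the
full output tuple. Data lines with fewer than five fields or a non-numeric
POS are rejected and counted, never fatal; only a stream with no header and
no data lines at all is an error. No FILTER-based exclusion is applied —
non-PASS variants are annotated and their FILTER value echoed, since
filtering policy belongs to the caller.

Chromosome names are canonicalized on both sides of the join
(case-insensitive, `chr` prefix stripped, `M` → `MT`), so `chr6` and `6`
match; unknown contig names are kept as-is and simply never match a human
database.

The Variant_type column prefers the database's own consequence annotation
(e.g. `missense`, `intron`); only when that is absent does the structural
REF/ALT comparison (SNP / insertion / deletion / complex) fill in.
Variant_id prefers the database rsID, falling back to the VCF ID column.

## The compiled store

The association TSV (columns mapped by a small key=value schema file, so
differently-headed exports of GWAS Catalog / GWASdb / GRASP-style tables
all load) is compiled once into a gzip-compressed JSON store with an
embedded format-version string and metadata (build tag, source name, record
count, dedup count). Exact duplicates — identical on all ten fields — are
collapsed; near-duplicates (same locus, disease and source but a different
p-value) are all kept, each becoming its own report row. The store is
written with a zeroed gzip timestamp and no embedded filename, so identical
inputs give byte-identical stores. A major-version mismatch on load is an
explicit error naming both versions; truncation or corruption is detected
via the record count and JSON integrity.

## The synthetic-data generator

`simulate(SimSpec(...))` builds matched database/VCF pairs for testing:
`n_db_records` associations at uniform loci over `chrom_set` ×
`pos_range` (defaults: the 24 human chromosomes, positions 1–10⁶), with
p-values drawn log-uniformly over [10⁻¹⁵, 1] and a `p_significant_fraction`
subset forced below the threshold — so near-boundary p-values around 10⁻⁷
occur routinely. A chosen `overlap_fraction` of the `n_vcf_lines` is
planted exactly at database loci (drawn without replacement; demanding more
planted lines than distinct loci is an error); the remaining lines are
placed at loci verified absent from the database, so a zero overlap
provably yields zero hits. About 10% of lines are multi-allelic and QUAL/
FILTER/INFO values are mixed, exercising the split and pass-through paths.
Defaults (200 records, 1000 lines, 10% overlap, 50% forced-significant)
give instances where every code path fires. Generation is fully
deterministic per seed, byte for byte.

The generator does **not** emulate linkage disequilibrium, realistic allele
frequencies, indel-heavy loci, or genotype columns. Passing tests therefore
demonstrate the correctness of the join, filtering, grouping and formatting
logic — not the biological yield of any particular real database snapshot.

The expected hit count of a simulated instance is measured by
`oracle_annotate`, a literal nested loop over every (variant, record) pair
with no index, written independently of the production matcher (including
its own inline variant-type classification). Every randomized test compares
the indexed join against this oracle as a multiset.

## Numerical and design choices

* p-value parsing accepts the Unicode minus sign and requires values in
  (0, 1]; rows failing that (or with unparseable positions, or empty
  disease/source fields) are dropped and counted, keeping a partly dirty
  TSV usable.
* Coordinates are 1-based throughout, matching VCF POS; the join is
  point-wise, no intervals.
* The database is the in-memory side of the join (it is the smaller,
  reusable side); with multiple VCFs in one invocation the store is loaded
  once and the files processed sequentially.
* Elapsed seconds are reported per file in CLI summaries but never asserted
  in tests; wall-clock time is hardware-dependent. The one timing property
  we do test is relative: with the database fixed, doubling the VCF from
  10⁵ to 2×10⁵ lines must scale the median of three runs by at most 2.5×,
  the testable form of linear scaling.
* Randomized test sizes: the oracle-equivalence property runs 50 seeded
  instances with up to ~3×10³ VCF lines × 4×10² records each (over 10⁷
  variant–record pairs exhaustively enumerated in total). These sizes keep
  the exhaustive O(n·m) oracle affordable while covering empty, sparse and
  dense overlap regimes; the production matcher itself is exercised at
  2×10⁵ lines in the scaling check.

## Known limitations

* No liftover: build mismatches between VCF and database are the user's
  responsibility (the build tag is metadata, not enforcement).
* Position-only default matching can pair a VCF indel with a database SNP
  at the same coordinate; the side-by-side allele columns expose this, and
  strict mode suppresses it.
* INFO is passed through verbatim, never parsed; genotype/sample columns
  are ignored entirely.
* The p-value field is treated uniformly as a p-value; if a source database
  supplies some other confidence score in that column, it is filtered by
  the same threshold.
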