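# genophen-store

A relational warehouse for large-scale genotype and phenotype data from
diversity panels and breeding programs: normalized, Chado-style storage
with referential integrity, a validating bulk VCF importer, generic
materialized views with strategic indices, a variant × germplasm genotype
matrix engine (genomic-range and pairwise-polymorphism filters, CSV and
HapMap export), IUPAC-annotated flanking sequence for marker assay
design, and a staged, validated phenotype import with per-site-year
distribution summaries.

It is written for researchers and database curators who need to answer
questions like *"which variants are polymorphic between these two
accessions inside a trait-implicated region?"* or *"does this accession
flower early or late relative to the panel?"* without bespoke scripts.

## Data model

Genotype calls live in a single linker table keyed by foreign keys to the
project, sequence variant, marker assay and germplasm (`stock`) records,
with the nucleotide genotype normalized into a shared `genotype` table
(one row per distinct allele multiset: `AA`, `AG`, `A,ATG`, …) and every
per-call VCF FORMAT metric (DP, GQ, …) in a JSON metadata column.
Phenotype measurements carry their full trait–method–unit tuple plus
stock, project, location, year and replicate. Both extensions are
backward-compatible with the Chado core shape: dropping the
`genotype_call` table and the three added `phenotype` columns leaves the
core tables untouched.

Query speed comes from three refreshable materialized views —
`mview_ndg_calls` (one row per call with compiled display names),
`mview_ndg_variants` (one row per variant location, indexed on
`(backbone, fmin)` for range queries) and `mview_phenotype` (replicates
averaged per trait × germplasm × site-year) — and matrix queries are
two-stage: filter the small variant view first, then fetch calls from the
large call view by its primary-key index. Every mview-backed query has a
direct normalized-join twin used to verify correctness and to benchmark
the speedup.

## Worked example

Generate a deterministic synthetic dataset (50 variants × 10 samples plus
3 traits × 4 site-years × 20 accessions), load it, and query it:

```
$ genophen seed --scale small --seed 1 --out fx
$ genophen init --store wh.db
$ genophen load-reference --store wh.db --fasta fx/reference.fasta
$ genophen load-vcf --store wh.db --project AGILE-sim --vcf fx/calls.vcf \
      --genus Lens --assembly Lc1.2-sim
           variants_seen: 50
            samples_seen: 10
          calls_inserted: 500
   calls_skipped_missing: 0
$ genophen mviews --store wh.db --which all
calls: 500 rows
variants: 50 rows
phenotypes: 240 rows
```

Which variants on LcChr1:1–2500 are polymorphic between two accessions?

```
$ genophen matrix --store wh.db --germplasm Lens-0001 --germplasm Lens-0002 \
      --polymorphic Lens-0001,Lens-0002 --range LcChr1:1-2500
variant       backbone      pos           Lens-0001     Lens-0002
LcChr1_48     LcChr1        48            CT            CC
LcChr1_93     LcChr1        93            GG            GT
LcChr1_2070   LcChr1        2070          AA            AT
LcChr1_2090   LcChr1        2090          AA            TT
(4 variants match; page 1)
```

Each cell is the consensus nucleotide call for that variant × accession
(empty cells mean no stored call; conflicting multi-source calls render
as the IUPAC code of the allele union). `--format csv|hapmap` exports the
full filtered set.

Flanking sequence for assay design — the focal variant is bracketed and
the known neighbouring variant three codons downstream shows as its
IUPAC code `W` (A or T):

```
$ genophen flank --store wh.db --variant LcChr1_2070 --assembly Lc1.2-sim --window 25
>LcChr1_2070 flank LcChr1:2045-2095 assembly=Lc1.2-sim focal=[T/A] substitutions=1
AGTGAGCTTACCTTCCCCGCCAATG[T/A]TGGCAGTAGACCGCGTACAWGTGTT
```

Phenotypes go through the staged upload (parse → validation ledger →
trait description → transactional load), then feed per-site-year
distribution series with box statistics (median, midpoint quartiles,
notch 95% CI of the median) and per-accession highlighting:

```
$ genophen load-phenotypes --store wh.db --project AGILE-sim --genus Lens \
      --tsv fx/phenotypes.tsv --traits traits.yaml
[PASS] year-plausible
[PASS] duplicate-measurement-key
inserted: 720  dropped (missing value): 0
$ genophen summary --store wh.db --genus Lens
   experiments: 1
        traits: 3
     germplasm: 20
    site_years: 4
  measurements: 720
$ genophen pheno-dist --store wh.db --trait "Days till Plants have One Open Flower" \
      --project AGILE-sim --highlight Lens-0001 --format json
```

The first site-year entry of that series reads, e.g., `Lucky Lake 2016:
median 67.93, highlight 66.76` — the highlighted accession flowered
slightly earlier than the panel median there.

## Layout

- `src/genophen_store/store.py` — schema, entity get-or-create, genotype canonicalization
- `src/genophen_store/vcf_import.py` — VCF validation, GT translation, batched transactional import
- `src/genophen_store/mviews.py` — materialized views, refresh, benchmark harness
- `src/genophen_store/matrix.py` — two-stage matrix queries, consensus, polymorphism, exports
- `src/genophen_store/flanking.py`, `iupac.py` — flanking annotation and ambiguity codes
- `src/genophen_store/phenotypes.py` — staged phenotype pipeline
- `src/genophen_store/summary.py` — distribution series and genus summaries
- `src/genophen_store/fixtures.py` — deterministic seeders and ground-truth manifests
- `docs/methods.md` — models, conventions and design choices in detail
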