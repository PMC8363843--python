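# Methods

This note records the data model, conventions, numerical choices and
known limitations of genophen-store, in the order a maintainer would
meet them.

## Storage model and engine

The schema follows the GMOD Chado core layout (project, stock, feature,
feature_relationship, featureloc, cvterm, genotype, phenotype) with two
additive extensions: the `genotype_call` linker table (one row per
project × variant × marker × germplasm observation, JSON metadata column
for VCF FORMAT metrics) and three foreign keys added to `phenotype`
(stock_id, unit_id, project_id) so a measurement carries its complete
trait–method–unit tuple. The backing engine is embedded SQLite with
`PRAGMA foreign_keys = ON`; the SQL is kept engine-portable (no
SQLite-only constructs beyond JSON-as-text), so a server-grade RDBMS
backend could be added behind the same `Store` interface, but none ships
in this build. JSONB semantics are approximated by canonical
(sorted-key) JSON text.

A structural test asserts backward compatibility as *additivity*: after
removing the declared extensions, every declared core table and core
column is still present and unmodified. Location, year and replicate are
stored as columns on `phenotype` rather than in satellite property
tables; this is a deliberate flattening — the queries this warehouse
exists for group by site-year on every access, and the columns make that
a single-table operation.

## Coordinates

Internally all placements are interbase (0-based, half-open), so a SNP
at VCF POS p occupies `fmin = p−1, fmax = p−1+len(REF)`. Every
user-facing range filter takes 1-based inclusive coordinates and
converts at the boundary; range containment is `start−1 ≤ fmin ≤ end−1`.
A variant may carry locations on several assemblies; the per-location
variant view makes this free with respect to the call table.

## Genotype canonicalization

The GT field is translated to nucleotide alleles and stored as an
*unordered* multiset: phase is discarded (`0|1` and `1|0` share one
genotype record), alleles sort lexicographically, single-base multisets
concatenate (`AG`) and any multiset containing a multi-base allele joins
with commas (`A,ATG`). One corner is ambiguous by construction: a
haploid multi-base call (`AT` as a single allele) renders identically to
the concatenated single-base multiset with the same sorted letters. The
collision is confined to haploid indel calls and accepted; the
alternative (a separator on every genotype) would change the display
form users expect.

Missing calls are never stored. A partially missing call (`./1`) is
treated as missing and skipped too — a half-specified call has no
canonical allele string — but counted separately in the import report.

## VCF import

The importer supports VCF v4.0+ and validates before loading: fileformat
line and version, `#CHROM` header, per-line column counts, GT syntax and
ALT index ranges, each reported as a (line, message) finding rather than
a hard stop, so a curator sees every problem at once. The import itself
is one transaction executed in configurable batches through SQLite's
`executemany` bulk path; an error anywhere (resolution failure in `fail`
mode, malformed record, duplicate call key under the default `reject`
policy) leaves zero rows from that import. Storage grows with observed
calls, not the full matrix, which matters for sparse datasets.

Markers do not exist in VCF, so each variant's marker is synthesized as
`<variant uniquename> + suffix` (default `.assay`, configurable) and
linked by a typed feature relationship. INFO fields are not stored; only
FORMAT subfields are per-call metrics. FORMAT values are typed by the
header's `Type` declaration (Integer/Float) when present, else kept as
text. Sample→germplasm mapping is identity unless a name map is given.

## Materialized views

Refresh is full rebuild (drop + repopulate), the simplest semantics that
make "refresh twice = no change" and "refresh after rename = new names"
trivially true. The index set is fixed: calls `(variant_id)`,
`(stock_id, variant_id)`, `(project_id)`; variants
`(backbone_name, fmin)` (compound, to serve range scans), `(variant_id)`;
phenotypes `(trait_id, project_id)`, `(stock_id)`.

The phenotype view averages quantitative replicate groups arithmetically
— values are summed in measurement (insertion) order, so recomputing the
mean from the same stored text values reproduces the float bit-for-bit —
and reduces qualitative groups to category counts plus a modal category.
Averaging is undefined for categories, so mode-plus-counts is this
package's choice; ties break to the lexicographically smallest category,
deterministically.

## Matrix queries and consensus

Queries are two-stage by design: stage 1 filters the variant-location
view (small), stage 2 fetches calls for the surviving variant ids from
the call view (large) via its indexed keys. A cell's consensus merges
all calls for the (variant, germplasm) pair across markers and projects
in scope: identical allele strings pass through; disagreeing calls
render as the IUPAC code of the allele union when all alleles are single
bases, else as slash-joined alleles. Pairwise polymorphism compares the
*consensus per variant* (not raw per-marker calls — documented choice),
and excludes variants where either member of the pair has no call: a
difference cannot be asserted against missing data. The contract is the
brute-force cell-by-cell definition, and tests hold the set-based
implementation to it on randomized matrices.

Pagination defaults to 100 variants per page and is applied after all
filtering; exports always stream the full filtered set. The HapMap
export uses the classic 11-column TASSEL-compatible dialect, `NN` for
missing cells and `NA` for unavailable metadata.

## Flanking annotation

The default window is 200 bases per side — a typical span for designing
a marker assay around a SNP. The focal variant renders as
`[REF/ALT,...]` with its observed alleles explicit, rather than as an
IUPAC code, because assay design needs the allele identities. Every
*other* catalogued single-base variant in the window (whether or not it
has stored calls) is substituted by the IUPAC code of its reference base
united with its observed alleles; multi-base or non-ACGT neighbours are
left untouched and listed with a skipped flag. Sequences are always
reported on the + strand, truncated (never padded) at contig ends, and
annotation is reversible: stripping the bracket and reverting
substitutions reproduces the reference slice byte-for-byte — a property
tested on a thousand random windows.

## Phenotype pipeline

The template has eight fixed columns — trait, method, unit, germplasm,
value, location, year, replicate — matched order-insensitively and
renameable through a header map. Validation is a ledger of six ordered
checks (required fields, germplasm existence by exact accession, value
type against known traits, positive-integer replicate, plausible year,
within-file duplicate keys); failures cite row numbers and never raise,
and loading is gated on an all-pass ledger. Duplicates against
already-stored measurements are rejected at load time by the database
constraint, which keeps a re-exported file re-validatable. Missing
values (empty, `NA`, `NaN`, `.`) drop the row with a count; nothing
empty is ever stored.

A trait whose name matches an existing trait for the genus exactly is
locked: its data type cannot change and its method/unit pairing must be
one already used with stored measurements. New traits need a
description; when the description omits the data type it is inferred —
all-numeric values mean quantitative, anything else qualitative.

## Distribution summaries

Replicates are averaged per germplasm; site-years stay separate, labeled
`"<location> <year>"`. Box statistics use the midpoint quantile
convention (the quartiles of {2,4,6,8} are 3 and 7) and the 95%
confidence interval is the box-plot notch formula
`median ± 1.58·IQR/√n`, applied to the median — the standard notch
definition; the package does not compute a CI of the mean. Violin
densities are deliberately not computed server-side: the series carries
the raw per-germplasm means and any renderer can bin or smooth them.
Qualitative site-year entries count one modal category per germplasm, so
frequencies sum to the number of contributing accessions.

## Synthetic data

The seeders emit a reference FASTA (uniform ACGT), a VCF (positions
sampled without replacement per backbone, REF from the reference, one or
two ALT alleles, diploid genotypes from per-variant Dirichlet allele
frequencies, DP per call) and a phenotype TSV (normal values around a
trait mean with per-site-year shifts; categorical draws for qualitative
traits), plus a manifest recording exact non-missing counts, per-variant
allele tallies and per-group replicate means. The manifest is the oracle
for every conservation and recovery test. All randomness flows through a
seeded generator; identical spec + seed gives byte-identical output, and
the seed is written into each output's header.

Defaults follow the stance that importers skip missing data: the missing
rate is 0 unless a test raises it. The "small" preset (50 variants × 10
samples; 3 traits × 4 site-years × 20 germplasm × 3 replicates) drives
the test suite; "medium" (10⁴ variants × 100 samples, ~10⁶ calls) drives
the benchmark harness, a deliberate desk-scale stand-in for
production-size datasets. What the generators do *not* emulate: linkage
disequilibrium, pedigree structure, genotype–environment interaction,
batch effects or genotyping error, so passing tests demonstrate
correctness of storage and query semantics, not robustness to the
noise structure of real assays.

## Benchmark harness

Five named query states are timed — Unfiltered, Range and Polymorphic
matrix queries; Quantitative Measurement Distribution and per-genus
Summary — each through the materialized-view path and the equivalent
direct normalized-join path. Result equality between the two paths is
asserted before any timing is reported (correctness precedes timing);
the report carries the median and (min, max) spread over the configured
repetitions, nine by default. Timings are hardware-dependent by nature;
the harness asserts nothing about the magnitude of the speedup.

## Known limitations

- Single-writer embedded engine; no concurrent-load story.
- No BCF, structural variants, phased-haplotype preservation or VCF
  writing; no imputation, LD or population-structure statistics.
- Ontology cross-references are stored as free-form identifiers; there
  is no live ontology lookup.
- The haploid multi-base genotype collision described above.
- Phenotype site-year fields are flat columns, not property records.
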