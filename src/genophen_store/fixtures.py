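"""Deterministic synthetic-data generators (database seeders).

Every module in the package is testable without downloads: these
generators emit a reference FASTA, a VCF of genotype calls and a
phenotype TSV that approximate the structure of real diversity-panel
data, together with a ground-truth manifest (exact non-missing call
counts, per-variant allele tallies, per-group replicate means) that
downstream conservation and recovery tests treat as the oracle.

All randomness flows through ``numpy.random.default_rng`` seeded from the
spec, so identical spec + seed yields byte-identical outputs; the seed is
recorded in every output's header line so fixtures are citable in bug
reports.  Following the stance that importers skip missing data, the
default missing rate is 0; tests raise it explicitly when exercising
sparse inputs.
"""
from __future__ import annotations

import io
import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np

_BASES = np.array(list("ACGT"))

_TRAIT_NAME_POOL = [
    "Days till Plants have One Open Flower",
    "Plant Height at Maturity",
    "Days to Maturity",
    "Hundred Seed Weight",
    "Canopy Width",
    "Pods per Plant",
    "Seed Diameter",
    "Days to Swollen Pods",
    "Vegetative Vigor Score",
    "Lowest Pod Height",
    "Peduncle Length",
    "Stem Diameter",
    "Days till Harvest",
    "Seeds per Pod",
    "Biomass at Flowering",
]
_QUAL_TRAIT_POOL = [
    ("Flower Colour", ["blue", "pink", "white", "violet"]),
    ("Seed Coat Pattern", ["absent", "dotted", "marbled", "spotted"]),
    ("Testa Colour", ["brown", "green", "grey", "tan"]),
    ("Cotyledon Colour", ["red", "yellow", "green"]),
    ("Growth Habit", ["erect", "semi-erect", "prostrate"]),
]
_LOCATIONS = [
    "Saskatoon", "Sutherland", "Rosthern", "Lucky Lake", "Floral",
    "Preston", "Meath Park", "Outlook", "Elrose", "Davidson",
    "Limerick", "Central Butte",
]
_YEARS = ["2016", "2017", "2018", "2019"]


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters for one synthetic dataset.

    The defaults are the "small" preset used throughout the test suite:
    50 variants x 10 samples of diploid calls with no missing data, and
    3 traits x 4 site-years x 20 germplasm x 3 replicates of phenotypes.
    """

    seed: int = 1
    # reference
    n_backbones: int = 2
    backbone_length: int = 5000
    # genotypes
    n_variants: int = 50
    n_samples: int = 10
    ploidy: int = 2
    missing_rate: float = 0.0
    biallelic_fraction: float = 0.9  # remainder get two ALT alleles
    # phenotypes
    n_traits: int = 3
    n_siteyears: int = 4
    n_reps: int = 3
    n_germplasm: int = 20
    quantitative_fraction: float = 2 / 3
    # naming
    genus: str = "Lens"
    project_name: str = "AGILE-sim"
    assembly_label: str = "Lc1.2-sim"

    def backbone_names(self) -> list[str]:
        return [f"LcChr{i + 1}" for i in range(self.n_backbones)]

    def germplasm_names(self) -> list[str]:
        n = max(self.n_germplasm, self.n_samples)
        return [f"Lens-{i + 1:04d}" for i in range(n)]

    def sample_names(self) -> list[str]:
        return self.germplasm_names()[: self.n_samples]


SMALL = FixtureSpec()
MEDIUM = FixtureSpec(
    n_backbones=3,
    backbone_length=200_000,
    n_variants=10_000,
    n_samples=100,
    n_traits=6,
    n_siteyears=6,
    n_germplasm=100,
)
PRESETS = {"small": SMALL, "medium": MEDIUM}


# ---------------------------------------------------------------------------
# Reference
# ---------------------------------------------------------------------------


def generate_reference(spec: FixtureSpec) -> str:
    """FASTA text: ``n_backbones`` contigs of uniform-random ACGT."""
    rng = np.random.default_rng([spec.seed, 11])
    out = []
    for name in spec.backbone_names():
        seq = "".join(_BASES[rng.integers(0, 4, spec.backbone_length)])
        out.append(f">{name} synthetic backbone seed={spec.seed}\n")
        for i in range(0, len(seq), 80):
            out.append(seq[i : i + 80] + "\n")
    return "".join(out)


def reference_contigs(spec: FixtureSpec) -> dict[str, str]:
    """The same contigs as :func:`generate_reference`, as a name->sequence map."""
    contigs = {}
    name = None
    buf: list[str] = []
    for line in generate_reference(spec).splitlines():
        if line.startswith(">"):
            if name is not None:
                contigs[name] = "".join(buf)
            name = line[1:].split()[0]
            buf = []
        else:
            buf.append(line)
    if name is not None:
        contigs[name] = "".join(buf)
    return contigs


# ---------------------------------------------------------------------------
# Genotypes (VCF)
# ---------------------------------------------------------------------------


def generate_vcf(spec: FixtureSpec) -> tuple[str, dict]:
    """VCF v4.2 text plus a ground-truth manifest.

    Positions are sampled without replacement per backbone and sorted; REF
    is the reference base at each position; each variant carries one or two
    ALT alleles; diploid GT per sample with ``missing_rate`` of "./.".
    The manifest records the exact non-missing count and per-variant allele
    tallies for oracle tests.
    """
    rng = np.random.default_rng([spec.seed, 23])
    contigs = reference_contigs(spec)
    names = spec.backbone_names()
    samples = spec.sample_names()

    # round-robin split of variants across backbones
    per_bb = [spec.n_variants // len(names)] * len(names)
    for i in range(spec.n_variants % len(names)):
        per_bb[i] += 1
    for n, name in zip(per_bb, names):
        if n > len(contigs[name]):
            raise ValueError(f"n_variants exceeds available positions on {name}")

    lines = [
        "##fileformat=VCFv4.2\n",
        f"##source=genophen-store fixtures seed={spec.seed}\n",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read Depth">\n',
    ]
    for name in names:
        lines.append(f"##contig=<ID={name},length={spec.backbone_length}>\n")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n")

    manifest_variants = []
    n_non_missing = 0
    n_missing = 0
    for n_v, chrom in zip(per_bb, names):
        seq = contigs[chrom]
        positions = np.sort(rng.choice(len(seq), size=n_v, replace=False)) + 1  # 1-based
        for pos in positions:
            ref = seq[pos - 1]
            others = [b for b in "ACGT" if b != ref]
            n_alt = 1 if rng.random() < spec.biallelic_fraction else 2
            alts = list(rng.choice(others, size=n_alt, replace=False))
            allele_pool = [ref] + alts
            freqs = rng.dirichlet(np.ones(len(allele_pool)) * 2.0)
            gt_idx = rng.choice(len(allele_pool), size=(spec.n_samples, spec.ploidy), p=freqs)
            missing = rng.random(spec.n_samples) < spec.missing_rate
            depths = rng.integers(5, 61, spec.n_samples)

            name = f"{chrom}_{pos}"
            fields = []
            tally: dict[str, int] = {}
            var_missing = 0
            for si in range(spec.n_samples):
                if missing[si]:
                    fields.append("./.:.")
                    var_missing += 1
                    n_missing += 1
                    continue
                idx = gt_idx[si]
                fields.append("/".join(str(int(i)) for i in idx) + f":{int(depths[si])}")
                for i in idx:
                    a = allele_pool[int(i)]
                    tally[a] = tally.get(a, 0) + 1
                n_non_missing += 1
            lines.append(
                f"{chrom}\t{int(pos)}\t{name}\t{ref}\t{','.join(alts)}\t.\tPASS\t.\tGT:DP\t"
                + "\t".join(fields)
                + "\n"
            )
            manifest_variants.append(
                {
                    "name": name,
                    "chrom": chrom,
                    "pos": int(pos),
                    "ref": ref,
                    "alts": alts,
                    "n_missing": var_missing,
                    "allele_counts": dict(sorted(tally.items())),
                }
            )

    manifest = {
        "seed": spec.seed,
        "n_variants": spec.n_variants,
        "n_samples": spec.n_samples,
        "samples": samples,
        "n_non_missing": n_non_missing,
        "n_missing": n_missing,
        "variants": manifest_variants,
    }
    return "".join(lines), manifest


# ---------------------------------------------------------------------------
# Phenotypes (TSV)
# ---------------------------------------------------------------------------


def trait_plan(spec: FixtureSpec) -> list[dict]:
    """The deterministic trait roster for a spec: names, types, categories."""
    n_quant = round(spec.quantitative_fraction * spec.n_traits)
    traits = []
    units = ["days", "cm", "g", "count", "score"]
    for i in range(spec.n_traits):
        if i < n_quant:
            name = _TRAIT_NAME_POOL[i % len(_TRAIT_NAME_POOL)]
            if i >= len(_TRAIT_NAME_POOL):
                name = f"{name} ({i // len(_TRAIT_NAME_POOL) + 1})"
            traits.append(
                {
                    "trait": name,
                    "method": "Average of ten representative plants",
                    "unit": units[i % len(units)],
                    "data_type": "quantitative",
                    "categories": None,
                }
            )
        else:
            qname, cats = _QUAL_TRAIT_POOL[(i - n_quant) % len(_QUAL_TRAIT_POOL)]
            if i - n_quant >= len(_QUAL_TRAIT_POOL):
                qname = f"{qname} ({(i - n_quant) // len(_QUAL_TRAIT_POOL) + 1})"
            traits.append(
                {
                    "trait": qname,
                    "method": "Visual assessment of the plot",
                    "unit": "category",
                    "data_type": "qualitative",
                    "categories": cats,
                }
            )
    return traits


def siteyears(spec: FixtureSpec) -> list[tuple[str, str]]:
    out = []
    i = 0
    while len(out) < spec.n_siteyears:
        loc = _LOCATIONS[i % len(_LOCATIONS)]
        year = _YEARS[(i // len(_LOCATIONS)) % len(_YEARS)]
        if (loc, year) not in out:
            out.append((loc, year))
        i += 1
        if i > 10 * spec.n_siteyears + len(_LOCATIONS) * len(_YEARS):
            # exhausts the location x year grid; extend years
            year = str(2016 + i)
            out.append((_LOCATIONS[i % len(_LOCATIONS)], year))
    return out[: spec.n_siteyears]


def generate_phenotypes(spec: FixtureSpec) -> tuple[str, dict]:
    """Phenotype TSV plus a manifest of true per-group replicate means.

    One row per trait x site-year x germplasm x replicate.  Quantitative
    values are normal around a trait mean with a site-year shift;
    qualitative values are drawn from the trait's category set.  The
    manifest's group means/counts are computed from the emitted values in
    emission (replicate) order, making them an exact oracle for the
    replicate-averaging materialized view.
    """
    rng = np.random.default_rng([spec.seed, 37])
    traits = trait_plan(spec)
    sys_ = siteyears(spec)
    germs = spec.germplasm_names()[: spec.n_germplasm]

    lines = [f"# genophen-store fixtures seed={spec.seed}\n"]
    lines.append("trait\tmethod\tunit\tgermplasm\tvalue\tlocation\tyear\treplicate\n")
    group_means: dict[str, float] = {}
    group_counts: dict[str, dict[str, int]] = {}
    n_rows = 0
    for t in traits:
        base = rng.uniform(20.0, 100.0)
        sd = rng.uniform(2.0, 8.0)
        shifts = rng.normal(0.0, 5.0, len(sys_))
        for (loc, year), shift in zip(sys_, shifts):
            for g in germs:
                key = f"{t['trait']}|{loc}|{year}|{g}"
                if t["data_type"] == "quantitative":
                    vals = [float(x) for x in rng.normal(base + shift, sd, spec.n_reps)]
                    for rep, v in enumerate(vals, start=1):
                        lines.append(
                            f"{t['trait']}\t{t['method']}\t{t['unit']}\t{g}\t{v!r}\t{loc}\t{year}\t{rep}\n"
                        )
                        n_rows += 1
                    # repr() round-trips floats exactly, so this mean is the
                    # same arithmetic the mview refresh performs after reload
                    group_means[key] = sum(vals) / len(vals)
                else:
                    cats = [str(c) for c in rng.choice(t["categories"], size=spec.n_reps)]
                    counts: dict[str, int] = {}
                    for rep, c in enumerate(cats, start=1):
                        lines.append(
                            f"{t['trait']}\t{t['method']}\t{t['unit']}\t{g}\t{c}\t{loc}\t{year}\t{rep}\n"
                        )
                        counts[c] = counts.get(c, 0) + 1
                        n_rows += 1
                    group_counts[key] = dict(sorted(counts.items()))

    manifest = {
        "seed": spec.seed,
        "project": spec.project_name,
        "genus": spec.genus,
        "n_rows": n_rows,
        "traits": traits,
        "siteyears": [list(sy) for sy in sys_],
        "germplasm": germs,
        "n_reps": spec.n_reps,
        "group_means": group_means,
        "group_category_counts": group_counts,
    }
    return "".join(lines), manifest


# ---------------------------------------------------------------------------
# Whole-set helpers
# ---------------------------------------------------------------------------


def write_fixture_set(spec: FixtureSpec, outdir) -> dict:
    """Write reference.fasta, calls.vcf, phenotypes.tsv and manifest.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fasta = generate_reference(spec)
    vcf, vcf_manifest = generate_vcf(spec)
    tsv, pheno_manifest = generate_phenotypes(spec)
    paths = {
        "reference": outdir / "reference.fasta",
        "vcf": outdir / "calls.vcf",
        "phenotypes": outdir / "phenotypes.tsv",
        "manifest": outdir / "manifest.json",
    }
    paths["reference"].write_text(fasta)
    paths["vcf"].write_text(vcf)
    paths["phenotypes"].write_text(tsv)
    paths["manifest"].write_text(
        json.dumps({"spec": asdict(spec), "vcf": vcf_manifest, "phenotypes": pheno_manifest}, indent=1)
    )
    return paths


def seed_store(store, spec: FixtureSpec, *, with_phenotypes: bool = True, refresh: bool = True) -> dict:
    """Populate a store end-to-end from a spec (the in-memory seeder).

    Loads the reference backbones, imports the VCF through the real
    importer, registers any extra germplasm, pushes the phenotype TSV
    through the full staged pipeline and (optionally) refreshes the three
    materialized views.  Returns the two manifests and the import report.
    """
    from . import mviews, phenotypes as pheno
    from .vcf_import import ImportConfig, import_vcf

    fasta = generate_reference(spec)
    store.load_reference_fasta(io.StringIO(fasta))
    vcf_text, vcf_manifest = generate_vcf(spec)
    report = import_vcf(
        store,
        io.StringIO(vcf_text),
        ImportConfig(
            project_name=spec.project_name,
            genus=spec.genus,
            assembly_label=spec.assembly_label,
        ),
    )
    result = {"vcf_manifest": vcf_manifest, "import_report": report, "pheno_manifest": None}
    if with_phenotypes:
        for g in spec.germplasm_names()[: spec.n_germplasm]:
            store.get_or_create_germplasm(g, g, spec.genus)
        tsv, pheno_manifest = generate_phenotypes(spec)
        descriptions = [
            pheno.TraitDescription(
                trait_name=t["trait"],
                definition=f"synthetic {t['data_type']} trait",
                data_type=t["data_type"],
            )
            for t in pheno_manifest["traits"]
        ]
        pheno.import_phenotype_tsv(
            store,
            io.StringIO(tsv),
            project=spec.project_name,
            genus=spec.genus,
            descriptions=descriptions,
        )
        result["pheno_manifest"] = pheno_manifest
    if refresh:
        mviews.refresh_all(store)
    return result
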