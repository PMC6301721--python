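"""Synthetic inputs with known ground truth: toy exomes, rate tables, null
and risk-spiked trio cohorts, gene sets, pLI tables, and expression
matrices. Every generator is a pure function of (config, seed)."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort_io import BASES, CohortSpec, DeNovoVariant
from .mutation_model import (
    GeneModel,
    RateTable,
    Transcript,
    allele_factor,
    enumerate_substitutions,
    revcomp,
    select_transcript,
)

_STOPS = {"TAA", "TAG", "TGA"}


@dataclass
class GeneratorConfig:
    """Knobs for all generators; ``seed`` is mandatory for every emission."""

    seed: int
    n_genes: int = 200
    cds_len_mean: int = 1200
    cds_len_sd: float | None = None  # defaults to cds_len_mean / 12; 0 fixes the length
    gc: float = 0.45
    frac_two_exon: float = 0.3
    frac_chrx: float = 0.0
    n_trios: int = 500
    male_frac: float = 0.586
    complex_frac: float = 0.412
    dmis_fraction: float = 0.3
    # toy-scaled so ~200 genes x 1.2 kb x 500 trios yields about one coding
    # variant per proband (real per-context rates are ~1.5e-8 and would
    # leave a toy exome empty)
    rate_mean: float = 9e-7
    rate_spectrum: str = "uniform"  # or "cpg"
    cpg_factor: float = 10.0
    risk_genes: tuple[str, ...] = ()
    relative_risk: float = 1.0
    expression_shift: float = 0.0

    def __post_init__(self) -> None:
        if self.n_genes <= 0 or self.cds_len_mean <= 0 or self.n_trios < 0:
            raise ValueError("counts must be positive")
        if not (0.0 < self.gc < 1.0):
            raise ValueError("gc must be in (0, 1)")
        if self.relative_risk < 1.0:
            raise ValueError("relative risk must be >= 1")


def gen_rate_table(cfg: GeneratorConfig) -> RateTable:
    """Strand-complement-symmetric rate table with all 192 entries.

    "uniform" draws log-normal rates around ``rate_mean``; "cpg" further
    multiplies C>T transitions in a CpG context by ``cpg_factor``.
    """
    rng = np.random.default_rng(cfg.seed)
    rates: dict[tuple[str, str], float] = {}
    for a in BASES:
        for b in BASES:
            for c in BASES:
                src = a + b + c
                for alt in BASES:
                    if alt == b:
                        continue
                    dst = a + alt + c
                    canonical = min((src, dst), (revcomp(src), revcomp(dst)))
                    if canonical in rates:
                        rates[(src, dst)] = rates[canonical]
                        continue
                    rate = float(cfg.rate_mean * rng.lognormal(0.0, 0.3))
                    # CpG C>T in either strand orientation of the canonical pair
                    c_src, c_dst = canonical
                    is_cpg = ((c_src[1] == "C" and c_src[2] == "G" and c_dst[1] == "T")
                              or (c_src[0] == "C" and c_src[1] == "G" and c_dst[1] == "A"))
                    if cfg.rate_spectrum == "cpg" and is_cpg:
                        rate *= cfg.cpg_factor
                    rates[canonical] = rate
                    rates[(src, dst)] = rate
    return RateTable(rates)


@dataclass
class Exome:
    """A toy exome: gene models plus the reference sequences they live on."""

    genes: list[GeneModel]
    genome: dict[str, str]

    def gene_names(self) -> list[str]:
        return [g.gene for g in self.genes]

    def cds_length(self, gene: GeneModel) -> int:
        return select_transcript(gene).cds_length


def _random_cds(rng: np.random.Generator, n_codons: int, gc: float) -> str:
    """ATG + random non-stop codons + one stop; realized GC follows the
    base-composition parameter."""
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    body = []
    for _ in range(n_codons - 2):
        while True:
            codon = "".join(rng.choice(list(BASES), size=3, p=probs))
            if codon not in _STOPS:
                body.append(codon)
                break
    return "ATG" + "".join(body) + "TGA"


def gen_exome(cfg: GeneratorConfig) -> Exome:
    """Deterministic toy exome: ``n_genes`` single- or two-exon genes laid
    out on chr1 (and chrX when ``frac_chrx`` > 0), CDS lengths divisible by
    3 with no internal stop codons."""
    rng = np.random.default_rng(cfg.seed)
    spacer = 30
    chrom_parts: dict[str, list[str]] = {}
    chrom_offsets: dict[str, int] = {}
    genes: list[GeneModel] = []

    def _append(chrom: str, seq: str) -> int:
        start = chrom_offsets.get(chrom, 0)
        chrom_parts.setdefault(chrom, []).append(seq)
        chrom_offsets[chrom] = start + len(seq)
        return start

    len_sd = cfg.cds_len_mean / 12 if cfg.cds_len_sd is None else cfg.cds_len_sd
    for i in range(cfg.n_genes):
        name = f"G{i + 1:04d}"
        n_codons = max(4, int(round(rng.normal(cfg.cds_len_mean / 3, len_sd / 3))))
        cds = _random_cds(rng, n_codons, cfg.gc)
        on_x = rng.random() < cfg.frac_chrx
        chrom = "chrX" if on_x else "chr1"
        strand = "+" if rng.random() < 0.5 else "-"
        two_exon = rng.random() < cfg.frac_two_exon and len(cds) >= 12

        pieces: list[str] = []
        rel_intervals: list[tuple[int, int]] = []  # relative to gene block start
        cursor = 0

        def _pad(n: int) -> None:
            nonlocal cursor
            pieces.append("".join(rng.choice(list(BASES), size=n)))
            cursor += n

        genomic_cds = cds if strand == "+" else revcomp(cds)
        _pad(spacer)
        if two_exon:
            cut = 3 * int(rng.integers(1, len(cds) // 3))
            # intron canonical on the coding strand: GT ... AG
            intron = "GT" + "".join(rng.choice(list(BASES), size=26)) + "AG"
            if strand == "+":
                exon1, exon2 = genomic_cds[:cut], genomic_cds[cut:]
                genomic_intron = intron
            else:
                exon1 = genomic_cds[: len(cds) - cut]
                exon2 = genomic_cds[len(cds) - cut:]
                genomic_intron = revcomp(intron)
            rel_intervals.append((cursor, cursor + len(exon1)))
            pieces.append(exon1)
            cursor += len(exon1)
            pieces.append(genomic_intron)
            cursor += len(genomic_intron)
            rel_intervals.append((cursor, cursor + len(exon2)))
            pieces.append(exon2)
            cursor += len(exon2)
        else:
            rel_intervals.append((cursor, cursor + len(genomic_cds)))
            pieces.append(genomic_cds)
            cursor += len(genomic_cds)
        _pad(spacer)

        block = "".join(pieces)
        start = _append(chrom, block)
        intervals = tuple((start + s, start + e) for s, e in rel_intervals)
        tx = Transcript(f"{name}.t1", chrom, strand, intervals)
        genes.append(GeneModel(name, [tx], chrx_nonpar=on_x))

    genome = {chrom: "".join(parts) for chrom, parts in chrom_parts.items()}
    return Exome(genes=genes, genome=genome)


@dataclass
class SiteCatalog:
    """Per-gene, per-class site lists with context rates, precomputed once
    so repeated cohort draws stay cheap."""

    exome: Exome
    per_gene: dict[str, dict[str, dict]] = field(default_factory=dict)
    gene_rates: dict[str, dict[str, float]] = field(default_factory=dict)

    @classmethod
    def build(cls, exome: Exome, rate_table: RateTable) -> "SiteCatalog":
        cat = cls(exome=exome)
        for g in exome.genes:
            tx = select_transcript(g)
            buckets: dict[str, dict[str, list]] = {
                c: {"pos": [], "ref": [], "alt": [], "context": [], "rate": []}
                for c in ("synonymous", "missense", "nonsense", "splice_site")
            }
            for sub in enumerate_substitutions(tx, exome.genome):
                b = buckets[sub.effect]
                b["pos"].append(sub.pos)
                b["ref"].append(sub.ref)
                b["alt"].append(sub.alt)
                b["context"].append(sub.context)
                b["rate"].append(rate_table.rate(sub.context, sub.alt))
            per_class = {}
            totals = {}
            for cls_name, b in buckets.items():
                rates = np.asarray(b["rate"], dtype=float)
                per_class[cls_name] = {
                    "pos": np.asarray(b["pos"], dtype=np.int64),
                    "ref": b["ref"], "alt": b["alt"], "context": b["context"],
                    "rate": rates,
                }
                totals[cls_name] = float(rates.sum())
            totals["frameshift"] = 1.1 * totals["nonsense"]
            cat.per_gene[g.gene] = per_class
            cat.gene_rates[g.gene] = totals
        return cat


def gen_cohort_spec(cfg: GeneratorConfig, rng: np.random.Generator) -> CohortSpec:
    strata = {}
    for i in range(cfg.n_trios):
        sex = "M" if rng.random() < cfg.male_frac else "F"
        group = "complex" if rng.random() < cfg.complex_frac else "isolated"
        strata[f"P{i + 1:05d}"] = (sex, group)
    n_male = sum(1 for s, _ in strata.values() if s == "M")
    return CohortSpec(n_trios=cfg.n_trios, n_male=n_male,
                      n_female=cfg.n_trios - n_male, strata=strata)


_CONSEQUENCE_OF = {"synonymous": "synonymous", "missense": "missense",
                   "nonsense": "nonsense", "splice_site": "splice_site"}


def _sample_cohort(
    catalog: SiteCatalog,
    cfg: GeneratorConfig,
    risk: Mapping[str, float],
) -> tuple[list[DeNovoVariant], CohortSpec, dict]:
    """Shared sampler behind the null and spiked cohort generators.

    Per gene x class, counts are Poisson with mean = class rate x cohort
    allele factor x relative risk; positions are drawn within-gene
    proportional to site rates; missense CADD scores are a two-component
    mixture so the D-mis fraction matches ``cfg.dmis_fraction``. Probands
    are assigned uniformly (an approximation on chrX, where male carriers
    should be rarer; totals still match the allele-count expectation).
    """
    rng = np.random.default_rng(cfg.seed)
    cohort = gen_cohort_spec(cfg, rng)
    probands = sorted(cohort.strata)
    by_x = {g.gene: g.chrx_nonpar for g in catalog.exome.genes}

    variants: list[DeNovoVariant] = []
    lam_totals = {c: 0.0 for c in ("synonymous", "missense", "nonsense",
                                   "splice_site", "frameshift")}
    for g in catalog.exome.genes:
        factor = allele_factor(cohort, by_x[g.gene])
        rr = risk.get(g.gene, 1.0)
        sites = catalog.per_gene[g.gene]
        for cls_name in ("synonymous", "missense", "nonsense", "splice_site"):
            bucket = sites[cls_name]
            lam = catalog.gene_rates[g.gene][cls_name] * factor * rr
            lam_totals[cls_name] += lam
            count = rng.poisson(lam)
            if count == 0 or len(bucket["rate"]) == 0:
                continue
            weights = bucket["rate"] / bucket["rate"].sum()
            idx = rng.choice(len(weights), size=count, p=weights)
            for j in idx:
                proband = probands[rng.integers(0, len(probands))]
                if cls_name == "missense":
                    if rng.random() < cfg.dmis_fraction:
                        cadd = float(rng.uniform(25.0, 45.0))
                    else:
                        cadd = float(rng.uniform(2.0, 24.9))
                elif cls_name == "synonymous":
                    cadd = float(rng.uniform(0.0, 10.0))
                else:
                    cadd = float(rng.uniform(20.0, 50.0))
                variants.append(DeNovoVariant(
                    chrom=g.transcripts[0].chrom,
                    pos=int(bucket["pos"][j]) + 1,
                    ref_allele=bucket["ref"][j],
                    alt_allele=bucket["alt"][j],
                    proband_id=proband,
                    gene=g.gene,
                    consequence=_CONSEQUENCE_OF[cls_name],
                    cadd_phred=cadd,
                    trinucleotide_context=bucket["context"][j],
                    platform="WGS",
                ))
        # frameshift indels: 1.1 x nonsense rate, uniform position in CDS
        lam_fs = catalog.gene_rates[g.gene]["frameshift"] * factor * rr
        lam_totals["frameshift"] += lam_fs
        tx = select_transcript(g)
        coding = tx.coding_positions()
        for _ in range(rng.poisson(lam_fs)):
            proband = probands[rng.integers(0, len(probands))]
            pos0 = coding[rng.integers(0, len(coding))]
            ref = catalog.exome.genome[tx.chrom][pos0]
            ins = BASES[rng.integers(0, 4)]
            variants.append(DeNovoVariant(
                chrom=tx.chrom, pos=pos0 + 1, ref_allele=ref, alt_allele=ref + ins,
                proband_id=proband, gene=g.gene, consequence="frameshift",
                cadd_phred=None, trinucleotide_context=None, platform="WGS",
            ))

    manifest = {
        "seed": cfg.seed,
        "n_trios": cfg.n_trios,
        "dmis_fraction": cfg.dmis_fraction,
        "risk_genes": sorted(risk),
        "relative_risk": {g: r for g, r in sorted(risk.items())},
        "expected_class_totals": lam_totals,
        "n_variants": len(variants),
    }
    return variants, cohort, manifest


def gen_null_cohort(catalog: SiteCatalog, cfg: GeneratorConfig
                    ) -> tuple[list[DeNovoVariant], CohortSpec, dict]:
    """Null trio cohort: per-gene, per-class counts at baseline rates."""
    return _sample_cohort(catalog, cfg, risk={})


def spike_risk(catalog: SiteCatalog, cfg: GeneratorConfig
               ) -> tuple[list[DeNovoVariant], CohortSpec, dict]:
    """Cohort with ``cfg.risk_genes`` class rates multiplied by
    ``cfg.relative_risk``; with relative risk 1 this reproduces
    :func:`gen_null_cohort` exactly under the same seed."""
    unknown = set(cfg.risk_genes) - set(catalog.per_gene)
    if unknown:
        raise ValueError(f"unknown risk genes: {', '.join(sorted(unknown))}")
    risk = {g: cfg.relative_risk for g in cfg.risk_genes}
    return _sample_cohort(catalog, cfg, risk=risk)


def gen_expression(
    cfg: GeneratorConfig,
    genes: Sequence[str],
    n_samples: int,
    carriers: Sequence[str],
    target_genes: Iterable[str],
) -> tuple[pd.DataFrame, dict]:
    """Log-scale expression matrix (genes x samples) with the target genes
    shifted by ``cfg.expression_shift`` standard deviations in carrier
    samples."""
    rng = np.random.default_rng(cfg.seed)
    samples = [f"S{i + 1:03d}" for i in range(n_samples)]
    carriers = list(carriers)
    targets = set(target_genes)
    if not set(carriers) <= set(samples):
        raise ValueError("carriers must be a subset of the generated samples")
    if not targets <= set(genes):
        raise ValueError("target genes must be a subset of the gene list")
    if not targets or not carriers or len(carriers) == len(samples):
        raise ValueError("carrier and non-carrier groups must both be non-empty")

    base = rng.normal(5.0, 2.0, size=len(genes))
    noise_sd = rng.uniform(0.5, 1.5, size=len(genes))
    values = base[:, None] + rng.normal(0.0, 1.0, size=(len(genes), n_samples)) * noise_sd[:, None]
    carrier_cols = [samples.index(s) for s in carriers]
    target_rows = [i for i, g in enumerate(genes) if g in targets]
    for i in target_rows:
        values[i, carrier_cols] += cfg.expression_shift * noise_sd[i]

    matrix = pd.DataFrame(values, index=list(genes), columns=samples)
    manifest = {"seed": cfg.seed, "shift": cfg.expression_shift,
                "carriers": carriers, "n_target": len(targets),
                "target_genes": sorted(targets)}
    return matrix, manifest


def gen_gene_sets(cfg: GeneratorConfig, universe: Sequence[str], n_sets: int,
                  size_range: tuple[int, int] = (5, 40)) -> tuple[dict[str, set[str]], dict]:
    rng = np.random.default_rng(cfg.seed)
    sets: dict[str, set[str]] = {}
    for i in range(n_sets):
        size = int(rng.integers(size_range[0], size_range[1] + 1))
        size = min(size, len(universe))
        members = rng.choice(len(universe), size=size, replace=False)
        sets[f"SET{i + 1:04d}"] = {universe[j] for j in members}
    manifest = {"seed": cfg.seed, "sizes": {k: len(v) for k, v in sets.items()}}
    return sets, manifest


def gen_pli(cfg: GeneratorConfig, genes: Sequence[str],
            frac_constrained: float = 0.25) -> dict[str, float]:
    rng = np.random.default_rng(cfg.seed)
    return {g: float(rng.uniform(0.5, 1.0)) if rng.random() < frac_constrained
            else float(rng.uniform(0.0, 0.5)) for g in genes}


def write_manifest(path, manifest: Mapping) -> None:
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")


def config_as_dict(cfg: GeneratorConfig) -> dict:
    return dataclasses.asdict(cfg)
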