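"""Variant records, functional classification, candidate de novo filters, and table I/O.

Coordinates are 1-based inclusive in all external files and 0-based
half-open internally; the readers/writers in this module are the only
place offsets change.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

BASES = "ACGT"
TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}

#: consequence values accepted on input
CONSEQUENCES = frozenset(
    {"synonymous", "missense", "inframe", "frameshift", "nonsense", "splice_site", "stop_loss"}
)

#: classification labels emitted by :func:`classify_variant`
CLASS_LABELS = ("synonymous", "missense", "D-mis", "LGD", "inframe", "unscored", "other")

DENOVO_COLUMNS = [
    "chrom", "pos", "ref", "alt", "proband", "sex", "group",
    "gene", "consequence", "cadd_phred", "platform",
]


class SchemaError(ValueError):
    """A required column or field is missing or malformed."""


@dataclass(frozen=True)
class DeNovoVariant:
    """One observed de novo coding variant.

    ``pos`` is 1-based (as in the external tables). ``trinucleotide_context``
    is the plus-strand 3-mer centered on ``pos`` and is present iff the
    variant is a SNV; indels carry no context and are excluded from all
    context-conditioned operations.
    """

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    proband_id: str
    gene: str
    consequence: str
    cadd_phred: float | None = None
    trinucleotide_context: str | None = None
    platform: str = "WES"

    def __post_init__(self) -> None:
        if self.ref_allele == self.alt_allele:
            raise ValueError(f"ref == alt ({self.ref_allele}) at {self.chrom}:{self.pos}")
        if self.consequence not in CONSEQUENCES:
            raise ValueError(f"unknown consequence {self.consequence!r}")
        if self.pos < 1:
            raise ValueError("pos must be 1-based and positive")
        if self.cadd_phred is not None and self.cadd_phred < 0:
            raise ValueError("cadd_phred must be non-negative")
        if self.platform not in ("WES", "WGS"):
            raise ValueError(f"unknown platform {self.platform!r}")
        if self.is_snv:
            if self.trinucleotide_context is not None:
                ctx = self.trinucleotide_context
                if len(ctx) != 3 or ctx[1] != self.ref_allele:
                    raise ValueError(f"context {ctx!r} does not center on ref {self.ref_allele}")
        elif self.trinucleotide_context is not None:
            raise ValueError("indels carry no trinucleotide context")

    @property
    def is_snv(self) -> bool:
        return len(self.ref_allele) == 1 and len(self.alt_allele) == 1

    @property
    def is_transition(self) -> bool:
        return self.is_snv and (self.ref_allele, self.alt_allele) in TRANSITIONS


@dataclass(frozen=True)
class VariantClassRule:
    """Deleteriousness rule: CADD cutoff for D-mis and the consequence
    values counted as likely gene disrupting."""

    dmis_threshold: float = 25.0
    lgd_members: frozenset[str] = frozenset({"frameshift", "nonsense", "splice_site", "stop_loss"})

    def __post_init__(self) -> None:
        if self.dmis_threshold <= 0:
            raise ValueError("dmis_threshold must be positive")
        if not self.lgd_members:
            raise ValueError("lgd_members must be non-empty")


def classify_variant(v: DeNovoVariant, rule: VariantClassRule = VariantClassRule()) -> str:
    """Assign one mutually exclusive class label to a variant.

    D-mis is the subset of missense with ``cadd_phred >= rule.dmis_threshold``
    and is reported as the more specific label. A missense variant without a
    CADD score is labelled ``unscored`` rather than silently down-classified.
    """
    c = v.consequence
    if c in rule.lgd_members:
        return "LGD"
    if c == "missense":
        if v.cadd_phred is None:
            return "unscored"
        return "D-mis" if v.cadd_phred >= rule.dmis_threshold else "missense"
    if c == "synonymous":
        return "synonymous"
    if c == "inframe":
        return "inframe"
    return "other"


def is_damaging(label: str) -> bool:
    return label in ("LGD", "D-mis")


@dataclass(frozen=True)
class TrioGenotypeRecord:
    """Read-level evidence for one candidate de novo site in one trio."""

    proband_alt_reads: int
    proband_total_reads: int
    proband_gq: float
    parent_ref_reads: tuple[int, int]
    parent_alt_fraction: tuple[float, float]
    parent_gq: tuple[float, float]
    population_af: float = 0.0
    is_indel: bool = False

    def __post_init__(self) -> None:
        if self.proband_alt_reads < 0 or self.proband_total_reads < 0:
            raise ValueError("read counts must be non-negative")
        if self.proband_alt_reads > self.proband_total_reads:
            raise ValueError("alt reads exceed total reads")
        if any(r < 0 for r in self.parent_ref_reads):
            raise ValueError("parent read counts must be non-negative")
        for f in (*self.parent_alt_fraction, self.population_af):
            if not (0.0 <= f <= 1.0):
                raise ValueError(f"fraction {f} outside [0, 1]")


@dataclass(frozen=True)
class FilterResult:
    passed: bool
    failed_rules: tuple[str, ...] = ()
    skipped_rules: tuple[str, ...] = ()

    def __bool__(self) -> bool:  # pragma: no cover - convenience
        return self.passed


def filter_candidate_denovo(
    rec: TrioGenotypeRecord,
    vqsr_tranche: float | None = None,
    fs: float | None = None,
    qd: float | None = None,
) -> FilterResult:
    """Apply the stringent candidate de novo filters.

    Proband: alt reads >= 5, alt fraction >= 20%, GQ >= 60, population
    AF <= 0.1%. Each parent: >= 10 reference reads, alt fraction < 5%
    (strict), GQ >= 30. Site level (skipped with a logged reason when the
    metric is absent): FS <= 25, QD >= 2, VQSR tranche <= 99.8 for SNVs /
    <= 99.0 for indels.
    """
    failed: list[str] = []
    skipped: list[str] = []

    if rec.proband_alt_reads < 5:
        failed.append("alt_reads")
    frac = rec.proband_alt_reads / rec.proband_total_reads if rec.proband_total_reads else 0.0
    if frac < 0.20:
        failed.append("alt_fraction")
    if rec.proband_gq < 60:
        failed.append("proband_gq")
    if rec.population_af > 0.001:
        failed.append("population_af")
    for i in range(2):
        if rec.parent_ref_reads[i] < 10:
            failed.append(f"parent{i + 1}_ref_reads")
        if rec.parent_alt_fraction[i] >= 0.05:
            failed.append(f"parent{i + 1}_alt_fraction")
        if rec.parent_gq[i] < 30:
            failed.append(f"parent{i + 1}_gq")

    for name, value, ok in (
        ("fs", fs, lambda x: x <= 25),
        ("qd", qd, lambda x: x >= 2),
        ("vqsr_tranche", vqsr_tranche,
         lambda x: x <= (99.0 if rec.is_indel else 99.8)),
    ):
        if value is None:
            skipped.append(name)
            logger.debug("site metric %s absent; rule skipped", name)
        elif not ok(value):
            failed.append(name)

    return FilterResult(passed=not failed, failed_rules=tuple(failed), skipped_rules=tuple(skipped))


@dataclass
class CohortSpec:
    """Trio counts by sex with per-proband sex/phenotype stratum labels."""

    n_trios: int
    n_male: int
    n_female: int
    strata: dict[str, tuple[str, str]] = field(default_factory=dict)  # proband -> (sex, group)

    def __post_init__(self) -> None:
        if self.n_male + self.n_female != self.n_trios:
            raise ValueError("n_male + n_female must equal n_trios")
        if self.n_trios < 0:
            raise ValueError("trio counts must be non-negative")

    @classmethod
    def from_table(cls, df: pd.DataFrame) -> "CohortSpec":
        for col in ("proband", "sex", "group"):
            if col not in df.columns:
                raise SchemaError(f"cohort table missing column {col!r}")
        strata = {str(r.proband): (str(r.sex), str(r.group)) for r in df.itertuples()}
        n_male = sum(1 for s, _ in strata.values() if s == "M")
        n_female = sum(1 for s, _ in strata.values() if s == "F")
        return cls(n_trios=len(strata), n_male=n_male, n_female=n_female, strata=strata)

    def subset(self, probands: Iterable[str]) -> "CohortSpec":
        keep = {p: sg for p, sg in self.strata.items() if p in set(probands)}
        n_male = sum(1 for s, _ in keep.values() if s == "M")
        return CohortSpec(n_trios=len(keep), n_male=n_male,
                          n_female=len(keep) - n_male, strata=keep)

    def groups(self) -> list[str]:
        return sorted({g for _, g in self.strata.values()})


def ts_tv_ratio(variants: Iterable[DeNovoVariant]) -> float:
    """Transition / transversion ratio over the SNVs in ``variants``."""
    ts = tv = 0
    for v in variants:
        if not v.is_snv:
            continue
        if v.is_transition:
            ts += 1
        else:
            tv += 1
    if tv == 0:
        raise ZeroDivisionError("no transversions observed")
    return ts / tv


# ---------------------------------------------------------------------------
# table I/O


def _context_from_reference(genome: Mapping[str, str], chrom: str, pos: int) -> str | None:
    seq = genome.get(chrom)
    if seq is None or pos < 2 or pos + 1 > len(seq):
        return None
    return seq[pos - 2:pos + 1].upper()


def read_denovo_table(
    path,
    genome: Mapping[str, str] | None = None,
) -> tuple[list[DeNovoVariant], CohortSpec]:
    """Read a de novo variant TSV and derive a cohort from its probands.

    Malformed rows are rejected with their 1-based line numbers. When a
    SNV row lacks a context and ``genome`` is supplied, the context is
    derived from the reference sequence.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in DENOVO_COLUMNS if c not in df.columns and c != "cadd_phred"]
    if missing:
        raise SchemaError(f"de novo table missing column(s): {', '.join(missing)}")

    variants: list[DeNovoVariant] = []
    errors: list[str] = []
    for idx, row in enumerate(df.itertuples(index=False), start=2):  # line 1 = header
        try:
            cadd = getattr(row, "cadd_phred", "")
            ref, alt = row.ref.upper(), row.alt.upper()
            ctx = getattr(row, "context", "") or ""
            if not ctx and genome is not None and len(ref) == 1 and len(alt) == 1:
                ctx = _context_from_reference(genome, row.chrom, int(row.pos)) or ""
            variants.append(DeNovoVariant(
                chrom=row.chrom,
                pos=int(row.pos),
                ref_allele=ref,
                alt_allele=alt,
                proband_id=row.proband,
                gene=row.gene,
                consequence=row.consequence,
                cadd_phred=float(cadd) if cadd not in ("", ".", "NA") else None,
                trinucleotide_context=ctx or None,
                platform=row.platform or "WES",
            ))
        except (ValueError, TypeError) as exc:
            errors.append(f"line {idx}: {exc}")
    if errors:
        raise SchemaError("rejected rows:\n" + "\n".join(errors))

    strata = {}
    for row in df.itertuples(index=False):
        strata[row.proband] = (row.sex, row.group)
    n_male = sum(1 for s, _ in strata.values() if s == "M")
    cohort = CohortSpec(n_trios=len(strata), n_male=n_male,
                        n_female=len(strata) - n_male, strata=strata)
    return variants, cohort


def write_denovo_table(path, variants: Sequence[DeNovoVariant], cohort: CohortSpec) -> None:
    rows = []
    for v in variants:
        sex, group = cohort.strata.get(v.proband_id, ("", ""))
        rows.append({
            "chrom": v.chrom, "pos": v.pos, "ref": v.ref_allele, "alt": v.alt_allele,
            "proband": v.proband_id, "sex": sex, "group": group, "gene": v.gene,
            "consequence": v.consequence,
            "cadd_phred": "" if v.cadd_phred is None else v.cadd_phred,
            "platform": v.platform,
            "context": v.trinucleotide_context or "",
        })
    pd.DataFrame(rows, columns=DENOVO_COLUMNS + ["context"]).to_csv(path, sep="\t", index=False)


def read_cohort_table(path) -> CohortSpec:
    return CohortSpec.from_table(pd.read_csv(path, sep="\t", dtype=str))


def write_cohort_table(path, cohort: CohortSpec) -> None:
    rows = [{"proband": p, "sex": s, "group": g} for p, (s, g) in sorted(cohort.strata.items())]
    pd.DataFrame(rows, columns=["proband", "sex", "group"]).to_csv(path, sep="\t", index=False)


def read_gene_sets(path, fmt: str = "GMT") -> dict[str, set[str]]:
    """Read gene sets from GMT (name, description, members...) or a
    one-gene-per-line list (single set named after the file stem)."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        if fmt.upper() == "GMT":
            for i, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line:
                    continue
                parts = line.split("\t")
                if len(parts) < 2:
                    raise SchemaError(f"line {i}: GMT needs name, description, members")
                name, members = parts[0], set(m for m in parts[2:] if m)
                if not members:
                    warnings.warn(f"gene set {name!r} is empty; dropped")
                    continue
                sets[name] = members
        elif fmt == "list":
            from pathlib import Path
            members = {line.strip() for line in fh if line.strip()}
            if members:
                sets[Path(path).stem] = members
            else:
                warnings.warn(f"{path} contains no genes")
        else:
            raise ValueError(f"unknown gene set format {fmt!r}")
    if not sets:
        warnings.warn(f"no gene sets read from {path}")
    return sets


def write_gene_sets(path, sets: Mapping[str, Iterable[str]]) -> None:
    with open(path, "w") as fh:
        for name in sorted(sets):
            fh.write("\t".join([name, "na", *sorted(sets[name])]) + "\n")


def read_pli_table(path) -> dict[str, float]:
    df = pd.read_csv(path, sep="\t", header=None, names=["gene", "pli"], comment="#")
    return dict(zip(df.gene.astype(str), df.pli.astype(float)))


def read_bed_mask(path) -> dict[str, list[tuple[int, int]]]:
    """Read a BED coverage mask (0-based half-open) into per-chromosome
    sorted interval lists."""
    mask: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise SchemaError(f"line {i}: BED needs chrom, start, end")
            mask.setdefault(parts[0], []).append((int(parts[1]), int(parts[2])))
    for chrom in mask:
        mask[chrom].sort()
    return mask


def write_run_manifest(path, *, seed: int | None, inputs: Mapping[str, str],
                       extra: Mapping | None = None) -> None:
    from . import __version__
    payload = {"seed": seed, "inputs": dict(inputs), "version": __version__}
    if extra:
        payload.update(extra)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
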