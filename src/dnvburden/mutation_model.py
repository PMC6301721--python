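"""Trinucleotide-context baseline mutation model.

Per-gene class-specific rates are obtained by enumerating every possible
single-base substitution in the CDS of the longest transcript (plus the two
canonical splice-site bases at each intron end), classifying each by its
codon effect, and summing the context-conditioned rates. Frameshift-indel
rates are derived as 1.1 times the nonsense rate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Iterable, Iterator, Mapping

import pandas as pd
from Bio.Data.CodonTable import standard_dna_table

from .cohort_io import BASES, CohortSpec

logger = logging.getLogger(__name__)

_CODON_TO_AA = dict(standard_dna_table.forward_table)
for _stop in standard_dna_table.stop_codons:
    _CODON_TO_AA[_stop] = "*"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: SNV effect classes produced by the enumerator
SNV_CLASSES = ("synonymous", "missense", "nonsense", "splice_site")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def translate_codon(codon: str) -> str:
    return _CODON_TO_AA[codon]


class RateTable:
    """Mapping (reference 3-mer, alternate 3-mer differing at the middle
    base) -> per-chromosome per-generation mutation probability.

    Lookup falls back to the reverse-complement key, so a strand-symmetric
    table needs only one orientation per context pair.
    """

    def __init__(self, rates: Mapping[tuple[str, str], float]):
        self._rates: dict[tuple[str, str], float] = {}
        for (src, dst), rate in rates.items():
            if len(src) != 3 or len(dst) != 3 or src[0] != dst[0] or src[2] != dst[2]:
                raise ValueError(f"malformed rate entry {src}>{dst}")
            if src[1] == dst[1]:
                raise ValueError(f"rate entry {src}>{dst} does not change the middle base")
            if rate <= 0:
                raise ValueError(f"rate for {src}>{dst} must be positive")
            self._rates[(src, dst)] = float(rate)

    def __len__(self) -> int:
        return len(self._rates)

    @property
    def is_complete(self) -> bool:
        return len(self.missing_contexts()) == 0

    def missing_contexts(self) -> list[tuple[str, str]]:
        missing = []
        for a in BASES:
            for b in BASES:
                for c in BASES:
                    src = a + b + c
                    for alt in BASES:
                        if alt == b:
                            continue
                        key = (src, a + alt + c)
                        if key not in self._rates and (revcomp(key[0]), revcomp(key[1])) not in self._rates:
                            missing.append(key)
        return missing

    def rate(self, context: str, alt: str) -> float:
        """Rate of the middle base of ``context`` mutating to ``alt``."""
        key = (context, context[0] + alt + context[2])
        r = self._rates.get(key)
        if r is None:
            r = self._rates.get((revcomp(key[0]), revcomp(key[1])))
        if r is None:
            raise KeyError(f"rate table has no entry for {key[0]}>{key[1]}")
        return r

    @classmethod
    def from_file(cls, path) -> "RateTable":
        """Read the whitespace-delimited 3-column dialect
        (from-trinucleotide, to-trinucleotide, rate); a header line is
        tolerated."""
        rates: dict[tuple[str, str], float] = {}
        with open(path) as fh:
            for i, line in enumerate(fh, start=1):
                parts = line.split()
                if not parts:
                    continue
                if len(parts) != 3:
                    raise ValueError(f"line {i}: expected 3 columns, got {len(parts)}")
                src, dst, raw = parts
                try:
                    rate = float(raw)
                except ValueError:
                    if i == 1:  # header
                        continue
                    raise ValueError(f"line {i}: non-numeric rate {raw!r}")
                rates[(src.upper(), dst.upper())] = rate
        return cls(rates)

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("from\tto\tmu_snp\n")
            for (src, dst), rate in sorted(self._rates.items()):
                fh.write(f"{src}\t{dst}\t{rate:.6e}\n")


@dataclass(frozen=True)
class Transcript:
    """One transcript: ordered CDS intervals on a chromosome.

    ``cds_intervals`` are 0-based half-open and sorted by genomic start
    regardless of strand; coding order is derived from ``strand``.
    """

    tx_id: str
    chrom: str
    strand: str
    cds_intervals: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        prev_end = -1
        for start, end in self.cds_intervals:
            if start >= end:
                raise ValueError(f"empty interval {start}-{end}")
            if start < prev_end:
                raise ValueError("CDS intervals overlap or are unsorted")
            prev_end = end

    @property
    def cds_length(self) -> int:
        return sum(end - start for start, end in self.cds_intervals)

    def coding_positions(self) -> list[int]:
        """Genomic 0-based positions of CDS bases in coding (5'->3') order."""
        pos = [p for start, end in self.cds_intervals for p in range(start, end)]
        return pos if self.strand == "+" else pos[::-1]

    def cds_sequence(self, genome: Mapping[str, str]) -> str:
        chrom_seq = genome[self.chrom]
        seq = "".join(chrom_seq[s:e] for s, e in self.cds_intervals).upper()
        return seq if self.strand == "+" else revcomp(seq)

    def splice_positions(self) -> list[int]:
        """Genomic 0-based positions of the 2 canonical splice bases at
        each intron end. Gaps shorter than 4 bases are treated as a mere
        partition of contiguous CDS, not introns, so splitting an interval
        never creates splice sites."""
        sites: list[int] = []
        for (s1, e1), (s2, e2) in zip(self.cds_intervals, self.cds_intervals[1:]):
            if s2 - e1 >= 4:
                sites.extend([e1, e1 + 1, s2 - 2, s2 - 1])
        return sites


@dataclass
class GeneModel:
    gene: str
    transcripts: list[Transcript]
    chrx_nonpar: bool = False

    def __post_init__(self) -> None:
        if not self.transcripts:
            raise ValueError(f"gene {self.gene} has no transcripts")


def select_transcript(g: GeneModel) -> Transcript:
    """The transcript with maximal CDS length; ties broken by
    lexicographically smallest transcript id."""
    valid = [t for t in g.transcripts if t.cds_length % 3 == 0]
    if not valid:
        raise ValueError(f"gene {g.gene}: no transcript with CDS length divisible by 3")
    return min(valid, key=lambda t: (-t.cds_length, t.tx_id))


@dataclass(frozen=True)
class Substitution:
    """One possible single-base substitution in a transcript, in genomic
    (plus-strand) coordinates with its plus-strand trinucleotide context."""

    chrom: str
    pos: int  # 0-based genomic
    ref: str
    alt: str
    context: str
    effect: str  # one of SNV_CLASSES


def enumerate_substitutions(
    tx: Transcript, genome: Mapping[str, str]
) -> Iterator[Substitution]:
    """Yield every possible single-base substitution in the CDS plus the
    canonical splice-site bases, classified by codon effect.

    Sites whose context contains N are skipped (and logged). Stop-loss is
    classified with nonsense; substitutions destroying the start codon are
    classified as missense.
    """
    chrom_seq = genome[tx.chrom].upper()
    cds = tx.cds_sequence(genome)
    if len(cds) % 3:
        raise ValueError(f"{tx.tx_id}: CDS length {len(cds)} not divisible by 3")

    skipped = 0
    for cds_idx, gpos in enumerate(tx.coding_positions()):
        context = chrom_seq[gpos - 1:gpos + 2]
        if len(context) != 3 or "N" in context:
            skipped += 1
            continue
        ref = context[1]
        codon_i = cds_idx // 3
        offset = cds_idx % 3
        codon = cds[codon_i * 3:codon_i * 3 + 3]
        ref_aa = translate_codon(codon)
        for alt in BASES:
            if alt == ref:
                continue
            coding_alt = alt if tx.strand == "+" else revcomp(alt)
            alt_codon = codon[:offset] + coding_alt + codon[offset + 1:]
            alt_aa = translate_codon(alt_codon)
            if alt_aa == ref_aa:
                effect = "synonymous"
            elif alt_aa == "*" or ref_aa == "*":
                effect = "nonsense"  # stop-gain or stop-loss
            else:
                effect = "missense"
            yield Substitution(tx.chrom, gpos, ref, alt, context, effect)

    for gpos in tx.splice_positions():
        context = chrom_seq[gpos - 1:gpos + 2]
        if len(context) != 3 or "N" in context:
            skipped += 1
            continue
        ref = context[1]
        for alt in BASES:
            if alt == ref:
                continue
            yield Substitution(tx.chrom, gpos, ref, alt, context, "splice_site")

    if skipped:
        logger.info("%s: skipped %d sites with N/edge context", tx.tx_id, skipped)


# deleteriousness mask: True where a missense substitution is deleterious
DmisMask = Callable[[str, int, str], bool]


def _as_mask(dmis) -> tuple[DmisMask | None, float]:
    if dmis is None:
        return None, 0.0
    if callable(dmis):
        return dmis, 0.0
    if isinstance(dmis, (set, frozenset, dict)):
        table = dmis
        return (lambda chrom, pos, alt: (chrom, pos, alt) in table), 0.0
    return None, float(dmis)


@dataclass(frozen=True)
class GeneRates:
    """Per-gene, per-generation baseline mutation rates by class."""

    gene: str
    chrom: str
    r_syn: float
    r_mis: float
    r_dmis: float
    r_non: float
    r_splice: float
    chrx_nonpar: bool = False

    def __post_init__(self) -> None:
        for name in ("r_syn", "r_mis", "r_dmis", "r_non", "r_splice"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.r_dmis > self.r_mis + 1e-15:
            raise ValueError("r_dmis cannot exceed r_mis")

    @property
    def r_frameshift(self) -> float:
        return 1.1 * self.r_non

    @property
    def r_lgd(self) -> float:
        """Nonsense + canonical splice + derived frameshift rate."""
        return self.r_non + self.r_splice + self.r_frameshift

    def class_rate(self, label: str) -> float:
        return {
            "synonymous": self.r_syn,
            "missense": self.r_mis,
            "D-mis": self.r_dmis,
            "LGD": self.r_lgd,
            "nonsense": self.r_non,
            "splice_site": self.r_splice,
            "frameshift": self.r_frameshift,
            "damaging": self.r_lgd + self.r_dmis,
        }[label]


def gene_class_rates(
    g: GeneModel,
    genome: Mapping[str, str],
    rate_table: RateTable,
    dmis=None,
) -> GeneRates:
    """Accumulate class-specific rates over all substitutions of the
    selected (longest) transcript.

    ``dmis`` is either a per-site-per-alt indicator — a callable
    ``(chrom, pos0, alt) -> bool`` or a set/dict of ``(chrom, pos0, alt)``
    keys — or a scalar fraction of the missense rate mass.
    """
    tx = select_transcript(g)
    mask, fraction = _as_mask(dmis)
    totals = {"synonymous": 0.0, "missense": 0.0, "nonsense": 0.0, "splice_site": 0.0}
    dmis_mass = 0.0
    for sub in enumerate_substitutions(tx, genome):
        r = rate_table.rate(sub.context, sub.alt)
        totals[sub.effect] += r
        if sub.effect == "missense" and mask is not None and mask(sub.chrom, sub.pos, sub.alt):
            dmis_mass += r
    if mask is None:
        dmis_mass = totals["missense"] * fraction
    return GeneRates(
        gene=g.gene,
        chrom=tx.chrom,
        r_syn=totals["synonymous"],
        r_mis=totals["missense"],
        r_dmis=min(dmis_mass, totals["missense"]),
        r_non=totals["nonsense"],
        r_splice=totals["splice_site"],
        chrx_nonpar=g.chrx_nonpar,
    )


def allele_factor(cohort: CohortSpec, chrx_nonpar: bool, male_scale: float = 1.0) -> float:
    """Number of mutable allele transmissions: 2N on autosomes; on chrX
    non-PAR, 2 per female plus ``male_scale`` per male (default 1)."""
    if chrx_nonpar:
        return 2.0 * cohort.n_female + male_scale * cohort.n_male
    return 2.0 * cohort.n_trios


def expected_count(rate: float, cohort: CohortSpec, chrx_nonpar: bool = False,
                   male_scale: float = 1.0) -> float:
    """Expected number of de novo variants: per-generation rate times the
    cohort allele factor."""
    if rate < 0:
        raise ValueError("rate must be non-negative")
    return rate * allele_factor(cohort, chrx_nonpar, male_scale)


def expected_set_count(
    rates: Mapping[str, GeneRates],
    genes: Iterable[str],
    variant_class: str,
    cohort: CohortSpec,
    male_scale: float = 1.0,
) -> float:
    """Expected count of ``variant_class`` variants summed over a gene set
    (genes absent from ``rates`` contribute nothing)."""
    lam = 0.0
    for gene in genes:
        gr = rates.get(gene)
        if gr is None:
            continue
        lam += expected_count(gr.class_rate(variant_class), cohort, gr.chrx_nonpar, male_scale)
    return lam


# ---------------------------------------------------------------------------
# transcript pack I/O (fully offline alternative to GTF + FASTA)

PACK_COLUMNS = ["gene", "transcript", "chrom", "strand", "cds_intervals", "chrx_nonpar"]


def write_transcript_pack(path, genes: Iterable[GeneModel]) -> None:
    """Intervals serialized 1-based inclusive as start-end;start-end."""
    rows = []
    for g in genes:
        for t in g.transcripts:
            ivals = ";".join(f"{s + 1}-{e}" for s, e in t.cds_intervals)
            rows.append({"gene": g.gene, "transcript": t.tx_id, "chrom": t.chrom,
                         "strand": t.strand, "cds_intervals": ivals,
                         "chrx_nonpar": int(g.chrx_nonpar)})
    pd.DataFrame(rows, columns=PACK_COLUMNS).to_csv(path, sep="\t", index=False)


def read_transcript_pack(path) -> list[GeneModel]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in PACK_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"transcript pack missing column(s): {', '.join(missing)}")
    genes: dict[str, GeneModel] = {}
    for row in df.itertuples(index=False):
        ivals = tuple(
            (int(part.split("-")[0]) - 1, int(part.split("-")[1]))
            for part in row.cds_intervals.split(";")
        )
        tx = Transcript(row.transcript, row.chrom, row.strand, ivals)
        flag = bool(int(row.chrx_nonpar))
        if row.gene in genes:
            genes[row.gene].transcripts.append(tx)
        else:
            genes[row.gene] = GeneModel(row.gene, [tx], chrx_nonpar=flag)
    return list(genes.values())


def read_genome_fasta(path) -> dict[str, str]:
    from Bio import SeqIO
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_genome_fasta(path, genome: Mapping[str, str]) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(genome):
            fh.write(f">{chrom}\n")
            seq = genome[chrom]
            for i in range(0, len(seq), 80):
                fh.write(seq[i:i + 80] + "\n")


def load_gene_models_gff(gff_path, genome: Mapping[str, str],
                         chrx: str = "chrX") -> list[GeneModel]:
    """Build gene models from a GFF3/GTF via gffutils (CDS features grouped
    by transcript). Provided for real-data use; tests run on transcript
    packs."""
    import gffutils

    db = gffutils.create_db(str(gff_path), ":memory:", merge_strategy="create_unique",
                            keep_order=True)
    genes: dict[str, GeneModel] = {}
    for tx in db.features_of_type(("mRNA", "transcript")):
        cds = sorted((c.start - 1, c.end) for c in db.children(tx, featuretype="CDS"))
        if not cds:
            continue
        gene_id = tx.attributes.get("gene_id", tx.attributes.get("Parent", [tx.id]))[0]
        t = Transcript(tx.id, tx.seqid, tx.strand, tuple(cds))
        if gene_id in genes:
            genes[gene_id].transcripts.append(t)
        else:
            genes[gene_id] = GeneModel(gene_id, [t], chrx_nonpar=(tx.seqid == chrx))
    return list(genes.values())


def rates_to_frame(rates: Mapping[str, GeneRates]) -> pd.DataFrame:
    rows = []
    for gene in sorted(rates):
        gr = rates[gene]
        for cls in ("synonymous", "missense", "D-mis", "nonsense", "splice_site",
                    "frameshift", "LGD"):
            rows.append({"gene": gene, "chrom": gr.chrom, "class": cls,
                         "rate": gr.class_rate(cls), "chrx_nonpar": int(gr.chrx_nonpar)})
    return pd.DataFrame(rows)
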