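"""Context-preserving variant placement simulation for gene-set enrichment.

Observed variants are re-placed across the exome so that every simulation
conserves, per variant, the trinucleotide context, the alternate base, and
the functional/deleteriousness category. SNVs are sampled uniformly within
their key's site list (conditioned on identical context and substitution
the rate model assigns equal rates); indels carry no context and are placed
across genes proportionally to CDS length within their functional class.
"""

from __future__ import annotations

import logging
from bisect import bisect_right
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .cohort_io import DeNovoVariant, VariantClassRule, classify_variant
from .mutation_model import GeneModel, enumerate_substitutions, select_transcript

logger = logging.getLogger(__name__)

#: deleteriousness categories used as placement keys
CATEGORIES = ("synonymous", "missense", "D-mis", "LGD")


class PlacementError(RuntimeError):
    pass


def _covered(mask: Mapping[str, Sequence[tuple[int, int]]] | None,
             chrom: str, pos: int) -> bool:
    if mask is None:
        return True
    intervals = mask.get(chrom)
    if not intervals:
        return False
    i = bisect_right(intervals, (pos, float("inf"))) - 1
    return i >= 0 and intervals[i][0] <= pos < intervals[i][1]


def _category(effect: str, is_dmis: bool) -> str:
    if effect == "synonymous":
        return "synonymous"
    if effect == "missense":
        return "D-mis" if is_dmis else "missense"
    return "LGD"  # nonsense (incl. stop-loss) and canonical splice


@dataclass
class SiteIndex:
    """All placeable sites, grouped by (context, alt, category) for SNVs.

    ``genes`` is the ordered gene vocabulary; site lists store integer gene
    ids for compact sampling. ``cds_lengths`` aligns with ``genes`` and
    drives length-proportional indel placement.
    """

    genes: list[str]
    cds_lengths: np.ndarray
    snv_sites: dict[tuple[str, str, str], np.ndarray]  # key -> array of gene ids
    site_positions: dict[tuple[str, str, str], list[tuple[str, int]]] = field(
        default_factory=dict)

    @property
    def n_sites(self) -> int:
        return sum(len(v) for v in self.snv_sites.values())

    def gene_id(self, gene: str) -> int:
        return self.genes.index(gene)


def build_site_index(
    gene_models: Iterable[GeneModel],
    genome: Mapping[str, str],
    dmis=None,
    coverage_mask: Mapping[str, Sequence[tuple[int, int]]] | None = None,
) -> SiteIndex:
    """Enumerate every placeable substitution in the selected transcripts.

    ``dmis`` follows the mutation-model convention: a per-site indicator
    (callable or set of ``(chrom, pos0, alt)``) marking deleterious missense
    substitutions; scalar fractions are not meaningful here and raise.
    When a coverage mask is supplied (WES mode), sites outside it are
    excluded; WGS mode passes ``None`` and keeps all sites.
    """
    if dmis is not None and not callable(dmis) and not isinstance(dmis, (set, frozenset, dict)):
        raise ValueError("placement needs a per-site deleteriousness indicator, not a scalar")
    is_dmis = (lambda c, p, a: False) if dmis is None else (
        dmis if callable(dmis) else (lambda c, p, a: (c, p, a) in dmis))

    genes: list[str] = []
    lengths: list[int] = []
    raw: dict[tuple[str, str, str], list[int]] = {}
    positions: dict[tuple[str, str, str], list[tuple[str, int]]] = {}
    for g in gene_models:
        tx = select_transcript(g)
        gid = len(genes)
        genes.append(g.gene)
        lengths.append(tx.cds_length)
        for sub in enumerate_substitutions(tx, genome):
            if not _covered(coverage_mask, sub.chrom, sub.pos):
                continue
            key = (sub.context, sub.alt,
                   _category(sub.effect, is_dmis(sub.chrom, sub.pos, sub.alt)))
            raw.setdefault(key, []).append(gid)
            positions.setdefault(key, []).append((sub.chrom, sub.pos))

    index = SiteIndex(
        genes=genes,
        cds_lengths=np.asarray(lengths, dtype=float),
        snv_sites={k: np.asarray(v, dtype=np.int64) for k, v in raw.items()},
        site_positions=positions,
    )
    if index.n_sites == 0:
        logger.warning("site index is empty (all sites masked out?)")
    return index


def variant_key(v: DeNovoVariant, rule: VariantClassRule) -> tuple:
    """Placement key of an observed variant: (context, alt, category) for
    SNVs, ("indel", class) for indels."""
    label = classify_variant(v, rule)
    if v.is_snv:
        if v.trinucleotide_context is None:
            raise PlacementError(f"SNV at {v.chrom}:{v.pos} lacks a trinucleotide context")
        if label == "unscored":
            raise PlacementError(f"missense variant at {v.chrom}:{v.pos} lacks a CADD score")
        cat = label if label in CATEGORIES else "LGD"
        return (v.trinucleotide_context, v.alt_allele, cat)
    return ("indel", "inframe" if v.consequence == "inframe" else "frameshift")


@dataclass
class Placements:
    """Simulated placements: per-simulation gene ids for every variant,
    grouped by key (so key-count conservation holds by construction and is
    assertable per simulation)."""

    index: SiteIndex
    n_sims: int
    observed_keys: dict[tuple, int]
    gene_matrix: np.ndarray  # shape (n_sims, n_variants), integer gene ids
    key_slices: dict[tuple, tuple[int, int]]  # key -> column range in gene_matrix
    seed: int

    def simulated_key_counts(self, sim: int) -> dict[tuple, int]:
        """Per-key variant counts in one simulation, validated against the
        index: every SNV placement must come from its key's own site list.
        Exposed so key-count conservation is assertable, not assumed."""
        counts: dict[tuple, int] = {}
        for key, (start, stop) in self.key_slices.items():
            drawn = self.gene_matrix[sim, start:stop]
            if key[0] != "indel":
                allowed = self.index.snv_sites[key]
                if not np.isin(drawn, allowed).all():
                    raise PlacementError(f"simulation {sim}: placement outside key {key}")
            counts[key] = stop - start
        return counts


def simulate_placements(
    observed: Sequence[DeNovoVariant],
    index: SiteIndex,
    n_sims: int,
    seed: int,
    rule: VariantClassRule = VariantClassRule(),
) -> Placements:
    """Re-place the observed variants ``n_sims`` times.

    Every simulation holds the per-key variant counts exactly equal to the
    observed counts; within a key, SNV sites are sampled uniformly and
    indels are placed gene-wise proportional to CDS length. Reproducible
    for a fixed seed and independent of site-list ordering (site lists are
    sorted before sampling).
    """
    rng = np.random.default_rng(seed)
    keys: dict[tuple, int] = {}
    for v in observed:
        k = variant_key(v, rule)
        keys[k] = keys.get(k, 0) + 1

    columns: list[np.ndarray] = []
    key_slices: dict[tuple, tuple[int, int]] = {}
    offset = 0
    total_len = float(index.cds_lengths.sum())
    for key in sorted(keys, key=repr):
        count = keys[key]
        key_slices[key] = (offset, offset + count)
        offset += count
        if key[0] == "indel":
            if total_len <= 0:
                raise PlacementError("no CDS length mass to place indels")
            probs = index.cds_lengths / total_len
            draws = rng.choice(len(index.genes), size=(n_sims, count), p=probs)
        else:
            sites = index.snv_sites.get(key)
            if sites is None or len(sites) == 0:
                raise PlacementError(f"no placeable site for key {key}")
            sites = np.sort(sites)
            draws = sites[rng.integers(0, len(sites), size=(n_sims, count))]
        columns.append(draws)

    gene_matrix = (np.concatenate(columns, axis=1) if columns
                   else np.empty((n_sims, 0), dtype=np.int64))
    return Placements(index=index, n_sims=n_sims, observed_keys=keys,
                      gene_matrix=gene_matrix, key_slices=key_slices, seed=seed)


@dataclass(frozen=True)
class PlacementNull:
    gene_set: str
    statistic: str
    observed: float
    expected: float
    fold: float
    p_empirical: float
    n_sims: int
    seed: int


def _genes_of(observed: Sequence[DeNovoVariant]) -> list[str]:
    return [v.gene for v in observed]


def empirical_enrichment(
    placements: Placements,
    gene_set: Iterable[str],
    observed: Sequence[DeNovoVariant],
    statistic: str = "genes_hit",
    set_name: str = "set",
) -> PlacementNull:
    """Empirical enrichment of a gene set against the placement null.

    ``statistic`` is ``genes_hit`` (distinct set genes carrying at least one
    placed variant; default, matching how overlapping genes are counted) or
    ``variants_in_set``. The empirical p uses the add-one estimator with the
    >= tie convention: p = (1 + #{sims >= observed}) / (1 + n_sims).
    """
    members = set(gene_set)
    gene_names = placements.index.genes
    member_ids = np.asarray([i for i, g in enumerate(gene_names) if g in members],
                            dtype=np.int64)
    if len(member_ids) == 0:
        logger.warning("gene set %s shares no genes with the site index", set_name)
        return PlacementNull(set_name, statistic, 0.0, 0.0, float("nan"), 1.0,
                             placements.n_sims, placements.seed)

    in_set = np.isin(placements.gene_matrix, member_ids)
    obs_genes = [g for g in _genes_of(observed) if g in members]
    if statistic == "variants_in_set":
        sims = in_set.sum(axis=1)
        obs_stat = len(obs_genes)
    elif statistic == "genes_hit":
        masked = np.where(in_set, placements.gene_matrix, -1)
        sims = np.asarray([len(np.unique(row[row >= 0])) for row in masked])
        obs_stat = len(set(obs_genes))
    else:
        raise ValueError(f"unknown statistic {statistic!r}")

    n = placements.n_sims
    p = (1 + int((sims >= obs_stat).sum())) / (1 + n)
    expected = float(sims.mean())
    fold = obs_stat / expected if expected > 0 else float("nan")
    return PlacementNull(set_name, statistic, float(obs_stat), expected, fold, p,
                         n, placements.seed)
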