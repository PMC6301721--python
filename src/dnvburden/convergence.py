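"""Expression-stratified burden, the target-gene expression-shift test, and
the functional enrichment-map builder."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .cohort_io import CohortSpec, DeNovoVariant, VariantClassRule
from .burden_stats import BurdenResult, stratified_burden
from .mutation_model import GeneRates

logger = logging.getLogger(__name__)


@dataclass
class ExpressionRanks:
    """Gene -> rank percentile in a tissue; smaller percentile = higher
    expression. Tied expression values share a percentile."""

    percentiles: dict[str, float]
    tissue: str = ""
    stage: str = ""
    n_unmapped: int = 0

    def quartile(self, gene: str) -> str:
        """Quartile label Q1 (top expression) .. Q4; ties on a boundary are
        assigned to the lower-numbered (higher-expression) quartile."""
        pct = self.percentiles.get(gene)
        if pct is None:
            return "unranked"
        for q, bound in enumerate((0.25, 0.5, 0.75, 1.0), start=1):
            if pct <= bound:
                return f"Q{q}"
        return "Q4"


def expression_rank(
    matrix: pd.DataFrame,
    ortholog_map: Mapping[str, Iterable[str]] | None = None,
    tissue: str = "",
    stage: str = "",
) -> ExpressionRanks:
    """Convert a genes x samples expression matrix to rank percentiles.

    Per-gene summary expression is the mean over samples. With an ortholog
    map (query gene -> source genes in the matrix), a query gene mapping to
    several source genes is assigned the highest expression level before
    ranking; query genes whose sources are all absent are excluded and
    tallied. Percentiles use min-ranking on descending expression so the
    highest-expressed gene gets the smallest percentile and ties share one.
    """
    summary = matrix.mean(axis=1)
    n_unmapped = 0
    if ortholog_map is not None:
        mapped = {}
        for query, sources in ortholog_map.items():
            values = [summary[s] for s in sources if s in summary.index]
            if not values:
                n_unmapped += 1
                continue
            mapped[query] = max(values)
        summary = pd.Series(mapped)
        if n_unmapped:
            logger.info("%d genes had no ortholog in the expression matrix", n_unmapped)

    ranks = summary.rank(method="min", ascending=False)
    pct = ranks / len(summary)
    return ExpressionRanks(percentiles=pct.to_dict(), tissue=tissue, stage=stage,
                           n_unmapped=n_unmapped)


def read_ortholog_map(path) -> dict[str, list[str]]:
    """2-column TSV: query gene, source (e.g. mouse) gene; many-to-many."""
    df = pd.read_csv(path, sep="\t", header=None, names=["query", "source"],
                     dtype=str, comment="#")
    out: dict[str, list[str]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(row.query, []).append(row.source)
    return out


def quartile_burden(
    variants: Sequence[DeNovoVariant],
    ranks: ExpressionRanks,
    rates: Mapping[str, GeneRates],
    cohort: CohortSpec,
    rule: VariantClassRule = VariantClassRule(),
    classes: Sequence[str] = ("LGD", "D-mis"),
    strata: Sequence[str] | None = None,
    male_scale: float = 1.0,
) -> tuple[list[BurdenResult], dict]:
    """Burden per expression quartile x class x stratum.

    Genes without a rank form an explicit fifth "unranked" cell rather than
    being dropped.
    """
    quartiles: dict[str, set[str]] = {f"Q{i}": set() for i in range(1, 5)}
    quartiles["unranked"] = set()
    for gene in rates:
        quartiles[ranks.quartile(gene)].add(gene)
    gene_sets = {name: members for name, members in quartiles.items() if members}
    for name in set(quartiles) - set(gene_sets):
        logger.info("expression quartile %s holds no rated genes", name)
    return stratified_burden(variants, cohort, rates, gene_sets, rule,
                             classes=classes, strata=strata, male_scale=male_scale)


@dataclass(frozen=True)
class ShiftTestResult:
    target_mean_z: float
    background_mean_z: float
    ks_statistic: float
    p_value: float
    direction: int  # sign of (target mean - background mean)
    n_target: int
    n_background: int
    n_excluded_constant: int


def target_shift_test(
    expr_matrix: pd.DataFrame,
    carrier_samples: Sequence[str],
    target_genes: Iterable[str],
) -> ShiftTestResult:
    """Test whether target genes' expression is systematically shifted in
    carrier samples.

    Each gene is standardized to z-scores across all samples; each gene's
    mean z over the carrier samples is its summary value. A two-sample
    Kolmogorov-Smirnov test compares these values between target genes and
    all other genes; direction is the sign of the difference in means.
    Constant-expression genes have undefined z and are excluded (tallied).
    """
    carriers = [s for s in carrier_samples if s in expr_matrix.columns]
    if not carriers:
        raise ValueError("no carrier samples present in the expression matrix")
    targets = {g for g in target_genes if g in expr_matrix.index}
    if not targets:
        raise ValueError("target set does not intersect the matrix genes")

    mu = expr_matrix.mean(axis=1)
    sd = expr_matrix.std(axis=1, ddof=1)
    keep = sd > 0
    n_excluded = int((~keep).sum())
    if n_excluded:
        logger.info("excluded %d constant-expression genes", n_excluded)
    z = expr_matrix.loc[keep].sub(mu[keep], axis=0).div(sd[keep], axis=0)
    carrier_mean_z = z[carriers].mean(axis=1)

    is_target = carrier_mean_z.index.isin(targets)
    target_vals = carrier_mean_z[is_target].to_numpy()
    background_vals = carrier_mean_z[~is_target].to_numpy()
    if len(target_vals) == 0 or len(background_vals) == 0:
        raise ValueError("target or background group empty after filtering")

    ks = stats.ks_2samp(target_vals, background_vals)
    diff = float(target_vals.mean() - background_vals.mean())
    return ShiftTestResult(
        target_mean_z=float(target_vals.mean()),
        background_mean_z=float(background_vals.mean()),
        ks_statistic=float(ks.statistic),
        p_value=float(ks.pvalue),
        direction=int(np.sign(diff)),
        n_target=len(target_vals),
        n_background=len(background_vals),
        n_excluded_constant=n_excluded,
    )


# ---------------------------------------------------------------------------
# enrichment map


def set_similarity(a: set, b: set) -> float:
    """Average of the Jaccard coefficient |A∩B|/|A∪B| and the overlap
    coefficient |A∩B|/min(|A|,|B|)."""
    inter = len(a & b)
    if inter == 0:
        return 0.0
    jaccard = inter / len(a | b)
    overlap = inter / min(len(a), len(b))
    return (jaccard + overlap) / 2


def hypergeom_enrichment_p(n_hits: int, set_size: int, query_size: int,
                           universe_size: int) -> float:
    """Over-representation p: P(X >= n_hits) drawing ``query_size`` genes
    without replacement from a universe containing ``set_size`` successes."""
    if n_hits == 0:
        return 1.0
    return float(stats.hypergeom.sf(n_hits - 1, universe_size, set_size, query_size))


def build_enrichment_map(
    query_genes: Iterable[str],
    annotation_sets: Mapping[str, Iterable[str]],
    universe: Iterable[str],
    fdr: float = 0.1,
    size_band: tuple[int, int] = (25, 750),
    sim_cutoff: float = 0.375,
) -> nx.Graph:
    """Hypergeometric over-representation of ``query_genes`` in each
    annotation set, Benjamini-Hochberg FDR, and a similarity network over
    the surviving sets.

    Sets are restricted to the universe; sets annotating fewer than
    ``size_band[0]`` or more than ``size_band[1]`` universe genes are
    discarded before testing. Nodes carry size/p/q attributes; edges link
    set pairs with similarity >= ``sim_cutoff``.
    """
    universe = set(universe)
    query = set(query_genes)
    offenders = query - universe
    if offenders:
        raise ValueError("query genes missing from universe: "
                         + ", ".join(sorted(offenders)[:10]))

    tested: list[tuple[str, set, int, float]] = []
    for name, members in annotation_sets.items():
        in_universe = set(members) & universe
        if not (size_band[0] <= len(in_universe) <= size_band[1]):
            continue
        hits = len(in_universe & query)
        p = hypergeom_enrichment_p(hits, len(in_universe), len(query), len(universe))
        tested.append((name, in_universe, hits, p))

    graph = nx.Graph()
    graph.graph.update(fdr=fdr, size_band=f"{size_band[0]}-{size_band[1]}",
                       sim_cutoff=sim_cutoff,
                       n_query=len(query), n_universe=len(universe))
    if not tested:
        return graph

    pvals = [t[3] for t in tested]
    reject, qvals, _, _ = multipletests(pvals, alpha=fdr, method="fdr_bh")
    surviving = []
    for (name, members, hits, p), q, keep in zip(tested, qvals, reject):
        if keep:
            graph.add_node(name, size=len(members), n_hits=hits,
                           p_value=p, q_value=float(q))
            surviving.append((name, members))

    surviving.sort()  # node/edge construction independent of input order
    for i, (name_a, a) in enumerate(surviving):
        for name_b, b in surviving[i + 1:]:
            sim = set_similarity(a, b)
            if sim >= sim_cutoff:
                graph.add_edge(name_a, name_b, similarity=sim)
    return graph


def write_enrichment_map(graph: nx.Graph, graphml_path, edges_path) -> None:
    nx.write_graphml(graph, graphml_path)
    rows = [{"set_a": a, "set_b": b, "similarity": d["similarity"]}
            for a, b, d in sorted(graph.edges(data=True))]
    pd.DataFrame(rows, columns=["set_a", "set_b", "similarity"]).to_csv(
        edges_path, sep="\t", index=False)
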