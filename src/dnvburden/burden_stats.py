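"""One-sided Poisson burden tests, fold enrichment with exact confidence
intervals, and the per-gene recurrence test with genome-wide Bonferroni
correction."""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy import stats

from .cohort_io import CohortSpec, DeNovoVariant, VariantClassRule, classify_variant
from .mutation_model import GeneRates, expected_count, expected_set_count

logger = logging.getLogger(__name__)

#: burden cells computed by default, in report order
BURDEN_CLASSES = ("synonymous", "missense", "D-mis", "LGD")


def poisson_upper_tail(observed: int, expected: float) -> float:
    """Inclusive one-sided Poisson p-value P(X >= observed | expected)."""
    if expected <= 0:
        raise ValueError("expected count must be positive")
    if observed < 0:
        raise ValueError("observed count must be non-negative")
    if observed == 0:
        return 1.0
    return float(stats.poisson.sf(observed - 1, expected))


def poisson_count_ci(observed: int, conf: float = 0.95) -> tuple[float, float]:
    """Exact (Garwood) confidence interval for a Poisson count."""
    alpha = 1.0 - conf
    lower = 0.0 if observed == 0 else stats.chi2.ppf(alpha / 2, 2 * observed) / 2
    upper = stats.chi2.ppf(1 - alpha / 2, 2 * observed + 2) / 2
    return float(lower), float(upper)


@dataclass(frozen=True)
class BurdenResult:
    """One (stratum x gene set x variant class) burden cell."""

    stratum: str
    gene_set: str
    variant_class: str
    observed: int
    expected: float
    fold: float
    p_value: float
    ci_low: float
    ci_high: float
    per_case: float
    n_trios: int

    def as_row(self) -> dict:
        return {
            "stratum": self.stratum, "gene_set": self.gene_set,
            "class": self.variant_class, "observed": self.observed,
            "expected": self.expected, "fold_enrichment": self.fold,
            "p_value": self.p_value, "ci_low": self.ci_low, "ci_high": self.ci_high,
            "per_case": self.per_case, "n_trios": self.n_trios,
        }


def poisson_burden(
    observed: int,
    expected: float,
    n_trios: int = 0,
    *,
    stratum: str = "all",
    gene_set: str = "all",
    variant_class: str = "",
    conf: float = 0.95,
) -> BurdenResult:
    """One-sided Poisson burden test for a single cell.

    Fold enrichment is observed/expected; the FE confidence interval is the
    exact Poisson interval for the observed count divided by the
    expectation.
    """
    p = poisson_upper_tail(observed, expected)
    lo, hi = poisson_count_ci(observed, conf)
    return BurdenResult(
        stratum=stratum, gene_set=gene_set, variant_class=variant_class,
        observed=observed, expected=expected, fold=observed / expected,
        p_value=p, ci_low=lo / expected, ci_high=hi / expected,
        per_case=(observed / n_trios) if n_trios else float("nan"),
        n_trios=n_trios,
    )


def _observed_in_class(label: str, variant_class: str) -> bool:
    # the missense cell counts all missense including the D-mis subset
    if variant_class == "missense":
        return label in ("missense", "D-mis")
    if variant_class == "damaging":
        return label in ("LGD", "D-mis")
    return label == variant_class


def stratified_burden(
    variants: Sequence[DeNovoVariant],
    cohort: CohortSpec,
    rates: Mapping[str, GeneRates],
    gene_sets: Mapping[str, Iterable[str]] | None = None,
    rule: VariantClassRule = VariantClassRule(),
    classes: Sequence[str] = BURDEN_CLASSES,
    strata: Sequence[str] | None = None,
    male_scale: float = 1.0,
) -> tuple[list[BurdenResult], dict]:
    """Burden table over (stratum x gene set x class) cells.

    Strata default to "all" plus each phenotype group present in the
    cohort. Gene sets default to all rated genes; variants in genes
    without a baseline rate are excluded from both observed and expected
    counts and reported in the reconciliation dict.
    """
    if gene_sets is None:
        gene_sets = {"all": set(rates)}
    gene_sets = {name: set(members) for name, members in gene_sets.items()}

    if strata is None:
        strata = ["all", *cohort.groups()]

    unrated = Counter(v.gene for v in variants if v.gene not in rates)
    unscored = sum(1 for v in variants if classify_variant(v, rule) == "unscored")
    reconciliation = {
        "unrated_genes": dict(unrated),
        "n_variants_in_unrated_genes": sum(unrated.values()),
        "n_unscored_missense": unscored,
    }
    if unrated:
        logger.warning("%d variants in %d genes without baseline rates excluded",
                       sum(unrated.values()), len(unrated))

    labelled = [(v, classify_variant(v, rule)) for v in variants if v.gene in rates]

    results: list[BurdenResult] = []
    for stratum in strata:
        if stratum == "all":
            sub_cohort = cohort
        else:
            probands = [p for p, (_, g) in cohort.strata.items() if g == stratum]
            sub_cohort = cohort.subset(probands)
        if sub_cohort.n_trios == 0:
            raise ValueError(f"stratum {stratum!r} has no trios")
        in_stratum = {p for p in sub_cohort.strata}
        for set_name, members in gene_sets.items():
            set_genes = members & set(rates)
            for cls in classes:
                obs = sum(
                    1 for v, label in labelled
                    if v.proband_id in in_stratum and v.gene in set_genes
                    and _observed_in_class(label, cls)
                )
                lam = expected_set_count(rates, set_genes, cls, sub_cohort, male_scale)
                if lam <= 0:
                    # sentinel cell: zero model mass, never silently dropped
                    logger.warning("cell (%s, %s, %s): zero expectation",
                                   stratum, set_name, cls)
                    results.append(BurdenResult(
                        stratum=stratum, gene_set=set_name, variant_class=cls,
                        observed=obs, expected=0.0, fold=float("nan"),
                        p_value=1.0 if obs == 0 else float("nan"),
                        ci_low=float("nan"), ci_high=float("nan"),
                        per_case=obs / sub_cohort.n_trios, n_trios=sub_cohort.n_trios,
                    ))
                    continue
                results.append(poisson_burden(
                    obs, lam, sub_cohort.n_trios,
                    stratum=stratum, gene_set=set_name, variant_class=cls,
                ))
    return results, reconciliation


def constrained_gene_sets(rates: Mapping[str, GeneRates], pli: Mapping[str, float],
                          threshold: float = 0.5) -> dict[str, set[str]]:
    """The paper's three-way partition: all genes, constrained (pLI >=
    threshold), and the remainder."""
    allg = set(rates)
    constrained = {g for g in allg if pli.get(g, 0.0) >= threshold}
    return {"all": allg, "constrained": constrained, "other": allg - constrained}


@dataclass(frozen=True)
class GeneTestResult:
    gene: str
    counts: Mapping[str, int]
    n_damaging: int
    expected_damaging: float
    p_value: float
    significant: bool
    threshold: float
    zero_expectation: bool = False


def per_gene_recurrence_test(
    gene: str,
    variants: Sequence[DeNovoVariant],
    rates: Mapping[str, GeneRates],
    cohort: CohortSpec,
    rule: VariantClassRule = VariantClassRule(),
    alpha: float = 0.01,
    n_genes: int = 20000,
    male_scale: float = 1.0,
) -> GeneTestResult:
    """One-sided Poisson recurrence test of damaging (LGD + D-mis) variants
    in one gene against its cohort-scaled baseline expectation; significance
    at the Bonferroni threshold alpha / n_genes."""
    labels = Counter(classify_variant(v, rule) for v in variants if v.gene == gene)
    n_dam = labels.get("LGD", 0) + labels.get("D-mis", 0)
    threshold = alpha / n_genes

    gr = rates.get(gene)
    lam = 0.0 if gr is None else expected_count(
        gr.class_rate("damaging"), cohort, gr.chrx_nonpar, male_scale)

    if lam <= 0:
        if n_dam > 0:
            logger.warning("gene %s: observed damaging variants but zero model "
                           "expectation; model coverage gap", gene)
            return GeneTestResult(gene, dict(labels), n_dam, 0.0, 5e-324, True,
                                  threshold, zero_expectation=True)
        return GeneTestResult(gene, dict(labels), 0, 0.0, 1.0, False, threshold,
                              zero_expectation=True)

    p = poisson_upper_tail(n_dam, lam)
    return GeneTestResult(gene, dict(labels), n_dam, lam, p, p < threshold, threshold)


def recurrent_gene_scan(
    variants: Sequence[DeNovoVariant],
    rule: VariantClassRule = VariantClassRule(),
    min_hits: int = 2,
    classes: frozenset[str] = frozenset({"LGD", "missense"}),
    rates: Mapping[str, GeneRates] | None = None,
    cohort: CohortSpec | None = None,
    pli: Mapping[str, float] | None = None,
    alpha: float = 0.01,
    n_genes: int = 20000,
) -> pd.DataFrame:
    """Rank genes hit by at least ``min_hits`` qualifying variants.

    ``classes`` is interpreted on consequence families: "missense" admits
    both plain missense and D-mis labels. Synonymous-only recurrences never
    qualify. When rates and a cohort are supplied, each gene is annotated
    with its recurrence-test p-value.
    """
    hits: Counter[str] = Counter()
    for v in variants:
        label = classify_variant(v, rule)
        family = "missense" if label in ("missense", "D-mis") else label
        if family in classes:
            hits[v.gene] += 1

    rows = []
    for gene, n in hits.items():
        if n < min_hits:
            continue
        row: dict = {"gene": gene, "n_hits": n}
        if pli is not None:
            row["pli"] = pli.get(gene, float("nan"))
        if rates is not None and cohort is not None:
            res = per_gene_recurrence_test(gene, variants, rates, cohort, rule,
                                           alpha=alpha, n_genes=n_genes)
            row["p_value"] = res.p_value
            row["significant"] = res.significant
        rows.append(row)
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    sort_cols = ["p_value", "gene"] if "p_value" in df.columns else ["n_hits", "gene"]
    ascending = [True, True] if "p_value" in df.columns else [False, True]
    return df.sort_values(sort_cols, ascending=ascending, ignore_index=True)


def burden_frame(results: Iterable[BurdenResult]) -> pd.DataFrame:
    """Tidy table with a fixed column order (machine precision retained)."""
    return pd.DataFrame([r.as_row() for r in results], columns=[
        "stratum", "gene_set", "class", "observed", "expected",
        "fold_enrichment", "p_value", "ci_low", "ci_high", "per_case", "n_trios",
    ])
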