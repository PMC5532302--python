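"""Downstream biomarker and annotation statistics.

Covers the post-pipeline analyses: hypergeometric over-representation of
module genes in annotation sets, interaction-network degree summaries,
outlier-based expression dichotomization against a normal-tissue
reference, Kaplan-Meier / log-rank survival comparison, Mann-Whitney
rank-sum comparison, and Pfaffl efficiency-corrected qPCR
quantification.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats as sps

from .datamodel import InteractionTable, ValidationError
from .differential import bh_fdr


@dataclasses.dataclass
class EnrichmentResult:
    """Hypergeometric over-representation of one gene set in one module."""

    module_id: str
    set_id: str
    overlap: int
    module_size: int
    set_size: int
    universe_size: int
    p_value: float
    q_value: float = float("nan")


def ora_test(
    module_genes: set[str],
    gene_set: set[str],
    universe: set[str],
    module_id: str = "",
    set_id: str = "",
) -> EnrichmentResult:
    """One-sided hypergeometric upper tail P(X >= overlap).

    ``module_genes`` and ``gene_set`` must be subsets of ``universe``.
    BH correction across many (module, set) pairs is the caller's job
    (see :func:`enrich_modules`).
    """
    if not universe:
        raise ValidationError("empty universe")
    if not module_genes <= universe or not gene_set <= universe:
        raise ValidationError("module and gene set must be subsets of the universe")
    N, K, n = len(universe), len(gene_set), len(module_genes)
    k = len(module_genes & gene_set)
    p = float(sps.hypergeom.sf(k - 1, N, K, n))  # P(X >= k)
    return EnrichmentResult(module_id, set_id, k, n, K, N, min(p, 1.0))


def enrich_modules(
    modules: Mapping[str, set[str]],
    collection: "Mapping[str, tuple[str, frozenset[str]]] | object",
    universe: set[str],
) -> list[EnrichmentResult]:
    """ORA of every module against every gene set, BH-corrected jointly."""
    sets = getattr(collection, "sets", collection)
    results = []
    for mid, genes in modules.items():
        for sid, (_, members) in sets.items():
            results.append(ora_test(genes & universe, set(members) & universe, universe, mid, sid))
    if results:
        qs = bh_fdr(np.array([r.p_value for r in results]))
        for r, q in zip(results, qs):
            r.q_value = float(q)
    return results


def ppi_degree(nodes: Iterable[str], edges: InteractionTable | Iterable[tuple[str, str]]) -> dict[str, int]:
    """Degree of each requested node in an undirected interaction graph."""
    g = nx.Graph()
    nodes = list(nodes)
    g.add_nodes_from(nodes)
    edge_iter = edges.edges if isinstance(edges, InteractionTable) else edges
    for e in edge_iter:
        a, b = sorted(e)
        g.add_edge(a, b)
    return {n: int(g.degree(n)) for n in nodes}


def dichotomize_by_outlier(
    tumor_expr: pd.Series,
    reference_expr: Sequence[float],
) -> pd.Series:
    """Label tumor samples high/low/neither by Tukey fences on the
    normal-tissue reference distribution.

    Fences are Q1 - 1.5*IQR and Q3 + 1.5*IQR of the reference.  With a
    constant reference the fences collapse onto that value and any
    deviation from it is an outlier.
    """
    ref = np.asarray(reference_expr, dtype=float)
    if len(ref) < 3:
        raise ValidationError("need >=3 reference values")
    q1, q3 = np.percentile(ref, [25, 75])
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    labels = pd.Series("neither", index=tumor_expr.index, dtype=object)
    labels[tumor_expr > hi] = "high"
    labels[tumor_expr < lo] = "low"
    return labels


@dataclasses.dataclass
class SurvivalComparison:
    """Log-rank comparison of two survival groups with KM curves."""

    groups: pd.Series               # sample -> group label
    logrank_statistic: float
    p_value: float
    km_curves: dict[str, pd.DataFrame]  # label -> (time, survival) step function


def km_curve(times: np.ndarray, events: np.ndarray) -> pd.DataFrame:
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    sf = kmf.survival_function_
    return pd.DataFrame({"time": sf.index.to_numpy(float),
                         "survival": sf.iloc[:, 0].to_numpy(float)})


def logrank_test(
    times: Sequence[float],
    events: Sequence[int],
    groups: Sequence,
) -> SurvivalComparison:
    """Two-group log-rank test with Kaplan-Meier curves.

    The statistic is the usual chi-square U^2/V with one degree of
    freedom, where U sums observed-minus-expected deaths in the first
    group over distinct event times and V the hypergeometric variances.
    With no events at all the statistic is 0 and P = 1.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    groups = pd.Series(list(groups))
    labels = sorted(groups.unique())
    if len(labels) != 2:
        raise ValidationError(f"need exactly two non-empty groups, got {labels}")
    mask = (groups == labels[0]).to_numpy()
    if events.sum() == 0:
        stat, p = 0.0, 1.0
    else:
        res = _ll_logrank(times[mask], times[~mask], events[mask], events[~mask])
        stat, p = float(res.test_statistic), float(res.p_value)
    curves = {
        str(lab): km_curve(times[groups.to_numpy() == lab], events[groups.to_numpy() == lab])
        for lab in labels
    }
    return SurvivalComparison(groups, stat, p, curves)


def mannwhitney(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Mann-Whitney U (exact rank-sum U statistic) with a two-sided
    normal-approximation p-value, tie-corrected."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    if len(x) == 0 or len(y) == 0:
        raise ValidationError("both samples must be non-empty")
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue)


def pfaffl_ratio(e_target: float, dct_target: float, e_ref: float, dct_ref: float) -> float:
    """Pfaffl efficiency-corrected relative expression ratio.

    ratio = E_target ** dCt_target / E_ref ** dCt_ref, with dCt = control
    minus sample cycle threshold and amplification efficiencies E in
    [1, 2] (2 = perfect doubling per cycle).
    """
    if e_target <= 0 or e_ref <= 0:
        raise ValidationError("amplification efficiencies must be > 0")
    return float(e_target**dct_target / e_ref**dct_ref)
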