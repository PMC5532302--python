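"""End-to-end integrative analysis: differential calls -> evidence ->
driver/passenger split -> module discovery -> regulator assignment ->
passenger-enrichment filter."""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd

from .datamodel import OmicsMatrix, PipelineConfig, TargetMap
from .differential import (
    DifferentialRecord,
    diff_cna,
    diff_expression,
    diff_methylation,
    diff_mirna,
)
from .modules import GibbsParams, ModuleSet, filter_modules, gibbs_cluster
from .regulators import Association, passenger_filter, rank_top, score_all
from .scoring import ScoredGene, build_evidence, score_genes, select_candidates

logger = logging.getLogger("omidriver")


@dataclasses.dataclass
class PipelineResult:
    """Everything the integrative pipeline produced."""

    differential: dict[str, list[DifferentialRecord]]
    scored: list[ScoredGene]
    drivers: set[str]
    passengers: set[str]
    module_set: ModuleSet
    associations_ranked: list[Association]
    associations_final: list[Association]

    @property
    def final_pairs(self) -> set[tuple[str, str]]:
        return {(a.regulator_id, a.module_id) for a in self.associations_final}


def module_profiles(expr: OmicsMatrix, module_set: ModuleSet) -> dict[str, pd.Series]:
    """Per-module mean profile of standardized member genes over tumors."""
    tumors = expr.tumor_samples
    vals = expr.values.loc[:, tumors]
    mu = vals.mean(axis=1)
    sd = vals.std(axis=1).replace(0.0, 1.0)
    z = vals.sub(mu, axis=0).div(sd, axis=0)
    out = {}
    for mid, members in module_set.modules().items():
        members = sorted(members & set(z.index))
        if members:
            out[mid] = z.loc[members].mean(axis=0)
    return out


def run_integration(
    matrices: dict[str, OmicsMatrix],
    targets: TargetMap,
    config: PipelineConfig | None = None,
    top_k: int | None = None,
) -> PipelineResult:
    """Run the full integrative analysis on a four-layer cohort.

    ``top_k`` overrides the top-percent association cut with an absolute
    count (useful at small cohort scale, where 1% of all pairs would be
    fewer associations than there are true regulators).
    """
    cfg = config or PipelineConfig()
    de = diff_expression(matrices["expression"], cfg.ge_fc_threshold, cfg.ge_ci_level)
    cna = diff_cna(matrices["cna"], cfg.cna_gain_threshold, cfg.cna_loss_threshold,
                   cfg.cna_min_fraction)
    me = diff_methylation(matrices["methylation"], cfg.me_alpha)
    mi = diff_mirna(matrices["mirna"], cfg.mirna_p_threshold, cfg.mirna_fdr_threshold)
    differential = {"expression": de, "cna": cna, "methylation": me, "mirna": mi}

    evidence = build_evidence(de, cna, me, mi, targets)
    scored = score_genes(evidence, alpha_bonus=cfg.alpha_bonus, freq_threshold=cfg.freq_threshold)
    if scored:
        drivers, passengers = select_candidates(scored, cfg.score_cutoff, cfg.min_other_layers)
    else:
        drivers, passengers = set(), set()

    de_genes = sorted(r.feature_id for r in de if r.significant)
    expr = matrices["expression"]
    sub = OmicsMatrix(layer=expr.layer,
                      values=expr.values.loc[de_genes],
                      groups=expr.groups.copy())
    params = GibbsParams(n_iter=cfg.gibbs_n_iter, burn_in=cfg.gibbs_burn_in,
                         concentration=cfg.gibbs_concentration,
                         min_module_size=cfg.min_module_size, seed=cfg.seed)
    modules_raw = gibbs_cluster(sub, params)
    module_set = filter_modules(modules_raw, cfg.min_module_size)

    if not drivers or not module_set.sizes:
        logger.warning("no drivers (%d) or no modules (%d): skipping regulator assignment",
                       len(drivers), len(module_set.sizes))
        return PipelineResult(differential, scored, drivers, passengers, module_set, [], [])

    profiles = module_profiles(expr, module_set)
    tumors = expr.tumor_samples
    pool = {g: expr.values.loc[g, tumors] for g in sorted(drivers)}
    associations = score_all(profiles, pool, cfg.tree_min_leaf, cfg.tree_max_depth)
    ranked = rank_top(associations, top_percent=cfg.top_percent, top_k=top_k)
    final = passenger_filter(ranked, passengers, module_set.modules(),
                             cfg.min_passenger_fraction)
    if cfg.association_cutoff is not None:
        final = [a for a in final if a.score >= cfg.association_cutoff]
    return PipelineResult(differential, scored, drivers, passengers, module_set, ranked, final)
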