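"""Integrative driver-candidate scoring.

A gene enters scoring only if it is differentially expressed.  Its
expression change is then compared with the other three layers:

* copy number is *concordant* if it has the same sign as the expression
  change (amplified & up, deleted & down);
* methylation is concordant if it has the opposite sign (hypomethylated
  & up, hypermethylated & down);
* miRNA regulation is concordant if the aggregated effect of its
  significant targeting miRNAs opposes the expression change.

The integrative score is the sum of the absolute expression effect and
the absolute effects of the concordant layers, multiplied by a frequency
bonus alpha (2 when the gene's copy-number alteration is seen in at
least 20% of tumors, else 1) and an agreement bonus beta = 1 + number of
concordant non-expression layers (so 4 when all three agree).  Discordant
layers contribute nothing.  Genes supported by fewer than two
non-expression layers are ineligible; among eligible genes a score
cutoff (numeric, or the midpoint between the lowest and highest score)
separates driver from passenger candidates.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from typing import Iterable, Mapping

import numpy as np

from .datamodel import Layer, TargetMap, ValidationError
from .differential import DifferentialRecord

logger = logging.getLogger("omidriver")


@dataclasses.dataclass
class GeneEvidence:
    """Per-gene aggregated effects across the four molecular layers.

    Absent layers are ``None`` — never silently 0.0 (except in packaged
    table fixtures, where a printed 0 encodes absence and is converted on
    load).
    """

    gene_id: str
    ge_fc: float
    cna_lr: float | None = None
    me_fc: float | None = None
    mirna_fc: float | None = None
    cna_fraction: float = 0.0
    chromosome: str = ""

    def __post_init__(self) -> None:
        if self.ge_fc is None:
            raise ValidationError(f"{self.gene_id}: only differentially expressed genes are scored")
        if not (0.0 <= self.cna_fraction <= 1.0):
            raise ValidationError(f"{self.gene_id}: cna_fraction outside [0, 1]")


@dataclasses.dataclass
class ConcordanceProfile:
    """Which non-expression layers agree with the expression change."""

    cna_concordant: bool
    me_concordant: bool
    mirna_concordant: bool

    @property
    def n_other(self) -> int:
        return int(self.cna_concordant) + int(self.me_concordant) + int(self.mirna_concordant)


@dataclasses.dataclass
class ScoredGene:
    """Integrative score and driver/passenger classification of one gene."""

    gene_id: str
    evidence: GeneEvidence
    profile: ConcordanceProfile
    alpha: float
    beta: int
    score: float
    klass: str = "ineligible"  # driver | passenger | ineligible


def aggregate_mirna(
    gene_id: str,
    de_mirnas: Iterable[DifferentialRecord],
    targets: TargetMap,
    ge_direction: float,
) -> float | None:
    """Aggregate the significant miRNAs opposing a gene's expression change.

    Selects significant differentially expressed miRNAs whose target set
    contains ``gene_id`` and whose effect sign is opposite to
    ``ge_direction``, and returns the sum of their signed effects.
    Returns ``None`` when no opposing regulator exists.
    """
    if ge_direction not in (1, -1, 1.0, -1.0):
        raise ValidationError("ge_direction must be +1 or -1")
    total, found = 0.0, False
    for rec in de_mirnas:
        if rec.layer != Layer.MIRNA or not rec.significant:
            continue
        if gene_id not in targets.targets_of(rec.feature_id):
            continue
        if np.sign(rec.effect) == -np.sign(ge_direction):
            total += rec.effect
            found = True
    return total if found else None


def classify_concordance(e: GeneEvidence) -> ConcordanceProfile:
    """Compare each non-expression layer's sign with the expression change.

    Copy number agrees on the same sign; methylation and miRNA agree on
    the opposite sign.  Absent layers are never concordant.
    """
    if e.ge_fc == 0:
        raise ValidationError(f"{e.gene_id}: ge_fc = 0 (not differentially expressed)")
    s = np.sign(e.ge_fc)
    return ConcordanceProfile(
        cna_concordant=e.cna_lr is not None and np.sign(e.cna_lr) == s,
        me_concordant=e.me_fc is not None and np.sign(e.me_fc) == -s,
        mirna_concordant=e.mirna_fc is not None and np.sign(e.mirna_fc) == -s,
    )


def integrative_score(
    e: GeneEvidence,
    profile: ConcordanceProfile | None = None,
    alpha_bonus: float = 2.0,
    freq_threshold: float = 0.20,
    meets_frequency: bool | None = None,
) -> ScoredGene:
    """Concordance-bonus integrative score of one gene.

    score = (|Ge| + sum of concordant layer |effects|) * alpha * beta with
    beta = 1 + n_other and alpha = ``alpha_bonus`` when the gene's
    alterations meet the 20%-of-patients frequency criterion (``meets_frequency``
    overrides the ``cna_fraction >= freq_threshold`` check), else 1.
    """
    if profile is None:
        profile = classify_concordance(e)
    beta = 1 + profile.n_other
    if meets_frequency is None:
        meets_frequency = e.cna_fraction >= freq_threshold
    alpha = alpha_bonus if meets_frequency else 1.0
    total = abs(e.ge_fc)
    if profile.cna_concordant:
        total += abs(e.cna_lr)
    if profile.me_concordant:
        total += abs(e.me_fc)
    if profile.mirna_concordant:
        total += abs(e.mirna_fc)
    return ScoredGene(e.gene_id, e, profile, alpha, beta, total * alpha * beta)


def select_candidates(
    scored: list[ScoredGene],
    cutoff: float | str = "midpoint",
    min_other_layers: int = 2,
) -> tuple[set[str], set[str]]:
    """Split scored genes into driver and passenger candidates.

    Genes supported by fewer than ``min_other_layers`` concordant
    non-expression layers are marked ineligible.  Among eligible genes,
    drivers score at or above the cutoff; ``cutoff="midpoint"`` uses the
    midpoint between the lowest and highest eligible score, a numeric
    cutoff overrides.  Mutates ``klass`` in place and returns the two id
    sets.
    """
    if not scored:
        raise ValidationError("select_candidates: empty input")
    eligible = [s for s in scored if s.profile.n_other >= min_other_layers]
    for s in scored:
        if s.profile.n_other < min_other_layers:
            s.klass = "ineligible"
    if not eligible:
        logger.warning("no gene is supported by >=%d non-expression layers", min_other_layers)
        return set(), set()
    if cutoff == "midpoint":
        lo = min(s.score for s in eligible)
        hi = max(s.score for s in eligible)
        cut = (lo + hi) / 2.0
    else:
        cut = float(cutoff)
    drivers, passengers = set(), set()
    for s in eligible:
        if s.score >= cut:
            s.klass = "driver"
            drivers.add(s.gene_id)
        else:
            s.klass = "passenger"
            passengers.add(s.gene_id)
    return drivers, passengers


def build_evidence(
    de_genes: Iterable[DifferentialRecord],
    cna: Iterable[DifferentialRecord],
    methylation: Iterable[DifferentialRecord],
    mirnas: Iterable[DifferentialRecord],
    targets: TargetMap,
    significant_only: bool = True,
) -> list[GeneEvidence]:
    """Assemble per-gene four-layer evidence from differential records.

    Only significant differentially expressed genes are carried forward;
    a non-expression layer contributes its effect when its own call is
    significant (with ``significant_only=False`` every estimated effect
    is carried, which is useful for null diagnostics).
    """
    def by_gene(records: Iterable[DifferentialRecord]) -> dict[str, DifferentialRecord]:
        return {r.feature_id: r for r in records if r.significant or not significant_only}

    cna_map, me_map = by_gene(cna), by_gene(methylation)
    mirna_records = list(mirnas)
    evidence = []
    for rec in de_genes:
        if significant_only and not rec.significant:
            continue
        if rec.effect == 0:
            continue
        cna_rec = cna_map.get(rec.feature_id)
        me_rec = me_map.get(rec.feature_id)
        mi = aggregate_mirna(rec.feature_id, mirna_records, targets, float(np.sign(rec.effect))) \
            if significant_only else _aggregate_any(rec, mirna_records, targets)
        evidence.append(GeneEvidence(
            gene_id=rec.feature_id,
            ge_fc=rec.effect,
            cna_lr=cna_rec.effect if cna_rec else None,
            me_fc=me_rec.effect if me_rec else None,
            mirna_fc=mi,
            cna_fraction=cna_rec.altered_fraction if cna_rec else 0.0,
        ))
    return evidence


def _aggregate_any(rec: DifferentialRecord, mirna_records, targets: TargetMap) -> float | None:
    """Unfiltered miRNA aggregation: signed sum over all opposing
    targeting miRNAs regardless of significance (null diagnostics)."""
    s = np.sign(rec.effect)
    vals = [r.effect for r in mirna_records
            if rec.feature_id in targets.targets_of(r.feature_id)
            and np.sign(r.effect) == -s]
    return float(sum(vals)) if vals else None


def score_genes(
    evidence: Iterable[GeneEvidence],
    alpha_bonus: float = 2.0,
    freq_threshold: float = 0.20,
    meets_frequency: bool | None = None,
) -> list[ScoredGene]:
    """Vector form of :func:`integrative_score` over a list of genes."""
    return [
        integrative_score(e, alpha_bonus=alpha_bonus, freq_threshold=freq_threshold,
                          meets_frequency=meets_frequency)
        for e in evidence
    ]
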