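"""Per-layer differential alteration calling.

Each molecular layer has its own published decision rule:

* expression — mean tumor-normal log2 difference with |FC| >= 0.6 and a
  95% Welch confidence interval excluding zero;
* copy number — per-sample gain/loss calls at +/-0.15 log ratio, altered
  in at least 20% of tumors;
* methylation — Welch test at P < 0.05;
* miRNA — t-test at P < 0.01 with Benjamini-Hochberg FDR < 0.05.

All tests are Welch (unequal variance) two-sample comparisons on the
gene-level matrices; the outputs are :class:`DifferentialRecord` rows
consumed by the integrative scoring stage.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datamodel import Layer, OmicsMatrix, ValidationError

logger = logging.getLogger("omidriver")


@dataclasses.dataclass
class DifferentialRecord:
    """Gene-level differential call in one molecular layer."""

    feature_id: str
    layer: Layer
    effect: float          # signed log2 fold change / mean log ratio
    statistic: float
    p_value: float
    q_value: float
    altered_fraction: float
    significant: bool


def _records_frame(records: list[DifferentialRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [dataclasses.asdict(r) for r in records]
    ).assign(layer=lambda d: d["layer"].map(lambda x: Layer(x).value))


def records_to_frame(records: list[DifferentialRecord]) -> pd.DataFrame:
    """Tabular view of a list of records (TSV-ready)."""
    return _records_frame(records)


def bh_fdr(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values.

    q_(i) = min_{j >= i} m * p_(j) / j over the sorted p-values, capped at
    1 and mapped back to the original order.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def _welch(tumor: np.ndarray, normal: np.ndarray) -> tuple[float, float, float, float]:
    """Welch t-test of tumor vs normal.

    Returns (effect, t, p, se).  Degenerate zero-variance comparisons are
    resolved by the limiting behaviour: distinct constant groups separate
    perfectly (p=0), identical ones carry no signal (p=1).
    """
    tumor = tumor[~np.isnan(tumor)]
    normal = normal[~np.isnan(normal)]
    effect = float(np.mean(tumor) - np.mean(normal))
    se = float(np.sqrt(np.var(tumor, ddof=1) / len(tumor) + np.var(normal, ddof=1) / len(normal)))
    if se == 0.0:
        if effect == 0.0:
            return effect, 0.0, 1.0, se
        return effect, np.inf if effect > 0 else -np.inf, 0.0, se
    t, p = stats.ttest_ind(tumor, normal, equal_var=False)
    return effect, float(t), float(p), se


def _welch_df(tumor: np.ndarray, normal: np.ndarray) -> float:
    """Welch-Satterthwaite degrees of freedom."""
    v1, n1 = np.var(tumor, ddof=1), len(tumor)
    v2, n2 = np.var(normal, ddof=1), len(normal)
    num = (v1 / n1 + v2 / n2) ** 2
    den = (v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1)
    return num / den if den > 0 else n1 + n2 - 2


def _direction_fraction(tumor: np.ndarray, normal_mean: float, sign: float) -> float:
    """Fraction of tumor samples deviating from the normal mean in the
    direction of the group effect — a per-sample penetrance summary."""
    tumor = tumor[~np.isnan(tumor)]
    if len(tumor) == 0 or sign == 0:
        return 0.0
    return float(np.mean(np.sign(tumor - normal_mean) == np.sign(sign)))


def _check_groups(m: OmicsMatrix, expected: Layer) -> tuple[pd.DataFrame, pd.DataFrame]:
    if m.layer != expected:
        raise ValidationError(f"expected a {expected.value} matrix, got {m.layer.value}")
    t, n = m.tumor_values(), m.normal_values()
    if t.shape[1] < 2 or n.shape[1] < 2:
        raise ValidationError("need >=2 tumor and >=2 normal samples")
    return t, n


def diff_expression(
    m: OmicsMatrix,
    fc_threshold: float = 0.6,
    ci_level: float = 0.95,
) -> list[DifferentialRecord]:
    """Differential expression: |mean log2 FC| >= ``fc_threshold`` and the
    Welch ``ci_level`` confidence interval of the difference excludes 0."""
    tv, nv = _check_groups(m, Layer.EXPRESSION)
    records = []
    pvals = []
    interim = []
    for gene in m.feature_ids:
        t_arr, n_arr = tv.loc[gene].to_numpy(float), nv.loc[gene].to_numpy(float)
        effect, t, p, se = _welch(t_arr, n_arr)
        if se > 0:
            df = _welch_df(t_arr[~np.isnan(t_arr)], n_arr[~np.isnan(n_arr)])
            tcrit = stats.t.ppf(0.5 + ci_level / 2, df)
            ci_excludes_zero = abs(effect) > tcrit * se
        else:
            ci_excludes_zero = effect != 0.0
        sig = abs(effect) >= fc_threshold and ci_excludes_zero
        frac = _direction_fraction(t_arr, float(np.nanmean(n_arr)), effect)
        interim.append((gene, effect, t, p, frac, sig))
        pvals.append(p)
    qvals = bh_fdr(np.array(pvals))
    for (gene, effect, t, p, frac, sig), q in zip(interim, qvals):
        records.append(DifferentialRecord(gene, Layer.EXPRESSION, effect, t, p, float(q), frac, sig))
    return records


def diff_cna(
    m: OmicsMatrix,
    gain_threshold: float = 0.15,
    loss_threshold: float = -0.15,
    min_fraction: float = 0.20,
) -> list[DifferentialRecord]:
    """Copy-number calling from tumor log ratios.

    A tumor sample carries a gain if its log ratio >= ``gain_threshold``
    and a loss if <= ``loss_threshold``.  ``altered_fraction`` is the
    frequency of the dominant call; the effect is the mean log ratio over
    the tumors carrying it.  Frequency ties fall back to the sign of the
    overall mean (a zero mean is called not significant).
    """
    if m.layer != Layer.CNA:
        raise ValidationError(f"expected a cna matrix, got {m.layer.value}")
    tv = m.tumor_values()
    if tv.shape[1] < 5:
        raise ValidationError("need >=5 tumor samples for frequency-based CNA calling")
    records = []
    for gene in m.feature_ids:
        vals = tv.loc[gene].to_numpy(float)
        vals = vals[~np.isnan(vals)]
        if len(vals) == 0:
            logger.warning("cna: gene %s has no observed tumor values; dropped", gene)
            continue
        n = len(vals)
        gains, losses = vals >= gain_threshold, vals <= loss_threshold
        freq_gain, freq_loss = gains.mean(), losses.mean()
        if freq_gain > freq_loss:
            direction, carriers = 1.0, gains
        elif freq_loss > freq_gain:
            direction, carriers = -1.0, losses
        else:  # tie: sign of the overall mean decides; zero mean -> no call
            mean = vals.mean()
            direction = 0.0 if abs(mean) < 1e-9 else float(np.sign(mean))
            carriers = gains if direction > 0 else losses
        frac = float(max(freq_gain, freq_loss))
        effect = float(vals[carriers].mean()) if direction != 0 and carriers.any() else 0.0
        sig = direction != 0 and frac >= min_fraction
        records.append(DifferentialRecord(gene, Layer.CNA, effect, direction * frac, 0.0, 0.0, frac, sig))
    return records


def diff_methylation(m: OmicsMatrix, alpha: float = 0.05) -> list[DifferentialRecord]:
    """Differential methylation: Welch test per gene, significant at
    P < ``alpha``; positive effect = hypermethylated in tumor."""
    tv, nv = _check_groups(m, Layer.METHYLATION)
    interim, pvals = [], []
    for gene in m.feature_ids:
        t_arr, n_arr = tv.loc[gene].to_numpy(float), nv.loc[gene].to_numpy(float)
        effect, t, p, se = _welch(t_arr, n_arr)
        frac = _direction_fraction(t_arr, float(np.nanmean(n_arr)), effect)
        interim.append((gene, effect, t, p, frac))
        pvals.append(p)
    qvals = bh_fdr(np.array(pvals))
    return [
        DifferentialRecord(g, Layer.METHYLATION, e, t, p, float(q), f, p < alpha)
        for (g, e, t, p, f), q in zip(interim, qvals)
    ]


def diff_mirna(
    m: OmicsMatrix,
    p_threshold: float = 0.01,
    fdr_threshold: float = 0.05,
) -> list[DifferentialRecord]:
    """Differential miRNA expression: t-test with joint criterion
    P < ``p_threshold`` and BH q < ``fdr_threshold``."""
    tv, nv = _check_groups(m, Layer.MIRNA)
    interim, pvals = [], []
    for mirna in m.feature_ids:
        t_arr, n_arr = tv.loc[mirna].to_numpy(float), nv.loc[mirna].to_numpy(float)
        effect, t, p, se = _welch(t_arr, n_arr)
        frac = _direction_fraction(t_arr, float(np.nanmean(n_arr)), effect)
        interim.append((mirna, effect, t, p, frac))
        pvals.append(p)
    qvals = bh_fdr(np.array(pvals))
    return [
        DifferentialRecord(mi, Layer.MIRNA, e, t, p, float(q), f,
                           p < p_threshold and q < fdr_threshold)
        for (mi, e, t, p, f), q in zip(interim, qvals)
    ]
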