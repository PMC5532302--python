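"""Packaged study tables.

Two small TSV fixtures ship with the package: the 47 driver candidates
with their per-layer effects and integrative scores, and the 22 filtered
regulator-module associations.  A printed 0 in an effect column encodes
"layer absent" and is converted to NaN on load; :func:`table1_evidence`
converts rows into :class:`~omidriver.scoring.GeneEvidence` with absent
layers as ``None``.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .scoring import GeneEvidence


def _data_path(name: str):
    return resources.files("omidriver").joinpath("data", name)


def table1_fixture() -> pd.DataFrame:
    """47 driver candidates: gene, chromosome, lr_cna, fc_ge, fc_me,
    fc_mirna, score.  Zeros in effect columns are returned as NaN
    (absent layer)."""
    with resources.as_file(_data_path("table1_driver_candidates.tsv")) as p:
        df = pd.read_csv(p, sep="\t", dtype={"chromosome": str})
    for col in ("lr_cna", "fc_me", "fc_mirna"):
        df[col] = df[col].replace(0.0, np.nan)
    return df


def table2_fixture() -> pd.DataFrame:
    """22 regulator-module associations: regulator, module,
    assignment_score, gene and passenger counts, annotation categories,
    drug-target flag."""
    with resources.as_file(_data_path("table2_module_associations.tsv")) as p:
        df = pd.read_csv(p, sep="\t", dtype={"msigdb_categories": str})
    df["msigdb_categories"] = df["msigdb_categories"].fillna("")
    return df


def table1_evidence() -> list[GeneEvidence]:
    """Fixture rows as scoring-ready evidence.

    The fixture carries no per-gene alteration frequency; the study
    selected these rows among genes altered in >20% of patients, so
    ``cna_fraction`` is set to 1.0 (frequency criterion met) for every
    row.
    """
    out = []
    for row in table1_fixture().itertuples(index=False):
        out.append(GeneEvidence(
            gene_id=row.gene,
            ge_fc=row.fc_ge,
            cna_lr=None if pd.isna(row.lr_cna) else row.lr_cna,
            me_fc=None if pd.isna(row.fc_me) else row.fc_me,
            mirna_fc=None if pd.isna(row.fc_mirna) else row.fc_mirna,
            cna_fraction=1.0,
            chromosome=row.chromosome,
        ))
    return out
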