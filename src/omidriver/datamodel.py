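"""Core data types shared by every pipeline stage.

A cohort is represented as one :class:`OmicsMatrix` per molecular layer
(gene expression, copy number, promoter methylation, miRNA expression),
all on a log2/ log-ratio scale, with a tumor/normal label for every
sample.  Auxiliary tables — miRNA target maps, gene-set collections,
clinical follow-up and protein interaction edges — have small dedicated
containers with validated invariants.
"""

from __future__ import annotations

import dataclasses
import enum
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml


class Layer(str, enum.Enum):
    """Molecular layer of an omics matrix."""

    EXPRESSION = "expression"
    CNA = "cna"
    METHYLATION = "methylation"
    MIRNA = "mirna"


class Group(str, enum.Enum):
    """Sample phenotype label."""

    TUMOR = "tumor"
    NORMAL = "normal"


class ValidationError(ValueError):
    """An input violates a structural invariant of the data model."""


class FormatError(ValueError):
    """A file does not conform to the expected tabular dialect."""


def _check_unique(ids: Iterable[str], what: str) -> list[str]:
    ids = list(ids)
    if len(ids) != len(set(ids)):
        seen: set[str] = set()
        dups = sorted({i for i in ids if i in seen or seen.add(i)})
        raise ValidationError(f"duplicate {what}: {dups[:5]}")
    return ids


@dataclasses.dataclass
class OmicsMatrix:
    """One molecular layer as a feature x sample real-valued matrix.

    Parameters
    ----------
    layer
        Which molecular layer the values describe.
    values
        ``features x samples`` DataFrame.  Expression and copy number are
        log2 tumor/reference ratios; methylation is a signed log-scale
        differential signal; miRNA expression is log2 scale.  Missing
        values (NaN) are permitted.
    groups
        Series mapping every sample id to :class:`Group`.

    Raises
    ------
    ValidationError
        On duplicate feature/sample ids or missing group labels.
    """

    layer: Layer
    values: pd.DataFrame
    groups: pd.Series

    def __post_init__(self) -> None:
        self.layer = Layer(self.layer)
        _check_unique(self.values.index, "feature ids")
        _check_unique(self.values.columns, "sample ids")
        missing = [s for s in self.values.columns if s not in self.groups.index]
        if missing:
            raise ValidationError(
                f"samples without a group label in layer {self.layer.value}: {missing[:5]}"
            )
        self.groups = self.groups.reindex(self.values.columns).map(Group)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def samples_in(self, group: Group) -> list[str]:
        return [s for s in self.sample_ids if self.groups[s] == group]

    @property
    def tumor_samples(self) -> list[str]:
        return self.samples_in(Group.TUMOR)

    @property
    def normal_samples(self) -> list[str]:
        return self.samples_in(Group.NORMAL)

    def tumor_values(self) -> pd.DataFrame:
        return self.values[self.tumor_samples]

    def normal_values(self) -> pd.DataFrame:
        return self.values[self.normal_samples]


@dataclasses.dataclass
class TargetMap:
    """miRNA -> predicted target genes.

    ``min_algorithms`` records how many prediction algorithms had to agree
    for an edge to enter the map; it is metadata describing how the map
    was built, not a filter applied here.
    """

    entries: dict[str, frozenset[str]]
    min_algorithms: int = 6

    def __post_init__(self) -> None:
        if self.min_algorithms < 1:
            raise ValidationError("min_algorithms must be >= 1")
        clean: dict[str, frozenset[str]] = {}
        for mirna, genes in self.entries.items():
            genes = frozenset(genes)
            if not genes:
                raise ValidationError(f"empty target set for {mirna}")
            clean[mirna] = genes
        self.entries = clean
        self._by_gene: dict[str, set[str]] = {}
        for mirna, genes in self.entries.items():
            for g in genes:
                self._by_gene.setdefault(g, set()).add(mirna)

    def targets_of(self, mirna: str) -> frozenset[str]:
        return self.entries.get(mirna, frozenset())

    def mirnas_targeting(self, gene: str) -> set[str]:
        return set(self._by_gene.get(gene, set()))


@dataclasses.dataclass
class GeneSetCollection:
    """Named gene sets (GO/KEGG/Reactome-style), GMT-compatible."""

    sets: dict[str, tuple[str, frozenset[str]]]

    def __post_init__(self) -> None:
        for set_id, (_, members) in list(self.sets.items()):
            members = frozenset(members)
            if not members:
                raise ValidationError(f"gene set {set_id} is empty")
            self.sets[set_id] = (self.sets[set_id][0], members)

    def members(self, set_id: str) -> frozenset[str]:
        return self.sets[set_id][1]

    def __len__(self) -> int:
        return len(self.sets)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, GeneSetCollection) and self.sets == other.sets


@dataclasses.dataclass
class ClinicalTable:
    """Per-sample survival follow-up: time in months, death/censor flag,
    and optional categorical covariates."""

    records: pd.DataFrame  # index sample_id; columns time_months, event, covariates...

    def __post_init__(self) -> None:
        df = self.records
        _check_unique(df.index, "clinical sample ids")
        for col in ("time_months", "event"):
            if col not in df.columns:
                raise ValidationError(f"clinical table missing column {col!r}")
        if (df["time_months"] < 0).any():
            raise ValidationError("negative survival time")
        if not df["event"].isin([0, 1]).all():
            raise ValidationError("event flag must be 0 (censored) or 1 (death)")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.records.index)


@dataclasses.dataclass
class InteractionTable:
    """Undirected interaction edges between gene/protein identifiers."""

    edges: frozenset[frozenset[str]]

    def __post_init__(self) -> None:
        edges = set()
        for e in self.edges:
            e = frozenset(e)
            if len(e) != 2:
                raise ValidationError(f"edge must join two distinct nodes: {sorted(e)}")
            edges.add(e)
        self.edges = frozenset(edges)

    @property
    def nodes(self) -> set[str]:
        return {n for e in self.edges for n in e}


@dataclasses.dataclass
class PipelineConfig:
    """All tunable thresholds of the pipeline with their defaults.

    Defaults follow the study design: expression calls need
    |log2 FC| >= 0.6 with a 95% CI excluding zero; copy-number calls need
    |log ratio| >= 0.15 in >= 20% of tumors; methylation P < 0.05; miRNA
    P < 0.01 with FDR < 0.05; eligibility requires two concordant
    non-expression layers; modules need >= 5 genes, and modules with
    < 10% passenger candidates are discarded.
    """

    ge_fc_threshold: float = 0.6
    ge_ci_level: float = 0.95
    cna_gain_threshold: float = 0.15
    cna_loss_threshold: float = -0.15
    cna_min_fraction: float = 0.20
    me_alpha: float = 0.05
    mirna_p_threshold: float = 0.01
    mirna_fdr_threshold: float = 0.05
    alpha_bonus: float = 2.0
    freq_threshold: float = 0.20
    min_other_layers: int = 2
    score_cutoff: float | str = "midpoint"
    gibbs_n_iter: int = 500
    gibbs_burn_in: int = 250
    gibbs_concentration: float = 1.0
    min_module_size: int = 5
    tree_min_leaf: int = 5
    tree_max_depth: int = 3
    top_percent: float = 1.0
    min_passenger_fraction: float = 0.10
    association_cutoff: float | None = None
    seed: int = 0

    _RANGES = {
        "ge_fc_threshold": (0.0, np.inf),
        "ge_ci_level": (0.5, 1.0),
        "cna_gain_threshold": (0.0, np.inf),
        "cna_min_fraction": (0.0, 1.0),
        "me_alpha": (0.0, 1.0),
        "mirna_p_threshold": (0.0, 1.0),
        "mirna_fdr_threshold": (0.0, 1.0),
        "freq_threshold": (0.0, 1.0),
        "top_percent": (0.0, 100.0),
        "min_passenger_fraction": (0.0, 1.0),
    }

    def __post_init__(self) -> None:
        for name, (lo, hi) in self._RANGES.items():
            v = getattr(self, name)
            if not (lo <= v <= hi):
                raise ValidationError(f"{name}={v} outside admissible range [{lo}, {hi}]")
        if self.cna_loss_threshold > 0:
            raise ValidationError("cna_loss_threshold must be <= 0")
        if self.gibbs_burn_in >= self.gibbs_n_iter:
            raise ValidationError("burn_in must be < n_iter")
        if self.min_module_size < 1:
            raise ValidationError("min_module_size must be >= 1")

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)
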