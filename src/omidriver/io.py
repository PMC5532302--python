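"""Readers and writers for the tabular dialects used by the pipeline.

Every matrix is tab-separated text with a header row of sample ids and a
first column of feature ids; decimal point ".", missing values "NA".
Group labels (tumor/normal) live in a two-column sidecar so matrices stay
standard.  Gene sets use the GMT dialect; target maps, edge lists and
clinical tables are plain TSV.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .datamodel import (
    ClinicalTable,
    FormatError,
    GeneSetCollection,
    Group,
    InteractionTable,
    Layer,
    OmicsMatrix,
    TargetMap,
    ValidationError,
)

logger = logging.getLogger("omidriver")

#: genes with more than this fraction of missing entries are dropped from a layer
MAX_MISSING_FRACTION = 0.20


def read_groups(path: str | Path) -> dict[str, Group]:
    """Read a two-column (sample_id, group) sidecar TSV."""
    groups: dict[str, Group] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) != 2:
            raise FormatError(f"{path}:{lineno}: expected 2 tab-separated fields")
        sample, label = fields
        if sample == "sample_id":  # optional header
            continue
        try:
            groups[sample] = Group(label)
        except ValueError:
            raise FormatError(f"{path}:{lineno}: unknown group label {label!r}") from None
    return groups


def read_matrix(
    path: str | Path,
    layer: Layer | str,
    group_spec: Mapping[str, Group | str] | str | Path,
) -> OmicsMatrix:
    """Read a feature x sample TSV matrix into a validated :class:`OmicsMatrix`.

    ``group_spec`` is either a mapping sample_id -> group or the path of a
    two-column sidecar TSV.  Duplicate feature rows are collapsed by mean
    (with a logged warning); rows with more than 20% missing values are
    dropped from the layer.  Rows are returned sorted by feature id, so the
    result is invariant under row permutation of the input file.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    if len(header) < 2:
        raise FormatError(f"{path}: malformed header (need a feature column and >=1 sample)")
    samples = header[1:]
    if len(samples) != len(set(samples)):
        raise ValidationError(f"{path}: repeated sample id in header")

    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric matrix entry ({exc})") from None
    df.columns = samples
    df.index = df.index.astype(str)
    df.index.name = "feature_id"

    if df.index.has_duplicates:
        dups = sorted(df.index[df.index.duplicated()].unique())
        logger.warning("%s: collapsing %d duplicated feature id(s) by mean (e.g. %s)",
                       path.name, len(dups), dups[:3])
        df = df.groupby(level=0).mean()

    frac_missing = df.isna().mean(axis=1)
    drop = frac_missing > MAX_MISSING_FRACTION
    if drop.any():
        logger.warning("%s: dropping %d feature(s) with >%.0f%% missing values",
                       path.name, int(drop.sum()), 100 * MAX_MISSING_FRACTION)
        df = df.loc[~drop]
    df = df.sort_index()

    if isinstance(group_spec, (str, Path)):
        groups = read_groups(group_spec)
    else:
        groups = {s: Group(g) for s, g in group_spec.items()}
    missing = [s for s in samples if s not in groups]
    if missing:
        raise ValidationError(f"{path}: samples absent from group spec: {missing[:5]}")
    return OmicsMatrix(
        layer=Layer(layer),
        values=df,
        groups=pd.Series({s: groups[s] for s in samples}),
    )


def write_matrix(m: OmicsMatrix, path: str | Path, groups_path: str | Path | None = None) -> None:
    m.values.to_csv(path, sep="\t", index_label="feature_id", na_rep="NA")
    if groups_path is not None:
        with open(groups_path, "w") as fh:
            for s in m.sample_ids:
                fh.write(f"{s}\t{m.groups[s].value}\n")


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: set_id <tab> description <tab> member genes..."""
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise FormatError(f"{path}:{lineno}: GMT line needs >=3 tab-separated fields")
        set_id, desc, *members = fields
        members = [g for g in members if g]
        if not members:
            raise FormatError(f"{path}:{lineno}: gene set {set_id!r} has no members")
        if set_id in sets:
            raise FormatError(f"{path}:{lineno}: duplicate set id {set_id!r}")
        sets[set_id] = (desc, frozenset(members))
    return GeneSetCollection(sets=sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for set_id in sorted(collection.sets):
            desc, members = collection.sets[set_id]
            fh.write("\t".join([set_id, desc, *sorted(members)]) + "\n")


def read_target_map(path: str | Path, min_algorithms: int = 6) -> TargetMap:
    """Read a two-column (miRNA_id, gene_id) TSV into a :class:`TargetMap`."""
    entries: dict[str, set[str]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) != 2:
            raise FormatError(f"{path}:{lineno}: expected 2 tab-separated fields")
        mirna, gene = fields
        if mirna == "mirna_id":
            continue
        entries.setdefault(mirna, set()).add(gene)
    return TargetMap(entries={m: frozenset(g) for m, g in entries.items()},
                     min_algorithms=min_algorithms)


def write_target_map(tm: TargetMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        for mirna in sorted(tm.entries):
            for gene in sorted(tm.entries[mirna]):
                fh.write(f"{mirna}\t{gene}\n")


def read_edge_list(path: str | Path) -> InteractionTable:
    edges = set()
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) != 2:
            raise FormatError(f"{path}:{lineno}: expected 2 tab-separated fields")
        a, b = fields
        if a == b:
            raise ValidationError(f"{path}:{lineno}: self-loop on {a!r}")
        edges.add(frozenset((a, b)))
    return InteractionTable(edges=frozenset(edges))


def read_clinical(path: str | Path) -> ClinicalTable:
    """Read a clinical TSV with columns sample_id, time_months, event [, covariates...]."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    if "sample_id" not in df.columns:
        raise FormatError(f"{path}: missing 'sample_id' column")
    df = df.set_index("sample_id")
    return ClinicalTable(records=df)


def write_clinical(ct: ClinicalTable, path: str | Path) -> None:
    ct.records.to_csv(path, sep="\t", index_label="sample_id")


@dataclasses.dataclass
class CohortReport:
    """Summary of sample overlap and group sizes across layers."""

    counts: dict[str, tuple[int, int]]            # layer -> (n_tumor, n_normal)
    intersections: dict[tuple[str, str], tuple[int, int]]  # layer pair -> shared (tumor, normal)
    warnings: list[str]

    @property
    def ok(self) -> bool:
        return all(t >= 2 and n >= 2 for t, n in self.counts.values())


def validate_cohort(matrices: Sequence[OmicsMatrix], clinical: ClinicalTable | None = None) -> CohortReport:
    """Check that the layers of a cohort can be integrated.

    Fails (ValidationError) if any layer has fewer than 2 tumors or 2
    normals, or if the expression and copy-number layers share no tumor
    samples (integration is then impossible).  Clinical samples missing
    for tumors are reported as warnings.
    """
    if not matrices:
        raise ValidationError("need at least one omics matrix")
    counts: dict[str, tuple[int, int]] = {}
    tumors: dict[str, set[str]] = {}
    normals: dict[str, set[str]] = {}
    warnings: list[str] = []
    for m in matrices:
        name = m.layer.value
        tumors[name] = set(m.tumor_samples)
        normals[name] = set(m.normal_samples)
        counts[name] = (len(tumors[name]), len(normals[name]))
        if counts[name][0] < 2 or counts[name][1] < 2:
            raise ValidationError(
                f"layer {name}: needs >=2 tumor and >=2 normal samples, has {counts[name]}"
            )
    inter: dict[tuple[str, str], tuple[int, int]] = {}
    names = list(counts)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            inter[(a, b)] = (len(tumors[a] & tumors[b]), len(normals[a] & normals[b]))
    if "expression" in counts and "cna" in counts:
        if not tumors["expression"] & tumors["cna"]:
            raise ValidationError("expression and cna layers share no tumor samples")
    if clinical is not None:
        all_tumors = set().union(*tumors.values())
        missing = sorted(all_tumors - set(clinical.sample_ids))
        if missing:
            msg = f"clinical table missing {len(missing)} tumor sample(s): {missing}"
            warnings.append(msg)
            logger.warning(msg)
    return CohortReport(counts=counts, intersections=inter, warnings=warnings)
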