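"""Synthetic multi-omics cohorts with planted ground truth.

The generator emulates the study conditions end to end: a small cohort
(20 tumors, 10 normals by default) measured on four layers, with

* planted *driver* genes whose expression shift is backed by concordant
  copy-number, methylation and/or opposing-miRNA events (per-driver
  layer patterns),
* co-expression *modules* whose members share a latent tumor profile
  driven by a regulator gene (a monotone link: members load linearly on
  the regulator's latent states),
* planted *passenger candidates* inside modules — eligible genes with
  weak two-layer concordant alterations that score below drivers,
* a *prognostic* gene whose standardized tumor expression multiplies an
  exponential baseline hazard, with independent uniform censoring.

Everything is drawn from a single seeded generator, so identical specs
and seeds give byte-identical cohorts.  :class:`PlantedTruth` records
the ground truth each pipeline stage is benchmarked against.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .datamodel import (
    ClinicalTable,
    Group,
    Layer,
    OmicsMatrix,
    TargetMap,
    ValidationError,
)


@dataclasses.dataclass
class CohortSpec:
    """Study-condition parameters of a synthetic cohort.

    Effect magnitudes are log2-scale and match the magnitudes the
    integrative score defaults were designed for: driver expression
    shifts |N(2, 0.5)|, copy-number log ratios +/-0.4 at 50% penetrance,
    methylation +/-1.5, opposing miRNAs +/-2.5.
    """

    n_tumor: int = 20
    n_normal: int = 10
    n_genes: int = 1000
    n_mirnas: int = 150
    n_modules: int = 8
    module_size_min: int = 10
    module_size_max: int = 40
    n_drivers: int = 16
    driver_ge_mean: float = 2.0
    driver_ge_sd: float = 0.5
    member_ge_mean: float = 1.2
    member_ge_sd: float = 0.3
    cna_lr: float = 0.4
    passenger_cna_lr: float = 0.2
    me_fc: float = 1.5
    passenger_me_fc: float = 0.8
    mirna_fc: float = 2.5
    noise_sd: float = 0.5
    cna_noise_sd: float = 0.05
    cna_penetrance: float = 0.5
    passenger_cna_penetrance: float = 0.4
    module_coupling: float = 0.8
    passenger_fraction_in_modules: float = 0.3
    mirnas_per_driver: int = 2
    prognostic_hr: float = 3.0
    baseline_median_months: float = 10.0
    censoring_window_months: float = 45.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_drivers > self.n_genes:
            raise ValidationError("n_drivers must be <= n_genes")
        if self.n_drivers < self.n_modules:
            raise ValidationError("need at least one driver per module to act as regulator")
        if not (0 < self.cna_penetrance <= 1):
            raise ValidationError("cna_penetrance must be in (0, 1]")
        if self.module_size_min < 1 or self.module_size_max < self.module_size_min:
            raise ValidationError("invalid module size range")
        for name in ("n_tumor", "n_normal", "n_genes", "n_mirnas", "n_modules"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")

    @classmethod
    def null(cls, **overrides) -> "CohortSpec":
        """A cohort with zero planted effects (pure noise on all layers)."""
        zeros = dict(
            driver_ge_mean=0.0, driver_ge_sd=0.0,
            member_ge_mean=0.0, member_ge_sd=0.0,
            cna_lr=0.0, passenger_cna_lr=0.0,
            me_fc=0.0, passenger_me_fc=0.0,
            mirna_fc=0.0, module_coupling=0.0,
            prognostic_hr=1.0,
        )
        zeros.update(overrides)
        return cls(**zeros)


@dataclasses.dataclass
class PlantedTruth:
    """Ground truth of a generated cohort."""

    drivers: dict[str, dict[str, bool]]      # gene -> {cna, me, mi} planted-concordant flags
    passengers: set[str]
    module_members: dict[str, set[str]]
    regulator_of: list[tuple[str, str]]      # (driver gene, module id)
    prognostic_gene: str
    opposing_mirnas: dict[str, set[str]]     # driver gene -> planted opposing miRNA ids


# driver layer patterns beyond the fully concordant regulators; cycled
_MIXED_PATTERNS = (
    {"cna": True, "me": True, "mi": False},
    {"cna": True, "me": False, "mi": True},
    {"cna": False, "me": True, "mi": True},
)


def generate_cohort(
    spec: CohortSpec,
) -> tuple[dict[str, OmicsMatrix], TargetMap, ClinicalTable, PlantedTruth]:
    """Generate the four-layer cohort, target map, clinical table and truth.

    Returns a dict with keys ``expression``, ``cna``, ``methylation``,
    ``mirna``.
    """
    rng = np.random.default_rng(spec.seed)
    tumors = [f"T{i + 1:02d}" for i in range(spec.n_tumor)]
    normals = [f"N{i + 1:02d}" for i in range(spec.n_normal)]
    samples = tumors + normals
    groups = pd.Series({**{s: Group.TUMOR for s in tumors},
                        **{s: Group.NORMAL for s in normals}})
    genes = [f"G{i + 1:04d}" for i in range(spec.n_genes)]
    mirnas = [f"miR-{i + 1:03d}" for i in range(spec.n_mirnas)]
    n_t, n_n = spec.n_tumor, spec.n_normal

    # --- roles ------------------------------------------------------------
    driver_genes = genes[: spec.n_drivers]
    regulators = driver_genes[: spec.n_modules]
    drivers: dict[str, dict[str, bool]] = {}
    for i, g in enumerate(driver_genes):
        if g in regulators:
            drivers[g] = {"cna": True, "me": True, "mi": True}
        else:
            drivers[g] = dict(_MIXED_PATTERNS[(i - spec.n_modules) % len(_MIXED_PATTERNS)])
    driver_sign = {g: (1.0 if rng.random() < 0.5 else -1.0) for g in driver_genes}
    prognostic_gene = regulators[0]
    driver_sign[prognostic_gene] = 1.0  # overexpressed prognostic marker

    pool = genes[spec.n_drivers:]
    module_members: dict[str, set[str]] = {}
    passengers: set[str] = set()
    passenger_sign: dict[str, float] = {}
    member_of: dict[str, str] = {}
    cursor = 0
    for m in range(spec.n_modules):
        size = int(rng.integers(spec.module_size_min, spec.module_size_max + 1))
        size = min(size, len(pool) - cursor)
        if size <= 0:
            raise ValidationError("n_genes too small for the requested modules")
        mid = f"PM{m + 1:02d}"
        members = set(pool[cursor: cursor + size])
        cursor += size
        module_members[mid] = members
        n_pass = int(round(spec.passenger_fraction_in_modules * size))
        for g in sorted(members)[:n_pass]:
            passengers.add(g)
    module_sign = {mid: driver_sign[reg] for mid, reg in
                   zip(module_members, regulators)}
    for mid, members in module_members.items():
        for g in members:
            member_of[g] = mid
            passenger_sign[g] = module_sign[mid]

    # --- expression -------------------------------------------------------
    expr = rng.normal(0.0, spec.noise_sd, size=(spec.n_genes, len(samples)))
    latent = {mid: rng.normal(0.0, 1.0, size=n_t) for mid in module_members}
    gi = {g: i for i, g in enumerate(genes)}
    if spec.module_coupling > 0:  # regulators carry their module's latent states
        for mid, reg in zip(module_members, regulators):
            expr[gi[reg], :n_t] += latent[mid]
    for g in driver_genes:
        shift = driver_sign[g] * abs(rng.normal(spec.driver_ge_mean, spec.driver_ge_sd))
        expr[gi[g], :n_t] += shift
    for mid, members in module_members.items():
        for g in sorted(members):
            shift = module_sign[mid] * abs(rng.normal(spec.member_ge_mean, spec.member_ge_sd))
            expr[gi[g], :n_t] += shift + spec.module_coupling * latent[mid]

    # --- copy number ------------------------------------------------------
    cna = rng.normal(0.0, spec.cna_noise_sd, size=(spec.n_genes, len(samples)))
    def plant_cna(g: str, lr: float, penetrance: float, sign: float) -> None:
        n_carriers = max(1, int(round(penetrance * n_t)))
        carriers = rng.choice(n_t, size=n_carriers, replace=False)
        cna[gi[g], carriers] += sign * lr
    for g in driver_genes:
        if drivers[g]["cna"] and spec.cna_lr > 0:
            plant_cna(g, spec.cna_lr, spec.cna_penetrance, driver_sign[g])
    for g in sorted(passengers):
        if spec.passenger_cna_lr > 0:
            plant_cna(g, spec.passenger_cna_lr, spec.passenger_cna_penetrance, passenger_sign[g])

    # --- methylation (opposite sign = concordant) -------------------------
    meth = rng.normal(0.0, spec.noise_sd, size=(spec.n_genes, len(samples)))
    for g in driver_genes:
        if drivers[g]["me"] and spec.me_fc > 0:
            meth[gi[g], :n_t] += -driver_sign[g] * spec.me_fc
    for g in sorted(passengers):
        if spec.passenger_me_fc > 0:
            meth[gi[g], :n_t] += -passenger_sign[g] * spec.passenger_me_fc

    # --- miRNA layer and target map ---------------------------------------
    mirna = rng.normal(0.0, spec.noise_sd, size=(spec.n_mirnas, len(samples)))
    entries: dict[str, set[str]] = {}
    opposing: dict[str, set[str]] = {}
    mi_cursor = 0
    if spec.mirna_fc > 0:  # no planted regulation -> no dedicated target edges
        for g in driver_genes:
            if not drivers[g]["mi"]:
                continue
            opposing[g] = set()
            for _ in range(spec.mirnas_per_driver):
                if mi_cursor >= spec.n_mirnas:
                    raise ValidationError("n_mirnas too small for the planted regulators")
                mi_id = mirnas[mi_cursor]
                mirna[mi_cursor, :n_t] += -driver_sign[g] * spec.mirna_fc
                mi_cursor += 1
                extra = set(rng.choice(genes, size=3, replace=False))
                entries[mi_id] = {g} | extra
                opposing[g].add(mi_id)
    for mi_id in mirnas[mi_cursor:]:
        entries[mi_id] = set(rng.choice(genes, size=3, replace=False))
    targets = TargetMap(entries={m: frozenset(g) for m, g in entries.items()},
                        min_algorithms=6)

    # --- clinical table ---------------------------------------------------
    prog_expr = expr[gi[prognostic_gene], :n_t]
    z = (prog_expr - prog_expr.mean()) / (prog_expr.std() or 1.0)
    h0 = np.log(2.0) / spec.baseline_median_months
    hazard = h0 * np.exp(np.log(spec.prognostic_hr) * z)
    t_event = rng.exponential(1.0 / hazard)
    t_censor = rng.uniform(0.0, spec.censoring_window_months, size=n_t)
    event = (t_event <= t_censor).astype(int)
    time = np.minimum(t_event, t_censor)
    clinical = ClinicalTable(records=pd.DataFrame(
        {"time_months": time, "event": event,
         "grade": rng.choice(["I-II", "III"], size=n_t, p=[0.6, 0.4])},
        index=pd.Index(tumors, name="sample_id"),
    ))

    def matrix(layer: Layer, values: np.ndarray, ids: list[str]) -> OmicsMatrix:
        return OmicsMatrix(layer=layer,
                           values=pd.DataFrame(values, index=ids, columns=samples),
                           groups=groups.copy())

    matrices = {
        "expression": matrix(Layer.EXPRESSION, expr, genes),
        "cna": matrix(Layer.CNA, cna, genes),
        "methylation": matrix(Layer.METHYLATION, meth, genes),
        "mirna": matrix(Layer.MIRNA, mirna, mirnas),
    }
    truth = PlantedTruth(
        drivers=drivers,
        passengers=passengers,
        module_members=module_members,
        regulator_of=list(zip(driver_genes[: spec.n_modules], module_members)),
        prognostic_gene=prognostic_gene,
        opposing_mirnas=opposing,
    )
    return matrices, targets, clinical, truth


def planted_blocks_matrix(
    n_blocks: int = 2,
    genes_per_block: int = 30,
    n_samples: int = 20,
    noise_sd: float = 0.3,
    seed: int = 11,
) -> tuple[OmicsMatrix, dict[str, int]]:
    """Benchmark matrix for module discovery: ``n_blocks`` planted blocks
    of co-expressed genes (shared latent profile + gene noise) over
    tumor samples.  Returns the matrix and the true block labels."""
    rng = np.random.default_rng(seed)
    samples = [f"T{i + 1:02d}" for i in range(n_samples)]
    rows, labels = [], {}
    ids = []
    for b in range(n_blocks):
        z = rng.normal(0.0, 1.0, size=n_samples)
        for g in range(genes_per_block):
            gid = f"B{b + 1}G{g + 1:03d}"
            rows.append(z + rng.normal(0.0, noise_sd, size=n_samples))
            ids.append(gid)
            labels[gid] = b
    m = OmicsMatrix(
        layer=Layer.EXPRESSION,
        values=pd.DataFrame(np.array(rows), index=ids, columns=samples),
        groups=pd.Series({s: Group.TUMOR for s in samples}),
    )
    return m, labels


def noise_matrix(n_genes: int = 60, n_samples: int = 20, seed: int = 0) -> OmicsMatrix:
    """Pure-noise expression matrix (null input for module discovery)."""
    rng = np.random.default_rng(seed)
    samples = [f"T{i + 1:02d}" for i in range(n_samples)]
    ids = [f"G{i + 1:03d}" for i in range(n_genes)]
    return OmicsMatrix(
        layer=Layer.EXPRESSION,
        values=pd.DataFrame(rng.normal(size=(n_genes, n_samples)), index=ids, columns=samples),
        groups=pd.Series({s: Group.TUMOR for s in samples}),
    )


def planted_regulator_benchmark(
    n_modules: int = 3,
    genes_per_module: int = 10,
    n_decoys: int = 30,
    n_samples: int = 40,
    effect: float = 2.0,
    noise_sd: float = 0.5,
    seed: int = 5,
) -> tuple[dict[str, pd.Series], dict[str, pd.Series], str]:
    """Benchmark for regulator scoring: one true regulator whose
    expression separates two sample states by ``effect`` standard
    deviations, driving ``n_modules`` modules; decoy candidates are
    standard-normal noise.  Returns (module profiles, candidate pool,
    true regulator id)."""
    rng = np.random.default_rng(seed)
    samples = [f"T{i + 1:02d}" for i in range(n_samples)]
    state = (np.arange(n_samples) < n_samples // 2).astype(float)
    state = rng.permutation(state)
    true_id = "REG_TRUE"
    pool = {true_id: pd.Series(effect * state + rng.normal(0, 1.0, n_samples), index=samples)}
    for d in range(n_decoys):
        pool[f"DECOY{d + 1:02d}"] = pd.Series(rng.normal(0, 1.0, n_samples), index=samples)
    profiles = {}
    for m in range(n_modules):
        members = np.array([
            1.5 * state + rng.normal(0, noise_sd, n_samples)
            for _ in range(genes_per_module)
        ])
        profiles[f"PM{m + 1:02d}"] = pd.Series(members.mean(axis=0), index=samples)
    return profiles, pool, true_id
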