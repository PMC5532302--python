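"""Co-expression module discovery by collapsed Gibbs sampling.

Gene expression profiles (standardized across tumor samples) are
clustered with a Chinese-restaurant-process mixture of diagonal
Gaussians.  Each sample dimension of a module carries a Normal-Gamma
conjugate prior (mean mu0 = 0, precision scaling lambda0, shape a0,
rate b0), so the component parameters integrate out and one Gibbs sweep
resamples every gene's module from the collapsed Student-t posterior
predictive of each existing module plus a fresh one.  The reported
partition is the post-burn-in sample with the highest joint log
posterior, which makes the output a deterministic function of the seed.

Two implementation contracts matter for reproducibility: genes are swept
in sorted-id order, and each gene draws from its own random stream
derived from (seed, gene id) — so permuting the rows of the input matrix
cannot change the result.
"""

from __future__ import annotations

import dataclasses
import logging
import zlib

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .datamodel import OmicsMatrix, ValidationError

logger = logging.getLogger("omidriver")


@dataclasses.dataclass
class GibbsParams:
    """Sampler settings and Normal-Gamma prior hyperparameters."""

    n_iter: int = 500
    burn_in: int = 250
    concentration: float = 1.0   # CRP gamma
    prior_scale: float = 1.0     # lambda0 (prior mean fixed at 0)
    prior_shape: float = 2.0     # a0
    prior_rate: float = 1.0      # b0
    min_module_size: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.burn_in >= self.n_iter:
            raise ValidationError("burn_in must be < n_iter")
        if self.min_module_size < 1:
            raise ValidationError("min_module_size must be >= 1")
        if min(self.concentration, self.prior_scale, self.prior_shape, self.prior_rate) <= 0:
            raise ValidationError("concentration and prior hyperparameters must be > 0")


@dataclasses.dataclass
class ModuleSet:
    """A partition of genes into co-expression modules."""

    assignment: dict[str, str | None]  # gene -> module id (None = unassigned after filtering)
    n_modules: int
    log_posterior: float
    sizes: dict[str, int]

    def members(self, module_id: str) -> set[str]:
        return {g for g, m in self.assignment.items() if m == module_id}

    def modules(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {m: set() for m in self.sizes}
        for g, m in self.assignment.items():
            if m is not None:
                out[m].add(g)
        return out


def _standardize_rows(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return (X - mu) / sd


def _gene_stream(seed: int, gene_id: str) -> np.random.Generator:
    return np.random.default_rng([seed & 0x7FFFFFFF, zlib.crc32(gene_id.encode())])


class _CollapsedCRP:
    """Sufficient statistics and collapsed predictives for the CRP
    mixture of diagonal Gaussians.

    Cluster statistics live in preallocated arrays (rows 0..k-1 active);
    per-count Student-t constants are tabulated once, since cluster
    counts are integers.
    """

    def __init__(self, n_dims: int, n_genes: int, p: GibbsParams):
        self.p = p
        self.S = n_dims
        self.k = 0
        cap = 16
        self.ns = np.zeros(cap)
        self.sums = np.zeros((cap, n_dims))
        self.sqs = np.zeros((cap, n_dims))
        # tabulated constants for n = 0..n_genes
        n = np.arange(n_genes + 1, dtype=float)
        self._lam = p.prior_scale + n
        self._a = p.prior_shape + n / 2.0
        nu = 2.0 * self._a
        self._nu = nu
        self._tconst = gammaln((nu + 1) / 2) - gammaln(nu / 2) - 0.5 * np.log(np.pi * nu)
        self._sig_fac = (self._lam + 1.0) / (self._a * self._lam)
        self._bfac = p.prior_scale * n / (2.0 * self._lam)
        with np.errstate(divide="ignore"):
            self._logn = np.log(np.maximum(n, 1e-300))
        self._marg_const = (  # per-dim terms of the marginal that depend on n only
            gammaln(self._a) - gammaln(p.prior_shape)
            + p.prior_shape * np.log(p.prior_rate)
            + 0.5 * (np.log(p.prior_scale) - np.log(self._lam))
            - (n / 2.0) * np.log(2.0 * np.pi)
        )

    def _grow(self) -> None:
        cap = len(self.ns)
        self.ns = np.concatenate([self.ns, np.zeros(cap)])
        self.sums = np.vstack([self.sums, np.zeros((cap, self.S))])
        self.sqs = np.vstack([self.sqs, np.zeros((cap, self.S))])

    def add(self, c: int, x: np.ndarray) -> None:
        self.ns[c] += 1
        self.sums[c] += x
        self.sqs[c] += x * x

    def remove(self, c: int, x: np.ndarray) -> int | None:
        """Remove x from cluster c; returns the index of a deleted empty
        cluster (indices above it shift down), or None."""
        self.ns[c] -= 1
        if self.ns[c] == 0:
            k = self.k
            self.ns[c:k - 1] = self.ns[c + 1:k]
            self.sums[c:k - 1] = self.sums[c + 1:k]
            self.sqs[c:k - 1] = self.sqs[c + 1:k]
            self.ns[k - 1] = 0.0
            self.sums[k - 1] = 0.0
            self.sqs[k - 1] = 0.0
            self.k -= 1
            return c
        self.sums[c] -= x
        self.sqs[c] -= x * x
        return None

    def new_cluster(self, x: np.ndarray) -> int:
        if self.k == len(self.ns):
            self._grow()
        c = self.k
        self.ns[c] = 1
        self.sums[c] = x
        self.sqs[c] = x * x
        self.k += 1
        return c

    def log_pred(self, x: np.ndarray) -> np.ndarray:
        """Log CRP weight + collapsed Student-t predictive log density of
        x under each existing cluster and (last entry) a new cluster."""
        k = self.k
        if k == len(self.ns):
            self._grow()
        # rows 0..k-1 are existing clusters; row k is all-zero = new cluster
        n_idx = self.ns[:k + 1].astype(int)
        sums = self.sums[:k + 1]
        sqs = self.sqs[:k + 1]
        lam_n = self._lam[n_idx]
        safe_n = np.maximum(n_idx, 1)[:, None]
        xbar = sums / safe_n
        b_n = (self.p.prior_rate
               + 0.5 * (sqs - n_idx[:, None] * xbar**2)
               + self._bfac[n_idx][:, None] * xbar**2)
        mu_n = sums / lam_n[:, None]
        nu = self._nu[n_idx]
        sigma2 = b_n * self._sig_fac[n_idx][:, None]
        z2 = (x[None, :] - mu_n) ** 2 / (nu[:, None] * sigma2)
        logt = self._tconst[n_idx][:, None] - 0.5 * np.log(sigma2) \
            - ((nu + 1) / 2)[:, None] * np.log1p(z2)
        logp = logt.sum(axis=1)
        logp[:k] += self._logn[n_idx[:k]]
        logp[k] += np.log(self.p.concentration)
        return logp

    def log_marginal(self) -> float:
        """Collapsed log marginal likelihood of all clusters."""
        k = self.k
        n_idx = self.ns[:k].astype(int)
        sums, sqs = self.sums[:k], self.sqs[:k]
        xbar = sums / n_idx[:, None]
        b_n = (self.p.prior_rate + 0.5 * (sqs - n_idx[:, None] * xbar**2)
               + self._bfac[n_idx][:, None] * xbar**2)
        per_dim = self._marg_const[n_idx][:, None] - self._a[n_idx][:, None] * np.log(b_n)
        return float(per_dim.sum())

    def log_crp(self, n_total: int) -> float:
        g = self.p.concentration
        return float(self.k * np.log(g) + gammaln(self.ns[:self.k]).sum()
                     + gammaln(g) - gammaln(g + n_total))

    def log_joint(self, n_total: int) -> float:
        return self.log_crp(n_total) + self.log_marginal()


def gibbs_cluster(expr: OmicsMatrix, params: GibbsParams | None = None) -> ModuleSet:
    """Partition genes into co-expression modules over tumor samples.

    Profiles are standardized per gene; the sampler runs ``n_iter``
    sweeps and returns the maximum-a-posteriori sampled partition after
    burn-in.  Module ids are relabeled ``M01, M02, ...`` by decreasing
    size.
    """
    params = params or GibbsParams()
    samples = expr.tumor_samples
    if len(samples) < 2:
        raise ValidationError("need >=2 tumor samples for module discovery")
    genes = sorted(expr.feature_ids)
    X = _standardize_rows(expr.values.loc[genes, samples].to_numpy(float))
    n_genes = len(genes)

    if n_genes < params.min_module_size:
        logger.warning("fewer genes (%d) than min_module_size (%d): single unfiltered module",
                       n_genes, params.min_module_size)
        return ModuleSet({g: "M01" for g in genes}, 1, 0.0, {"M01": n_genes})

    crp = _CollapsedCRP(X.shape[1], n_genes, params)
    # init: every gene its own module (merges mix faster than splits)
    assign = np.zeros(n_genes, dtype=int)
    for i in range(n_genes):
        assign[i] = crp.new_cluster(X[i])
    init_log_joint = crp.log_joint(n_genes)
    init_assign = assign.copy()

    streams = [_gene_stream(params.seed, g) for g in genes]
    best_assign, best_lp = assign.copy(), -np.inf
    for sweep in range(params.n_iter):
        for i in range(n_genes):
            x = X[i]
            deleted = crp.remove(assign[i], x)
            if deleted is not None:
                assign[assign > deleted] -= 1
            logp = crp.log_pred(x)
            probs = np.exp(logp - logsumexp(logp))
            u = streams[i].random()
            c = int(np.searchsorted(np.cumsum(probs), u))
            c = min(c, crp.k)  # guard against floating cumsum < 1
            if c == crp.k:
                crp.new_cluster(x)
            else:
                crp.add(c, x)
            assign[i] = c
        if sweep >= params.burn_in:
            lp = crp.log_joint(n_genes)
            if lp > best_lp:
                best_lp, best_assign = lp, assign.copy()

    if best_lp < init_log_joint:  # MAP over sampled states never worse than init
        best_lp, best_assign = init_log_joint, init_assign

    # canonical labels by decreasing size, ties by smallest member id
    clusters: dict[int, list[str]] = {}
    for g, c in zip(genes, best_assign):
        clusters.setdefault(int(c), []).append(g)
    order = sorted(clusters, key=lambda c: (-len(clusters[c]), min(clusters[c])))
    width = max(2, len(str(len(order))))
    labels = {c: f"M{rank + 1:0{width}d}" for rank, c in enumerate(order)}
    assignment = {g: labels[int(c)] for g, c in zip(genes, best_assign)}
    sizes = {labels[c]: len(clusters[c]) for c in clusters}
    return ModuleSet(assignment, len(sizes), float(best_lp), sizes)


def filter_modules(ms: ModuleSet, min_size: int = 5) -> ModuleSet:
    """Drop modules smaller than ``min_size``; their genes become
    unassigned (``None``)."""
    keep = {m for m, n in ms.sizes.items() if n >= min_size}
    assignment = {g: (m if m in keep else None) for g, m in ms.assignment.items()}
    sizes = {m: n for m, n in ms.sizes.items() if m in keep}
    return ModuleSet(assignment, len(sizes), ms.log_posterior, sizes)
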