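"""Multi-trait case/control ascertainment from simulated genotypes.

Individuals are drawn from a genotype pool and assigned to shared controls or
one of D disease groups by a rejection scheme driven by per-disease logistic
disease probabilities: with baseline log-odds log(prevalence) and per-allele
log odds ratios at the causal SNPs, each candidate's disease probabilities
p_k are computed, a uniform u1 is compared against them, and ties (u1 below
several p_k) are broken by a second uniform.  Sampling continues until every
group quota is filled; each group is then truncated to its first N_k rows.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.special import expit

__all__ = [
    "SimulationSpec",
    "CaseControlStudy",
    "ExhaustionError",
    "assign_multitrait",
]


class ExhaustionError(RuntimeError):
    """Candidate pool exhausted before a group quota was filled."""


@dataclass(frozen=True)
class SimulationSpec:
    """Causal model and target sample sizes for a multi-disease simulation.

    ``causal_effects`` lists (snp_id, disease_index, odds_ratio) with disease
    indices 1..D; ``target_counts`` gives N_0..N_D (controls first).  The
    odds ratio is per minor-allele copy (multiplicative model) and the
    baseline log-odds is log(prevalence).
    """

    causal_effects: tuple[tuple[str, int, float], ...]
    target_counts: tuple[int, ...]
    prevalence: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        for snp, k, orr in self.causal_effects:
            if orr <= 0:
                raise ValueError(f"odds ratio for {snp!r} must be > 0, got {orr}")
            if not 1 <= k <= self.n_diseases:
                raise ValueError(f"disease index {k} outside 1..{self.n_diseases}")
        if sum(self.target_counts) < 0 or len(self.target_counts) < 2:
            raise ValueError("target_counts must list N_0..N_D")
        if not 0 < self.prevalence < 1:
            raise ValueError("prevalence must be in (0, 1)")

    @property
    def n_diseases(self) -> int:
        return len(self.target_counts) - 1


@dataclass
class CaseControlStudy:
    """Dosage matrix with multi-class status (0 = shared controls)."""

    dosages: np.ndarray
    snp_ids: list[str]
    status: np.ndarray
    covariates: np.ndarray = field(default=None)  # type: ignore[assignment]
    population: np.ndarray = field(default=None)  # type: ignore[assignment]
    shared_controls: bool = True
    positions: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        self.status = np.asarray(self.status, dtype=np.int32)
        n = self.dosages.shape[0]
        if len(self.status) != n:
            raise ValueError("status length must match dosage rows")
        if self.dosages.shape[1] != len(self.snp_ids):
            raise ValueError("snp_ids must match dosage columns")
        if self.covariates is None:
            self.covariates = np.empty((n, 0))
        self.covariates = np.asarray(self.covariates, dtype=float)
        if self.population is None:
            self.population = np.array(["pop1"] * n)
        self.population = np.asarray(self.population)
        if self.positions is None:
            self.positions = np.arange(1, len(self.snp_ids) + 1) * 1000
        for pop in np.unique(self.population):
            mask = self.population == pop
            st = self.status[mask]
            if np.any(st > 0) and not np.any(st == 0):
                raise ValueError(f"population {pop!r} has cases but no controls")

    @property
    def n_ind(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_diseases(self) -> int:
        return int(self.status.max(initial=0))

    def class_counts(self) -> np.ndarray:
        return np.bincount(self.status, minlength=self.n_diseases + 1)

    def snp_index(self, snp_id: str) -> int:
        return self.snp_ids.index(snp_id)

    def maf(self) -> np.ndarray:
        return self.dosages.mean(axis=0) / 2.0


def assign_multitrait(
    genotypes: np.ndarray,
    snp_ids: Sequence[str],
    spec: SimulationSpec,
    genotype_factory: Callable[[int, int], np.ndarray] | None = None,
    max_factor: int = 100,
) -> CaseControlStudy:
    """Ascertain control/disease status for candidates until quotas are met.

    ``genotypes`` seeds the candidate pool; when it runs out,
    ``genotype_factory(n, seed)`` is called for further batches.  At most
    ``max_factor * sum(target_counts)`` candidates are considered before an
    :class:`ExhaustionError` names the group still short of its quota.

    For two diseases the assignment follows the two-uniform scheme exactly
    (the tie between diseases is broken by u2 < 0.5 with a quota check on
    disease 1); for D > 2 the tie-break is a uniform choice among the tied
    diseases with unfilled quotas.
    """
    genotypes = np.asarray(genotypes)
    snp_ids = list(snp_ids)
    targets = np.asarray(spec.target_counts, dtype=int)
    d = spec.n_diseases
    rng = np.random.default_rng(spec.seed)
    beta0 = np.log(spec.prevalence)
    # per-disease effect vectors over causal columns
    causal_idx: dict[str, int] = {}
    for snp, _, _ in spec.causal_effects:
        if snp not in snp_ids:
            raise ValueError(f"causal SNP {snp!r} not present in genotypes")
        causal_idx[snp] = snp_ids.index(snp)
    cols = sorted(set(causal_idx.values()))
    beta = np.zeros((len(cols), d))
    for snp, k, orr in spec.causal_effects:
        beta[cols.index(causal_idx[snp]), k - 1] += np.log(orr)

    groups: list[list[np.ndarray]] = [[] for _ in range(d + 1)]
    n = np.zeros(d + 1, dtype=int)
    cap = max_factor * max(int(targets.sum()), 1)
    pool = genotypes
    used = 0
    batch = 1
    while np.any(n < targets):
        if pool.shape[0] == 0 or used > 0:
            if genotype_factory is None:
                short = int(np.argmin(n - targets))
                raise ExhaustionError(
                    f"genotype pool exhausted with group {short} at "
                    f"{n[short]}/{targets[short]}"
                )
            pool = np.asarray(genotype_factory(max(pool.shape[0], 1000), spec.seed + batch))
            batch += 1
        # vectorised disease probabilities and uniforms for the whole pool;
        # the per-candidate pass below only resolves quota-dependent ties
        x = pool[:, cols].astype(float)
        p = expit(beta0 + x @ beta)  # (pool, d)
        if d == 2:
            u = rng.random((pool.shape[0], 2))
        else:
            u = rng.random((pool.shape[0], 1))
        u1 = u[:, 0]
        hits = u1[:, None] <= p
        n_hits = hits.sum(axis=1)
        provisional = np.where(n_hits == 0, 0, np.argmax(hits, axis=1) + 1)
        if d == 1:
            # no tie-breaks possible: take the first N_k of each class directly
            for k in (0, 1):
                need = targets[k] - n[k]
                if need > 0:
                    take = np.where(provisional == k)[0][:need]
                    groups[k].extend(pool[take])
                    n[k] += len(take)
            if np.any(n < targets):
                used += pool.shape[0]
                if used >= cap:
                    short = int(np.argmin(n - targets))
                    raise ExhaustionError(
                        f"exceeded {cap} candidates with group {short} at "
                        f"{n[short]}/{targets[short]} — check prevalence/targets"
                    )
            continue
        for j in range(pool.shape[0]):
            if not np.any(n < targets):
                break
            if used >= cap:
                short = int(np.argmin(n - targets))
                raise ExhaustionError(
                    f"exceeded {cap} candidates with group {short} at "
                    f"{n[short]}/{targets[short]} — check prevalence/targets"
                )
            used += 1
            if n_hits[j] <= 1:
                k = int(provisional[j])
            elif d == 2:
                k = 1 if (u[j, 1] < 0.5 and n[1] < targets[1]) else 2
            else:
                hit = np.where(hits[j])[0] + 1
                unfilled = [kk for kk in hit if n[kk] < targets[kk]]
                k = int(rng.choice(unfilled if unfilled else hit))
            n[k] += 1
            if n[k] <= targets[k]:
                groups[k].append(pool[j])

    rows = []
    status = []
    for k in range(d + 1):
        kept = groups[k][: targets[k]]
        rows.extend(kept)
        status.extend([k] * len(kept))
    if rows:
        dosages = np.vstack(rows)
    else:
        dosages = np.empty((0, genotypes.shape[1]), dtype=np.int8)
    return CaseControlStudy(
        dosages=dosages,
        snp_ids=snp_ids,
        status=np.array(status, dtype=np.int32),
        shared_controls=True,
    )
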