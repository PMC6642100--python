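"""Haplotype frequency estimation and haplotype disease-risk effects.

Phase over a small set of SNPs (k <= 10) is resolved by an EM algorithm on
unphased genotypes: the E-step distributes each individual's genotype over
its compatible ordered haplotype pairs under Hardy-Weinberg, the M-step
re-estimates haplotype frequencies from expected counts.  Disease effects
per haplotype (log OR with 95% CI against the most frequent haplotype) are
estimated by drawing several phase imputations from the per-individual
posterior, fitting a logistic regression of status on haplotype counts in
each, and pooling with the standard multiple-imputation rules
(point estimate = mean; variance = within + (1 + 1/m) between, with the
Barnard-Rubin degrees of freedom for the CI).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from ._glm import fit_logistic_safe
from .simulate import CaseControlStudy

__all__ = [
    "HaplotypeTable",
    "EMResult",
    "em_haplotypes",
    "haplotype_effects",
]

OTHER = "other"


@dataclass
class EMResult:
    """Converged EM state over the 2^k haplotypes of the selected SNPs."""

    haplotypes: list[str]  # allele strings, e.g. "010"
    freq: np.ndarray
    posterior: list[list[tuple[int, int, float]]]  # per ind: (h1, h2, prob)
    loglik_trace: list[float]
    converged: bool


def _compatible_pairs(geno: np.ndarray, k: int) -> list[tuple[int, int]]:
    """Unordered haplotype index pairs consistent with a genotype vector.

    Missing genotypes (negative or NaN) are marginalised over both alleles.
    """
    options: list[list[tuple[int, int]]] = []
    for g in geno:
        if np.isnan(g) or g < 0:
            options.append([(0, 0), (0, 1), (1, 0), (1, 1)])
        elif g == 0:
            options.append([(0, 0)])
        elif g == 2:
            options.append([(1, 1)])
        else:
            options.append([(0, 1), (1, 0)])
    pairs = set()
    for combo in itertools.product(*options):
        h1 = 0
        h2 = 0
        for bit1, bit2 in combo:
            h1 = (h1 << 1) | bit1
            h2 = (h2 << 1) | bit2
        pairs.add((min(h1, h2), max(h1, h2)))
    return sorted(pairs)


def em_haplotypes(
    dosages: np.ndarray,
    max_iter: int = 200,
    tol: float = 1e-8,
) -> EMResult:
    """EM haplotype-frequency estimation over k <= 10 SNPs.

    ``dosages`` is individuals x k with values {0,1,2} (NaN or negative =
    missing, marginalised in the E-step).  The log-likelihood is
    non-decreasing across iterations; convergence is declared when its
    change drops below ``tol``.
    """
    G = np.asarray(dosages, dtype=float)
    n, k = G.shape
    if k > 10:
        raise ValueError(
            f"{k} SNPs would enumerate 2^{k} haplotypes; restrict to <= 10 "
            "SNPs (haplotype analyses target small credible sets)"
        )
    n_hap = 2**k
    haplotypes = [format(h, f"0{k}b") for h in range(n_hap)]
    pair_lists = [_compatible_pairs(G[i], k) for i in range(n)]
    freq = np.full(n_hap, 1.0 / n_hap)
    trace: list[float] = []
    converged = False
    for _ in range(max_iter):
        ll = 0.0
        counts = np.zeros(n_hap)
        post: list[list[tuple[int, int, float]]] = []
        for pairs in pair_lists:
            ws = np.array(
                [(2.0 if h1 != h2 else 1.0) * freq[h1] * freq[h2] for h1, h2 in pairs]
            )
            tot = ws.sum()
            if tot <= 0:
                # degenerate frequencies; re-spread to keep EM total
                ws = np.ones(len(pairs))
                tot = ws.sum()
            ll += np.log(tot)
            ws /= tot
            post.append([(h1, h2, float(w)) for (h1, h2), w in zip(pairs, ws)])
            for (h1, h2), w in zip(pairs, ws):
                counts[h1] += w
                counts[h2] += w
        trace.append(float(ll))
        freq_new = counts / (2 * n)
        if len(trace) > 1 and trace[-1] - trace[-2] < tol:
            converged = True
            freq = freq_new
            break
        freq = freq_new
    return EMResult(
        haplotypes=haplotypes,
        freq=freq,
        posterior=post,
        loglik_trace=trace,
        converged=converged,
    )


@dataclass
class HaplotypeTable:
    """Per-haplotype frequency and pooled disease effect vs the reference."""

    haplotypes: list[str]
    freq: np.ndarray
    log_or: np.ndarray
    ci_lo: np.ndarray
    ci_hi: np.ndarray
    reference: str

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "haplotype": self.haplotypes,
                "freq": self.freq,
                "logOR": self.log_or,
                "ci_lo": self.ci_lo,
                "ci_hi": self.ci_hi,
            }
        )


def haplotype_effects(
    study: CaseControlStudy,
    snps: list[str],
    disease: int = 1,
    n_imputations: int = 10,
    seed: int = 0,
    pool_floor: float = 0.01,
    em_kwargs: dict | None = None,
) -> HaplotypeTable:
    """Haplotype log ORs with 95% CI for one disease vs shared controls.

    Phase is estimated by :func:`em_haplotypes` on all individuals of the
    disease/control subset; ``n_imputations`` phase draws are analysed by
    logistic regression of status on per-haplotype counts (reference = most
    frequent haplotype; haplotypes rarer than ``pool_floor`` pooled into
    "other") and combined with Rubin's rules.  Covariates in the study are
    included in every fit.
    """
    mask = (study.status == 0) | (study.status == disease)
    idx = [study.snp_index(s) for s in snps]
    G = study.dosages[mask][:, idx].astype(float)
    y = (study.status[mask] == disease).astype(float)
    covars = study.covariates[mask]
    em = em_haplotypes(G, **(em_kwargs or {}))
    if not em.converged:
        warnings.warn("EM did not converge; effects use the final iterate")
    # keep common haplotypes; pool the rest
    keep = [h for h in range(len(em.haplotypes)) if em.freq[h] >= pool_floor]
    keep.sort(key=lambda h: -em.freq[h])
    if not keep:
        raise ValueError("no haplotype reaches the pooling floor")
    ref = keep[0]
    others = keep[1:]
    labels = [em.haplotypes[h] for h in others]
    pooled_mass = float(
        sum(em.freq[h] for h in range(len(em.haplotypes)) if h not in keep)
    )
    has_other = pooled_mass > 1e-6
    cols = labels + ([OTHER] if has_other else [])

    rng = np.random.default_rng(seed)
    n = G.shape[0]
    ests = []
    variances = []
    for _ in range(n_imputations):
        X_h = np.zeros((n, len(cols)))
        for i, pairs in enumerate(em.posterior):
            probs = np.array([w for _, _, w in pairs])
            j = rng.choice(len(pairs), p=probs / probs.sum())
            h1, h2, _ = pairs[j]
            for h in (h1, h2):
                if h == ref:
                    continue
                if h in others:
                    X_h[i, others.index(h)] += 1
                elif has_other:
                    X_h[i, len(labels)] += 1
        X = np.concatenate([np.ones((n, 1)), covars, X_h], axis=1)
        fit = fit_logistic_safe(X, y)
        sl = slice(1 + covars.shape[1], None)
        ests.append(fit.beta[sl].copy())
        variances.append(np.diag(fit.cov)[sl].copy())
    est = np.mean(ests, axis=0)
    within = np.mean(variances, axis=0)
    if n_imputations > 1:
        between = np.var(ests, axis=0, ddof=1)
    else:
        between = np.zeros_like(est)
    m = n_imputations
    total_var = within + (1 + 1 / m) * between
    # Barnard-Rubin small-sample df; infinite when between-variance is 0
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (1 + 1 / m) * between / within
        df = np.where(r > 0, (m - 1) * (1 + 1 / r) ** 2, np.inf)
    tcrit = np.where(np.isinf(df), stats.norm.ppf(0.975), stats.t.ppf(0.975, np.where(np.isinf(df), 1, df)))
    half = tcrit * np.sqrt(total_var)

    haps = [em.haplotypes[ref]] + [em.haplotypes[h] for h in others]
    freqs = [em.freq[ref]] + [em.freq[h] for h in others]
    log_or = [0.0] + list(est[: len(others)])
    lo = [0.0] + list(est[: len(others)] - half[: len(others)])
    hi = [0.0] + list(est[: len(others)] + half[: len(others)])
    if has_other:
        haps.append(OTHER)
        freqs.append(pooled_mass)
        log_or.append(float(est[-1]))
        lo.append(float(est[-1] - half[-1]))
        hi.append(float(est[-1] + half[-1]))
    return HaplotypeTable(
        haplotypes=haps,
        freq=np.array(freqs),
        log_or=np.array(log_or),
        ci_lo=np.array(lo),
        ci_hi=np.array(hi),
        reference=em.haplotypes[ref],
    )
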