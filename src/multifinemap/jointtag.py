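"""Expected GWAS Z-scores under specified causal models and joint-tag scans.

A non-causal SNP carried on haplotypes together with two distinct causal
variants of similar effect can attain a smaller expected single-SNP p-value
than either causal variant — the joint-tagging phenomenon that traps
forward stepwise selection.  This module computes first-order expected
score-test Z profiles for arbitrary causal sets,

    E[Z_j] = sqrt(n0 n1 / (n0 + n1)) * sum_c rho_jc * gamma_c * sigma_c,

with rho the genotype correlation, gamma the causal log odds ratios and
sigma_c = sqrt(2 f_c (1 - f_c)) under Hardy-Weinberg, and uses them to find
the minimum-expected-p SNP, build odds-ratio-grid "sunbeam" classifications
for SNP trios, and scan panels for potential joint tags.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy import stats

from .panel import HaplotypePanel

__all__ = [
    "ExpectedZProfile",
    "expected_z",
    "min_p_snp",
    "sunbeam",
    "trio_scan",
    "z_threshold_for_p",
]


def z_threshold_for_p(p: float = 5e-8) -> float:
    """Two-sided |Z| threshold equivalent to significance level p."""
    return float(stats.norm.isf(p / 2))


@dataclass(frozen=True)
class ExpectedZProfile:
    """Per-SNP expected Z under a causal model, with the inputs that built it."""

    snp_ids: tuple[str, ...]
    z: np.ndarray
    causal: dict[str, float]  # SNP id -> log OR (natural log)
    n0: int
    n1: int

    def __getitem__(self, snp: str) -> float:
        return float(self.z[self.snp_ids.index(snp)])


def expected_z(
    panel: HaplotypePanel,
    causal: Mapping[str, float],
    n0: int,
    n1: int,
) -> ExpectedZProfile:
    """First-order expected single-SNP score-test Z at every panel SNP.

    ``causal`` maps SNP ids to log odds ratios (natural log, per
    minor-allele copy).  Monomorphic-in-practice SNPs (zero variance in the
    panel) get E[Z] = 0 with a warning.
    """
    if n0 < 1 or n1 < 1:
        raise ValueError("n0 and n1 must be >= 1")
    for snp in causal:
        if snp not in panel.snp_ids:
            raise ValueError(f"causal SNP {snp!r} not in panel")
    f = panel.maf
    sigma = np.sqrt(2 * f * (1 - f))
    rho = panel.r_matrix()
    mono = sigma == 0
    if mono.any():
        warnings.warn("monomorphic SNPs present; their expected Z is set to 0")
        rho = np.nan_to_num(rho)
    scale = np.sqrt(n0 * n1 / (n0 + n1))
    z = np.zeros(panel.n_snp)
    for snp, gamma in causal.items():
        c = panel.snp_ids.index(snp)
        z += rho[:, c] * gamma * sigma[c]
    z *= scale
    z[mono] = 0.0
    return ExpectedZProfile(
        snp_ids=tuple(panel.snp_ids),
        z=z,
        causal=dict(causal),
        n0=n0,
        n1=n1,
    )


def min_p_snp(
    profile: ExpectedZProfile, z_threshold: float | None = None
) -> str | None:
    """SNP with the smallest expected p-value, or None below threshold.

    Returns argmax |E[Z]| when it reaches ``z_threshold`` (default: the
    two-sided 5e-8 genome-wide level), else None; ties break by SNP id.
    """
    if len(profile.snp_ids) == 0:
        raise ValueError("empty profile")
    if z_threshold is None:
        z_threshold = z_threshold_for_p()
    absz = np.abs(profile.z)
    mx = absz.max()
    ties = [i for i in range(len(absz)) if absz[i] == mx]
    best = min(ties, key=lambda i: profile.snp_ids[i])
    if absz[best] < z_threshold:
        return None
    return profile.snp_ids[best]


def sunbeam(
    trio: HaplotypePanel,
    or_grid_1: np.ndarray,
    or_grid_2: np.ndarray,
    n0: int,
    n1: int,
    z_threshold: float | None = None,
):
    """Odds-ratio-grid winner classification for a 3-SNP trio.

    SNPs 1 and 2 are causal with the grid odds ratios; SNP 3 is the
    candidate tag.  Returns a DataFrame (or1, or2, winner) where winner is
    the trio SNP with the smallest expected p-value, or "none" where no SNP
    reaches the significance threshold (the white region of the plot).
    """
    import pandas as pd

    if trio.n_snp != 3:
        raise ValueError("sunbeam needs a 3-SNP trio panel")
    s1, s2, _ = trio.snp_ids
    rows = []
    for or1 in np.asarray(or_grid_1, dtype=float):
        for or2 in np.asarray(or_grid_2, dtype=float):
            prof = expected_z(
                trio, {s1: np.log(or1), s2: np.log(or2)}, n0, n1
            )
            winner = min_p_snp(prof, z_threshold)
            rows.append({"or1": or1, "or2": or2, "winner": winner or "none"})
    return pd.DataFrame(rows)


def trio_scan(
    panel: HaplotypePanel,
    maf_min: float = 0.05,
    n0: int = 5000,
    n1: int = 5000,
) -> dict:
    """Scan all SNP trios for potential joint tags under equal causal ORs.

    For each unordered pair of candidate causal SNPs (MAF > ``maf_min``) and
    each third SNP, the third is flagged as a potential joint tag when
    |E[Z_tag]| strictly exceeds both causal SNPs' |E[Z]|.  Under equal log
    odds ratios the comparison is invariant to the common OR magnitude
    (gamma factors out of every |E[Z]| ratio), so no magnitude need be
    chosen.  Returns the fraction of flagged trios and the fraction of
    causal pairs with at least one potential tag.
    """
    eligible = [i for i, f in enumerate(panel.maf) if f > maf_min]
    if len(eligible) < 3:
        return {"trio_fraction": 0.0, "pair_fraction": 0.0, "n_trios": 0, "n_pairs": 0}
    f = panel.maf
    sigma = np.sqrt(2 * f * (1 - f))
    rho = panel.r_matrix()
    n_trio = 0
    n_flag = 0
    n_pair = 0
    n_pair_tagged = 0
    for ai in range(len(eligible)):
        for bi in range(ai + 1, len(eligible)):
            a, b = eligible[ai], eligible[bi]
            n_pair += 1
            tagged = False
            # |E[Z_j]| proportional to |rho_ja sigma_a + rho_jb sigma_b|
            score = np.abs(rho[:, a] * sigma[a] + rho[:, b] * sigma[b])
            for j in range(panel.n_snp):
                if j == a or j == b:
                    continue
                n_trio += 1
                if score[j] > max(score[a], score[b]):
                    n_flag += 1
                    tagged = True
            if tagged:
                n_pair_tagged += 1
    return {
        "trio_fraction": n_flag / n_trio if n_trio else 0.0,
        "pair_fraction": n_pair_tagged / n_pair if n_pair else 0.0,
        "n_trios": n_trio,
        "n_pairs": n_pair,
    }
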