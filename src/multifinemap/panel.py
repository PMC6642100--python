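"""Synthetic haplotype panels with block-structured linkage disequilibrium.

A :class:`HaplotypePanel` holds phased binary haplotypes (rows) over SNPs
(columns), coded so that 1 is the minor allele.  Panels are the source of LD
and allele-frequency structure for everything downstream: genotype
resampling, case/control ascertainment, expected-Z computations and the
three-SNP "joint tag" constructions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.stats import multivariate_normal, norm

__all__ = [
    "HaplotypePanel",
    "InfeasibleLDError",
    "make_block_panel",
    "sample_genotypes",
    "embed_trio",
]


class InfeasibleLDError(ValueError):
    """Requested MAF/correlation combination admits no haplotype distribution."""


@dataclass
class HaplotypePanel:
    """Phased binary haplotypes (haplotypes x SNPs, 1 = minor allele)."""

    alleles: np.ndarray
    snp_ids: list[str]
    positions: np.ndarray
    maf: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        if self.alleles.ndim != 2:
            raise ValueError("alleles must be a 2-d matrix")
        if self.alleles.shape[1] != len(self.snp_ids):
            raise ValueError("snp_ids length must match number of columns")
        if len(self.positions) != len(self.snp_ids):
            raise ValueError("positions length must match number of columns")
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")
        freq = self.alleles.mean(axis=0)
        if np.any(freq == 0):
            bad = [self.snp_ids[i] for i in np.where(freq == 0)[0]]
            raise ValueError(f"monomorphic SNPs not allowed in a panel: {bad}")
        if np.any(freq > 0.5):
            raise ValueError("alleles must be minor-coded (column mean <= 0.5)")
        self.maf = freq

    @property
    def n_hap(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_snp(self) -> int:
        return self.alleles.shape[1]

    def r_matrix(self) -> np.ndarray:
        """Pairwise haplotype allele correlation (signed r, not r^2)."""
        return np.corrcoef(self.alleles.astype(float), rowvar=False)


def _minor_code(alleles: np.ndarray) -> np.ndarray:
    """Flip columns so the coded allele is the minor one; fix empty columns."""
    alleles = alleles.astype(np.int8)
    freq = alleles.mean(axis=0)
    flip = freq > 0.5
    alleles[:, flip] = 1 - alleles[:, flip]
    # a drawn column may come out monomorphic at small n; give it one copy of
    # the minor allele so MAF invariants hold
    zero = alleles.sum(axis=0) == 0
    if zero.any():
        alleles[0, zero] = 1
    return alleles


def _latent_rho_for_binary_r(target_r: float, maf: float) -> float:
    """Latent Gaussian correlation giving binary (phi) correlation target_r.

    Alleles are thresholded Gaussians: X = 1[Z > qnorm(1-maf)].  The binary
    correlation is attenuated relative to the latent one; invert numerically.
    """
    if target_r <= 0:
        return 0.0
    tau = norm.ppf(1 - maf)

    def binary_r(rho: float) -> float:
        if rho >= 1:
            return 1.0
        cov = [[1.0, rho], [rho, 1.0]]
        p11 = 1 - 2 * norm.cdf(tau) + multivariate_normal(cov=cov).cdf([tau, tau])
        return (p11 - maf**2) / (maf * (1 - maf))

    if binary_r(0.9999) <= target_r:
        return 0.9999
    return brentq(lambda rho: binary_r(rho) - target_r, 0.0, 0.9999, xtol=1e-6)


def make_block_panel(
    n_hap: int,
    block_sizes: Sequence[int],
    within_block_r: float,
    maf_range: tuple[float, float] = (0.05, 0.5),
    seed: int = 0,
) -> HaplotypePanel:
    """Generate a panel of independent LD blocks with a target within-block r.

    Each block draws a single MAF from ``maf_range`` (shared by its SNPs —
    binary correlation is bounded above by MAF mismatch, so matched
    frequencies are required to realise arbitrary targets) and an
    equicorrelated latent Gaussian thresholded at the MAF quantile.  Blocks
    are mutually independent.
    """
    if n_hap < 100:
        raise ValueError("n_hap must be >= 100")
    if not (0 <= within_block_r < 1):
        raise ValueError("within_block_r must be in [0, 1)")
    lo, hi = maf_range
    if not (0 < lo <= hi <= 0.5):
        raise ValueError(f"infeasible maf_range {maf_range}: need 0 < lo <= hi <= 0.5")
    rng = np.random.default_rng(seed)
    cols = []
    for size in block_sizes:
        maf = rng.uniform(lo, hi)
        rho = _latent_rho_for_binary_r(within_block_r, maf) if size > 1 else 0.0
        tau = norm.ppf(1 - maf)
        shared = rng.standard_normal((n_hap, 1))
        noise = rng.standard_normal((n_hap, size))
        z = np.sqrt(rho) * shared + np.sqrt(1 - rho) * noise
        cols.append((z > tau).astype(np.int8))
    alleles = _minor_code(np.concatenate(cols, axis=1))
    n_snp = alleles.shape[1]
    ids = [f"snp{i + 1}" for i in range(n_snp)]
    positions = np.arange(1, n_snp + 1) * 1000
    return HaplotypePanel(alleles=alleles, snp_ids=ids, positions=positions)


def sample_genotypes(
    panel: HaplotypePanel,
    n_ind: int,
    switch_rate: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Diploid genotypes (individuals x SNPs, {0,1,2}) by mosaic resampling.

    Each individual is the sum of two mosaic haplotypes: a haplotype copies a
    random panel row and, at each SNP interval, switches to a fresh random
    template row with probability ``switch_rate``.  With switch_rate = 0
    haplotypes are exact panel rows; with switch_rate = 1 per-SNP allele
    frequencies are preserved but all LD is destroyed.
    """
    if panel.n_hap == 0 or panel.n_snp == 0:
        raise ValueError("cannot sample from an empty panel")
    if n_ind < 1:
        raise ValueError("n_ind must be >= 1")
    if not (0 <= switch_rate <= 1):
        raise ValueError("switch_rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    m = 2 * n_ind
    s = panel.n_snp
    # segment index at each SNP for each mosaic haplotype
    if switch_rate == 0:
        seg = np.zeros((m, s), dtype=np.int32)
    else:
        switches = rng.random((m, s - 1)) < switch_rate
        seg = np.zeros((m, s), dtype=np.int32)
        np.cumsum(switches, axis=1, out=seg[:, 1:])
    templates = rng.integers(0, panel.n_hap, size=(m, s), dtype=np.int32)
    rows = np.take_along_axis(templates, seg, axis=1)
    hap = panel.alleles[rows, np.arange(s)[None, :]]
    return (hap[0::2] + hap[1::2]).astype(np.int8)


def embed_trio(
    maf1: float,
    maf2: float,
    maf3: float,
    r12: float,
    r13: float,
    r23: float,
    n_hap: int = 10000,
) -> HaplotypePanel:
    """Build a 3-SNP panel realising prescribed MAFs and pairwise correlations.

    The 8 haplotype frequencies are determined by the three MAFs, the three
    pairwise moments and one free triple moment t = P(1,1,1); every cell
    probability is linear in t, so feasibility reduces to a non-empty
    interval for t.  The returned panel uses largest-remainder rounding of
    the frequencies to ``n_hap`` haplotype counts.
    """
    f = np.array([maf1, maf2, maf3], dtype=float)
    if np.any((f <= 0) | (f > 0.5)):
        raise InfeasibleLDError(f"MAFs must be in (0, 0.5], got {f}")
    sd = np.sqrt(f * (1 - f))
    r = {(0, 1): r12, (0, 2): r13, (1, 2): r23}
    m = {}
    for (i, j), rij in r.items():
        mij = f[i] * f[j] + rij * sd[i] * sd[j]
        lo = max(0.0, f[i] + f[j] - 1.0)
        hi = min(f[i], f[j])
        if mij < lo - 1e-12 or mij > hi + 1e-12:
            raise InfeasibleLDError(
                f"pairwise moment P(x{i + 1}=1,x{j + 1}=1)={mij:.4f} for "
                f"r={rij} violates Frechet bounds [{lo:.4f}, {hi:.4f}]"
            )
        m[(i, j)] = float(np.clip(mij, lo, hi))
    m12, m13, m23 = m[(0, 1)], m[(0, 2)], m[(1, 2)]
    t_lo = max(0.0, m12 + m13 - f[0], m12 + m23 - f[1], m13 + m23 - f[2])
    t_hi = min(m12, m13, m23, 1 - f.sum() + m12 + m13 + m23)
    if t_lo > t_hi + 1e-12:
        raise InfeasibleLDError(
            "no valid haplotype frequency vector: triple-moment bounds "
            f"require t in [{t_lo:.4f}, {t_hi:.4f}] (empty); the haplotype "
            "frequency constraint max(pairwise sums) <= min(pairwise moments) "
            "is violated"
        )
    t = 0.5 * (t_lo + t_hi)
    p = np.empty(8)
    # cells indexed by bits (x1, x2, x3)
    p[0b111] = t
    p[0b110] = m12 - t
    p[0b101] = m13 - t
    p[0b011] = m23 - t
    p[0b100] = f[0] - m12 - m13 + t
    p[0b010] = f[1] - m12 - m23 + t
    p[0b001] = f[2] - m13 - m23 + t
    p[0b000] = 1 - f.sum() + m12 + m13 + m23 - t
    p = np.clip(p, 0.0, None)
    p /= p.sum()
    counts = _largest_remainder(p, n_hap)
    rows = []
    for cell in range(8):
        bits = [(cell >> 2) & 1, (cell >> 1) & 1, cell & 1]
        rows.extend([bits] * counts[cell])
    alleles = np.array(rows, dtype=np.int8)
    return HaplotypePanel(
        alleles=alleles,
        snp_ids=["snp1", "snp2", "snp3"],
        positions=np.array([1000, 2000, 3000]),
    )


def _largest_remainder(p: np.ndarray, total: int) -> np.ndarray:
    scaled = p * total
    counts = np.floor(scaled).astype(int)
    short = total - counts.sum()
    order = np.argsort(-(scaled - counts))
    counts[order[:short]] += 1
    return counts
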