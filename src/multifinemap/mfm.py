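"""Joint fine-mapping of multiple diseases with shared controls.

A *configuration* assigns one causal-variant model to each disease.  The
multinomial Bayes factor of a configuration against the all-null
configuration is approximated by the sum of the per-disease logistic log
Bayes factors plus an offset determined by sample and model sizes
(:func:`multinomial_offset`); information is borrowed between diseases by a
sharing prior that multiplies the weight of configurations in which any two
diseases share a causal SNP by a factor kappa.  Per-disease marginal
posteriors are computed by a decomposition over per-disease aggregate sums
and SNP-indexed disjointness sums, never by enumerating the configuration
cross-product (the alternative per-pair kappa policy, which has no such
decomposition, enumerates under a cost cap).

kappa is calibrated from a target prior probability that no pair of
diseases shares a causal variant; for d diseases the default target is
0.5^sqrt(d-1).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .finemap import ModelPosterior, SNPModel

__all__ = [
    "SharingPrior",
    "JointResult",
    "CostCapError",
    "no_sharing_target",
    "pairwise_disjoint_prob",
    "kappa_from_no_share_prob",
    "calibrate_kappa",
    "prior_no_sharing",
    "multinomial_offset",
    "joint_logbf",
    "combine",
    "combine_multipop",
]

logger = logging.getLogger(__name__)


class CostCapError(RuntimeError):
    """Decomposed combination exceeded its cost cap.

    Drop models below a posterior-probability floor (e.g. truncate each
    disease's posterior to cumulative pp 0.9999) and renormalise, or raise
    the cap.
    """


def no_sharing_target(d: int) -> float:
    """Default prior probability that d diseases share no causal variant.

    0.5^sqrt(d-1): the exponent is the geometric mean of the exponents in
    the extremes 0.5^(d-1) (all pairs independent) and 0.5^1 (fully
    dependent diseases).
    """
    if d < 1:
        raise ValueError(f"d must be >= 1, got {d}")
    return 0.5 ** math.sqrt(d - 1)


@dataclass(frozen=True)
class SharingPrior:
    """kappa-weighted configuration prior over per-disease model priors."""

    kappa: float
    target_no_sharing: float
    n_diseases: int
    policy: str = "any"  # "any": kappa once if any pair shares; "pair": kappa^pairs

    def __post_init__(self) -> None:
        if self.kappa < 1:
            raise ValueError(f"kappa must be >= 1, got {self.kappa}")
        if not 0 < self.target_no_sharing <= 1:
            raise ValueError("target_no_sharing must be in (0, 1]")
        if self.n_diseases < 1:
            raise ValueError("n_diseases must be >= 1")
        if self.policy not in ("any", "pair"):
            raise ValueError(f"unknown sharing policy {self.policy!r}")


# ---------------------------------------------------------------------------
# kappa calibration


def pairwise_disjoint_prob(
    p_snps: int, expected_causals: Sequence[float]
) -> float:
    """P(models of all diseases are pairwise disjoint) under kappa = 1.

    Each disease draws a model independently: size k ~ Binomial(p_snps, pi_i)
    with pi_i = expected_i/p_snps, uniform over the C(p_snps, k) models of
    that size.  All-pairs disjointness is equivalent to each successive model
    avoiding the union of its predecessors, giving an exact dynamic
    programme over the cumulative number of occupied SNPs.
    """
    if p_snps < 1:
        raise ValueError("p_snps must be >= 1")
    dp = {0: 1.0}
    for exp_c in expected_causals:
        pi = exp_c / p_snps
        if not 0 < pi < 1:
            raise ValueError(f"expected_causals {exp_c} outside (0, p_snps)")
        new: dict[int, float] = {}
        for occupied, prob in dp.items():
            free = p_snps - occupied
            for k in range(free + 1):
                # P(size k) * P(model avoids the occupied set)
                w = (
                    math.comb(p_snps, k)
                    * pi**k
                    * (1 - pi) ** (p_snps - k)
                    * (math.comb(free, k) / math.comb(p_snps, k))
                )
                if w > 0:
                    new[occupied + k] = new.get(occupied + k, 0.0) + prob * w
        dp = new
    return float(sum(dp.values()))


def kappa_from_no_share_prob(no_share_kappa1: float, target_no_sharing: float) -> float:
    """Closed-form kappa hitting a no-sharing target.

    With the any-sharing indicator weight, the prior no-sharing mass at
    weight kappa is A/(A + kappa (1-A)) where A is the kappa = 1 mass;
    solving for the target t gives kappa = A(1-t) / (t(1-A)).
    """
    a = no_share_kappa1
    if not 0 < target_no_sharing < 1:
        raise ValueError("target_no_sharing must be in (0, 1)")
    if a >= 1 or a <= 0:
        raise ValueError(
            f"no-sharing probability at kappa=1 is {a}; sharing must be "
            "possible (overlapping SNP universes) to calibrate kappa"
        )
    t = target_no_sharing
    return a * (1 - t) / (t * (1 - a))


def calibrate_kappa(
    p_snps: int,
    expected_causals: Sequence[float],
    target_no_sharing: float | None = None,
) -> float:
    """Calibrate kappa so that P(no pair of diseases shares a SNP) = target.

    ``expected_causals`` holds each disease's prior expected model size over
    the ``p_snps``-SNP universe.  The default target is
    :func:`no_sharing_target` for the number of diseases.
    """
    d = len(expected_causals)
    if d < 2:
        raise ValueError("kappa calibration needs >= 2 diseases")
    if target_no_sharing is None:
        target_no_sharing = no_sharing_target(d)
    a = pairwise_disjoint_prob(p_snps, expected_causals)
    return kappa_from_no_share_prob(a, target_no_sharing)


def prior_no_sharing(
    kappa: float, p_snps: int, expected_causals: Sequence[float]
) -> float:
    """Prior mass on configurations with no sharing, under weight kappa."""
    a = pairwise_disjoint_prob(p_snps, expected_causals)
    return a / (a + kappa * (1 - a))


# ---------------------------------------------------------------------------
# multinomial Bayes factor


def multinomial_offset(
    model_sizes: Sequence[int], class_counts: Sequence[int]
) -> float:
    """Offset converting summed logistic log BFs to the multinomial log BF.

    Under the BIC-form approximate Bayes factor, each disease's logistic BF
    penalises its |M_d| SNP coefficients with log(n_0 + n_d) while the
    multinomial model fits all diseases on the pooled N = n_0 + sum n_k
    individuals, so

        offset = sum_d (|M_d| / 2) (log(n_0 + n_d) - log N).

    Zero when every model is null, and zero when controls are not shared
    (each cohort's pooled size is then its own n_0 + n_d).
    """
    counts = np.asarray(class_counts, dtype=float)
    if len(counts) != len(model_sizes) + 1:
        raise ValueError("class_counts must be n_0..n_D for D model sizes")
    n_total = counts.sum()
    n0 = counts[0]
    off = 0.0
    for size, nd in zip(model_sizes, counts[1:]):
        off += 0.5 * size * (math.log(n0 + nd) - math.log(n_total))
    return off


def joint_logbf(
    models: Sequence[SNPModel],
    logbfs: Sequence[float],
    class_counts: Sequence[int],
    shared_controls: bool = True,
) -> float:
    """Approximate multinomial log BF of a configuration vs the null.

    The sum of per-disease logistic log BFs plus :func:`multinomial_offset`
    (omitted when controls are not shared, where the sum is exact).
    """
    total = float(sum(logbfs))
    if shared_controls:
        total += multinomial_offset([m.size for m in models], class_counts)
    return total


# ---------------------------------------------------------------------------
# combination


@dataclass
class JointResult:
    """Per-disease marginal posteriors under the joint multinomial model."""

    posteriors: dict[int, ModelPosterior]
    kappa: float
    policy: str
    diagnostics: dict = field(default_factory=dict)
    input_posteriors: dict[int, ModelPosterior] = field(default_factory=dict)
    class_counts: tuple[int, ...] | None = None


def _weight_tables(
    posteriors: Mapping[int, ModelPosterior],
    class_counts: Sequence[int] | None,
    use_bf: bool = True,
) -> dict[int, list[tuple[SNPModel, frozenset, float]]]:
    """Per-disease lists of (model, snp set, weight); weights are rescaled
    per disease by the maximum log weight (the common factor cancels from
    every marginal and diagnostic ratio)."""
    diseases = sorted(posteriors)
    if class_counts is not None:
        counts = list(class_counts)
        c = {
            d: 0.5 * (math.log(counts[0] + counts[i + 1]) - math.log(sum(counts)))
            for i, d in enumerate(diseases)
        }
    else:
        c = {d: 0.0 for d in diseases}
    tables = {}
    for d in diseases:
        entries = posteriors[d].entries
        logws = {}
        for m, (lbf, lpr, _) in entries.items():
            logw = (lbf if use_bf else 0.0) + lpr + c[d] * m.size
            logws[m] = logw
        top = max(logws.values())
        tables[d] = [
            (m, frozenset(m.snps), math.exp(w - top)) for m, w in logws.items()
        ]
    return tables


def _disjoint_sum(
    lists: list[list[tuple[SNPModel, frozenset, float]]],
    idx: int,
    used: frozenset,
    relevant: list[frozenset],
    memo: dict,
    budget: list[int],
) -> float:
    """Sum over model choices for lists[idx:] that are pairwise disjoint and
    disjoint from ``used``."""
    if idx == len(lists):
        return 1.0
    key = (idx, used & relevant[idx])
    if key in memo:
        return memo[key]
    total = 0.0
    for _, snps, g in lists[idx]:
        budget[0] -= 1
        if budget[0] < 0:
            raise CostCapError(
                "sharing decomposition exceeded its cost cap; truncate the "
                "per-disease posteriors (drop models below a pp floor and "
                "renormalise) or raise cost_cap"
            )
        if snps & used:
            continue
        total += g * _disjoint_sum(
            lists, idx + 1, used | snps, relevant, memo, budget
        )
    memo[key] = total
    return total


def _sharing_pairs(models: Sequence[frozenset]) -> int:
    n = 0
    for i in range(len(models)):
        for j in range(i + 1, len(models)):
            if models[i] & models[j]:
                n += 1
    return n


def combine(
    posteriors: Mapping[int, ModelPosterior],
    kappa: float,
    class_counts: Sequence[int] | None = None,
    policy: str = "any",
    pp_truncate: float = 0.9999,
    cost_cap: int = 20_000_000,
) -> JointResult:
    """Combine per-disease posteriors under the kappa-weighted sharing prior.

    ``class_counts`` (n_0..n_D, ordered by sorted disease label) supplies the
    multinomial offset; pass None for zero offset (non-shared controls or
    pre-offset Bayes factors).  With kappa = 1 and zero offset the marginals
    equal the inputs exactly.

    The default "any" policy upweights configurations in which at least one
    pair of diseases shares a SNP by kappa; marginals are computed from
    per-disease totals and recursive disjoint-configuration sums.  The
    "pair" policy (kappa per sharing pair) enumerates configurations under
    the cost cap.
    """
    if kappa <= 0:
        raise ValueError("kappa must be positive")
    diseases = sorted(posteriors)
    trunc = {d: posteriors[d].truncate(pp_truncate) for d in diseases}
    tables = _weight_tables(trunc, class_counts)
    budget = [cost_cap]
    if policy == "any":
        marginals, diag = _combine_any(tables, kappa, budget)
    elif policy == "pair":
        marginals, diag = _combine_pair(tables, kappa, budget)
    else:
        raise ValueError(f"unknown sharing policy {policy!r}")
    # prior sharing diagnostics on the same truncated space
    prior_tables = _weight_tables(trunc, None, use_bf=False)
    if policy == "any":
        _, pdiag = _combine_any(prior_tables, kappa, [cost_cap], marginals_too=False)
    else:
        _, pdiag = _combine_pair(prior_tables, kappa, [cost_cap])
    out: dict[int, ModelPosterior] = {}
    for d in diseases:
        entries = {}
        norm = sum(marginals[d].values())
        for m, (lbf, lpr, _) in trunc[d].entries.items():
            entries[m] = (lbf, lpr, marginals[d][m] / norm)
        out[d] = ModelPosterior(
            disease=d,
            entries=entries,
            n_snps_region=trunc[d].n_snps_region,
            search_meta={**trunc[d].search_meta, "combined": "mfm"},
        )
    diagnostics = {
        "posterior_sharing_mass": diag["sharing_mass"],
        "prior_sharing_mass": pdiag["sharing_mass"],
        "kappa": kappa,
        "policy": policy,
    }
    return JointResult(
        posteriors=out,
        kappa=kappa,
        policy=policy,
        diagnostics=diagnostics,
        input_posteriors=dict(posteriors),
        class_counts=tuple(class_counts) if class_counts is not None else None,
    )


def _combine_any(
    tables: dict[int, list[tuple[SNPModel, frozenset, float]]],
    kappa: float,
    budget: list[int],
    marginals_too: bool = True,
) -> tuple[dict[int, dict[SNPModel, float]], dict]:
    diseases = sorted(tables)
    z = {d: sum(g for _, _, g in tables[d]) for d in diseases}
    lists_all = [tables[d] for d in diseases]
    relevant_all = _relevant(lists_all)
    noshare_all = _disjoint_sum(lists_all, 0, frozenset(), relevant_all, {}, budget)
    z_all = math.prod(z.values())
    total = kappa * z_all - (kappa - 1) * noshare_all
    sharing_mass = kappa * (z_all - noshare_all) / total if total > 0 else 0.0
    marginals: dict[int, dict[SNPModel, float]] = {}
    if marginals_too:
        for d in diseases:
            others = [tables[o] for o in diseases if o != d]
            rel = _relevant(others)
            z_rest = math.prod(z[o] for o in diseases if o != d)
            memo: dict = {}
            md = {}
            for m, snps, g in tables[d]:
                if kappa == 1.0:
                    md[m] = g * z_rest
                else:
                    d_rest = _disjoint_sum(others, 0, snps, rel, memo, budget)
                    md[m] = g * (kappa * z_rest - (kappa - 1) * d_rest)
            marginals[d] = md
    return marginals, {"sharing_mass": sharing_mass}


def _combine_pair(
    tables: dict[int, list[tuple[SNPModel, frozenset, float]]],
    kappa: float,
    budget: list[int],
) -> tuple[dict[int, dict[SNPModel, float]], dict]:
    diseases = sorted(tables)
    sizes = [len(tables[d]) for d in diseases]
    n_cfg = math.prod(sizes)
    if n_cfg > budget[0]:
        raise CostCapError(
            f"pair policy would enumerate {n_cfg} configurations, over the "
            "cost cap; truncate the per-disease posteriors or use the 'any' "
            "policy"
        )
    marginals: dict[int, dict[SNPModel, float]] = {
        d: {m: 0.0 for m, _, _ in tables[d]} for d in diseases
    }
    total = 0.0
    share_total = 0.0
    import itertools as _it

    for cfg in _it.product(*(tables[d] for d in diseases)):
        snpsets = [snps for _, snps, _ in cfg]
        w = math.prod(g for _, _, g in cfg) * kappa ** _sharing_pairs(snpsets)
        total += w
        if _sharing_pairs(snpsets) > 0:
            share_total += w
        for d, (m, _, _) in zip(diseases, cfg):
            marginals[d][m] += w
    return marginals, {"sharing_mass": share_total / total if total > 0 else 0.0}


def _relevant(lists: list[list[tuple[SNPModel, frozenset, float]]]) -> list[frozenset]:
    rel: list[frozenset] = [frozenset()] * len(lists)
    acc: frozenset = frozenset()
    for i in range(len(lists) - 1, -1, -1):
        for _, snps, _ in lists[i]:
            acc = acc | snps
        rel[i] = acc
    return rel


def combine_multipop(
    result: JointResult,
    extras: Mapping[int, Mapping[SNPModel, float]],
    pp_truncate: float = 0.9999,
    cost_cap: int = 20_000_000,
) -> JointResult:
    """Add disease-specific log BFs from distinct (non-shared-control) cohorts.

    Each extra cohort's log BF table is added to its disease's logistic log
    BFs before marginalisation (no offset applies across populations: with
    non-shared controls the joint log BF is a plain sum).  Models missing
    from an extra table contribute log BF 0, with a logged warning.  With
    empty extras the combination is unchanged.
    """
    adjusted: dict[int, ModelPosterior] = {}
    for d, post in result.input_posteriors.items():
        table = extras.get(d)
        if not table:
            adjusted[d] = post
            continue
        entries = {}
        missing = 0
        for m, (lbf, lpr, pp) in post.entries.items():
            extra = table.get(m)
            if extra is None:
                missing += 1
                extra = 0.0
            entries[m] = (lbf + extra, lpr, pp)
        if missing:
            logger.warning(
                "disease %s: %d models missing from extra-cohort table; "
                "treated as log BF 0",
                d,
                missing,
            )
        # pp is stale after adjusting logBF; renormalise from scores
        logw = {m: lbf + lpr for m, (lbf, lpr, _) in entries.items()}
        top = max(logw.values())
        norm = sum(math.exp(v - top) for v in logw.values())
        entries = {
            m: (lbf, lpr, math.exp(logw[m] - top) / norm)
            for m, (lbf, lpr, _) in entries.items()
        }
        adjusted[d] = ModelPosterior(
            disease=post.disease,
            entries=entries,
            n_snps_region=post.n_snps_region,
            search_meta={**post.search_meta, "multipop": True},
        )
    return combine(
        adjusted,
        kappa=result.kappa,
        class_counts=result.class_counts,
        policy=result.policy,
        pp_truncate=pp_truncate,
        cost_cap=cost_cap,
    )
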