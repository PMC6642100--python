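"""Grouping of substitutable SNPs and grouped model posteriors.

Stochastic-search posteriors typically spread mass over many models that
differ only by swapping one SNP for a close LD proxy.  SNPs with
non-negligible inclusion probability are therefore clustered into groups of
substitutable variants: high pairwise LD (r^2), negative model-selection
correlation (rarely selected together), and low joint inclusion
probability.  Posteriors are then re-expressed over group patterns (GPP)
and group inclusion probabilities (gMPPI), and the stepwise model can be
classified against the grouped stochastic-search result.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .finemap import ModelPosterior, StepwiseResult

__all__ = [
    "SNPGroupSet",
    "GroupedModelTable",
    "model_selection_correlation",
    "build_groups",
    "grouped_posteriors",
    "classify_agreement",
]

INTRA_GROUP_SUFFIX = "(x2)"


@dataclass
class SNPGroupSet:
    """Disjoint groups of substitutable SNPs with per-disease gMPPI."""

    groups: dict[str, frozenset]  # label -> SNP ids
    gmppi: dict[int, dict[str, float]] = field(default_factory=dict)
    min_r2: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for label, members in self.groups.items():
            if seen & members:
                raise ValueError(f"group {label!r} overlaps another group")
            seen |= members

    def label_of(self, snp: str) -> str | None:
        for label, members in self.groups.items():
            if snp in members:
                return label
        return None


@dataclass
class GroupedModelTable:
    """Map from group patterns (sorted label tuples) to GPP, per disease."""

    gpp: dict[tuple[str, ...], float]
    remainder: float  # mass of models not expressible as one-SNP-per-group
    disease: int

    def top_pattern(self) -> tuple[str, ...]:
        return max(self.gpp, key=lambda p: (self.gpp[p], p))


def model_selection_correlation(
    posterior: ModelPosterior, snp_i: str, snp_j: str
) -> float:
    """pp-weighted Pearson correlation of two SNPs' model-inclusion indicators.

    Negative values mean the SNPs are rarely selected together — the
    signature of substitutable variants.  If either indicator has zero
    weighted variance the correlation is undefined and 0 is returned with a
    warning.
    """
    pps = []
    xi = []
    xj = []
    for model, (_, _, pp) in posterior.entries.items():
        pps.append(pp)
        xi.append(1.0 if snp_i in model else 0.0)
        xj.append(1.0 if snp_j in model else 0.0)
    w = np.asarray(pps)
    total = w.sum()
    if total <= 0:
        warnings.warn("posterior has no mass; r_model undefined, returning 0")
        return 0.0
    w = w / total
    xi = np.asarray(xi)
    xj = np.asarray(xj)
    mi, mj = w @ xi, w @ xj
    vi = w @ (xi - mi) ** 2
    vj = w @ (xj - mj) ** 2
    if vi <= 0 or vj <= 0:
        warnings.warn(
            f"zero-variance inclusion indicator for {snp_i if vi <= 0 else snp_j}; "
            "r_model undefined, returning 0"
        )
        return 0.0
    cov = w @ ((xi - mi) * (xj - mj))
    return float(cov / np.sqrt(vi * vj))


def _joint_inclusion(posterior: ModelPosterior, snp_i: str, snp_j: str) -> float:
    return sum(
        pp
        for model, (_, _, pp) in posterior.entries.items()
        if snp_i in model and snp_j in model
    )


def _pairs_ok(
    snps: list[str],
    posteriors: Mapping[int, ModelPosterior],
    mppi: dict[int, dict[str, float]],
    r2: np.ndarray,
    index: dict[str, int],
    mppi_min: float,
    r2_min: float,
    joint_max: float,
) -> bool:
    """All three substitutability criteria for every pair, in every disease
    where both SNPs pass the inclusion threshold."""
    for a in range(len(snps)):
        for b in range(a + 1, len(snps)):
            si, sj = snps[a], snps[b]
            if r2[index[si], index[sj]] <= r2_min:
                return False
            for d, post in posteriors.items():
                if mppi[d].get(si, 0.0) > mppi_min and mppi[d].get(sj, 0.0) > mppi_min:
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        rm = model_selection_correlation(post, si, sj)
                    if rm >= 0:
                        return False
                    if _joint_inclusion(post, si, sj) >= joint_max:
                        return False
    return True


def build_groups(
    posteriors: Mapping[int, ModelPosterior],
    dosages: np.ndarray,
    snp_ids: list[str],
    mppi_min: float = 0.001,
    r2_min: float = 0.5,
    joint_max: float = 0.01,
) -> SNPGroupSet:
    """Group substitutable SNPs within and across diseases.

    Per disease, SNPs with MPPI above ``mppi_min`` are clustered by complete
    linkage on the dissimilarity 1 - r^2 sign(r_model) (clipped to [0, 2])
    and the tree is cut at the coarsest height at which every within-group
    pair has r^2 > ``r2_min``, r_model < 0 and joint inclusion probability
    below ``joint_max`` (checked explicitly after the cut).  Groups from
    different diseases that overlap are merged when the merged group still
    meets the criteria in every contributing disease, otherwise offending
    SNPs (fewest satisfied pairs first, ties by id) are split off as
    singletons.
    """
    X = np.asarray(dosages, dtype=float)
    index = {s: i for i, s in enumerate(snp_ids)}
    with np.errstate(invalid="ignore"):
        r2_full = np.corrcoef(X, rowvar=False) ** 2
    r2_full = np.atleast_2d(np.nan_to_num(r2_full))
    mppi = {d: post.mppi for d, post in posteriors.items()}

    per_disease_groups: list[set[str]] = []
    for d, post in sorted(posteriors.items()):
        selected = sorted(
            [s for s, v in mppi[d].items() if v > mppi_min and s in index]
        )
        if not selected:
            continue
        if len(selected) == 1:
            per_disease_groups.append({selected[0]})
            continue
        m = len(selected)
        dis = np.zeros((m, m))
        for a in range(m):
            for b in range(a + 1, m):
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    rm = model_selection_correlation(post, selected[a], selected[b])
                r2ab = r2_full[index[selected[a]], index[selected[b]]]
                # substitutable pairs (high r^2, negative r_model) must sit
                # close: dissimilarity 1 + r^2 sign(r_model) is ~0 for them,
                # ~2 for co-selected pairs, ~1 for unlinked ones
                dis[a, b] = dis[b, a] = float(
                    np.clip(1.0 + r2ab * np.sign(rm), 0.0, 2.0)
                )
        tree = linkage(squareform(dis, checks=False), method="complete")
        heights = sorted({0.0} | {float(h) for h in tree[:, 2]}, reverse=True)
        chosen = None
        for h in heights:
            labels = fcluster(tree, t=h, criterion="distance")
            clusters = [
                [selected[i] for i in range(m) if labels[i] == c]
                for c in sorted(set(labels))
            ]
            if all(
                _pairs_ok(
                    cl, {d: post}, mppi, r2_full, index, mppi_min, r2_min, joint_max
                )
                for cl in clusters
            ):
                chosen = clusters
                break
        if chosen is None:
            chosen = [[s] for s in selected]
        per_disease_groups.extend(set(cl) for cl in chosen)

    # cross-disease reconciliation: merge overlapping groups (union-find),
    # then split offenders
    merged: list[set[str]] = []
    for grp in per_disease_groups:
        grp = set(grp)
        absorbed = []
        for existing in merged:
            if existing & grp:
                absorbed.append(existing)
        for ex in absorbed:
            merged.remove(ex)
            grp |= ex
        merged.append(grp)

    final: list[set[str]] = []
    for grp in merged:
        final.extend(
            _split_until_ok(
                grp, posteriors, mppi, r2_full, index, mppi_min, r2_min, joint_max
            )
        )

    final = sorted(final, key=lambda g: min(g))
    labels = {}
    min_r2 = {}
    for i, members in enumerate(final):
        label = _group_label(i)
        labels[label] = frozenset(members)
        mem = sorted(members)
        if len(mem) > 1:
            min_r2[label] = float(
                min(
                    r2_full[index[a], index[b]]
                    for ai, a in enumerate(mem)
                    for b in mem[ai + 1 :]
                )
            )
        else:
            min_r2[label] = 1.0
    gmppi = {
        d: _gmppi(post, labels) for d, post in posteriors.items()
    }
    return SNPGroupSet(groups=labels, gmppi=gmppi, min_r2=min_r2)


def _split_until_ok(
    grp: set[str],
    posteriors,
    mppi,
    r2,
    index,
    mppi_min,
    r2_min,
    joint_max,
) -> list[set[str]]:
    """Remove minimum-degree offending SNPs into singletons until the group
    satisfies all criteria in every disease (deterministic tie-break by id)."""
    grp = set(grp)
    singles: list[set[str]] = []
    while len(grp) > 1 and not _pairs_ok(
        sorted(grp), posteriors, mppi, r2, index, mppi_min, r2_min, joint_max
    ):
        # degree = number of within-group pairs a SNP satisfies
        degree = {}
        mem = sorted(grp)
        for s in mem:
            degree[s] = sum(
                1
                for t in mem
                if t != s
                and _pairs_ok(
                    [s, t], posteriors, mppi, r2, index, mppi_min, r2_min, joint_max
                )
            )
        worst = min(mem, key=lambda s: (degree[s], s))
        grp.remove(worst)
        singles.append({worst})
    return [grp] + singles if grp else singles


def _group_label(i: int) -> str:
    label = ""
    i += 1
    while i > 0:
        i, rem = divmod(i - 1, 26)
        label = chr(ord("A") + rem) + label
    return label


def _gmppi(posterior: ModelPosterior, groups: dict[str, frozenset]) -> dict[str, float]:
    out = {}
    for label, members in groups.items():
        out[label] = sum(
            pp
            for model, (_, _, pp) in posterior.entries.items()
            if members & set(model.snps)
        )
    return out


def grouped_posteriors(
    posterior: ModelPosterior, groups: SNPGroupSet
) -> tuple[GroupedModelTable, dict[str, float]]:
    """Grouped model posteriors (GPP) and group inclusion probabilities.

    A model's pattern is the multiset of group labels of its SNPs (SNPs in
    no group act as their own singleton, labelled by id).  Models with two
    or more SNPs from one group form distinct "intra-group pair" patterns,
    marked with a suffix, and are reported separately.  Total GPP plus the
    remainder equals the posterior mass exactly.
    """
    gpp: dict[tuple[str, ...], float] = {}
    remainder = 0.0
    for model, (_, _, pp) in posterior.entries.items():
        labels = []
        counts: dict[str, int] = {}
        for snp in model.snps:
            lab = groups.label_of(snp) or snp
            labels.append(lab)
            counts[lab] = counts.get(lab, 0) + 1
        if any(v > 1 for v in counts.values()):
            pattern = tuple(
                sorted(
                    lab + (INTRA_GROUP_SUFFIX if counts[lab] > 1 else "")
                    for lab in counts
                )
            )
            remainder += pp
        else:
            pattern = tuple(sorted(labels))
        gpp[pattern] = gpp.get(pattern, 0.0) + pp
    gmppi = _gmppi(posterior, groups.groups)
    return GroupedModelTable(gpp=gpp, remainder=remainder, disease=posterior.disease), gmppi


def classify_agreement(
    stepwise: StepwiseResult,
    grouped: GroupedModelTable,
    groups: SNPGroupSet,
    split_margin: float = 0.1,
) -> str:
    """Classify stepwise vs stochastic-search agreement at the group level.

    Returns "match" when the stepwise group pattern equals the top-GPP
    pattern, "nested" when it is a strict subset, "split-signal" when its
    GPP is within ``split_margin`` of the top pattern's, else "discrepant".
    """
    if not grouped.gpp:
        raise ValueError("grouped model table is empty")
    sw_pattern = tuple(
        sorted(groups.label_of(s) or s for s in stepwise.model.snps)
    )
    top = grouped.top_pattern()
    if sw_pattern == top:
        return "match"
    if set(sw_pattern) < set(top):
        return "nested"
    sw_gpp = grouped.gpp.get(sw_pattern, 0.0)
    if grouped.gpp[top] - sw_gpp <= split_margin:
        return "split-signal"
    return "discrepant"
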