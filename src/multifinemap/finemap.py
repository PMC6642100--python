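"""Single-disease Bayesian fine-mapping of a case/control region.

Models are sets of SNPs; each model's evidence is an approximate Bayes
factor against the null computed from logistic fits of one disease's cases
against the shared controls (BIC / unit-information-prior approximation:
log BF = -(BIC_model - BIC_null)/2).  The prior over models is binomial on
model size with a stated expected number of causal variants, flat across
models of equal size.  Posteriors are obtained either by exhaustive
enumeration (small regions) or by shotgun stochastic search (add/drop/swap
moves over the model space), with tag-SNP compression (r^2 >= 0.99) and
post-hoc tag expansion.  Forward stepwise regression and BIC tables are
provided for comparison with the Bayesian results.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.special import logsumexp

from ._glm import LogisticFit, fit_logistic_safe
from .simulate import CaseControlStudy

__all__ = [
    "SNPModel",
    "ModelPosterior",
    "StepwiseResult",
    "tag_snps",
    "log_abf",
    "log_model_prior",
    "n_models",
    "exhaustive_posterior",
    "shotgun_search",
    "expand_tags",
    "forward_stepwise",
    "bic_table",
]


@dataclass(frozen=True, order=True)
class SNPModel:
    """A causal-variant model: a canonical (sorted) set of SNP ids."""

    snps: tuple[str, ...]

    def __init__(self, snps=()):  # type: ignore[no-untyped-def]
        raw = tuple(snps)
        canonical = tuple(sorted(set(raw)))
        if len(canonical) != len(raw):
            raise ValueError(f"duplicate SNP ids in model: {raw}")
        object.__setattr__(self, "snps", canonical)

    @property
    def size(self) -> int:
        return len(self.snps)

    def __contains__(self, snp: str) -> bool:
        return snp in self.snps

    def add(self, snp: str) -> "SNPModel":
        return SNPModel(self.snps + (snp,))

    def drop(self, snp: str) -> "SNPModel":
        return SNPModel(tuple(s for s in self.snps if s != snp))

    def __str__(self) -> str:
        return ",".join(self.snps) if self.snps else "(null)"


NULL_MODEL = SNPModel(())


@dataclass
class ModelPosterior:
    """Posterior over SNP models for one disease.

    ``entries`` maps models to (logBF, logprior, pp) with pp normalised over
    the evaluated model set; ``mppi`` is the per-SNP marginal posterior
    inclusion probability (sum of pp over models containing the SNP).
    """

    disease: int
    entries: dict[SNPModel, tuple[float, float, float]]
    n_snps_region: int
    search_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        total = sum(pp for _, _, pp in self.entries.values())
        if total > 1 + 1e-9:
            raise ValueError(f"posterior mass {total} exceeds 1")

    @property
    def models(self) -> list[SNPModel]:
        return list(self.entries)

    def pp(self, model: SNPModel) -> float:
        return self.entries[model][2]

    def logbf(self, model: SNPModel) -> float:
        return self.entries[model][0]

    @property
    def mppi(self) -> dict[str, float]:
        out: dict[str, float] = {}
        for model, (_, _, pp) in self.entries.items():
            for snp in model.snps:
                out[snp] = out.get(snp, 0.0) + pp
        return out

    def top_model(self) -> SNPModel:
        return max(self.entries, key=lambda m: (self.entries[m][2], m.snps))

    def truncate(self, pp_floor_cum: float = 0.9999) -> "ModelPosterior":
        """Smallest model set reaching cumulative pp >= pp_floor_cum, renormalised."""
        order = sorted(self.entries.items(), key=lambda kv: (-kv[1][2], kv[0].snps))
        kept: dict[SNPModel, tuple[float, float, float]] = {}
        cum = 0.0
        for model, (lbf, lpr, pp) in order:
            kept[model] = (lbf, lpr, pp)
            cum += pp
            if cum >= pp_floor_cum:
                break
        total = sum(pp for _, _, pp in kept.values())
        kept = {m: (lbf, lpr, pp / total) for m, (lbf, lpr, pp) in kept.items()}
        return ModelPosterior(
            disease=self.disease,
            entries=kept,
            n_snps_region=self.n_snps_region,
            search_meta=dict(self.search_meta),
        )

    def renormalised(self) -> "ModelPosterior":
        return self.truncate(pp_floor_cum=1.1)


@dataclass
class StepwiseResult:
    """Forward stepwise selection outcome: final model and per-step p-values."""

    model: SNPModel
    step_pvalues: tuple[float, ...]
    trace: tuple[tuple[str, float], ...]


# ---------------------------------------------------------------------------
# tagging


def tag_snps(
    dosages: np.ndarray,
    snp_ids: list[str],
    r2_threshold: float = 0.99,
) -> tuple[list[str], dict[str, str]]:
    """Greedy r^2 tagging: returns (representatives, snp -> representative).

    Every SNP maps to a representative with which its r^2 meets the
    threshold; representatives are mutually below it.  Greedy in column
    order, so deterministic.
    """
    if len(snp_ids) == 0:
        return [], {}
    X = np.asarray(dosages, dtype=float)
    sd = X.std(axis=0)
    if np.any(sd == 0):
        bad = [snp_ids[i] for i in np.where(sd == 0)[0]]
        raise ValueError(f"monomorphic SNPs must be removed before tagging: {bad}")
    r2 = np.corrcoef(X, rowvar=False) ** 2
    if r2.ndim == 0:
        r2 = np.array([[1.0]])
    reps: list[str] = []
    tag_map: dict[str, str] = {}
    for i, snp in enumerate(snp_ids):
        if snp in tag_map:
            continue
        reps.append(snp)
        tag_map[snp] = snp
        for j in range(i + 1, len(snp_ids)):
            if snp_ids[j] not in tag_map and r2[i, j] >= r2_threshold:
                tag_map[snp_ids[j]] = snp
    return reps, tag_map


# ---------------------------------------------------------------------------
# Bayes factors and priors


def _design(
    study: CaseControlStudy, disease: int, model: SNPModel
) -> tuple[np.ndarray, np.ndarray, int]:
    mask = (study.status == 0) | (study.status == disease)
    if not np.any(study.status[mask] == disease):
        raise ValueError(f"disease class {disease} has no cases")
    y = (study.status[mask] == disease).astype(float)
    cols = [np.ones((mask.sum(), 1)), study.covariates[mask]]
    if model.size:
        idx = [study.snp_index(s) for s in model.snps]
        cols.append(study.dosages[mask][:, idx].astype(float))
    X = np.concatenate(cols, axis=1)
    return X, y, int(mask.sum())


def _fit_model(
    study: CaseControlStudy, disease: int, model: SNPModel
) -> tuple[LogisticFit, int]:
    X, y, n = _design(study, disease, model)
    return fit_logistic_safe(X, y), n


def log_abf(
    study: CaseControlStudy,
    disease: int,
    model: SNPModel,
    _cache: dict | None = None,
) -> float:
    """Approximate log Bayes factor of ``model`` vs the null (natural log).

    BIC form: logBF = (ll_M - ll_0) - (|M|/2) log n, with covariates present
    in both fits so they cancel only through the likelihood.  Separated fits
    fall back to a flagged ridge refit (see :mod:`multifinemap._glm`).
    """
    if _cache is not None and model in _cache:
        return _cache[model]
    if model.size == 0:
        val = 0.0
    else:
        null_key = ("__null__", disease)
        if _cache is not None and null_key in _cache:
            ll0 = _cache[null_key]
        else:
            fit0, _ = _fit_model(study, disease, NULL_MODEL)
            ll0 = fit0.loglik
            if _cache is not None:
                _cache[null_key] = ll0
        fit, n = _fit_model(study, disease, model)
        val = (fit.loglik - ll0) - 0.5 * model.size * math.log(n)
    if _cache is not None:
        _cache[model] = val
    return val


def n_models(p_snps: int, k: int) -> int:
    """Number of distinct size-k models in a p-SNP region: C(p, k)."""
    return math.comb(p_snps, k)


def log_model_prior(
    k: int,
    p_snps: int,
    expected_causals: float = 2.0,
    max_k: int | None = None,
) -> float:
    """Natural-log prior of one size-k model under the binomial size prior.

    P(size = k) = Binom(k; p_snps, pi) with pi = expected/p_snps, shared
    equally by the C(p_snps, k) models of that size, i.e. the per-model
    prior is pi^k (1-pi)^(p_snps-k).  Summed over all models of all sizes
    0..p_snps this is exactly 1.
    """
    if max_k is None:
        max_k = p_snps
    if not 0 <= k <= max_k <= p_snps:
        raise ValueError(f"need 0 <= k <= max_k <= p_snps, got k={k}, max_k={max_k}")
    if not 0 < expected_causals < p_snps:
        raise ValueError(
            f"expected_causals must be in (0, p_snps), got {expected_causals}"
        )
    pi = expected_causals / p_snps
    return k * math.log(pi) + (p_snps - k) * math.log1p(-pi)


# ---------------------------------------------------------------------------
# posteriors


def _posterior_from_scores(
    disease: int,
    scores: dict[SNPModel, tuple[float, float]],
    n_snps_region: int,
    search_meta: dict | None = None,
) -> ModelPosterior:
    models = list(scores)
    logpost = np.array([lbf + lpr for lbf, lpr in scores.values()])
    pp = np.exp(logpost - logsumexp(logpost))
    entries = {
        m: (scores[m][0], scores[m][1], float(w)) for m, w in zip(models, pp)
    }
    return ModelPosterior(
        disease=disease,
        entries=entries,
        n_snps_region=n_snps_region,
        search_meta=search_meta or {},
    )


def _score_model(
    study: CaseControlStudy,
    disease: int,
    model: SNPModel,
    p_snps: int,
    expected_causals: float,
    max_k: int,
    cache: dict,
) -> tuple[float, float]:
    lbf = log_abf(study, disease, model, _cache=cache)
    lpr = log_model_prior(model.size, p_snps, expected_causals, max_k)
    return lbf, lpr


def exhaustive_posterior(
    study: CaseControlStudy,
    disease: int,
    max_k: int = 2,
    expected_causals: float = 2.0,
    snp_ids: list[str] | None = None,
    n_snps_region: int | None = None,
    model_cap: int = 200_000,
) -> ModelPosterior:
    """Posterior by enumerating every model of size 0..max_k.

    ``n_snps_region`` sets the SNP count used in the prior (the full region
    may be larger than the analysed subset); defaults to the analysed count.
    """
    snps = snp_ids if snp_ids is not None else study.snp_ids
    # the full region's SNP count enters the prior even when only a subset
    # (e.g. tag representatives) is analysed
    p_region = n_snps_region if n_snps_region is not None else len(study.snp_ids)
    total = sum(n_models(len(snps), k) for k in range(max_k + 1))
    if total > model_cap:
        raise ValueError(
            f"{total} models exceeds cap {model_cap}; use shotgun_search"
        )
    cache: dict = {}
    scores: dict[SNPModel, tuple[float, float]] = {}
    for k in range(max_k + 1):
        for combo in itertools.combinations(snps, k):
            m = SNPModel(combo)
            scores[m] = _score_model(
                study, disease, m, p_region, expected_causals, max_k, cache
            )
    return _posterior_from_scores(
        disease, scores, p_region, {"search": "exhaustive", "n_models": total}
    )


def shotgun_search(
    study: CaseControlStudy,
    disease: int,
    n_iter: int = 200,
    n_chains: int = 3,
    expected_causals: float = 3.0,
    max_k: int = 6,
    seed: int = 0,
    snp_ids: list[str] | None = None,
    n_snps_region: int | None = None,
) -> ModelPosterior:
    """Shotgun stochastic search over SNP models.

    Each chain starts from a top marginal SNP, then repeatedly scores the
    full add/drop/swap neighbourhood of the current model and moves to a
    neighbour sampled proportionally to its posterior score.  The returned
    posterior is normalised over every model scored by any chain, so with
    enough iterations on a small panel it coincides with the exhaustive
    posterior.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    snps = snp_ids if snp_ids is not None else study.snp_ids
    p_region = n_snps_region if n_snps_region is not None else len(study.snp_ids)
    rng = np.random.default_rng(seed)
    cache: dict = {}
    scores: dict[SNPModel, tuple[float, float]] = {}

    def score(m: SNPModel) -> float:
        if m not in scores:
            scores[m] = _score_model(
                study, disease, m, p_region, expected_causals, max_k, cache
            )
        return sum(scores[m])

    # rank starting SNPs by single-SNP evidence
    singles = sorted(snps, key=lambda s: -score(SNPModel((s,))))
    score(NULL_MODEL)
    chain_tops: list[SNPModel] = []
    accepted = 0
    proposals = 0
    for c in range(n_chains):
        current = SNPModel((singles[c % len(singles)],))
        best = current
        for _ in range(n_iter):
            nbrs = _neighbours(current, snps, max_k)
            logw = np.array([score(m) for m in nbrs])
            w = np.exp(logw - logw.max())
            nxt = nbrs[rng.choice(len(nbrs), p=w / w.sum())]
            proposals += 1
            if nxt != current:
                accepted += 1
            current = nxt
            if score(current) > score(best):
                best = current
        chain_tops.append(best)
    meta = {
        "search": "shotgun",
        "n_iter": n_iter,
        "n_chains": n_chains,
        "seed": seed,
        "accept_fraction": accepted / max(proposals, 1),
        "chain_top_models": [str(m) for m in chain_tops],
        "chain_concordance": len(set(chain_tops)) == 1,
        "n_models_visited": len(scores),
    }
    return _posterior_from_scores(disease, scores, p_region, meta)


def _neighbours(model: SNPModel, snps: list[str], max_k: int) -> list[SNPModel]:
    out = [model]
    absent = [s for s in snps if s not in model]
    if model.size < max_k:
        out.extend(model.add(s) for s in absent)
    for s in model.snps:
        out.append(model.drop(s))
        dropped = model.drop(s)
        out.extend(dropped.add(a) for a in absent)
    return out


def expand_tags(
    posterior: ModelPosterior,
    tag_map: dict[str, str],
    study: CaseControlStudy,
    pp_cover: float = 0.99,
    expected_causals: float = 2.0,
    max_k: int | None = None,
) -> ModelPosterior:
    """Re-expand tagged SNPs inside the credible model set.

    Models in the smallest set with cumulative pp >= ``pp_cover`` are
    expanded to every substitution of a tag representative by one of the
    SNPs it tags; log BFs are refitted on the full study and the posterior
    renormalised over the expanded set.
    """
    groups: dict[str, list[str]] = {}
    for snp, rep in tag_map.items():
        groups.setdefault(rep, []).append(snp)
    order = sorted(
        posterior.entries.items(), key=lambda kv: (-kv[1][2], kv[0].snps)
    )
    covered: list[SNPModel] = []
    cum = 0.0
    for model, (_, _, pp) in order:
        covered.append(model)
        cum += pp
        if cum >= pp_cover:
            break
    if max_k is None:
        max_k = max((m.size for m in covered), default=0) or 1
    cache: dict = {}
    scores: dict[SNPModel, tuple[float, float]] = {}
    for model in covered:
        choices = [sorted(groups.get(s, [s])) for s in model.snps]
        if not choices:
            expanded = [NULL_MODEL]
        else:
            expanded = [
                SNPModel(combo)
                for combo in itertools.product(*choices)
                if len(set(combo)) == len(combo)
            ]
        for m in expanded:
            if m not in scores:
                lbf = log_abf(study, posterior.disease, m, _cache=cache)
                lpr = log_model_prior(
                    m.size, posterior.n_snps_region, expected_causals, max_k
                )
                scores[m] = (lbf, lpr)
    meta = dict(posterior.search_meta)
    meta["tag_expanded"] = True
    return _posterior_from_scores(
        posterior.disease, scores, posterior.n_snps_region, meta
    )


# ---------------------------------------------------------------------------
# stepwise and BIC


def forward_stepwise(
    study: CaseControlStudy,
    disease: int,
    p_threshold: float = 1e-6,
    snp_ids: list[str] | None = None,
) -> StepwiseResult:
    """Greedy forward selection by conditional Wald p-value.

    At each step every remaining SNP is added to the current model in turn;
    the SNP with the smallest Wald p is retained if p < threshold, else the
    search stops.  Deterministic given the data (ties broken by SNP id).
    """
    snps = snp_ids if snp_ids is not None else study.snp_ids
    model = NULL_MODEL
    trace: list[tuple[str, float]] = []
    while True:
        best: tuple[float, str] | None = None
        for snp in snps:
            if snp in model:
                continue
            cand = model.add(snp)
            fit, _ = _fit_model(study, disease, cand)
            j = cand.snps.index(snp)
            col = 1 + study.covariates.shape[1] + j
            z = fit.beta[col] / fit.se[col]
            p = 2 * stats.norm.sf(abs(z))
            if best is None or (p, snp) < best:
                best = (p, snp)
        if best is None or best[0] >= p_threshold:
            break
        model = model.add(best[1])
        trace.append((best[1], best[0]))
    return StepwiseResult(
        model=model,
        step_pvalues=tuple(p for _, p in trace),
        trace=tuple(trace),
    )


def bic_table(
    study: CaseControlStudy,
    disease: int,
    models: list[SNPModel],
):
    """Per-model BIC (-2 loglik + n_params log n), sorted ascending.

    Returns a pandas DataFrame with columns model, size, loglik, bic.
    """
    import pandas as pd

    rows = []
    for model in models:
        fit, n = _fit_model(study, disease, model)
        k = 1 + study.covariates.shape[1] + model.size
        bic = -2 * fit.loglik + k * math.log(n)
        rows.append(
            {"model": str(model), "size": model.size, "loglik": fit.loglik, "bic": bic}
        )
    return pd.DataFrame(rows).sort_values("bic", kind="mergesort").reset_index(
        drop=True
    )
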