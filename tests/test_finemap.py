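"""Single-disease fine-mapping: ABFs, priors, searches, stepwise, BIC."""

import itertools
import math

import numpy as np
import pytest
from scipy.special import logsumexp

import multifinemap as mf
from multifinemap.finemap import NULL_MODEL, SNPModel, log_abf, n_models


class TestSNPModel:
    def test_canonical_ordering_and_equality(self):
        assert SNPModel(("b", "a")) == SNPModel(("a", "b"))
        assert SNPModel(()).size == 0
        with pytest.raises(ValueError):
            SNPModel(("a", "a"))


class TestTagSnps:
    def test_identical_columns_share_one_representative(self):
        col = np.random.default_rng(1).integers(0, 3, 200)
        dosages = np.column_stack([col, col])
        reps, tag_map = mf.tag_snps(dosages, ["s1", "s2"])
        assert reps == ["s1"]
        assert tag_map == {"s1": "s1", "s2": "s1"}

    def test_uncorrelated_snps_map_to_themselves(self, indep_panel):
        geno = mf.sample_genotypes(indep_panel, 2000, 0.0, seed=2)
        reps, tag_map = mf.tag_snps(geno, indep_panel.snp_ids)
        assert reps == indep_panel.snp_ids
        assert all(tag_map[s] == s for s in indep_panel.snp_ids)

    def test_tight_blocks_collapse_to_one_representative_each(self):
        panel = mf.make_block_panel(4000, [5, 5], 0.997, (0.2, 0.4), seed=3)
        geno = mf.sample_genotypes(panel, 6000, 0.0, seed=4)
        r2 = np.corrcoef(geno.astype(float), rowvar=False) ** 2
        reps, tag_map = mf.tag_snps(geno, panel.snp_ids, r2_threshold=0.99)
        # representatives mutually below threshold; members tagged above it
        for a, b in itertools.combinations(reps, 2):
            i, j = panel.snp_ids.index(a), panel.snp_ids.index(b)
            assert r2[i, j] < 0.99
        for s, rep in tag_map.items():
            i, j = panel.snp_ids.index(s), panel.snp_ids.index(rep)
            assert r2[i, j] >= 0.99 or s == rep

    def test_empty_input(self):
        reps, tag_map = mf.tag_snps(np.empty((0, 0)), [])
        assert reps == [] and tag_map == {}


class TestLogABF:
    def test_null_model_is_zero(self, single_causal_study):
        assert log_abf(single_causal_study, 1, NULL_MODEL) == 0.0

    def test_causal_snp_attains_max_single_snp_logbf(self, indep_panel):
        """The causal SNP wins the 1-SNP logBF comparison in >= 90% of
        replicates (30 replicates, >= 27)."""
        wins = 0
        reps = 30
        for rep in range(reps):
            geno = mf.sample_genotypes(indep_panel, 60000, 0.0, seed=300 + rep)
            spec = mf.SimulationSpec(
                causal_effects=(("snp4", 1, 1.4),), target_counts=(3000, 3000), seed=rep
            )
            study = mf.assign_multitrait(geno, indep_panel.snp_ids, spec)
            cache = {}
            bfs = {
                s: log_abf(study, 1, SNPModel((s,)), _cache=cache)
                for s in indep_panel.snp_ids
            }
            wins += max(bfs, key=bfs.get) == "snp4"
        assert wins >= round(0.9 * reps)

    def test_permuted_status_gives_negative_logbf(self, single_causal_study):
        """Under permuted labels the BIC-form logBF of any 1-SNP model is
        negative in >= 95% of permutations (40 permutations, >= 38)."""
        rng = np.random.default_rng(5)
        ok = 0
        reps = 40
        study = single_causal_study
        for _ in range(reps):
            perm = mf.CaseControlStudy(
                dosages=study.dosages,
                snp_ids=study.snp_ids,
                status=rng.permutation(study.status),
            )
            cache = {}
            bfs = [
                log_abf(perm, 1, SNPModel((s,)), _cache=cache) for s in study.snp_ids
            ]
            ok += all(b < 0 for b in bfs)
        assert ok >= round(0.95 * reps)


class TestModelPrior:
    def test_size_zero_closed_form(self):
        assert mf.log_model_prior(0, 100, 2.0) == pytest.approx(
            100 * math.log(0.98), abs=1e-12
        )

    def test_model_counts_match_reported_combinatorics(self):
        assert n_models(1000, 2) == 499_500
        assert n_models(1000, 3) == 166_167_000

    def test_prior_sums_to_one_by_enumeration(self):
        p = 12
        total = sum(
            n_models(p, k) * math.exp(mf.log_model_prior(k, p, 2.0))
            for k in range(p + 1)
        )
        assert total == pytest.approx(1.0, abs=1e-10)

    def test_invalid_expectation_rejected(self):
        with pytest.raises(ValueError):
            mf.log_model_prior(1, 10, 10.0)
        with pytest.raises(ValueError):
            mf.log_model_prior(5, 10, 2.0, max_k=3)


class TestExhaustivePosterior:
    def test_posterior_normalised_and_null_logbf_zero(self, single_causal_study):
        post = mf.exhaustive_posterior(single_causal_study, 1, max_k=2)
        assert sum(pp for _, _, pp in post.entries.values()) == pytest.approx(1.0, abs=1e-9)
        assert post.logbf(NULL_MODEL) == 0.0

    def test_causal_model_beats_noncausal(self, single_causal_study):
        post = mf.exhaustive_posterior(single_causal_study, 1, max_k=1)
        pps = {m: post.pp(m) for m in post.models if m.size == 1}
        assert max(pps, key=pps.get) == SNPModel(("snp1",))

    def test_posterior_arithmetic_matches_hand_computation(self, single_causal_study):
        post = mf.exhaustive_posterior(
            single_causal_study, 1, max_k=1, snp_ids=["snp1", "snp2"]
        )
        logw = {m: lbf + lpr for m, (lbf, lpr, _) in post.entries.items()}
        norm = logsumexp(list(logw.values()))
        for m in post.models:
            assert post.pp(m) == pytest.approx(math.exp(logw[m] - norm), abs=1e-12)

    def test_null_data_prefers_null_model(self, indep_panel):
        """On unassociated data the null model has the highest pp in >= 90%
        of replicates (30 replicates, >= 27)."""
        ok = 0
        reps = 30
        for rep in range(reps):
            geno = mf.sample_genotypes(indep_panel, 30000, 0.0, seed=400 + rep)
            spec = mf.SimulationSpec(
                causal_effects=(), target_counts=(2500, 2500), seed=rep
            )
            study = mf.assign_multitrait(geno, indep_panel.snp_ids, spec)
            post = mf.exhaustive_posterior(study, 1, max_k=2)
            ok += post.top_model() == NULL_MODEL
        assert ok >= round(0.9 * reps)

    def test_model_cap_directs_to_shotgun(self, single_causal_study):
        with pytest.raises(ValueError, match="shotgun"):
            mf.exhaustive_posterior(single_causal_study, 1, max_k=3, model_cap=10)

    def test_mppi_equals_direct_summation(self, single_causal_study):
        post = mf.exhaustive_posterior(single_causal_study, 1, max_k=2)
        for snp, val in post.mppi.items():
            direct = sum(post.pp(m) for m in post.models if snp in m)
            assert val == pytest.approx(direct, abs=1e-12)


class TestShotgunSearch:
    def test_one_snp_region_matches_exhaustive(self, single_causal_study):
        ss = mf.shotgun_search(
            single_causal_study, 1, n_iter=5, n_chains=1, max_k=1,
            expected_causals=0.5, seed=1, snp_ids=["snp1"],
        )
        ex = mf.exhaustive_posterior(
            single_causal_study, 1, max_k=1, expected_causals=0.5, snp_ids=["snp1"]
        )
        assert set(ss.entries) == set(ex.entries)
        for m in ex.models:
            assert ss.pp(m) == pytest.approx(ex.pp(m), abs=1e-12)

    def test_full_visit_equals_exhaustive(self, single_causal_study):
        """Run long enough to score every model of the 6-SNP space: the pp
        must then agree with exhaustive enumeration to 1e-6."""
        ex = mf.exhaustive_posterior(single_causal_study, 1, max_k=2)
        ss = mf.shotgun_search(
            single_causal_study, 1, n_iter=60, n_chains=3, max_k=2,
            expected_causals=2.0, seed=2,
        )
        assert ss.search_meta["n_models_visited"] == len(ex.entries)
        for m in ex.models:
            assert ss.pp(m) == pytest.approx(ex.pp(m), abs=1e-6)

    def test_same_seed_identical(self, single_causal_study):
        a = mf.shotgun_search(single_causal_study, 1, n_iter=15, seed=3, max_k=2)
        b = mf.shotgun_search(single_causal_study, 1, n_iter=15, seed=3, max_k=2)
        assert a.entries == b.entries

    def test_top_model_agrees_with_exhaustive(self, block_panel):
        """On a 20-SNP block panel with one causal SNP, shotgun and exhaustive
        agree on the top model in >= 95% of replicates (20 replicates, all)."""
        agree = 0
        reps = 20
        for rep in range(reps):
            geno = mf.sample_genotypes(block_panel, 40000, 0.0, seed=500 + rep)
            spec = mf.SimulationSpec(
                causal_effects=(("snp1", 1, 1.4),), target_counts=(3000, 3000), seed=rep
            )
            study = mf.assign_multitrait(geno, block_panel.snp_ids, spec)
            reps_ids, tag_map = mf.tag_snps(study.dosages, study.snp_ids)
            ex = mf.exhaustive_posterior(
                study, 1, max_k=2, snp_ids=reps_ids, n_snps_region=20
            )
            ss = mf.shotgun_search(
                study, 1, n_iter=50, n_chains=2, max_k=2, seed=rep,
                expected_causals=2.0, snp_ids=reps_ids, n_snps_region=20,
            )
            agree += ss.top_model() == ex.top_model()
        assert agree >= round(0.95 * reps)


class TestExpandTags:
    def test_identity_tag_map_preserves_posterior(self, single_causal_study):
        post = mf.exhaustive_posterior(single_causal_study, 1, max_k=1)
        tag_map = {s: s for s in single_causal_study.snp_ids}
        out = mf.expand_tags(post, tag_map, single_causal_study, pp_cover=1.0, max_k=1)
        for m in post.models:
            assert out.pp(m) == pytest.approx(post.pp(m), abs=1e-9)

    def test_near_duplicates_get_similar_logbf(self):
        # three near-identical columns: one founder column copied with a
        # handful of allele flips (r^2 ~ 0.999)
        rng = np.random.default_rng(6)
        base = (rng.random(8000) < 0.3).astype(np.int8)
        cols = [base]
        for flips in (2, 3):
            c = base.copy()
            idx = rng.choice(len(c), flips, replace=False)
            c[idx] = 1 - c[idx]
            cols.append(c)
        panel = mf.HaplotypePanel(
            alleles=np.column_stack(cols),
            snp_ids=["snp1", "snp2", "snp3"],
            positions=np.array([1000, 2000, 3000]),
        )
        geno = mf.sample_genotypes(panel, 50000, 0.0, seed=7)
        spec = mf.SimulationSpec(
            causal_effects=(("snp1", 1, 1.3),), target_counts=(2000, 2000), seed=8
        )
        study = mf.assign_multitrait(geno, panel.snp_ids, spec)
        reps_ids, tag_map = mf.tag_snps(study.dosages, study.snp_ids, 0.99)
        post = mf.exhaustive_posterior(study, 1, max_k=1, snp_ids=reps_ids, n_snps_region=3)
        out = mf.expand_tags(post, tag_map, study, pp_cover=0.99, max_k=1)
        one_snp = [m for m in out.models if m.size == 1]
        assert len(one_snp) == 3
        bfs = [out.logbf(m) for m in one_snp]
        assert max(bfs) - min(bfs) < 0.5

    def test_full_cover_expands_all_models(self, single_causal_study):
        post = mf.exhaustive_posterior(
            single_causal_study, 1, max_k=1, snp_ids=["snp1", "snp2"]
        )
        out = mf.expand_tags(
            post, {s: s for s in ["snp1", "snp2"]}, single_causal_study,
            pp_cover=1.0, max_k=1,
        )
        assert set(out.entries) == set(post.entries)


class TestForwardStepwise:
    def test_null_data_selects_nothing(self, indep_panel):
        """Empty model on unassociated data in >= 99% of replicates (20/20)."""
        for rep in range(20):
            geno = mf.sample_genotypes(indep_panel, 30000, 0.0, seed=600 + rep)
            spec = mf.SimulationSpec(
                causal_effects=(), target_counts=(2000, 2000), seed=rep
            )
            study = mf.assign_multitrait(geno, indep_panel.snp_ids, spec)
            assert mf.forward_stepwise(study, 1).model == NULL_MODEL

    def test_causal_snp_selected_first(self, indep_panel):
        """The causal SNP is the first selection in >= 95% of replicates
        (20 replicates; no proxies exist on an independent panel)."""
        hits = 0
        reps = 20
        for rep in range(reps):
            geno = mf.sample_genotypes(indep_panel, 60000, 0.0, seed=700 + rep)
            spec = mf.SimulationSpec(
                causal_effects=(("snp1", 1, 1.5),), target_counts=(5000, 5000), seed=rep
            )
            study = mf.assign_multitrait(geno, indep_panel.snp_ids, spec)
            sw = mf.forward_stepwise(study, 1)
            hits += bool(sw.trace) and sw.trace[0][0] == "snp1"
        assert hits >= round(0.95 * reps)

    def test_joint_tag_traps_stepwise(self, jointtag_trio):
        """With two equal-effect causal SNPs both positively correlated with a
        tag, stepwise picks the tag first in the majority of replicates."""
        first_tag = 0
        reps = 20
        for rep in range(reps):
            geno = mf.sample_genotypes(jointtag_trio, 60000, 0.0, seed=800 + rep)
            spec = mf.SimulationSpec(
                causal_effects=(("snp1", 1, 1.6), ("snp2", 1, 1.6)),
                target_counts=(5000, 5000),
                seed=rep,
            )
            study = mf.assign_multitrait(geno, jointtag_trio.snp_ids, spec)
            sw = mf.forward_stepwise(study, 1)
            first_tag += bool(sw.trace) and sw.trace[0][0] == "snp3"
        assert first_tag > reps / 2

    def test_retained_pvalues_below_threshold(self, single_causal_study):
        sw = mf.forward_stepwise(single_causal_study, 1, p_threshold=1e-6)
        assert all(p < 1e-6 for p in sw.step_pvalues)
        assert len(sw.trace) == sw.model.size


class TestBICTable:
    def test_identical_models_identical_bic(self, single_causal_study):
        tab = mf.bic_table(single_causal_study, 1, [NULL_MODEL, NULL_MODEL])
        assert tab["bic"].iloc[0] == tab["bic"].iloc[1]

    def test_sorted_ascending(self, single_causal_study):
        tab = mf.bic_table(
            single_causal_study, 1,
            [NULL_MODEL, SNPModel(("snp1",)), SNPModel(("snp2",))],
        )
        assert list(tab["bic"]) == sorted(tab["bic"])
        assert tab["model"].iloc[0] == "snp1"

    def test_nested_null_penalty_is_log_n(self, indep_panel):
        """On null data, each extra SNP raises BIC by ~log(n) on average
        (within 3 over 30 replicates)."""
        diffs = []
        for rep in range(30):
            geno = mf.sample_genotypes(indep_panel, 20000, 0.0, seed=900 + rep)
            spec = mf.SimulationSpec(
                causal_effects=(), target_counts=(1000, 1000), seed=rep
            )
            study = mf.assign_multitrait(geno, indep_panel.snp_ids, spec)
            tab = mf.bic_table(
                study, 1, [NULL_MODEL, SNPModel(("snp1",))]
            ).set_index("model")
            diffs.append(tab.loc["snp1", "bic"] - tab.loc["(null)", "bic"])
        assert abs(np.mean(diffs) - math.log(2000)) < 3

    def test_true_two_snp_model_beats_joint_tag(self, jointtag_trio):
        """The generating 2-SNP model has lower BIC than its joint tag's
        1-SNP model in >= 80% of replicates at large n (15 replicates)."""
        wins = 0
        reps = 15
        for rep in range(reps):
            geno = mf.sample_genotypes(jointtag_trio, 120000, 0.0, seed=950 + rep)
            spec = mf.SimulationSpec(
                causal_effects=(("snp1", 1, 1.4), ("snp2", 1, 1.4)),
                target_counts=(10000, 10000),
                seed=rep,
            )
            study = mf.assign_multitrait(geno, jointtag_trio.snp_ids, spec)
            tab = mf.bic_table(
                study, 1, [SNPModel(("snp1", "snp2")), SNPModel(("snp3",))]
            ).set_index("model")
            wins += tab.loc["snp1,snp2", "bic"] < tab.loc["snp3", "bic"]
        assert wins >= round(0.8 * reps)
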