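import numpy as np
import pandas as pd
import pytest

from gsbreed import presets
from gsbreed.index import IndexValue, index_scores
from gsbreed.scheme import (
    SchemeConfig,
    apply_mortality,
    rank_individuals,
    run_program,
    run_ps_cycle,
    selection_overlap,
    true_index,
    update_marker_panel,
)
from gsbreed.simulate import (
    GenotypeMatrix,
    build_trait_architecture,
    make_map,
    simulate_founders,
)


@pytest.fixture(scope="module")
def mini_map():
    return make_map(150, 4, 100.0, 0.5, seed=101)


@pytest.fixture(scope="module")
def mini_arch(mini_map):
    return build_trait_architecture(
        mini_map, presets.target_architecture_corr().to_numpy(), h2=0.5,
        n_qtl=50, seed=102, trait_names=["seed_yield"] + presets.TRAIT_NAMES,
    )


@pytest.fixture(scope="module")
def mini_config():
    return SchemeConfig(scheme="GS", years=1, gs_cycle1_size=48,
                        gs_cycle2_size=24, ps_size=48, n_selected=6,
                        bottleneck_k=20, founder_size=60,
                        eval_sample_size=12, seed=103)


@pytest.fixture(scope="module")
def gs_result(mini_config, mini_map, mini_arch, index_model):
    return run_program(mini_config, mini_map, mini_arch, index_model)


class TestSelectionPrimitives:
    def test_rank_deterministic_with_ties(self):
        vals = [IndexValue("b", 1.0, "observed"), IndexValue("a", 1.0, "observed"),
                IndexValue("c", 2.0, "observed")]
        assert rank_individuals(vals) == ["c", "a", "b"]

    def test_rank_from_series(self):
        s = pd.Series({"x": 0.5, "y": 2.0, "z": 1.0})
        assert rank_individuals(s) == ["y", "z", "x"]

    def test_mortality_none(self):
        ranked = list("abcdefghij")
        assert apply_mortality(ranked, 3) == ["a", "b", "c"]

    def test_mortality_nine_of_twelve_dead(self):
        ranked = [f"p{i}" for i in range(24)]
        deaths = set(ranked[:12]) - {"p0", "p5", "p11"}  # 9 of the top 12 die
        sel = apply_mortality(ranked, 12, deaths)
        assert sel == ["p0", "p5", "p11"] + ranked[12:21]

    def test_mortality_all_top_dead(self):
        ranked = [f"p{i}" for i in range(20)]
        sel = apply_mortality(ranked, 5, set(ranked[:5]))
        assert sel == ranked[5:10]

    def test_mortality_insufficient_survivors(self):
        with pytest.raises(ValueError, match="survivors"):
            apply_mortality(["a", "b"], 2, {"a"})

    def test_duplicate_ranking_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            apply_mortality(["a", "a"], 1)


class TestSelectionOverlap:
    def test_identical_rankings(self):
        r = list("abcdef")
        assert selection_overlap(r, list(r), 4) == 4

    def test_disjoint_topk(self):
        assert selection_overlap(list("abcd"), list("cdab"), 2) == 0

    def test_duplicates_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            selection_overlap(["a", "a"], ["a", "b"], 1)

    def test_hypergeometric_expectation(self):
        # random independent rankings of 192, k=12: E[overlap] = 144/192 = 0.75
        rng = np.random.default_rng(104)
        ids = np.arange(192)
        overlaps = [
            selection_overlap(list(rng.permutation(ids)),
                              list(rng.permutation(ids)), 12)
            for _ in range(1000)
        ]
        assert abs(np.mean(overlaps) - 0.75) < 0.2


class TestMarkerPanel:
    def _geno(self, vals):
        n, m = vals.shape
        return GenotypeMatrix(
            np.array([f"i{k}" for k in range(n)], dtype=object),
            np.array([f"m{k}" for k in range(m)], dtype=object),
            vals.astype(float),
            np.array(["codominant"] * m, dtype=object),
        )

    def test_fully_polymorphic_unchanged(self):
        rng = np.random.default_rng(105)
        geno = self._geno(rng.integers(0, 3, (20, 10)))
        panel = [f"m{k}" for k in range(10)]
        assert update_marker_panel(panel, geno) == panel

    def test_constant_column_removed(self):
        vals = np.random.default_rng(106).integers(0, 3, (20, 3)).astype(float)
        vals[:, 1] = 2.0
        geno = self._geno(vals)
        assert update_marker_panel(["m0", "m1", "m2"], geno) == ["m0", "m2"]

    def test_empty_panel_rejected(self):
        geno = self._geno(np.ones((5, 2)))
        with pytest.raises(ValueError, match="empty"):
            update_marker_panel(["m0", "m1"], geno)

    def test_panel_sizes_non_increasing_over_program(self, gs_result):
        sizes = [gs_result.panel_sizes[r.cycle_label] for r in gs_result.records]
        assert all(a >= b for a, b in zip(sizes, sizes[1:]))


class TestCycleContracts:
    def test_gs_cycle1_post_pollination_semantics(self, gs_result, mini_config):
        rec = gs_result.records[0]
        assert rec.cycle_label == "GS1"
        assert rec.selection_source == "expected"
        assert len(rec.selected_ids) == mini_config.n_selected
        assert rec.seed_parent_ids == rec.selected_ids
        # sires are the whole population, not the selected subset
        assert len(rec.pollen_parent_ids) == mini_config.gs_cycle1_size
        offspring = gs_result.populations["post_gs1"]
        assert set(offspring.dam) <= set(rec.selected_ids)
        assert len(set(offspring.sire)) > mini_config.n_selected / 2

    def test_gs_cycle2_pre_pollination_semantics(self, gs_result, mini_config):
        rec = gs_result.records[1]
        assert rec.cycle_label == "GS2"
        assert rec.selection_source == "predicted"
        assert rec.pollen_parent_ids == rec.seed_parent_ids == rec.selected_ids
        offspring = gs_result.populations["post_gs2"]
        assert set(offspring.dam) <= set(rec.selected_ids)
        assert set(offspring.sire) <= set(rec.selected_ids)

    def test_no_selfing_anywhere(self, gs_result):
        for label, pop in gs_result.populations.items():
            if label == "initial" and pop.dam[0] is None:
                continue
            assert all(d != s for d, s in zip(pop.dam, pop.sire))

    def test_offspring_are_parental_mosaics(self, gs_result):
        parents = gs_result.populations["post_gs1"]
        child_pop = gs_result.populations["post_gs2"]
        by_id = {i: k for k, i in enumerate(parents.ids)}
        for k in range(min(5, child_pop.n)):
            dam_h = parents.haplotypes[by_id[child_pop.dam[k]]]
            assert np.all((child_pop.haplotypes[k, :, 0] == dam_h[:, 0])
                          | (child_pop.haplotypes[k, :, 0] == dam_h[:, 1]))

    def test_ps_cycle_observed_selection(self, mini_map, mini_arch, index_model):
        cfg = SchemeConfig(scheme="PS", years=1, ps_size=48, n_selected=6,
                           gs_cycle1_size=48, gs_cycle2_size=24,
                           bottleneck_k=20, founder_size=60,
                           eval_sample_size=12, seed=107)
        pop = simulate_founders(48, mini_map, seed=108)
        off, phenos, rec = run_ps_cycle(pop, mini_map, mini_arch, index_model,
                                        cfg, "PS1", seed=109)
        assert rec.selection_source == "observed"
        # with the observed index the selected set is exactly the top-n
        scores = index_scores(phenos, index_model)
        assert set(rec.selected_ids) == set(rank_individuals(scores)[:6])
        assert off.n == cfg.ps_size

    def test_perfect_index_selects_truly_best(self, mini_map, index_model):
        # error_sd = 0: observed phenotype equals genetic value
        arch = build_trait_architecture(
            mini_map, presets.target_architecture_corr().to_numpy(), h2=1.0,
            n_qtl=50, seed=110, trait_names=["seed_yield"] + presets.TRAIT_NAMES,
        )
        cfg = SchemeConfig(scheme="PS", years=1, ps_size=48, n_selected=6,
                           gs_cycle1_size=48, gs_cycle2_size=24,
                           bottleneck_k=20, founder_size=60,
                           eval_sample_size=12, seed=111)
        pop = simulate_founders(48, mini_map, seed=112)
        _, _, rec = run_ps_cycle(pop, mini_map, arch, index_model, cfg, "PS1", seed=113)
        best_true = rank_individuals(true_index(pop, arch, index_model))[:6]
        assert set(rec.selected_ids) == set(best_true)


class TestRunProgram:
    def test_cycle_bookkeeping(self, gs_result):
        assert [r.cycle_label for r in gs_result.records] == ["GS1", "GS2"]
        assert set(gs_result.populations) == {"initial", "post_gs1", "post_gs2"}
        assert set(gs_result.eval_phenotypes) == set(gs_result.populations)

    def test_three_year_gs_labels(self, mini_map, mini_arch, index_model):
        cfg = SchemeConfig(scheme="GS", years=3, gs_cycle1_size=40,
                           gs_cycle2_size=20, ps_size=40, n_selected=5,
                           bottleneck_k=15, founder_size=50,
                           eval_sample_size=10, seed=114)
        res = run_program(cfg, mini_map, mini_arch, index_model)
        assert [r.cycle_label for r in res.records] == [
            "GS1", "GS2", "GS3", "GS4", "GS5", "GS6"]

    def test_ps_program_labels(self, mini_map, mini_arch, index_model):
        cfg = SchemeConfig(scheme="PS", years=3, ps_size=40, n_selected=5,
                           gs_cycle1_size=40, gs_cycle2_size=20,
                           bottleneck_k=15, founder_size=50,
                           eval_sample_size=10, seed=115)
        res = run_program(cfg, mini_map, mini_arch, index_model)
        assert [r.cycle_label for r in res.records] == ["PS1", "PS2", "PS3"]

    def test_trajectory_determinism(self, mini_config, mini_map, mini_arch, index_model):
        a = run_program(mini_config, mini_map, mini_arch, index_model)
        b = run_program(mini_config, mini_map, mini_arch, index_model)
        for label in a.populations:
            np.testing.assert_array_equal(a.populations[label].haplotypes,
                                          b.populations[label].haplotypes)
        assert [r.selected_ids for r in a.records] == [r.selected_ids for r in b.records]
        for label in a.eval_phenotypes:
            pd.testing.assert_frame_equal(a.eval_phenotypes[label],
                                          b.eval_phenotypes[label])

    def test_selection_gain_positive(self, gs_result, mini_arch, index_model):
        ti = {lab: true_index(p, mini_arch, index_model).mean()
              for lab, p in gs_result.populations.items()}
        assert ti["post_gs2"] > ti["initial"]

    def test_mortality_contingency_in_program(self, mini_map, mini_arch, index_model):
        cfg = SchemeConfig(scheme="GS", years=1, gs_cycle1_size=48,
                           gs_cycle2_size=24, ps_size=48, n_selected=6,
                           bottleneck_k=20, founder_size=60, eval_sample_size=12,
                           mortality_rate=0.3, seed=116)
        res = run_program(cfg, mini_map, mini_arch, index_model)
        for rec in res.records:
            assert len(rec.selected_ids) == 6

    def test_random_index_no_systematic_gain(self, mini_map, mini_arch, index_model):
        # selection accuracy forced to zero: rank by pure noise
        from gsbreed.simulate import random_mate

        rng = np.random.default_rng(118)
        gains = []
        for _ in range(60):
            pop = simulate_founders(48, mini_map, seed=int(rng.integers(2**31)))
            noise = pd.Series(rng.standard_normal(pop.n), index=pop.ids)
            selected = rank_individuals(noise)[:6]
            off = random_mate(pop, 48, mini_map, dams=selected, sires=None,
                              seed=int(rng.integers(2**31)))
            gains.append(true_index(off, mini_arch, index_model).mean()
                         - true_index(pop, mini_arch, index_model).mean())
        se = np.std(gains, ddof=1) / np.sqrt(len(gains))
        assert abs(np.mean(gains)) < 4 * se + 1e-3

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError, match="scheme"):
            SchemeConfig(scheme="XX")
        with pytest.raises(ValueError, match="n_selected"):
            SchemeConfig(n_selected=100, gs_cycle2_size=48)
        with pytest.raises(ValueError, match="policy"):
            SchemeConfig(update_policy="sometimes")


class TestUpdatePolicy:
    def test_annual_updating_beats_frozen_models_at_final_cycle(self, index_model):
        # accuracy of the models actually used at the 5th cycle, paired by seed
        from gsbreed.gblup import expected_index
        from gsbreed.simulate import build_trait_architecture, make_map

        rng = np.random.default_rng(120)
        diffs = []
        for _ in range(8):
            seed = int(rng.integers(2**31))
            gm = make_map(400, 8, 100.0, 0.5, seed=seed)
            arch = build_trait_architecture(
                gm, presets.target_architecture_corr().to_numpy(), h2=0.5,
                n_qtl=80, seed=seed + 1,
                trait_names=["seed_yield"] + presets.TRAIT_NAMES,
            )
            acc = {}
            for policy in ("annual", "never"):
                cfg = SchemeConfig(scheme="GS", years=3, gs_cycle1_size=96,
                                   gs_cycle2_size=24, n_selected=8,
                                   bottleneck_k=30, founder_size=120,
                                   eval_sample_size=10, update_policy=policy,
                                   seed=seed + 2)
                res = run_program(cfg, gm, arch, index_model)
                models = res.models_by_version[res.records[4].model_version]
                exp = np.array([v.value for v in expected_index(
                    models, res.genotypes["GS5"], index_model)])
                obs = index_scores(res.phenotypes["GS5"][index_model.trait_names],
                                   index_model).to_numpy()
                acc[policy] = np.corrcoef(exp, obs)[0, 1]
            diffs.append(acc["annual"] - acc["never"])
        assert np.mean(diffs) > 0

    def test_never_policy_keeps_first_model_version(self, index_model):
        from gsbreed.simulate import build_trait_architecture, make_map

        gm = make_map(200, 4, 100.0, 0.5, seed=121)
        arch = build_trait_architecture(
            gm, presets.target_architecture_corr().to_numpy(), h2=0.5,
            n_qtl=50, seed=122, trait_names=["seed_yield"] + presets.TRAIT_NAMES,
        )
        cfg = SchemeConfig(scheme="GS", years=2, gs_cycle1_size=48,
                           gs_cycle2_size=16, n_selected=6, bottleneck_k=20,
                           founder_size=60, eval_sample_size=10,
                           update_policy="never", seed=123)
        res = run_program(cfg, gm, arch, index_model)
        assert all(r.model_version == "GS1" for r in res.records)
        assert list(res.models_by_version) == ["GS1"]
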