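"""Hedges' g* effect sizes and DerSimonian-Laird combination, cross-checked
against statsmodels' meta-analysis routines."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from statsmodels.stats.meta_analysis import combine_effects

from prognet.meta import (
    EffectSize,
    GroupSummary,
    effect_from_values,
    hedges_g_star,
    random_effects_combine,
    run_grade_meta,
)
from prognet.simulate import gen_grade_datasets


class TestHedgesGStar:
    def test_hand_example_n10(self):
        e = hedges_g_star(GroupSummary(10, 1.0, 1.0), GroupSummary(10, 0.0, 1.0))
        assert e.g == pytest.approx(1.0)
        assert e.g_star == pytest.approx(1.0 - 3.0 / 71.0)       # 0.957746...
        expected_se = np.sqrt(20 / 100 + e.g_star**2 / (2 * (20 - 3.94)))
        assert e.se == pytest.approx(expected_se)
        assert e.g_star == pytest.approx(0.9577, abs=1e-4)
        assert e.se == pytest.approx(0.4781, abs=1e-3)

    def test_zero_effect_se_reduces_to_size_term(self):
        e = hedges_g_star(GroupSummary(12, 2.0, 1.5), GroupSummary(8, 2.0, 1.5))
        assert e.g == 0.0 and e.g_star == 0.0
        assert e.se == pytest.approx(np.sqrt(20 / 96))

    @given(
        n1=st.integers(4, 60),
        n2=st.integers(4, 60),
        m1=st.floats(-3, 3),
        m2=st.floats(-3, 3),
        sd=st.floats(0.2, 3),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_antisymmetric_under_group_swap(self, n1, n2, m1, m2, sd):
        a, b = GroupSummary(n1, m1, sd), GroupSummary(n2, m2, sd)
        fwd, rev = hedges_g_star(a, b), hedges_g_star(b, a)
        assert fwd.g == pytest.approx(-rev.g, abs=1e-12)
        assert fwd.g_star == pytest.approx(-rev.g_star, abs=1e-12)
        assert fwd.se == pytest.approx(rev.se, abs=1e-12)
        assert abs(fwd.g_star) <= abs(fwd.g) + 1e-15

    def test_correction_vanishes_for_large_samples(self):
        for n in (40, 80, 200):
            e = hedges_g_star(GroupSummary(n, 1.0, 1.0), GroupSummary(n, 0.0, 1.0))
            if 2 * n >= 80:
                assert abs(e.g_star - e.g) < 0.01 * abs(e.g)

    def test_degenerate_groups_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            hedges_g_star(GroupSummary(10, 1.0, 0.0), GroupSummary(10, 0.0, 0.0))
        with pytest.raises(ValueError):
            hedges_g_star(GroupSummary(2, 1.0, 1.0), GroupSummary(1, 0.0, 1.0))


class TestRandomEffects:
    def test_homogeneous_effects_force_tau2_zero(self):
        effects = [EffectSize(0.5, 0.5, 0.1, 10, 10)] * 5
        res = random_effects_combine(effects)
        assert res.tau2 == 0.0
        assert res.combined_smd == pytest.approx(0.5)
        assert res.se == pytest.approx(0.1 / np.sqrt(5))

    def test_symmetric_pair_combines_to_midpoint(self):
        effects = [EffectSize(0.0, 0.0, 0.2, 10, 10), EffectSize(1.0, 1.0, 0.2, 10, 10)]
        res = random_effects_combine(effects)
        assert res.combined_smd == pytest.approx(0.5)

    def test_zero_tau2_equals_fixed_effect(self, rng):
        y = rng.normal(0.4, 0.05, size=6)
        se = rng.uniform(0.1, 0.3, size=6)
        effects = [EffectSize(v, v, s, 20, 20) for v, s in zip(y, se)]
        res = random_effects_combine(effects)
        if res.tau2 == 0.0:
            w = 1 / se**2
            assert res.combined_smd == pytest.approx(np.sum(w * y) / np.sum(w))

    def test_matches_statsmodels_dersimonian_laird(self, rng):
        # statsmodels reports the untruncated moment estimate, which can go
        # negative; the conventional DL estimator truncates at zero, so only
        # heterogeneous draws are compared directly.
        n_compared = 0
        for _ in range(30):
            k = int(rng.integers(3, 12))
            y = rng.normal(0.5, 0.6, size=k)
            v = rng.uniform(0.02, 0.2, size=k)
            effects = [EffectSize(a, a, float(np.sqrt(b)), 10, 10)
                       for a, b in zip(y, v)]
            res = random_effects_combine(effects)
            sm = combine_effects(y, v, method_re="dl")
            if float(sm.tau2) < 0:
                assert res.tau2 == 0.0
                continue
            n_compared += 1
            assert res.tau2 == pytest.approx(float(sm.tau2), rel=1e-8, abs=1e-12)
            frame = sm.summary_frame()
            assert res.combined_smd == pytest.approx(
                float(frame.loc["random effect", "eff"]), rel=1e-8
            )
            assert res.se == pytest.approx(
                float(frame.loc["random effect", "sd_eff"]), rel=1e-8
            )
        assert n_compared >= 10

    def test_dl_and_reml_match_r_metafor(self, rng):
        import subprocess

        y = rng.normal(0.6, 0.5, 8)
        v = rng.uniform(0.03, 0.2, 8)
        effects = [EffectSize(a, a, float(np.sqrt(b)), 10, 10)
                   for a, b in zip(y, v)]
        dl = random_effects_combine(effects, method="dl")
        reml = random_effects_combine(effects, method="reml")
        ys = ",".join(f"{x:.17g}" for x in y)
        vs = ",".join(f"{x:.17g}" for x in v)
        script = (
            "suppressMessages(library(metafor));"
            f"yi <- c({ys}); vi <- c({vs});"
            'd <- rma(yi, vi, method="DL"); r <- rma(yi, vi, method="REML");'
            'cat(d$tau2, d$beta, d$se, r$tau2, r$beta, r$se, sep="\\n")'
        )
        out = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, check=True
        )
        vals = [float(x) for x in out.stdout.split()]
        for got, ref in zip(
            [dl.tau2, dl.combined_smd, dl.se, reml.tau2, reml.combined_smd, reml.se],
            vals,
        ):
            # metafor iterates Fisher scoring with its own stopping rule;
            # agreement is to optimizer tolerance, not machine precision
            assert got == pytest.approx(ref, rel=1e-3, abs=1e-5)

    def test_unknown_method_rejected(self):
        effects = [EffectSize(0.5, 0.5, 0.1, 10, 10)] * 3
        with pytest.raises(ValueError, match="method"):
            random_effects_combine(effects, method="ml")

    def test_single_effect_rejected(self):
        with pytest.raises(ValueError):
            random_effects_combine([EffectSize(0.5, 0.5, 0.1, 10, 10)])


class TestRunGradeMeta:
    @staticmethod
    def _as_runner_inputs(config):
        return gen_grade_datasets(config, as_matrices=True)

    def test_recovers_planted_smd(self, small_config):
        cfg = dataclasses.replace(small_config, planted_smd=0.8, tau=0.0)
        result, effects = run_grade_meta(self._as_runner_inputs(cfg), gene="GENE")
        assert len(effects) == cfg.n_grade_datasets
        assert result.combined_smd == pytest.approx(0.8, abs=3 * result.se)

    def test_ineligible_datasets_excluded(self, small_config):
        datasets = self._as_runner_inputs(small_config)
        # cripple one dataset: relabel most grade I tumors as grade II
        g1 = [s for s, g in datasets[0]["grades"].items() if g == "I"]
        for s in g1[: len(g1) - 5]:
            datasets[0]["grades"][s] = "II"
        result, effects = run_grade_meta(datasets, gene="GENE")
        assert result.k == small_config.n_grade_datasets - 1

    def test_all_ineligible_is_an_error(self, small_config):
        datasets = self._as_runner_inputs(small_config)
        for ds in datasets:
            ds["grades"] = {s: "II" for s in ds["grades"]}
        with pytest.raises(ValueError, match="eligible"):
            run_grade_meta(datasets, gene="GENE")

    def test_duplicate_patients_deduplicated(self, small_config):
        datasets = self._as_runner_inputs(small_config)
        ds = datasets[0]
        # collapse the first 8 samples onto 4 patients; the rest stay unique
        ids = list(ds["grades"])
        ds["patient_ids"] = {
            s: (f"pt{j // 2}" if j < 8 else s) for j, s in enumerate(ids)
        }
        _, effects = run_grade_meta(datasets[:3], gene="GENE")
        first = next(e for e in effects if e.label == "dataset_1")
        assert first.n1 + first.n2 == len(ids) - 4

    def test_requires_exactly_one_target(self, small_config):
        datasets = self._as_runner_inputs(small_config)
        with pytest.raises(ValueError):
            run_grade_meta(datasets)
        with pytest.raises(ValueError):
            run_grade_meta(datasets, gene="GENE", genes=["GENE"])


def test_effect_from_values_matches_summaries(rng):
    a = rng.normal(1.0, 1.0, 30)
    b = rng.normal(0.0, 1.2, 25)
    e1 = effect_from_values(a, b)
    e2 = hedges_g_star(GroupSummary.from_values(a), GroupSummary.from_values(b))
    assert e1 == e2
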