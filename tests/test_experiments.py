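"""Perturbation experiments: controls, monotonicity, thresholds, the t-test."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import special, stats

from mirflux.engine import simulate, steady_state
from mirflux.experiments import (
    ACTIVATION_EPSILON,
    EXPERIMENT_CONFIG,
    OVEREXPRESSION_LEVEL,
    PerturbationSpec,
    ReadoutSet,
    ScreenResult,
    activation_threshold,
    anti_mirna_screen,
    control_state,
    dose_scan,
    log2_ratio,
    overexpression_experiment,
    rank_anti_mirnas,
    t_test_p_value,
    target_count_histogram,
)
from mirflux.experiments import _silenced, _with_clamps
from mirflux.model import TargetTable, UnknownEntityError, mrna_id, protein_id

AKT_READOUTS = ReadoutSet(
    "akt_dependent",
    ("P-AKT", "P-BAD-1", "P-TP53", "P-MDM2", "P-CDKN1", "P-MTOR"))


class TestControlState:
    def test_control_vs_itself_is_zero(self, fixture_model):
        ctrl = control_state(fixture_model)
        ids = list(ctrl)
        assert (log2_ratio(ctrl, ctrl, ids) == 0.0).all()

    def test_control_reproducible(self, fixture_model):
        a = control_state(fixture_model)
        b = control_state(fixture_model)
        assert a == b

    def test_expressed_genes_make_protein(self, fixture_inputs, fixture_model):
        _, table = fixture_inputs
        ctrl = control_state(fixture_model, no_mirnas=True)
        for _, target, _ in table.rows:
            assert ctrl[protein_id(target)] > 0.0


class TestOverexpression:
    def test_level_zero_is_the_control(self, fixture_model):
        ratios = overexpression_experiment(fixture_model, "mir-192", 0.0)
        assert (ratios == 0.0).all()

    def test_represses_all_and_only_direct_targets(self, fixture_inputs,
                                                   fixture_model):
        """Every direct-target transcript drops beyond the heatmap mask and
        every other transcript stays inside it."""
        _, table = fixture_inputs
        for mirna in table.mirnas():
            ratios = overexpression_experiment(
                fixture_model, mirna, OVEREXPRESSION_LEVEL)
            targets = {mrna_id(t) for t in table.targets_of(mirna)}
            for eid, value in ratios.items():
                if eid in targets:
                    assert value < -0.001, (mirna, eid)
                else:
                    assert abs(value) < 0.001, (mirna, eid)

    def test_unknown_mirna_rejected(self, fixture_model):
        with pytest.raises(UnknownEntityError):
            overexpression_experiment(fixture_model, "mir-404", 1.0)


class TestDoseScan:
    def test_direct_and_downstream_monotone_non_increasing(self, fixture_model):
        """The mir-192 archetype: direct-target proteins and downstream
        actives fall monotonically with the miRNA gene level (the receptor
        itself is a target)."""
        readouts = ReadoutSet("t", tuple(
            protein_id(g) for g in ("TP53", "PTEN", "MDM2", "CDKN1"))
            + ("P-AKT", "P-ERK"))
        spec = PerturbationSpec("mirna_overexpression", "mir-192",
                                (0, 1, 10, 100, 1000, 10000))
        table = dose_scan(fixture_model, spec, readouts)
        diffs = table.diff().dropna()
        assert (diffs <= 0).all().all()

    def test_single_level_matches_overexpression_state(self, fixture_model):
        spec = PerturbationSpec("mirna_overexpression", "mir-489", (0.0, 5.0))
        table = dose_scan(fixture_model, spec)
        state = steady_state(
            _with_clamps(fixture_model,
                         _silenced(fixture_model, keep="mir-489", level=5.0)),
            cfg=EXPERIMENT_CONFIG)
        for eid in table.columns:
            assert table.loc[5.0, eid] == pytest.approx(state[eid])

    def test_needs_two_levels(self, fixture_model):
        with pytest.raises(ValueError):
            dose_scan(fixture_model,
                      PerturbationSpec("mirna_overexpression", "mir-192", (1.0,)))


class TestActivationThreshold:
    LEVELS = tuple(float(10 ** e) for e in np.arange(-4, 1.01, 0.25))

    def test_repressor_raises_the_threshold(self, fixture_model):
        """The mir-181c archetype: with the miRNA expressed at 1 nM the EGFR
        level needed to activate the AKT-dependent readouts is strictly
        larger than after knocking the miRNA out."""
        with_mir = _with_clamps(fixture_model,
                                _silenced(fixture_model, keep="mir-181c", level=1.0))
        without = _with_clamps(fixture_model, _silenced(fixture_model))
        t_with = activation_threshold(with_mir, "EGFR", self.LEVELS, AKT_READOUTS)
        t_without = activation_threshold(without, "EGFR", self.LEVELS, AKT_READOUTS)
        assert t_without is not None and t_with is not None
        assert t_with > t_without

    def test_threshold_non_decreasing_in_mirna_level(self, fixture_model):
        thresholds = []
        for level in (0.0, 1.0, 3.0):
            m = _with_clamps(fixture_model,
                             _silenced(fixture_model, keep="mir-181c", level=level))
            thresholds.append(
                activation_threshold(m, "EGFR", self.LEVELS, AKT_READOUTS))
        assert all(t is not None for t in thresholds)
        assert thresholds == sorted(thresholds)

    def test_never_met_returns_sentinel(self, fixture_model):
        crit = lambda x: x > 1e9
        m = _with_clamps(fixture_model, _silenced(fixture_model))
        assert activation_threshold(m, "EGFR", (0.1, 1.0), AKT_READOUTS,
                                    criterion=crit) is None

    def test_levels_must_increase(self, fixture_model):
        with pytest.raises(ValueError):
            activation_threshold(fixture_model, "EGFR", (1.0, 1.0), AKT_READOUTS)


class TestAntiMirnaReversal:
    @pytest.mark.parametrize("mirna", ["mir-489", "mir-34a"])
    def test_saturating_dose_restores_control(self, fixture_inputs,
                                              fixture_model, mirna):
        """At a saturating inhibitor dose, direct and indirect readouts sit
        within |log2| < 0.05 of the miRNA-free control."""
        _, table = fixture_inputs
        baseline = control_state(fixture_model, no_mirnas=True)
        overrides = _silenced(fixture_model, keep=mirna,
                              level=OVEREXPRESSION_LEVEL)
        overrides[f"anti-{mirna}"] = 100.0 * OVEREXPRESSION_LEVEL
        state = steady_state(_with_clamps(fixture_model, overrides),
                             cfg=EXPERIMENT_CONFIG)
        readouts = ([mrna_id(t) for t in table.targets_of(mirna)]
                    + [protein_id(t) for t in table.targets_of(mirna)]
                    + ["P-AKT", "P-ERK", "P-BAD-1"])
        ratios = log2_ratio(state, baseline, readouts)
        assert float(ratios.abs().max()) < 0.05

    def test_inert_complex_accumulates_monotonically(self, fixture_model):
        overrides = _silenced(fixture_model, keep="mir-489", level=1.0)
        overrides["anti-mir-489"] = 10.0
        traj = simulate(_with_clamps(fixture_model, overrides), n_steps=200,
                        cfg=EXPERIMENT_CONFIG)
        col = traj.markings[:, traj.ids.index("mir-489:anti-mir-489")]
        assert np.all(np.diff(col) >= -1e-12)
        assert col[-1] > 0.0

    def test_zero_dose_is_bit_identical_to_unmodified(self, fixture_model):
        overrides = _silenced(fixture_model, keep="mir-489", level=1.0)
        a = simulate(_with_clamps(fixture_model, overrides), n_steps=50)
        overrides["anti-mir-489"] = 0.0
        b = simulate(_with_clamps(fixture_model, overrides), n_steps=50)
        shared = [i for i in a.ids]
        assert np.array_equal(a.markings, b.markings[:, [b.ids.index(i) for i in shared]])


class TestTTest:
    def test_identical_markings_give_one(self):
        m = {"a": 1.0, "b": 2.0, "c": 0.0}
        assert t_test_p_value(m, dict(m)) == 1.0

    def test_matches_textbook_t_cdf(self):
        """Constructed pair: p agrees with the incomplete-beta form of the
        t CDF to 1e-10."""
        state = {f"c{i}": v for i, v in enumerate(
            [1.2, 0.8, 1.5, 2.0, 0.3, 1.1, 0.9, 1.7])}
        control = {f"c{i}": v for i, v in enumerate(
            [1.0, 1.0, 1.0, 1.5, 0.2, 1.0, 1.0, 1.0])}
        d = np.array([state[k] - control[k] for k in sorted(state)])
        n = len(d)
        t = d.mean() / (d.std(ddof=1) / math.sqrt(n))
        nu = n - 1
        # two-sided tail via the regularized incomplete beta function
        p_ref = special.betainc(nu / 2.0, 0.5, nu / (nu + t * t))
        assert t_test_p_value(state, control) == pytest.approx(p_ref, abs=1e-10)

    def test_larger_uniform_shift_smaller_p(self):
        rng = np.random.default_rng(7)
        base = rng.uniform(0.5, 1.5, size=30)
        noise = rng.normal(0, 0.05, size=30)
        previous = 1.0
        for shift in (0.01, 0.05, 0.2, 1.0):
            control = {f"c{i}": v for i, v in enumerate(base)}
            state = {f"c{i}": v + shift + noise[i] for i, v in enumerate(base)}
            p = t_test_p_value(state, control)
            assert p <= previous
            previous = p

    def test_mismatched_components_rejected(self):
        with pytest.raises(ValueError):
            t_test_p_value({"a": 1.0, "b": 1.0}, {"a": 1.0, "c": 1.0})

    def test_welch_variant_available(self):
        state = {f"c{i}": float(i) for i in range(6)}
        control = {f"c{i}": float(i) + 0.5 for i in range(6)}
        p_paired = t_test_p_value(state, control)
        p_welch = t_test_p_value(state, control, paired=False)
        assert 0 < p_welch <= 1 and p_paired != p_welch


class TestScreenAndRanking:
    def test_screen_contract_on_fixture(self, fixture_model):
        res = anti_mirna_screen(fixture_model, anti_ids=["anti-mir-489"],
                                dose_levels=(1.0, 1000.0))
        assert set(res.p_values.index) == {"anti-mir-489"}
        assert 0 < float(res.p_values.iloc[0]) <= 1
        heat = res.heatmap.ratios
        assert list(heat.index.get_level_values("dose_nM")) == [1.0, 1000.0]
        # direct-target proteins recover with dose (non-decreasing log2 ratio)
        for col in ("P-AKT",):
            assert heat[col].iloc[1] >= heat[col].iloc[0] - 1e-12

    def test_empty_screen_empty_ranking(self):
        ranking = rank_anti_mirnas(
            ScreenResult(p_values=__import__("pandas").Series(dtype=float)))
        assert ranking.empty

    def test_ranking_sorted_with_lexicographic_ties(self):
        s = ScreenResult(p_values=pd.Series(
            {"anti-mir-b": 0.01, "anti-mir-a": 0.01, "anti-mir-c": 0.002}))
        ranking = rank_anti_mirnas(s, alpha=0.05)
        assert list(ranking["anti_mirna"]) == ["anti-mir-c", "anti-mir-a", "anti-mir-b"]
        assert ranking["significant"].all()
        assert (ranking["p_bh"] >= ranking["p_value"] - 1e-15).all()


class TestTargetCounts:
    def test_fixture_counts_match_curated_lists(self, fixture_inputs):
        _, table = fixture_inputs
        per_mirna, per_target = target_count_histogram(table)
        assert per_mirna["mir-34a"] == 14
        assert per_mirna["mir-489"] == 4
        assert per_mirna["mir-192"] == 6
        assert per_target["TP53"] == 3  # mir-192, mir-489, mir-34a

    def test_empty_table(self):
        per_mirna, per_target = target_count_histogram(TargetTable([]))
        assert per_mirna.empty and per_target.empty

    def test_counts_are_distinct_not_rowwise(self):
        t = TargetTable([("m1", "g1", "a"), ("m1", "g2", "b"), ("m2", "g1", "c")])
        per_mirna, per_target = target_count_histogram(t)
        assert per_mirna.to_dict() == {"m1": 2, "m2": 1}
        assert per_target.to_dict() == {"g1": 2, "g2": 1}
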