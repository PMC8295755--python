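"""Transforms, repeatability, evolvability, ANOVA and model selection."""

import math

import numpy as np
import pandas as pd
import pytest

from conftest import make_response_table
from droughtgen.quantgen import (
    VarianceComponents,
    compact_letter_display,
    evolvability,
    evolvability_table,
    posthoc_pairwise,
    provenance_repeatability,
    reml_variance_components,
    repeatability,
    repeatability_summary,
    repeated_measures_selection,
    species_repeatability,
    standardize_log,
    two_way_anova,
)
from droughtgen.simulate import SimulationConfig, simulate_response_table


class TestStandardizeLog:
    def test_powers_of_e_map_to_unit_grid(self):
        tr = standardize_log([1.0, math.e, math.e**2])
        np.testing.assert_allclose(tr.values, [-1.0, 0.0, 1.0])

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            standardize_log([2.0, 2.0, 2.0])

    def test_nonpositive_rejected_with_positions(self):
        with pytest.raises(ValueError, match="positions"):
            standardize_log([1.0, 0.0, 2.0])

    def test_output_mean_zero_sd_one(self):
        rng = np.random.default_rng(4)
        tr = standardize_log(rng.lognormal(0.2, 0.6, 200))
        assert tr.values.mean() == pytest.approx(0.0, abs=1e-12)
        assert tr.values.std(ddof=1) == pytest.approx(1.0)

    def test_transform_invertible(self):
        x = np.array([0.4, 0.9, 1.7, 0.2])
        tr = standardize_log(x)
        np.testing.assert_allclose(tr.inverse(), x)


class TestRepeatability:
    def test_hand_arithmetic(self):
        comp = VarianceComponents(1.0, 3.0, cov=np.eye(2) * 1e-4)
        assert repeatability(comp).r == pytest.approx(0.25)

    def test_zero_among_variance(self):
        comp = VarianceComponents(0.0, 1.0, boundary=True)
        res = repeatability(comp)
        assert res.r == 0.0 and res.se_r == 0.0 and res.boundary

    def test_zero_within_variance(self):
        comp = VarianceComponents(1.0, 0.0)
        assert repeatability(comp).r == pytest.approx(1.0)

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            repeatability(VarianceComponents(0.0, 0.0))

    def test_affine_invariance_of_r(self):
        rng = np.random.default_rng(9)
        n, k = 60, 3
        y = (rng.normal(0, 0.5, n)[:, None] + rng.normal(0, 0.8, (n, k))).ravel()
        g = np.repeat(np.arange(n), k)
        c1 = reml_variance_components(y, g)
        c2 = reml_variance_components(3.0 * y + 7.0, g)
        r1 = c1.sigma2_A / (c1.sigma2_A + c1.sigma2_W)
        r2 = c2.sigma2_A / (c2.sigma2_A + c2.sigma2_W)
        assert r1 == pytest.approx(r2, abs=1e-8)

    def test_monte_carlo_recovery_500_trees(self):
        # single-replicate sampling SD of sigma2_A here is ~0.035, so the
        # +/-0.05 recovery band is checked on the mean of a few replicates
        a, w = 0.3, 0.7
        n, k = 500, 3
        est_a, est_w = [], []
        for seed in range(100, 106):
            rng = np.random.default_rng(seed)
            y = (rng.normal(0, math.sqrt(a), n)[:, None]
                 + rng.normal(0, math.sqrt(w), (n, k))).ravel()
            comp = reml_variance_components(y, np.repeat(np.arange(n), k))
            est_a.append(comp.sigma2_A)
            est_w.append(comp.sigma2_W)
        assert np.mean(est_a) == pytest.approx(a, abs=0.05)
        assert np.mean(est_w) == pytest.approx(w, abs=0.05)


class TestTableRepeatability:
    def test_species_model_recovers_true_r(self):
        cfg = SimulationConfig(seed=41, n_provenances=20, trees_per_provenance=25)
        tab, truth = simulate_response_table(cfg)
        sp = species_repeatability(tab, "Res")
        assert sp.r == pytest.approx(truth.r_true, abs=0.07)
        assert sp.scope == "species"

    def test_single_provenance_directed_to_provenance_model(self):
        cfg = SimulationConfig(seed=42, n_provenances=1)
        tab, _ = simulate_response_table(cfg)
        with pytest.raises(ValueError, match="provenance_repeatability"):
            species_repeatability(tab, "Res")

    def test_zero_provenance_variance_matches_single_factor_model(self):
        cfg = SimulationConfig(seed=43, provenance_effect_sd=0.0, n_provenances=12,
                               trees_per_provenance=20)
        tab, _ = simulate_response_table(cfg)
        sp = species_repeatability(tab, "Res")
        d = tab.defined("Res")
        comp = reml_variance_components(standardize_log(d["Res"].to_numpy()).values,
                                        d["tree_id"].to_numpy())
        r_single = comp.sigma2_A / (comp.sigma2_A + comp.sigma2_W)
        assert sp.r == pytest.approx(r_single, abs=0.02)

    def test_provenance_with_one_tree_missing_with_reason(self):
        tab = make_response_table({"A": [[0.5, 0.6, 0.7]],
                                   "B": [[0.4, 0.5, 0.6], [0.7, 0.5, 0.6]]}, [1, 2, 3])
        res = provenance_repeatability(tab, "Res", "A")
        assert math.isnan(res.r) and res.reason is not None

    def test_provenance_recovery_at_moderate_r(self):
        w = 0.25
        a = math.sqrt(0.4 / 0.6) * w  # r_true = 0.4
        hits = []
        for rep in range(40):
            cfg = SimulationConfig(seed=5000 + rep, n_provenances=1, trees_per_provenance=16,
                                   tree_sensitivity_sd=a, provenance_effect_sd=0.0)
            tab, _ = simulate_response_table(cfg)
            hits.append(provenance_repeatability(tab, "Res", "P01").r)
        assert np.mean(hits) == pytest.approx(0.4, abs=0.1)

    def test_summary_counts_significant_provenances(self):
        cfg = SimulationConfig(seed=44)
        tab, _ = simulate_response_table(cfg)
        summ = repeatability_summary(tab, "Res")
        assert summ["n_prov"] == 11
        assert 0 <= summ["n_sig"] <= 11
        assert summ["share_sig"] == pytest.approx(summ["n_sig"] / 11)


class TestEvolvability:
    def test_hand_arithmetic(self):
        ev = evolvability(0.25, 0.04, 0.5)
        assert ev.V_A == pytest.approx(0.01)
        assert ev.CV_A == pytest.approx(20.0)

    def test_zero_repeatability(self):
        assert evolvability(0.0, 0.04, 0.5).CV_A == 0.0

    def test_scale_invariance_of_cva(self):
        c = 3.7
        ev1 = evolvability(0.3, 0.05, 0.6)
        ev2 = evolvability(0.3, 0.05 * c**2, 0.6 * c)
        assert ev1.CV_A == pytest.approx(ev2.CV_A)

    def test_nonpositive_mean_rejected(self):
        with pytest.raises(ValueError):
            evolvability(0.3, 0.05, 0.0)

    def test_table_has_one_row_per_provenance(self):
        cfg = SimulationConfig(seed=45, n_provenances=5, trees_per_provenance=10)
        tab, _ = simulate_response_table(cfg)
        out = evolvability_table(tab, "Res")
        assert len(out) == 5
        ok = out.dropna(subset=["CV_A"])
        assert (ok["CV_A"] >= 0).all()


def anova_dataset(seed=0, n_species=4, n_events=3, n_per_cell=20):
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_species):
        for e in range(n_events):
            mu = 0.6 + 0.1 * s - 0.05 * e + 0.03 * s * e
            for i in range(n_per_cell):
                rows.append((f"sp{s}", 2000 + e, mu + rng.normal(0, 0.1)))
    return pd.DataFrame(rows, columns=["species", "event_year", "Res"])


class TestTwoWayAnova:
    def test_degrees_of_freedom_four_species_three_events(self):
        out = two_way_anova(anova_dataset(), "Res")
        assert out.loc["species", "df"] == 3
        assert out.loc["drought_year", "df"] == 2
        assert out.loc["interaction", "df"] == 6

    def test_sums_of_squares_match_projection_oracle(self):
        df = anova_dataset(seed=2, n_per_cell=7)
        out = two_way_anova(df, "Res")
        # explicit design-matrix least-squares oracle (balanced: partial = sequential)
        y = df["Res"].to_numpy()
        sp = pd.get_dummies(df["species"], drop_first=True, dtype=float).to_numpy()
        ev = pd.get_dummies(df["event_year"].astype(str), drop_first=True, dtype=float).to_numpy()
        inter = np.column_stack([sp[:, i] * ev[:, j]
                                 for i in range(sp.shape[1]) for j in range(ev.shape[1])])
        ones = np.ones((len(y), 1))

        def rss(X):
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            return float(np.sum((y - X @ beta) ** 2))

        X_full = np.column_stack([ones, sp, ev, inter])
        ss_species = rss(np.column_stack([ones, ev])) - rss(np.column_stack([ones, sp, ev]))
        ss_event = rss(np.column_stack([ones, sp])) - rss(np.column_stack([ones, sp, ev]))
        ss_inter = rss(np.column_stack([ones, sp, ev])) - rss(X_full)
        assert out.loc["species", "sum_sq"] == pytest.approx(ss_species, rel=1e-8)
        assert out.loc["drought_year", "sum_sq"] == pytest.approx(ss_event, rel=1e-8)
        assert out.loc["interaction", "sum_sq"] == pytest.approx(ss_inter, rel=1e-8)

    def test_empty_cell_named_in_error(self):
        df = anova_dataset(n_per_cell=3)
        df = df[~((df["species"] == "sp1") & (df["event_year"] == 2001))]
        with pytest.raises(ValueError, match="sp1"):
            two_way_anova(df, "Res")


class TestPosthoc:
    def test_single_group_single_letter(self):
        df = pd.DataFrame({"g": ["a"] * 5, "v": [1.0, 1.1, 0.9, 1.2, 1.0]})
        out = posthoc_pairwise(df, "v", "g")
        assert list(out["letters"]) == ["a"]

    def test_well_separated_groups_get_distinct_letters(self):
        rng = np.random.default_rng(6)
        df = pd.DataFrame({
            "g": np.repeat(["lo", "hi"], 30),
            "v": np.concatenate([rng.normal(0, 0.1, 30), rng.normal(5, 0.1, 30)]),
        })
        out = posthoc_pairwise(df, "v", "g").set_index("group")
        assert out.loc["hi", "letters"] != out.loc["lo", "letters"]

    def test_identical_groups_share_letter_mostly(self):
        shared = 0
        reps = 40
        for rep in range(reps):
            rng = np.random.default_rng(700 + rep)
            df = pd.DataFrame({
                "g": np.repeat(["a", "b", "c"], 20),
                "v": rng.normal(0, 1, 60),
            })
            out = posthoc_pairwise(df, "v", "g")
            letters = set(out["letters"])
            shared += letters == {"a"}
        assert shared / reps >= 0.9

    def test_cld_transitive_chain(self):
        # a > c significant; a~b and b~c not: b shares letters with both
        cld = compact_letter_display(["a", "b", "c"], {frozenset(("a", "c"))})
        assert set(cld["b"]) & set(cld["a"])
        assert set(cld["b"]) & set(cld["c"])
        assert not set(cld["a"]) & set(cld["c"])


class TestModelSelection:
    def test_loglik_non_decreasing_and_lr_definition(self):
        cfg = SimulationConfig(seed=46)
        tab, _ = simulate_response_table(cfg)
        sel = repeated_measures_selection(tab, "Res").table
        ll = sel["logLik"].to_numpy()
        assert np.all(np.diff(ll) >= -1e-8)
        for i in range(1, 4):
            assert sel["L_ratio"].iloc[i] == pytest.approx(2 * (ll[i] - ll[i - 1]), abs=1e-8)

    def test_intercept_model_has_three_parameters(self):
        cfg = SimulationConfig(seed=47, n_provenances=3, trees_per_provenance=8)
        tab, _ = simulate_response_table(cfg)
        sel = repeated_measures_selection(tab, "Res").table
        assert sel.loc[sel["model"] == "intercept", "n_params"].iloc[0] == 3

    def test_drought_effect_detected_provenance_null_not(self):
        detected, false_pos = 0, 0
        reps = 30
        for rep in range(reps):
            cfg = SimulationConfig(seed=6000 + rep, provenance_effect_sd=0.0,
                                   event_log_offsets=(0.0, -0.2, 0.2))
            tab, _ = simulate_response_table(cfg)
            sel = repeated_measures_selection(tab, "Res").table.set_index("model")
            detected += sel.loc["drought", "p_value"] < 0.05
            false_pos += sel.loc["provenance", "p_value"] < 0.05
        assert detected / reps >= 0.9
        assert false_pos / reps <= 0.2  # near-nominal at this replicate count

    def test_single_event_rejected(self):
        tab = make_response_table({"A": [[0.5]], "B": [[0.6]]}, [2000])
        with pytest.raises(ValueError):
            repeated_measures_selection(tab, "Res")
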