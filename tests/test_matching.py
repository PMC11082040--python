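"""Greedy tree matching, F-score, detection rates, and error summaries."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from uasforest.data import ParameterError, TreePlot, TreeRecord
from uasforest.matching import (
    detection_rates,
    dominance_class,
    error_summary,
    f_score,
    match_trees,
)

from conftest import make_random_plot


def replay_greedy(uas, field_plot, max_dist=4.0, max_h=2.0):
    """Literal step-by-step replay of the stated matching rule (oracle)."""
    uas_sorted = sorted(uas.trees, key=lambda t: (-t.height_m, t.tree_id))
    available = {t.tree_id: t for t in field_plot.trees}
    matches, fps = [], []
    for u in uas_sorted:
        candidates = []
        for f in available.values():
            dist = np.hypot(u.x_m - f.x_m, u.y_m - f.y_m)
            dh = abs(u.height_m - f.height_m)
            if dist <= max_dist and dh < max_h:
                candidates.append((dh, dist, f.tree_id))
        if candidates:
            dh, dist, fid = min(candidates)
            matches.append((u.tree_id, fid))
            del available[fid]
        else:
            fps.append(u.tree_id)
    return matches, fps, sorted(available)


class TestMatchTrees:
    def test_self_match_identity(self, random_plot):
        uas = random_plot.with_trees(
            [dataclasses.replace(t, source="uas") for t in random_plot.trees]
        )
        m = match_trees(uas, random_plot)
        assert m.tp == len(random_plot) and m.fp == 0 and m.fn == 0

    def test_empty_uas(self, random_plot):
        m = match_trees(TreePlot("u", [], bounds=random_plot.bounds), random_plot)
        assert m.tp == 0 and m.fn == len(random_plot)

    def test_competition_follows_stated_greedy_rule(self):
        # two UAS trees both near one field tree; taller UAS processed first
        field = TreePlot("f", [TreeRecord("f1", 10, 10, 10.0)])
        uas = TreePlot(
            "u",
            [
                TreeRecord("u1", 11, 10, 11.0, source="uas"),
                TreeRecord("u2", 10.5, 10, 9.5, source="uas"),
            ],
        )
        m = match_trees(uas, field)
        # u1 (taller) grabs f1 despite u2 having the smaller height error
        assert m.matches[0][0] == "u1" and m.matches[0][1] == "f1"
        assert m.false_positives == ["u2"]

    @pytest.mark.parametrize("seed", range(500))
    def test_matches_step_by_step_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n_f, n_u = rng.integers(0, 25, 2)
        size = 30.0
        field = TreePlot(
            "f",
            [
                TreeRecord(f"f{i}", *rng.uniform(0, size, 2), rng.uniform(1.5, 20))
                for i in range(n_f)
            ],
            bounds=(0, 0, size, size),
        )
        uas = TreePlot(
            "u",
            [
                TreeRecord(f"u{i}", *rng.uniform(0, size, 2), rng.uniform(1.5, 20),
                           source="uas")
                for i in range(n_u)
            ],
            bounds=(0, 0, size, size),
        )
        m = match_trees(uas, field)
        o_matches, o_fps, o_fns = replay_greedy(uas, field)
        assert [(a, b) for a, b, _, _ in m.matches] == o_matches
        assert m.false_positives == o_fps
        assert sorted(m.false_negatives) == o_fns
        # count conservation
        assert m.tp + m.fp == n_u
        assert m.tp + m.fn == n_f

    def test_row_order_invariance(self, random_plot):
        out = perturbed = make_random_plot(3, n=30)
        uas = out.with_trees([dataclasses.replace(t, source="uas") for t in perturbed.trees])
        m1 = match_trees(uas, random_plot)
        uas_rev = uas.with_trees(list(reversed(uas.trees)))
        field_rev = random_plot.with_trees(list(reversed(random_plot.trees)))
        m2 = match_trees(uas_rev, field_rev)
        assert sorted(m1.matches) == sorted(m2.matches)

    def test_tp_monotone_in_height_tolerance(self, random_plot):
        uas = make_random_plot(9, n=40).with_trees(
            [dataclasses.replace(t, source="uas") for t in make_random_plot(9, n=40).trees]
        )
        tps = [
            match_trees(uas, random_plot, max_height_err_m=tol).tp
            for tol in (4.0, 2.0, 1.0, 0.5)
        ]
        assert tps == sorted(tps, reverse=True)

    def test_invalid_tolerances(self, random_plot):
        with pytest.raises(ParameterError):
            match_trees(random_plot, random_plot, max_dist_m=0.0)


class TestFScore:
    @pytest.mark.parametrize(
        "tp,fp,fn,expected", [(10, 0, 0, 1.0), (0, 3, 5, 0.0), (8, 2, 2, 0.8)]
    )
    def test_values(self, tp, fp, fn, expected):
        assert f_score(tp, fp, fn) == pytest.approx(expected)

    def test_matches_harmonic_mean_closed_form(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            tp, fp, fn = rng.integers(0, 50, 3)
            if tp + fp + fn == 0:
                continue
            got = f_score(int(tp), int(fp), int(fn))
            if tp == 0:
                assert got == 0.0
            else:
                p, r = tp / (tp + fp), tp / (tp + fn)
                assert got == pytest.approx(2 * p * r / (p + r))

    def test_all_zero_undefined(self):
        with pytest.raises(ParameterError):
            f_score(0, 0, 0)


class TestDetectionRates:
    def test_perfect_match(self, random_plot):
        uas = random_plot.with_trees(
            [dataclasses.replace(t, source="uas") for t in random_plot.trees]
        )
        m = match_trees(uas, random_plot)
        rates = detection_rates(m, uas, random_plot)
        for cls, entry in rates.per_class.items():
            assert entry["tp_rate"] == 1.0
            assert entry["fn_rate"] == 0.0
            assert entry["fp_rate"] == 0.0
            assert entry["f_score"] == 1.0

    def test_boundary_five_meters_is_intermediate(self):
        assert dominance_class(5.0) == "intermediate"
        assert dominance_class(15.0) == "intermediate"
        assert dominance_class(4.999) == "understory"
        assert dominance_class(15.001) == "overstory"

    def test_empty_class_absent_not_zero(self):
        field = TreePlot("f", [TreeRecord("f1", 5, 5, 20.0)])
        uas = TreePlot("u", [TreeRecord("u1", 5, 5, 20.0, source="uas")])
        rates = detection_rates(match_trees(uas, field), uas, field)
        assert "understory" not in rates.per_class
        assert "intermediate" not in rates.per_class
        assert rates["overstory"]["f_score"] == 1.0

    def test_class_specific_fn_recovery(self):
        """Per-class deletion rates are recovered from pooled match counts."""
        from uasforest.synthetic import PerturbationParams, perturb_to_uas

        truth = make_random_plot(33, n=120, height_range=(2, 25))
        params = PerturbationParams(
            fn_rate_by_class={"understory": 0.5, "intermediate": 0.1, "overstory": 0.05},
            fp_rate_by_class={},
            xy_sd_m=0.0, height_bias_m=0.0, height_sd_m=0.0, ingrowth_rate=0.0,
        )
        counts = {c: [0, 0] for c in ("understory", "intermediate", "overstory")}
        for s in range(60):
            out = perturb_to_uas(truth, params, seed=s)
            m = match_trees(out.plot, truth)
            r = detection_rates(m, out.plot, truth)
            for c in counts:
                counts[c][0] += r[c]["fn"]
                counts[c][1] += r[c]["tp"] + r[c]["fn"]
        assert counts["understory"][0] / counts["understory"][1] == pytest.approx(0.5, abs=0.04)
        assert counts["intermediate"][0] / counts["intermediate"][1] == pytest.approx(0.1, abs=0.03)
        assert counts["overstory"][0] / counts["overstory"][1] == pytest.approx(0.05, abs=0.03)


class TestErrorSummary:
    def make_pair_plots(self, errors, heights=None, dbh_errors=None):
        heights = heights or [10.0] * len(errors)
        field = TreePlot(
            "f",
            [
                TreeRecord(f"f{i}", 5.0 * i, 5.0, h, dbh_cm=20.0)
                for i, h in enumerate(heights)
            ],
            bounds=(0, 0, 500, 10),
        )
        uas = TreePlot(
            "u",
            [
                TreeRecord(
                    f"u{i}", 5.0 * i, 5.0, h + e, source="uas",
                    dbh_cm=20.0 + (dbh_errors[i] if dbh_errors else 0.0),
                )
                for i, (h, e) in enumerate(zip(heights, errors))
            ],
            bounds=(0, 0, 500, 10),
        )
        return uas, field

    def test_constant_bias(self):
        uas, field = self.make_pair_plots([0.36] * 20)
        m = match_trees(uas, field)
        df = error_summary(m, uas, field).set_index("height_class")
        assert df.loc["all", "height_me_m"] == pytest.approx(0.36)
        assert df.loc["all", "height_rmse_m"] == pytest.approx(0.36)

    def test_single_pair_signs(self):
        uas, field = self.make_pair_plots([-1.9])
        m = match_trees(uas, field)
        df = error_summary(m, uas, field).set_index("height_class")
        assert df.loc["all", "height_me_m"] == pytest.approx(-1.9)
        assert df.loc["all", "height_rmse_m"] == pytest.approx(1.9)

    def test_matches_independent_formulas(self):
        rng = np.random.default_rng(4)
        errs = rng.uniform(-1.9, 1.9, 30)
        dbh_errs = rng.uniform(-5, 5, 30)
        heights = rng.uniform(2, 24, 30)
        uas, field = self.make_pair_plots(list(errs), list(heights), list(dbh_errs))
        m = match_trees(uas, field)
        df = error_summary(m, uas, field).set_index("height_class")
        assert df.loc["all", "height_me_m"] == pytest.approx(errs.mean())
        assert df.loc["all", "height_rmse_m"] == pytest.approx(np.sqrt((errs**2).mean()))
        assert df.loc["all", "dbh_me_cm"] == pytest.approx(dbh_errs.mean())
        assert df.loc["all", "dbh_rmse_cm"] == pytest.approx(np.sqrt((dbh_errs**2).mean()))
        # binning by field height into 5-m classes
        cls0 = df.index[df.index.str.startswith("0-5")]
        if len(cls0):
            sub = errs[heights < 5]
            assert df.loc["0-5", "n"] == len(sub)

    def test_rmse_at_least_abs_me(self):
        rng = np.random.default_rng(5)
        uas, field = self.make_pair_plots(list(rng.uniform(-1.5, 1.5, 25)))
        m = match_trees(uas, field)
        df = error_summary(m, uas, field)
        assert (df["height_rmse_m"] >= df["height_me_m"].abs() - 1e-12).all()


@settings(max_examples=60, deadline=None, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_match_count_conservation_property(seed):
    """|matches| + |FP| = #UAS and |matches| + |FN| = #field, for any input."""
    rng = np.random.default_rng(seed)
    n_f, n_u = rng.integers(0, 15, 2)
    field = TreePlot(
        "f",
        [TreeRecord(f"f{i}", *rng.uniform(0, 20, 2), rng.uniform(1.5, 20))
         for i in range(n_f)],
        bounds=(0, 0, 20, 20),
    )
    uas = TreePlot(
        "u",
        [TreeRecord(f"u{i}", *rng.uniform(0, 20, 2), rng.uniform(1.5, 20), source="uas")
         for i in range(n_u)],
        bounds=(0, 0, 20, 20),
    )
    m = match_trees(uas, field)
    assert m.tp + m.fp == n_u
    assert m.tp + m.fn == n_f
    ids = [a for a, _, _, _ in m.matches] + m.false_positives
    assert len(set(ids)) == len(ids)
    fids = [b for _, b, _, _ in m.matches] + m.false_negatives
    assert len(set(fids)) == len(fids)
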