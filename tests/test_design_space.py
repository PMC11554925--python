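import numpy as np
import pandas as pd
import pytest

from dcfba.design_space import (
    SweepGrid,
    classify_regions,
    extract_pareto_front,
    fit_pareto_quadratic,
    sweep_solution_space,
)
from dcfba.errors import ConfigError, InsufficientDataError


def synthetic_space(T, productivity, titer=None, mu_lb=0.005,
                    objective="productivity"):
    """Minimal sweep-shaped frame for the classification unit tests."""
    T = np.asarray(T, float)
    productivity = np.asarray(productivity, float)
    titer = productivity * T if titer is None else np.asarray(titer, float)
    return pd.DataFrame({
        "T": T,
        "mu_lb": mu_lb,
        "objective": objective,
        "titer": titer,
        "productivity": productivity,
        "gcon": 150.0,
        "t_s1_frac": 0.3,
        "all_glucose_consumed": True,
        "status": "oracle",
    })


class TestSweepGrid:
    def test_record_count(self, pe):
        grid = SweepGrid(T=[15.0, 30.0], mu_lb=[0.005, 0.02])
        space = sweep_solution_space(grid, pe)
        assert len(space) == 2 * 2 * 2  # T x mu_lb x objectives

    def test_unknown_objective_rejected(self):
        with pytest.raises(ConfigError):
            SweepGrid(objectives=("titer", "profit"))

    def test_unknown_mode_rejected(self, pe):
        with pytest.raises(ConfigError):
            sweep_solution_space(SweepGrid(T=[15.0, 30.0]), pe, mode="magic")

    def test_failed_points_recorded_not_dropped(self, pe):
        # mu_lb above the envelope domain: problem construction fails
        grid = SweepGrid(T=[50.0, 60.0], mu_lb=[0.7], objectives=("titer",))
        space = sweep_solution_space(grid, pe)
        assert len(space) == 2
        assert space["status"].str.startswith("failed").all()
        assert space["titer"].isna().all()


class TestClassifyRegions:
    def test_interior_peak_split(self):
        space = synthetic_space(
            T=[10, 15, 20, 25, 30], productivity=[1.0, 1.4, 1.5, 1.3, 1.1]
        )
        T_star, region = classify_regions(space)
        assert T_star == 20.0
        assert (region[space["T"] < 20].unique() == ["proportionality"]).all()
        assert (region[space["T"] > 20].unique() == ["trade-off"]).all()
        assert (region[space["T"] == 20] == "optimum").all()

    def test_monotone_profile_puts_peak_at_edge(self):
        space = synthetic_space(
            T=[10, 15, 20, 25], productivity=[1.0, 1.2, 1.3, 1.4]
        )
        T_star, region = classify_regions(space)
        assert T_star == 25.0
        assert (region[space["T"] < 25] == "proportionality").all()

    def test_non_unimodal_warns(self):
        space = synthetic_space(
            T=[10, 15, 20, 25, 30], productivity=[1.0, 1.5, 1.2, 1.4, 1.0]
        )
        with pytest.warns(UserWarning, match="not unimodal"):
            classify_regions(space)

    def test_too_few_lengths(self):
        space = synthetic_space(T=[10, 20, 30], productivity=[1.0, 1.2, 1.1])
        with pytest.raises(InsufficientDataError):
            classify_regions(space)


class TestParetoFront:
    def test_requires_region_column(self):
        with pytest.raises(ConfigError, match="region"):
            extract_pareto_front(synthetic_space([10, 20, 30, 40],
                                                 [1, 2, 2, 1]))

    def test_dominated_point_removed(self):
        space = synthetic_space(T=[30.0, 40.0], productivity=[2.0, 1.0],
                                titer=[50.0, 40.0])
        space["region"] = "trade-off"
        front = extract_pareto_front(space)
        # (50, 2) dominates (40, 1): singleton front
        assert len(front) == 1
        assert front.loc[0, "titer"] == 50.0

    def test_front_sorted_and_antichain(self):
        rng = np.random.default_rng(0)
        titer = rng.uniform(30, 70, 40)
        prod = rng.uniform(0.5, 2.0, 40)
        space = synthetic_space(T=np.arange(40) + 10.0, productivity=prod,
                                titer=titer)
        space["region"] = "trade-off"
        front = extract_pareto_front(space)
        assert (np.diff(front["titer"]) > 0).all()
        assert (np.diff(front["productivity"]) < 0).all()

    def test_quadratic_exact_recovery(self):
        a, b, c = -0.003, 0.26, -3.0
        x = np.linspace(40, 70, 8)
        front = pd.DataFrame({
            "titer": x, "productivity": a * x**2 + b * x + c,
        })
        (fa, fb, fc), r2 = fit_pareto_quadratic(front)
        assert (fa, fb, fc) == pytest.approx((a, b, c), abs=1e-9)
        assert r2 == pytest.approx(1.0, abs=1e-12)

    def test_quadratic_needs_four_points(self):
        front = pd.DataFrame({"titer": [1.0, 2.0, 3.0],
                              "productivity": [1.0, 2.0, 1.0]})
        with pytest.raises(InsufficientDataError):
            fit_pareto_quadratic(front)


@pytest.fixture(scope="module")
def fixture_space(pe):
    grid = SweepGrid(
        T=np.concatenate([np.linspace(10.0, 25.0, 7),
                          np.linspace(30.0, 60.0, 7)]),
        mu_lb=[0.005, 0.02, 0.05],
    )
    return sweep_solution_space(grid, pe), grid


class TestFixtureSweep:
    def test_deterministic(self, pe, fixture_space):
        space, grid = fixture_space
        again = sweep_solution_space(grid, pe)
        pd.testing.assert_frame_equal(space, again)

    def test_all_points_solved(self, fixture_space):
        space, _ = fixture_space
        assert (space["status"] == "oracle").all()

    def test_unique_interior_t_star(self, fixture_space):
        space, grid = fixture_space
        T_star, region = classify_regions(space)
        assert grid.T.min() < T_star < grid.T.max()

    def test_region_monotonicity(self, fixture_space):
        """Proportionality: titer and productivity rise together with T.
        Trade-off: productivity falls while titer keeps rising."""
        space, _ = fixture_space
        T_star, region = classify_regions(space)
        space = space.assign(region=region)
        mu0 = space["mu_lb"].min()
        for objective in ("titer", "productivity"):
            sub = space[(space["mu_lb"] == mu0)
                        & (space["objective"] == objective)].sort_values("T")
            prop = sub[sub["T"] <= T_star]
            trade = sub[sub["T"] >= T_star]
            assert (np.diff(prop["titer"]) > 0).all()
            assert (np.diff(prop["productivity"]) > 0).all()
            assert (np.diff(trade["productivity"]) < 0).all()
        # titer keeps increasing into the trade-off region when optimizing it
        tit = space[(space["mu_lb"] == mu0) & (space["objective"] == "titer")
                    & (space["T"] >= T_star)].sort_values("T")
        assert (np.diff(tit["titer"]) >= -1e-9).all()

    def test_glucose_exhausted_at_productivity_optimum(self, fixture_space):
        space, grid = fixture_space
        T_star, _ = classify_regions(space)
        mu0 = space["mu_lb"].min()
        opt = space[(space["T"] == T_star) & (space["mu_lb"] == mu0)
                    & (space["objective"] == "productivity")]
        assert opt["all_glucose_consumed"].all()
        assert opt["gcon"].iloc[0] == pytest.approx(grid.Gmax, rel=1e-3)

    def test_mu_lb_relaxation_never_hurts(self, fixture_space):
        """A smaller stage-2 growth floor weakly improves every objective."""
        space, _ = fixture_space
        mus = np.sort(space["mu_lb"].unique())
        for objective, col in (("titer", "titer"),
                               ("productivity", "productivity")):
            sub = space[space["objective"] == objective]
            piv = sub.pivot(index="T", columns="mu_lb", values=col)
            for lo, hi in zip(mus[:-1], mus[1:]):
                assert (piv[lo] >= piv[hi] - 1e-9).all()

    def test_stage1_fraction_shrinks_with_T_in_tradeoff(self, fixture_space):
        space, _ = fixture_space
        T_star, region = classify_regions(space)
        space = space.assign(region=region)
        mu0 = space["mu_lb"].min()
        sub = space[(space["mu_lb"] == mu0)
                    & (space["objective"] == "titer")
                    & (space["T"] >= T_star)].sort_values("T")
        assert (np.diff(sub["t_s1_frac"]) <= 1e-6).all()

    def test_pareto_fit_quality(self, fixture_space):
        space, _ = fixture_space
        _, region = classify_regions(space)
        front = extract_pareto_front(space.assign(region=region))
        assert len(front) >= 4
        _, r2 = fit_pareto_quadratic(front)
        assert r2 >= 0.99
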