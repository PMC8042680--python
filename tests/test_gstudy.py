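"""ANOVA mean squares and EMS variance-component estimation.

Two independent oracles guard the estimator: a brute-force sums-of-squares
computation from marginal-mean deviations (vs. the implementation's
marginal-total machine formulas), and a REML fit of the crossed
random-effects model via lme4, which coincides with the ANOVA solution on
balanced data whenever all estimates are interior (positive).
"""

import shutil
import subprocess
import textwrap

import numpy as np
import pytest

from gcross import (
    SimulationSpec,
    anova_mean_squares,
    estimate_components,
    percent_of_total,
    simulate_ratings,
    solve_variance_components,
)
from gcross.gstudy import COMPONENT_NAMES, EstimabilityError

EFFECTS = ("p", "t", "r", "pt", "pr", "tr", "e")


def brute_force_mean_squares(y: np.ndarray) -> dict[str, float]:
    """Sums of squares computed directly from marginal-mean deviations."""
    n_p, n_t, n_r = y.shape
    gm = y.mean()
    mp = y.mean(axis=(1, 2))
    mt = y.mean(axis=(0, 2))
    mr = y.mean(axis=(0, 1))
    mpt = y.mean(axis=2)
    mpr = y.mean(axis=1)
    mtr = y.mean(axis=0)
    ss = {
        "p": n_t * n_r * ((mp - gm) ** 2).sum(),
        "t": n_p * n_r * ((mt - gm) ** 2).sum(),
        "r": n_p * n_t * ((mr - gm) ** 2).sum(),
        "pt": n_r * ((mpt - mp[:, None] - mt[None, :] + gm) ** 2).sum(),
        "pr": n_t * ((mpr - mp[:, None] - mr[None, :] + gm) ** 2).sum(),
        "tr": n_p * ((mtr - mt[:, None] - mr[None, :] + gm) ** 2).sum(),
        "e": (
            (
                y
                - mpt[:, :, None] - mpr[:, None, :] - mtr[None, :, :]
                + mp[:, None, None] + mt[None, :, None] + mr[None, None, :]
                - gm
            )
            ** 2
        ).sum(),
    }
    df = {
        "p": n_p - 1, "t": n_t - 1, "r": n_r - 1,
        "pt": (n_p - 1) * (n_t - 1), "pr": (n_p - 1) * (n_r - 1),
        "tr": (n_t - 1) * (n_r - 1), "e": (n_p - 1) * (n_t - 1) * (n_r - 1),
    }
    return {k: ss[k] / df[k] for k in EFFECTS}


def ems_matrix_solve(ms, n_p, n_t, n_r):
    """Solve the full 7x7 EMS system by linear algebra (independent of the
    implementation's triangular substitution)."""
    order = EFFECTS
    coeff = {
        "p": {"p": n_t * n_r, "pt": n_r, "pr": n_t, "e": 1},
        "t": {"t": n_p * n_r, "pt": n_r, "tr": n_p, "e": 1},
        "r": {"r": n_p * n_t, "pr": n_t, "tr": n_p, "e": 1},
        "pt": {"pt": n_r, "e": 1},
        "pr": {"pr": n_t, "e": 1},
        "tr": {"tr": n_p, "e": 1},
        "e": {"e": 1},
    }
    A = np.array([[coeff[row].get(col, 0) for col in order] for row in order], float)
    b = np.array([ms[k] for k in order])
    return dict(zip(order, np.linalg.solve(A, b)))


class TestAnovaMeanSquares:
    def test_constant_cube_all_zero(self, make_cube):
        ms = anova_mean_squares(make_cube(np.full((3, 2, 2), 6.0)))
        assert all(v == pytest.approx(0.0, abs=1e-12) for v in ms.ms.values())

    def test_person_only_variation(self, make_cube):
        """Persons at 4 and 6, constant over tasks/raters: ms_p = n_t*n_r*var."""
        scores = np.empty((2, 2, 2))
        scores[0], scores[1] = 4.0, 6.0
        ms = anova_mean_squares(make_cube(scores))
        assert ms.ms["p"] == pytest.approx(8.0)
        for k in EFFECTS[1:]:
            assert ms.ms[k] == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("shape", [(2, 2, 2), (3, 2, 2), (4, 3, 3), (4, 2, 3)])
    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_agrees_with_brute_force_oracle(self, random_cube, shape, seed):
        cube = random_cube(*shape, seed=seed, integer=(seed % 2 == 0))
        ms = anova_mean_squares(cube)
        oracle = brute_force_mean_squares(cube.scores)
        for k in EFFECTS:
            assert ms.ms[k] == pytest.approx(oracle[k], abs=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_anova_identity(self, random_cube, seed):
        """Sum over effects of df * MS equals total squared deviation."""
        cube = random_cube(5, 3, 2, seed=seed)
        ms = anova_mean_squares(cube)
        total = ((cube.scores - cube.scores.mean()) ** 2).sum()
        assert ms.total_ss() == pytest.approx(total, rel=1e-9)

    def test_singleton_facet_not_estimable(self, make_cube):
        with pytest.raises(EstimabilityError, match="rater"):
            anova_mean_squares(make_cube(np.zeros((3, 2, 1)) + 5))


class TestSolveVarianceComponents:
    def test_zero_mean_squares_give_zero_components(self, make_cube):
        vc = estimate_components(make_cube(np.full((2, 2, 2), 5.0)))
        assert all(v == pytest.approx(0.0, abs=1e-12) for v in vc.sigma2.values())

    def test_inverts_person_only_case(self, make_cube):
        scores = np.empty((2, 2, 2))
        scores[0], scores[1] = 4.0, 6.0
        vc = estimate_components(make_cube(scores))
        assert vc.sigma2["p"] == pytest.approx(2.0)
        assert vc.raw["pt"] == pytest.approx(0.0, abs=1e-12)
        assert vc.raw["e"] == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_matrix_solution_of_ems_system(self, random_cube, seed):
        cube = random_cube(3, 2, 2, seed=seed, integer=True)
        ms = anova_mean_squares(cube)
        vc = solve_variance_components(ms)
        oracle = ems_matrix_solve(ms.ms, 3, 2, 2)
        for k in EFFECTS:
            assert vc.raw[k] == pytest.approx(oracle[k], abs=1e-9)

    @pytest.mark.parametrize("seed", range(6))
    def test_truncation_reports_nonnegative_and_preserves_positive(self, random_cube, seed):
        vc = estimate_components(random_cube(4, 2, 2, seed=seed))
        for k in EFFECTS:
            assert vc.sigma2[k] >= 0.0
            if vc.raw[k] >= 0:
                assert vc.sigma2[k] == vc.raw[k]

    def test_translation_invariance_in_grand_mean(self, random_cube, make_cube):
        cube = random_cube(5, 2, 2, seed=11)
        shifted = make_cube(cube.scores + 100.0)
        a, b = estimate_components(cube), estimate_components(shifted)
        for k in EFFECTS:
            assert a.raw[k] == pytest.approx(b.raw[k], abs=1e-8)


class TestUnbiasedness:
    def test_raw_estimates_unbiased_over_replications(self):
        """Mean raw EMS estimate tracks truth within 3 Monte-Carlo SEs
        over 1000 replications of a 20x4x3 design with known components."""
        truth = {"p": 1.0, "t": 0.4, "r": 0.3, "pt": 1.5, "pr": 0.6, "tr": 0.2, "e": 0.8}
        n_reps = 1000
        rng = np.random.default_rng(2024)
        est = {k: np.empty(n_reps) for k in EFFECTS}
        spec = SimulationSpec(n_p=20, n_t=4, n_r=3, sigma2=truth, seed=0)
        from gcross.simulate import _draw_cube

        for rep in range(n_reps):
            vc = estimate_components(_draw_cube(spec, rng))
            for k in EFFECTS:
                est[k][rep] = vc.raw[k]
        for k in EFFECTS:
            mean = est[k].mean()
            se = est[k].std(ddof=1) / np.sqrt(n_reps)
            assert abs(mean - truth[k]) < 3 * se, f"component {k}: {mean} vs {truth[k]}"


class TestPercentOfTotal:
    @pytest.mark.parametrize(
        "components, person_share",
        [
            # published component columns for the LAST/MH pairing
            ({"p": 1.10, "pt": 2.14, "pr": 0.42, "tr": 0.16, "e": 0.81}, 23.8),
            ({"p": 1.01, "pt": 1.93, "pr": 0.60, "e": 0.79}, 23.3),
        ],
    )
    def test_person_share_matches_published_tables(self, components, person_share):
        from gcross import VarianceComponents

        vc = VarianceComponents.from_values(components)
        assert percent_of_total(vc)["p"] == pytest.approx(person_share, abs=0.05)

    def test_single_nonzero_component_is_100_percent(self):
        from gcross import VarianceComponents

        vc = VarianceComponents.from_values({"pt": 0.7})
        pct = percent_of_total(vc)
        assert pct["pt"] == 100.0
        assert sum(pct.values()) == 100.0

    def test_all_zero_components_undefined(self, make_cube):
        vc = estimate_components(make_cube(np.full((2, 2, 2), 5.0)))
        with pytest.raises(ValueError, match="undefined"):
            percent_of_total(vc)

    @pytest.mark.parametrize("seed", range(3))
    def test_shares_sum_to_100_within_rounding(self, random_cube, seed):
        pct = percent_of_total(estimate_components(random_cube(6, 3, 2, seed=seed)))
        assert sum(pct.values()) == pytest.approx(100.0, abs=0.35)


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript not available")
def test_reml_cross_check_on_balanced_interior_data(tmp_path):
    """On balanced data with all-positive estimates, REML (lme4) coincides
    with the ANOVA/EMS solution for the crossed random model."""
    spec = SimulationSpec(
        n_p=12, n_t=3, n_r=3, seed=4,
        sigma2={"p": 1.0, "t": 0.8, "r": 0.6, "pt": 1.2, "pr": 0.9, "tr": 0.5, "e": 0.7},
    )
    cube = simulate_ratings(spec)
    vc = estimate_components(cube)
    assert all(v > 0 for v in vc.raw.values()), "fixture seed must give interior estimates"

    csv_path = tmp_path / "cube.csv"
    with open(csv_path, "w") as fh:
        fh.write("p,t,r,y\n")
        for i, p in enumerate(cube.persons):
            for j, t in enumerate(cube.tasks):
                for k, r in enumerate(cube.raters):
                    fh.write(f"{p},{t},{r},{float(cube.scores[i, j, k])!r}\n")
    script = tmp_path / "reml.R"
    script.write_text(textwrap.dedent(f"""
        suppressMessages(library(lme4))
        d <- read.csv("{csv_path}", colClasses=c("character","character","character","numeric"))
        fit <- lmer(y ~ 1 + (1|p) + (1|t) + (1|r) + (1|p:t) + (1|p:r) + (1|t:r), data=d,
                    control=lmerControl(check.nobs.vs.nlev="ignore", check.nobs.vs.nRE="ignore"))
        vc <- as.data.frame(VarCorr(fit))
        write.csv(vc[,c("grp","vcov")], "{tmp_path / 'out.csv'}", row.names=FALSE)
    """))
    subprocess.run(["Rscript", str(script)], check=True, capture_output=True)
    import csv as csvmod

    with open(tmp_path / "out.csv") as fh:
        reml = {row["grp"]: float(row["vcov"]) for row in csvmod.DictReader(fh)}
    mapping = {"p": "p", "t": "t", "r": "r", "p:t": "pt", "p:r": "pr", "t:r": "tr", "Residual": "e"}
    for grp, name in mapping.items():
        # lme4's optimizer converges to ~1e-4 relative precision
        assert reml[grp] == pytest.approx(vc.raw[name], rel=1e-3, abs=1e-4)
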