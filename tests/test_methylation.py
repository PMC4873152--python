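"""Beta/M transforms, detection filtering, site associations, group deltas."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from aneuscreen.methylation import (
    MethylationMatrix,
    beta_to_m,
    detection_filter,
    flag_negative_sites,
    group_methylation_difference,
    m_to_beta,
    site_expression_association,
)
from aneuscreen.phenotype import SummaryStat
from tests.conftest import METHYLATION_SUMMARIES


def make_meth(beta, detection=None, n_nd=None, manifest=None):
    beta = pd.DataFrame(beta) if not isinstance(beta, pd.DataFrame) else beta
    beta.index = [f"cg{i:02d}" for i in range(beta.shape[0])]
    beta.columns = [f"s{i}" for i in range(beta.shape[1])]
    if detection is None:
        detection = pd.DataFrame(
            0.001, index=beta.index, columns=beta.columns
        )
    else:
        detection = pd.DataFrame(
            np.asarray(detection, dtype=float), index=beta.index, columns=beta.columns
        )
    n_nd = beta.shape[1] if n_nd is None else n_nd
    group = pd.Series(
        ["ND"] * n_nd + ["T2D"] * (beta.shape[1] - n_nd), index=beta.columns
    )
    return MethylationMatrix(
        beta=beta, detection_p=detection, group=group, manifest=manifest
    )


class TestBetaMTransform:
    @pytest.mark.parametrize(
        "beta,m", [(0.5, 0.0), (0.8, 2.0), (0.25, -1.5849625007211563)]
    )
    def test_known_points(self, beta, m):
        assert beta_to_m(beta) == pytest.approx(m, rel=1e-12)

    def test_round_trip_bijection_on_grid(self):
        grid = np.linspace(1e-4, 1 - 1e-4, 10_000)
        back = m_to_beta(beta_to_m(grid))
        assert np.allclose(back, grid, rtol=1e-12, atol=0)

    def test_strictly_increasing(self):
        grid = np.linspace(0.01, 0.99, 500)
        assert np.all(np.diff(beta_to_m(grid)) > 0)

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.1, 1.1])
    def test_out_of_range_rejected_never_clamped(self, bad):
        with pytest.raises(ValueError):
            beta_to_m(bad)


class TestDetectionFilter:
    def test_high_mean_detection_probe_removed(self):
        m = make_meth([[0.5] * 4, [0.5] * 4], detection=[[0.02] * 4, [0.0] * 4])
        result = detection_filter(m, threshold=0.01)
        assert result.removed == ("cg00",)
        assert result.matrix.probes == ["cg01"]

    def test_probe_at_exact_threshold_retained(self):
        m = make_meth([[0.5] * 4], detection=[[0.01] * 4])
        assert detection_filter(m, threshold=0.01).removed == ()

    def test_idempotent(self):
        m = make_meth(
            [[0.4] * 4, [0.6] * 4], detection=[[0.05] * 4, [0.001] * 4]
        )
        once = detection_filter(m).matrix
        twice = detection_filter(once)
        assert twice.removed == () and twice.matrix.probes == once.probes

    def test_all_probes_removed_allowed_for_reporting(self):
        m = make_meth([[0.5] * 4], detection=[[0.5] * 4])
        result = detection_filter(m)
        assert result.matrix.probes == [] and result.removed == ("cg00",)


class TestSiteExpressionAssociation:
    def test_noise_free_linear_signal_recovered_exactly(self):
        n = 30
        expr = pd.Series(
            np.linspace(0.1, 1.5, n), index=[f"s{i}" for i in range(n)]
        )
        m_values = -2.0 * expr.to_numpy() + 0.25
        matrix = make_meth(m_to_beta(m_values)[None, :])
        assoc = site_expression_association(matrix, expr)[0]
        assert assoc.slope == pytest.approx(-2.0, rel=1e-9)
        assert assoc.p_value < 1e-20
        assert assoc.direction == -1

    def test_no_covariates_equals_closed_form_simple_regression(self, rng):
        n = 40
        expr = pd.Series(rng.normal(size=n), index=[f"s{i}" for i in range(n)])
        m_values = -0.7 * expr.to_numpy() + rng.normal(0, 1, size=n)
        matrix = make_meth(m_to_beta(m_values)[None, :])
        assoc = site_expression_association(matrix, expr)[0]
        lin = stats.linregress(expr.to_numpy(), m_values)
        assert assoc.slope == pytest.approx(lin.slope, rel=1e-10)
        assert assoc.stderr == pytest.approx(lin.stderr, rel=1e-10)
        assert assoc.p_value == pytest.approx(lin.pvalue, rel=1e-10)

    def test_covariate_adjustment_removes_confounding(self, rng):
        """A batch-driven M shift disappears once batch is a covariate."""
        n = 60
        idx = [f"s{i}" for i in range(n)]
        batch = np.repeat(["b1", "b2"], n // 2)
        expr = pd.Series(
            rng.normal(size=n) + (batch == "b2") * 1.5, index=idx
        )
        m_values = (batch == "b2") * 2.0 + rng.normal(0, 0.3, size=n)
        matrix = make_meth(m_to_beta((m_values - 1.0))[None, :])
        covariates = pd.DataFrame({"batch": batch}, index=idx)
        marginal = site_expression_association(matrix, expr)[0]
        adjusted = site_expression_association(matrix, expr, covariates)[0]
        assert marginal.p_value < 0.01  # confounded signal
        assert abs(adjusted.slope) < abs(marginal.slope)

    def test_planted_slope_recovered_within_2se(self, rng):
        slope, n, reps = -0.5, 89, 120
        estimates, stderrs = [], []
        for _ in range(reps):
            expr = pd.Series(rng.normal(size=n), index=[f"s{i}" for i in range(n)])
            m_values = slope * expr.to_numpy() + rng.normal(0, 1, size=n)
            assoc = site_expression_association(
                make_meth(m_to_beta(m_values)[None, :]), expr
            )[0]
            estimates.append(assoc.slope)
            stderrs.append(assoc.stderr)
        se_of_mean = np.mean(stderrs) / np.sqrt(reps)
        assert abs(np.mean(estimates) - slope) < 2 * se_of_mean + 0.01

    def test_rank_deficient_design_names_columns(self, rng):
        n = 20
        idx = [f"s{i}" for i in range(n)]
        expr = pd.Series(rng.normal(size=n), index=idx)
        covariates = pd.DataFrame({"dup": expr.to_numpy()}, index=idx)
        matrix = make_meth(rng.uniform(0.3, 0.7, size=(1, n)))
        with pytest.raises(ValueError, match="collinear"):
            site_expression_association(matrix, expr, covariates)

    def test_mismatched_samples_rejected(self, rng):
        matrix = make_meth(rng.uniform(0.3, 0.7, size=(1, 10)))
        expr = pd.Series(rng.normal(size=10), index=[f"x{i}" for i in range(10)])
        with pytest.raises(ValueError, match="do not match"):
            site_expression_association(matrix, expr)


def _assoc(probe, slope, p):
    from aneuscreen.methylation import SiteAssociation

    return SiteAssociation(probe_id=probe, slope=slope, stderr=0.1, p_value=p)


class TestFlagNegativeSites:
    def test_direction_gate_blocks_positive_slopes(self):
        assocs = [_assoc("pos", 0.9, 1e-12), _assoc("neg", -0.9, 1e-12)]
        assert flag_negative_sites(assocs) == {"neg"}

    def test_bonferroni_threshold_within_panel(self):
        # 16 probes: p must fall below 0.05/16 = 0.003125
        assocs = [_assoc(f"cg{i}", -1.0, 0.004) for i in range(16)]
        assert flag_negative_sites(assocs, 0.05, "bonferroni") == frozenset()
        assocs[0].p_value = 0.003
        assert flag_negative_sites(assocs, 0.05, "bonferroni") == {"cg0"}

    def test_family_wise_false_flag_rate_controlled(self, rng):
        """16-probe global null: any-flag frequency <= 0.05 + 2 MC SE."""
        n, reps = 49, 400
        any_flag = 0
        x = rng.normal(size=(reps, n))
        noise = rng.normal(size=(reps, 16, n))
        for r in range(reps):
            sx = x[r] - x[r].mean()
            sxx = (sx**2).sum()
            slopes = noise[r] @ sx / sxx
            resid = noise[r] - np.outer(slopes, sx)
            dfree = n - 2
            stderr = np.sqrt((resid**2).sum(axis=1) / dfree / sxx)
            t = slopes / stderr
            p = 2 * stats.t.sf(np.abs(t), dfree)
            flagged = (slopes < 0) & (p * 16 < 0.05)
            any_flag += flagged.any()
        rate = any_flag / reps
        assert rate <= 0.05 + 2 * np.sqrt(0.05 * 0.95 / reps)


class TestGroupMethylationDifference:
    @pytest.mark.parametrize(
        "site,delta,bound",
        [("cg05056497", 12.8, 1e-3), ("cg21301258", 9.9, 1e-2)],
    )
    def test_published_site_summaries(self, site, delta, bound):
        (nd_m, nd_s, nd_n), (t_m, t_s, t_n) = METHYLATION_SUMMARIES[site]
        data = {
            site: (SummaryStat(nd_m, nd_s, nd_n), SummaryStat(t_m, t_s, t_n))
        }
        out = group_methylation_difference(data)
        assert out.loc[site, "delta"] == pytest.approx(delta)
        assert out.loc[site, "p_value"] < bound

    def test_identical_groups_give_zero_delta_p1(self):
        stat = SummaryStat(50.0, 1.0, 20)
        out = group_methylation_difference({"cg": (stat, stat)})
        assert out.loc["cg", "delta"] == 0.0
        assert out.loc["cg", "p_value"] == 1.0

    def test_matrix_mode_matches_summary_mode(self, rng):
        nd = rng.uniform(0.45, 0.55, size=20)
        t2d = rng.uniform(0.30, 0.40, size=10)
        matrix = make_meth(np.concatenate([nd, t2d])[None, :], n_nd=20)
        out_matrix = group_methylation_difference(matrix, scale="beta_percent")
        pairs = {
            "cg00": (
                SummaryStat.from_values(nd * 100),
                SummaryStat.from_values(t2d * 100),
            )
        }
        out_summary = group_methylation_difference(pairs)
        assert out_matrix.loc["cg00", "delta"] == pytest.approx(
            out_summary.loc["cg00", "delta"]
        )
        assert out_matrix.loc["cg00", "p_value"] == pytest.approx(
            out_summary.loc["cg00", "p_value"]
        )
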