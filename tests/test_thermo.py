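"""Fermi-Dirac occupancy scoring: analytic identities, oracles, properties."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from comir.thermo import (
    RT_DEFAULT,
    BindingSite,
    GeneScoreTable,
    chemical_potential,
    fd_gene_score,
    fd_gene_scores,
    fd_site_probability,
    naive_gene_score,
    naive_gene_scores,
    top_fraction_targets,
)
from conftest import make_sites


def brute_force_fd(rows, expr, rt=RT_DEFAULT, scale=1.0):
    """Independent per-site summation with plain math.exp."""
    total = 0.0
    for _, mirna, energy in rows:
        mu = rt * math.log(expr[mirna] * scale)
        total += 1.0 / (1.0 + math.exp((energy - mu) / rt))
    return total


class TestChemicalPotential:
    def test_unit_level_gives_zero(self):
        assert chemical_potential(1.0, RT_DEFAULT) == 0.0

    def test_analytic_value(self):
        assert chemical_potential(math.e ** 2, 0.5) == pytest.approx(1.0)

    @pytest.mark.parametrize("level", [0.0, -3.0])
    def test_nonpositive_level_rejected(self, level):
        with pytest.raises(ValueError, match="abundance"):
            chemical_potential(level)

    def test_strictly_increasing_in_level(self):
        levels = np.linspace(0.1, 1000, 50)
        mu = chemical_potential(levels)
        assert np.all(np.diff(mu) > 0)


class TestSiteProbability:
    def test_half_occupancy_at_chemical_potential(self):
        assert fd_site_probability(-5.0, -5.0) == pytest.approx(0.5)

    def test_three_quarters_at_rt_ln3_below(self):
        mu = -6.0
        e = mu - RT_DEFAULT * math.log(3)
        assert fd_site_probability(e, mu) == pytest.approx(0.75)

    def test_limits(self):
        assert fd_site_probability(np.inf, 0.0) == 0.0
        assert fd_site_probability(-np.inf, 0.0) == 1.0

    def test_stable_for_extreme_arguments(self):
        # |E - mu| / RT up to 1e4 must neither overflow nor lose the limits
        assert fd_site_probability(1e4 * RT_DEFAULT, 0.0) == pytest.approx(0.0)
        assert fd_site_probability(-1e4 * RT_DEFAULT, 0.0) == pytest.approx(1.0)

    def test_rt_must_be_positive(self):
        with pytest.raises(ValueError, match="RT"):
            fd_site_probability(-5.0, -5.0, rt=0.0)

    @settings(max_examples=50, derandomize=True)
    @given(
        e=st.floats(-30, 5),
        mu=st.floats(-20, 0),
        rt=st.floats(0.1, 3.0),
    )
    def test_bounded_and_monotone(self, e, mu, rt):
        p = fd_site_probability(e, mu, rt)
        assert 0.0 <= p <= 1.0
        # decreasing in E, increasing in mu
        assert fd_site_probability(e + 0.5, mu, rt) <= p
        assert fd_site_probability(e, mu + 0.5, rt) >= p

    def test_equals_half_iff_at_potential(self):
        assert fd_site_probability(-4.0, -4.0) == 0.5
        assert fd_site_probability(-4.01, -4.0) != 0.5


class TestFdGeneScore:
    def test_empty_site_list_scores_zero(self):
        assert fd_gene_score(make_sites([]), {"mirA": 10.0}) == 0.0

    def test_three_sites_at_potential_score_1_5(self):
        expr = {"mirA": 100.0}
        mu = chemical_potential(100.0)
        sites = make_sites([("g1", "mirA", mu)] * 3)
        sites["start"] = [0, 8, 16]
        sites["end"] = [7, 15, 23]
        assert fd_gene_score(sites, expr) == pytest.approx(1.5)

    def test_matches_brute_force_on_random_instances(self, rng):
        for _ in range(200):
            mirnas = [f"m{i}" for i in range(rng.integers(1, 6))]
            expr = {m: float(rng.uniform(1, 1e4)) for m in mirnas}
            rows = [
                ("g1", mirnas[rng.integers(len(mirnas))], float(rng.normal(-8, 3)))
                for _ in range(10)
            ]
            expected = brute_force_fd(rows, expr)
            assert fd_gene_score(make_sites(rows), expr) == pytest.approx(
                expected, abs=1e-12
            )

    def test_additive_over_disjoint_site_lists(self, rng):
        expr = {"mirA": 200.0, "mirB": 30.0}
        rows1 = [("g1", "mirA", -7.0), ("g1", "mirB", -9.0)]
        rows2 = [("g1", "mirA", -4.5), ("g1", "mirB", -11.0), ("g1", "mirA", -8.0)]
        s1 = fd_gene_score(make_sites(rows1), expr)
        s2 = fd_gene_score(make_sites(rows2), expr)
        s12 = fd_gene_score(make_sites(rows1 + rows2), expr)
        assert s12 == pytest.approx(s1 + s2, abs=1e-12)

    def test_monotone_in_expression(self):
        rows = [("g1", "mirA", -8.0), ("g1", "mirB", -6.0)]
        lo = fd_gene_score(make_sites(rows), {"mirA": 10.0, "mirB": 10.0})
        hi = fd_gene_score(make_sites(rows), {"mirA": 50.0, "mirB": 10.0})
        assert hi > lo

    def test_expression_rescaling_raises_every_occupancy(self):
        # scale covariance: c > 1 on all levels strictly increases the score
        rows = [("g1", "mirA", -8.0), ("g2", "mirB", -5.0)]
        expr = {"mirA": 20.0, "mirB": 400.0}
        base = fd_gene_scores(make_sites(rows), expr)
        scaled = fd_gene_scores(make_sites(rows), expr, expression_scale=3.0)
        assert (scaled.scores > base.scores).all()

    def test_unexpressed_mirna_sites_dropped_with_warning(self, caplog):
        rows = [("g1", "mirA", -8.0), ("g1", "mirGhost", -20.0)]
        with caplog.at_level("WARNING"):
            table = fd_gene_scores(make_sites(rows), {"mirA": 100.0})
        assert "mirGhost" in caplog.text
        assert table.scores["g1"] < 1.0  # the strong ghost site did not count

    def test_scores_bounded_by_site_count(self, rng):
        rows = [("g1", "mirA", float(rng.normal(-8, 3))) for _ in range(7)]
        score = fd_gene_score(make_sites(rows), {"mirA": 500.0})
        assert 0.0 <= score <= 7.0


class TestNaiveScore:
    def test_empty_scores_zero(self):
        assert naive_gene_score(make_sites([])) == 0.0

    def test_energies_negated_on_orientation(self):
        sites = make_sites([("g1", "mirA", -5.0), ("g1", "mirB", -3.0)])
        assert naive_gene_score(sites, negate=True) == pytest.approx(8.0)

    def test_matches_plain_sum(self, rng):
        rows = [("g1", "mirA", float(rng.normal(0, 4))) for _ in range(15)]
        expected = sum(r[2] for r in rows)
        assert naive_gene_score(make_sites(rows)) == pytest.approx(expected)

    def test_ignores_expression_entirely(self):
        sites = make_sites([("g1", "mirA", -2.0), ("g2", "mirB", -2.0)])
        table = naive_gene_scores(sites, negate=True)
        assert table.scores["g1"] == table.scores["g2"]


class TestTopFraction:
    def test_distinct_scores_top_tenth(self):
        scores = pd.Series({f"g{i}": float(i) for i in range(20)})
        table = GeneScoreTable(scores, tool="t", method="fd")
        assert top_fraction_targets(table, 0.1) == {"g18", "g19"}

    def test_full_fraction_returns_all(self):
        table = GeneScoreTable(
            pd.Series({"a": 1.0, "b": 2.0}), tool="t", method="fd"
        )
        assert top_fraction_targets(table, 1.0) == {"a", "b"}

    def test_boundary_ties_all_included(self):
        table = GeneScoreTable(
            pd.Series({"g1": 1.0, "g2": 2.0, "g3": 2.0, "g4": 3.0}),
            tool="t", method="fd",
        )
        assert top_fraction_targets(table, 0.25) == {"g4"}
        assert top_fraction_targets(table, 0.5) == {"g2", "g3", "g4"}

    def test_empty_table_rejected(self):
        table = GeneScoreTable(pd.Series(dtype=float), tool="t", method="fd")
        with pytest.raises(ValueError, match="empty"):
            top_fraction_targets(table, 0.1)

    @pytest.mark.parametrize("q", [0.0, -0.1, 1.5])
    def test_invalid_fraction_rejected(self, q):
        table = GeneScoreTable(pd.Series({"a": 1.0}), tool="t", method="fd")
        with pytest.raises(ValueError):
            top_fraction_targets(table, q)


class TestBindingSite:
    def test_rejects_inverted_interval(self):
        with pytest.raises(ValueError, match="interval"):
            BindingSite("g", "m", 10, 10, "t", -1.0)

    def test_rejects_non_finite_score(self):
        with pytest.raises(ValueError, match="finite"):
            BindingSite("g", "m", 0, 7, "t", float("nan"))
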