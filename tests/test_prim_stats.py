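"""PRIM: windowing, Poisson GLM via IRLS against grid-search and
statsmodels oracles, tail probabilities, Bonferroni tests, null
comparison, and occupancy."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import primsite as p
from primsite.prim_stats import (
    DegenerateFitError,
    assign_observed,
    build_windows,
    compare_random_null,
    fit_prim,
    index_ta_sites,
    occupancy_histogram,
    poisson_upper_tail,
)
from primsite.prim_stats import test_windows as run_window_tests

from oracles import grid_fit_poisson, naive_ta_scan, poisson_sf_series


def _sites_frame(pairs, chrom_default="chr1"):
    rows = []
    for i, it in enumerate(pairs, 1):
        chrom, pos = it if isinstance(it, tuple) else (chrom_default, it)
        rows.append({"chromosome": chrom, "position": int(pos),
                     "orientation": "+", "support_reads": 1,
                     "site_id": f"s{i:04d}"})
    return pd.DataFrame(rows)


def _windows_frame(ta_counts, observed, chroms=None, width=20_000):
    n = len(ta_counts)
    chroms = chroms or ["chr1"] * n
    return pd.DataFrame({
        "window_id": [f"w{i:06d}" for i in range(1, n + 1)],
        "chromosome": chroms,
        "start": [i * width for i in range(n)],
        "end": [(i + 1) * width for i in range(n)],
        "ta_count": ta_counts,
        "observed_insertions": observed,
        "short": [False] * n,
    })


# ---------------------------------------------------------------------------
# TA index and windows


def test_index_ta_overlap_convention():
    g = p.ReferenceGenome({"chr1": "TATA" + "G" * 9_996})
    assert index_ta_sites(g)["chr1"].tolist() == [0, 2]


def test_index_ta_none():
    g = p.ReferenceGenome({"chr1": "GGCC" * 2_500})
    assert index_ta_sites(g)["chr1"].tolist() == []


def test_index_ta_matches_naive_scan(small_genome):
    for name, seq in small_genome.chromosomes.items():
        assert index_ta_sites(small_genome)[name].tolist() == naive_ta_scan(seq)


def test_build_windows_tiling_and_short_flag():
    cfg = p.SimulationConfig(seed=41, n_chromosomes=1, chromosome_lengths=50_000)
    g = p.generate_genome(cfg)
    w = build_windows(g, 20_000)
    assert [(r.start, r.end, r.short) for r in w.itertuples()] == [
        (0, 20_000, False), (20_000, 40_000, False), (40_000, 50_000, True)]
    assert w.ta_count.sum() == len(index_ta_sites(g)["chr1"])


def test_window_ta_counts_match_recount_oracle(small_genome):
    w = build_windows(small_genome, 10_000)
    rng = np.random.default_rng(42)
    for i in rng.choice(len(w), size=20, replace=False):
        row = w.iloc[int(i)]
        seq = small_genome.chromosomes[row.chromosome]
        direct = sum(
            1 for j in range(row.start, min(row.end, len(seq) - 1))
            if seq[j : j + 2] == "TA"
        )
        assert row.ta_count == direct


def test_assign_observed_empty_and_boundary(small_genome):
    w = build_windows(small_genome, 20_000)
    out = assign_observed(w, _sites_frame([]))
    assert out.observed_insertions.sum() == 0
    # half-open boundary: position 20000 belongs to the second window
    g = p.ReferenceGenome({"chr1": "TA" * 25_000})
    w1 = build_windows(g, 20_000)
    out = assign_observed(w1, _sites_frame([20_000]))
    assert out.observed_insertions.tolist() == [0, 1, 0]


def test_assign_observed_matches_bucketing_oracle(small_genome):
    evs = p.simulate_integrations(small_genome, 300, seed=43)
    sites = _sites_frame([(e.chromosome, e.position) for e in evs])
    w = assign_observed(build_windows(small_genome, 10_000), sites)
    brute = {}
    for e in evs:
        brute[(e.chromosome, e.position // 10_000)] = brute.get(
            (e.chromosome, e.position // 10_000), 0) + 1
    for row in w.itertuples():
        assert row.observed_insertions == brute.get(
            (row.chromosome, row.start // 10_000), 0)
    assert w.observed_insertions.sum() == 300


def test_assign_observed_site_outside_genome_raises(small_genome):
    w = build_windows(small_genome, 20_000)
    with pytest.raises(ValueError):
        assign_observed(w, _sites_frame([(" chrX", 1)]))


# ---------------------------------------------------------------------------
# GLM fit


def test_intercept_only_closed_form():
    """With one chromosome and the TA coefficient fixed at 0, the MLE
    intercept is log(total insertions / fitted windows)."""
    w = _windows_frame([100] * 10, [3, 1, 0, 2, 4, 0, 1, 2, 3, 4])
    fit = fit_prim(w, ta_coefficient=0.0)
    assert fit.converged
    assert fit.intercept == pytest.approx(math.log(20 / 10), abs=1e-8)
    assert fit.fitted.sum() == pytest.approx(20, rel=1e-6)


def test_score_equation_sum_fitted_equals_sum_observed(small_genome):
    evs = p.simulate_integrations(small_genome, 250, seed=44)
    sites = _sites_frame([(e.chromosome, e.position) for e in evs])
    w = assign_observed(build_windows(small_genome, 10_000), sites)
    fit = fit_prim(w)
    assert fit.fitted.sum() == pytest.approx(250, rel=1e-6)


def test_irls_matches_grid_search_oracle():
    """On a 6-window, 3-parameter instance the IRLS optimum coincides with
    dense grid-search maximum likelihood to 1e-3 in every coefficient."""
    w = _windows_frame(
        ta_counts=[50, 120, 80, 200, 60, 150],
        observed=[2, 5, 1, 9, 3, 4],
        chroms=["chr1", "chr1", "chr1", "chr2", "chr2", "chr2"],
    )
    fit = fit_prim(w)
    X = np.column_stack([
        np.ones(6),
        np.array([0, 0, 0, 1, 1, 1], dtype=float),
        np.log(w.ta_count.to_numpy(float)),
    ])
    y = w.observed_insertions.to_numpy(float)
    beta_grid, ll_grid = grid_fit_poisson(X, y, lo=-8, hi=8, points=11)
    irls_beta = np.array([fit.intercept, fit.chromosome_effects["chr2"],
                          fit.ta_coefficient])
    assert np.all(np.abs(irls_beta - beta_grid) < 1e-3)
    assert fit.log_likelihood >= ll_grid - 1e-6


def test_irls_matches_statsmodels():
    """Independent cross-check: coefficients agree with statsmodels GLM."""
    import statsmodels.api as sm

    rng = np.random.default_rng(45)
    n = 200
    chrom = np.repeat(["chr1", "chr2"], n // 2)
    ta = rng.integers(20, 400, size=n)
    X = np.column_stack([np.ones(n), (chrom == "chr2").astype(float), np.log(ta)])
    beta_true = np.array([-4.0, 0.4, 0.8])
    y = rng.poisson(np.exp(X @ beta_true))
    w = _windows_frame(ta.tolist(), y.tolist(), chroms=chrom.tolist())
    fit = fit_prim(w)
    sm_fit = sm.GLM(y, X, family=sm.families.Poisson()).fit()
    ours = [fit.intercept, fit.chromosome_effects["chr2"], fit.ta_coefficient]
    assert np.allclose(ours, sm_fit.params, atol=1e-6)


def test_coefficient_recovery_from_simulation():
    """Simulated counts from known coefficients are recovered within
    +-0.1 at ~2000 insertions over 500 windows (intercept compared at the
    mean covariate, where it is identifiable)."""
    rng = np.random.default_rng(46)
    n = 500
    chrom = np.repeat(["chr1", "chr2"], n // 2)
    ta = rng.integers(100, 2_000, size=n)
    mean_log_ta = float(np.log(ta).mean())
    beta_true = np.array([-1.0, 0.5, 0.3])
    X = np.column_stack([np.ones(n), (chrom == "chr2").astype(float), np.log(ta)])
    mu = np.exp(X @ beta_true)
    mu *= 2_000 / mu.sum()
    beta0 = beta_true[0] + math.log(2_000 / np.exp(X @ beta_true).sum())
    y = rng.poisson(mu)
    w = _windows_frame(ta.tolist(), y.tolist(), chroms=chrom.tolist())
    fit = fit_prim(w)
    got = np.array([fit.intercept + fit.ta_coefficient * mean_log_ta,
                    fit.chromosome_effects["chr2"], fit.ta_coefficient])
    want = np.array([beta0 + beta_true[2] * mean_log_ta,
                     beta_true[1], beta_true[2]])
    assert np.all(np.abs(got - want) < 0.1)


def test_zero_ta_windows_excluded():
    w = _windows_frame([0, 100, 100, 0, 100], [5, 2, 3, 1, 4])
    fit = fit_prim(w)
    assert set(fit.fitted.index) == {"w000002", "w000003", "w000005"}


def test_degenerate_all_zero_observed_raises():
    w = _windows_frame([100] * 5, [0] * 5)
    with pytest.raises(DegenerateFitError):
        fit_prim(w)


def test_separated_chromosome_effect_capped():
    w = _windows_frame([100] * 6, [3, 2, 4, 0, 0, 0],
                       chroms=["chr1"] * 3 + ["chr2"] * 3)
    fit = fit_prim(w, ta_coefficient=0.0)
    assert fit.converged
    assert fit.chromosome_effects["chr2"] == -20.0
    assert fit.capped_chromosomes == ["chr2"]
    assert fit.fitted.sum() == pytest.approx(9, rel=1e-6)


# ---------------------------------------------------------------------------
# Tail probabilities


def test_tail_k0_is_one():
    for mu in (0.01, 1.0, 50.0):
        assert poisson_upper_tail(0, mu) == 1.0


def test_tail_k1_closed_form():
    for mu in (0.1, 1.0, 5.0):
        assert poisson_upper_tail(1, mu) == pytest.approx(1 - math.exp(-mu),
                                                          rel=1e-14)


def test_tail_k3_series():
    direct = poisson_sf_series(3, 0.5)
    assert poisson_upper_tail(3, 0.5) == pytest.approx(direct, rel=1e-12)


def test_tail_large_k_stable():
    v = poisson_upper_tail(1_000_000, 10.0)
    assert 0.0 <= v < 1e-300 or v == 0.0


def test_tail_domain_error():
    with pytest.raises(ValueError):
        poisson_upper_tail(1, 0.0)


# ---------------------------------------------------------------------------
# Window tests


def test_bonferroni_cap():
    w = _windows_frame([100] * 100, [1] * 100)
    fit = fit_prim(w, ta_coefficient=0.0)
    t = run_window_tests(w, fit)
    # raw p for observed=1 at mu=1 is ~0.632; capped at 1 after x100
    assert (t.adjusted_p == 1.0).all()
    assert not t.enriched.any()


def test_extreme_window_is_enriched():
    obs = [0] * 99 + [50]
    w = _windows_frame([100] * 100, obs)
    fit = fit_prim(w, ta_coefficient=0.0)
    t = run_window_tests(w, fit)
    assert bool(t.enriched.iloc[-1])
    assert t.raw_p.iloc[-1] < 1e-30
    assert int(t.enriched.sum()) == 1


def test_zero_ta_windows_reported_untested():
    w = _windows_frame([0, 100, 100], [0, 3, 2])
    fit = fit_prim(w)
    t = run_window_tests(w, fit)
    assert not bool(t.tested.iloc[0])
    assert np.isnan(t.raw_p.iloc[0])


def test_pvalues_stochastically_valid_under_null():
    """Raw null p-values are no smaller than uniform (discrete
    conservatism allowed): the empirical CDF at alpha never exceeds
    alpha by more than binomial noise."""
    rng = np.random.default_rng(47)
    n = 400
    ta = rng.integers(100, 1_000, size=n)
    mu = 0.6 * ta / ta.mean()
    y = rng.poisson(mu)
    w = _windows_frame(ta.tolist(), y.tolist())
    fit = fit_prim(w)
    t = run_window_tests(w, fit)
    for alpha in (0.01, 0.05, 0.1):
        frac = float((t.raw_p <= alpha).mean())
        assert frac <= alpha + 3 * math.sqrt(alpha * (1 - alpha) / n)


# ---------------------------------------------------------------------------
# Null comparison and occupancy


def test_identical_tables_give_zero_chi_square(small_genome):
    evs = p.simulate_integrations(small_genome, 100, seed=48)
    sites = _sites_frame([(e.chromosome, e.position) for e in evs])
    comp = compare_random_null(sites, sites)
    assert comp.chi_square == 0.0
    assert comp.p_value == 1.0


def test_concentrated_observed_rejects_homogeneity():
    cfg = p.SimulationConfig(seed=49, n_chromosomes=4, chromosome_lengths=100_000)
    g = p.generate_genome(cfg)
    ta1 = index_ta_sites(g)["chr1"]
    obs = _sites_frame([("chr1", int(x)) for x in ta1[:300]])
    rnd_ev = p.simulate_integrations(g, 300, seed=49)
    rnd = _sites_frame([(e.chromosome, e.position) for e in rnd_ev])
    comp = compare_random_null(obs, rnd)
    assert comp.p_value < 0.001


def test_null_vs_null_not_systematically_rejected(small_genome):
    pvals = []
    for seed in range(20):
        a = p.simulate_integrations(small_genome, 150, seed=500 + seed)
        b = p.simulate_integrations(small_genome, 150, seed=900 + seed)
        comp = compare_random_null(
            _sites_frame([(e.chromosome, e.position) for e in a]),
            _sites_frame([(e.chromosome, e.position) for e in b]))
        pvals.append(comp.p_value)
    # at alpha=0.05 expect ~1 rejection in 20; allow binomial headroom
    assert sum(pv < 0.05 for pv in pvals) <= 4


def test_empty_tables_raise(small_genome):
    evs = p.simulate_integrations(small_genome, 5, seed=50)
    sites = _sites_frame([(e.chromosome, e.position) for e in evs])
    with pytest.raises(ValueError):
        compare_random_null(sites, _sites_frame([]))


def test_occupancy_no_insertions():
    w = _windows_frame([10] * 7, [0] * 7)
    assert occupancy_histogram(w) == {0: 7}


def test_occupancy_conservation_identity(small_genome):
    evs = p.simulate_integrations(small_genome, 120, seed=51)
    sites = _sites_frame([(e.chromosome, e.position) for e in evs])
    w = assign_observed(build_windows(small_genome, 10_000), sites)
    hist = occupancy_histogram(w)
    assert sum(k * v for k, v in hist.items()) == 120
    assert sum(hist.values()) == len(w)
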