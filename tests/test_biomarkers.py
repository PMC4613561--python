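"""Critical-r cutoffs, correlation loadings, change tables, t-tests."""

import numpy as np
import pytest
from scipy import stats

from thyromet.biomarkers import (build_change_table, compare_groups_univariate,
                                 correlation_loadings, critical_r,
                                 display_critical_r, format_change_table,
                                 load_region_map, univariate_ttest)
from thyromet.chemometrics import fit_oplsda
from thyromet.errors import ValidationError
from thyromet.preprocess import preprocess
from thyromet.simulate import (SimulationConfig, generate_glutathione_table,
                               generate_spectra)


# --- critical r ------------------------------------------------------------

def test_published_cutoffs():
    """The displayed thresholds for the two clinical comparison sizes."""
    assert display_critical_r(44, 0.05) == 0.29
    assert display_critical_r(25, 0.05) == 0.39


def test_critical_r_small_n_oracle():
    """n=6: t*(0.975, 4) = 2.776 => r = 2.776/sqrt(2.776^2+4) = 0.811."""
    assert abs(critical_r(6, 0.05) - 0.811) <= 1e-3


def test_truncation_not_rounding():
    # full-precision values round to 0.30/0.40 but must display 0.29/0.39
    assert round(critical_r(44), 2) == 0.30
    assert round(critical_r(25), 2) == 0.40


def test_critical_r_monotone_grid():
    ns = [5, 10, 20, 44, 100, 500]
    rs = [critical_r(n) for n in ns]
    assert all(a > b for a, b in zip(rs, rs[1:]))  # decreasing in n
    alphas = [0.01, 0.05, 0.10, 0.20]
    rs_a = [critical_r(30, a) for a in alphas]
    assert all(a > b for a, b in zip(rs_a, rs_a[1:]))  # decreasing in alpha
    # i.e. increasing as alpha grows smaller


def test_critical_r_validation():
    with pytest.raises(ValidationError):
        critical_r(2)
    with pytest.raises(ValidationError):
        critical_r(10, alpha=1.5)


# --- correlation loadings --------------------------------------------------

def _fit_small(rng, n=20, p=15):
    y = np.array([0] * (n // 2) + [1] * (n - n // 2))
    X = rng.normal(size=(n, p)) + np.outer(y, rng.normal(size=p))
    model = fit_oplsda(X, y, n_ortho=0)
    return X, y, model


def test_bucket_identical_to_score_has_r_one(rng):
    X, y, model = _fit_small(rng)
    X2 = np.column_stack([X, model.t])
    model2 = fit_oplsda(X2, y, n_ortho=0)
    rep = correlation_loadings(model2, X2)
    j = np.argmax(np.abs(rep.r))
    assert rep.r[-1] > 0.99  # the appended copy of t correlates ~1 with t


def test_r_matches_textbook_pearson(rng):
    """r_j agrees with the direct sum-formula Pearson correlation."""
    X, y, model = _fit_small(rng)
    rep = correlation_loadings(model, X)
    t = model.t
    for j in range(X.shape[1]):
        x = X[:, j]
        num = ((x - x.mean()) * (t - t.mean())).sum()
        den = np.sqrt(((x - x.mean()) ** 2).sum() * ((t - t.mean()) ** 2).sum())
        assert abs(rep.r[j] - num / den) < 1e-10


def test_coefficient_sign_matches_r_sign(rng):
    X, y, model = _fit_small(rng)
    rep = correlation_loadings(model, X)
    nz = np.abs(rep.r) > 1e-12
    assert np.all(np.sign(rep.coefficient[nz]) == np.sign(rep.r[nz]))
    assert np.all((np.abs(rep.coefficient) < 1e-12) == (np.abs(rep.r) < 1e-12))


def test_zero_variance_bucket_flagged(rng):
    X, y, model = _fit_small(rng)
    X2 = X.copy()
    X2[:, 4] = 3.0
    model2 = fit_oplsda(X2, y, n_ortho=0)
    rep = correlation_loadings(model2, X2)
    assert rep.zero_variance[4] and rep.r[4] == 0.0 and not rep.significant[4]


def test_planted_lactate_region_positive_and_significant():
    """The lactate doublet region comes out positive and significant in
    >=95% of replicates under the default planted lesion effect."""
    hits = 0
    n_rep = 100
    for rep_i in range(n_rep):
        cfg = SimulationConfig(group_sizes=(12, 6, 6), seed=7000 + rep_i,
                               tissue_mode="extract", ppm_range=(0.5, 4.19),
                               resolution=800)
        spectra, truth = generate_spectra(cfg)
        table = preprocess(spectra, ppm_range=(0.5, 4.19), water_region=None)
        y = (table.groups != "healthy").astype(int)
        model = fit_oplsda(table, y, n_ortho=1)
        rep = correlation_loadings(model, table)
        j = np.argmin(np.abs(table.bucket_centers - 1.332))
        hits += rep.significant[j] and rep.r[j] > 0
    assert hits / n_rep >= 0.95


# --- change table ----------------------------------------------------------

def _report_from(r_values, centers, n=30):
    from thyromet.biomarkers import LoadingsReport
    r = np.asarray(r_values, dtype=float)
    rc = critical_r(n)
    return LoadingsReport(
        bucket_centers=np.asarray(centers, dtype=float),
        coefficient=r.copy(), r=r, significant=np.abs(r) > rc,
        zero_variance=np.zeros(r.size, bool), n=n, alpha=0.05, r_crit=rc)


def test_change_table_all_ns():
    rep = _report_from([0.1, -0.05, 0.2], [1.33, 1.48, 3.20])
    table = build_change_table(rep, {"lactate": [(1.31, 1.35)],
                                     "alanine": [(1.46, 1.50)]})
    assert set(table["direction"]) == {"ns"}


def test_change_table_directions_and_strongest_bucket():
    rep = _report_from([0.9, 0.5, -0.8], [1.32, 1.34, 3.20])
    table = build_change_table(rep, {"lactate": [(1.31, 1.35)],
                                     "choline": [(3.19, 3.21)]})
    lact = table[table["metabolite"] == "lactate"].iloc[0]
    chol = table[table["metabolite"] == "choline"].iloc[0]
    assert lact["direction"] == "up" and lact["r"] == 0.9  # strongest |r| wins
    assert chol["direction"] == "down"


def test_water_window_metabolite_not_evaluable():
    """A metabolite whose only region fell in the excluded water window is
    flagged not-evaluable, not ns."""
    rep = _report_from([0.9], [1.33])
    table = build_change_table(rep, {"threonine": [(4.24, 4.26)]})
    assert table.iloc[0]["direction"] == "not_evaluable"
    disp = format_change_table(table)
    assert disp.iloc[0]["r"] == "not_evaluable"


def test_change_table_empty_region_rejected():
    rep = _report_from([0.9], [1.33])
    with pytest.raises(ValidationError):
        build_change_table(rep, {"lactate": []})


def test_bundled_region_map_loads():
    regions = load_region_map()
    assert len(regions) == 38  # the full resonance-key assignment set
    assert all(lo < hi for rs in regions.values() for lo, hi in rs)
    assert "lactate" in regions and "U1" in regions


# --- univariate t-tests ----------------------------------------------------

def test_identical_groups_not_significant():
    a = np.array([1.0, 2.0, 3.0, 4.0])
    t, p, sig = univariate_ttest(a, a.copy())
    assert abs(t) < 1e-12 and abs(p - 1.0) < 1e-12 and not sig


def test_ttest_matches_textbook_formula():
    """Two groups of 5 with known means/sds; pooled-variance arithmetic."""
    a = np.array([5.1, 4.9, 5.0, 5.2, 4.8])
    b = np.array([5.6, 5.4, 5.5, 5.7, 5.3])
    sp2 = (4 * a.var(ddof=1) + 4 * b.var(ddof=1)) / 8
    t_oracle = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / 5 + 1 / 5))
    p_oracle = 2 * stats.t.sf(abs(t_oracle), 8)
    t, p, sig = univariate_ttest(a, b)
    assert abs(t - t_oracle) < 1e-12 and abs(p - p_oracle) < 1e-12 and sig


def test_ttest_group_size_validation():
    with pytest.raises(ValidationError):
        univariate_ttest([1.0], [1.0, 2.0])


def test_glutathione_significance_pattern():
    """GSH is elevated in both lesion groups vs healthy tissue but does not
    differ between benign and malignant. The planted pattern must reproduce
    in >=90% of replicates, and GSSG (no planted effect) must flag only at
    the false-positive rate."""
    hits = 0
    gssg_flags = 0
    n_rep = 100
    for rep_i in range(n_rep):
        cfg = SimulationConfig(group_sizes=(46, 25, 28), seed=8000 + rep_i)
        df = generate_glutathione_table(cfg)
        res = compare_groups_univariate(df, ["GSH", "GSSG"])
        res = res.set_index(["feature", "comparison"])
        ok = (res.loc[("GSH", "benign-vs-healthy"), "significant"]
              and res.loc[("GSH", "malignant-vs-healthy"), "significant"]
              and not res.loc[("GSH", "malignant-vs-benign"), "significant"])
        hits += bool(ok)
        gssg_flags += int(res.loc["GSSG", "significant"].sum())
    assert hits / n_rep >= 0.90
    assert gssg_flags / (3 * n_rep) < 0.12  # ~ alpha per comparison
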