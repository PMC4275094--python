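"""ANOVA engine: sums of squares, EMS, quasi-F construction, permutation."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from ncii import DesignSpec, FixedEffects, SimOptions, VarianceComponents, \
    anova_table, build_f_ratio, expected_mean_squares, simulate_dataset, \
    simulate_replicates, sums_of_squares
from ncii.anova import AnovaEngine
from ncii.design import RESIDUAL_LABEL, enumerate_terms

from conftest import one_factor_toy


# ---------------------------------------------------------------------------
# sums of squares

def test_one_factor_toy_hand_values():
    records, design = one_factor_toy()
    tab = sums_of_squares(records, design)
    assert tab.loc["Ma(Bl)", "SS"] == pytest.approx(16.0)
    assert tab.loc["Ma(Bl)", "df"] == 1
    assert tab.loc["Ma(Bl)", "MS"] == pytest.approx(16.0)
    assert tab.loc[RESIDUAL_LABEL, "SS"] == pytest.approx(4.0)
    assert tab.loc[RESIDUAL_LABEL, "MS"] == pytest.approx(2.0)
    eng = AnovaEngine(records, design, "percent")
    f = eng.f_values(eng.ms())
    assert f["Ma(Bl)"] == pytest.approx(8.0)


def test_constant_response_gives_zero_ss(ref_design, sim_dataset):
    df = sim_dataset.copy()
    df["percent"] = 42.0
    tab = sums_of_squares(df, ref_design)
    assert np.allclose(tab["SS"], 0.0, atol=1e-8)


def test_ss_decomposition_identity(ref_design, sim_dataset):
    tab = sums_of_squares(sim_dataset, ref_design)
    y = sim_dataset["percent"]
    total = ((y - y.mean()) ** 2).sum()
    assert tab["SS"].sum() == pytest.approx(total, rel=1e-10)
    assert (tab["SS"] >= -1e-9).all()


def test_unbalanced_dataset_refused(ref_design, sim_dataset):
    with pytest.raises(ValueError, match="not balanced"):
        sums_of_squares(sim_dataset.iloc[:-1], ref_design)


# ---------------------------------------------------------------------------
# expected mean squares

def test_two_factor_random_textbook_ems():
    """Crossed two-way random model: E[MS_A] = s2e + n s2_AB + b n s2_A."""
    a, b, n = 4, 3, 2
    d = DesignSpec(n_blocks=1, sires_per_block=a, dams_per_block=b,
                   env_factors=(), n_replicates=n)
    ems = expected_mean_squares(d)
    row = ems.loc["Ma(Bl)"]
    assert row["Ma(Bl)"] == b * n
    assert row["Ma(Bl) × Fe(Bl)"] == n
    assert row[RESIDUAL_LABEL] == 1
    assert row["Fe(Bl)"] == 0
    assert (ems.loc[RESIDUAL_LABEL] == pd.Series(
        {c: float(c == RESIDUAL_LABEL) for c in ems.columns})).all()


def test_ref_design_ems_against_simulation_oracle(ref_design):
    """Activate one component at a time and compare the mean observed MS to
    the tabulated multiplier (brute-force Cornfield-Tukey check)."""
    ems = expected_mean_squares(ref_design)
    eng = None
    rng_seed = 17
    for comp, sigma2 in [("Ma(Bl)", 25.0), ("Fe(Bl) × Te", 25.0)]:
        key = {"Ma(Bl)": "sire", "Fe(Bl) × Te": "dam_temperature"}[comp]
        vc = VarianceComponents(**{key: sigma2, "residual": 1e-9})
        ms_sum = None
        n_rep = 400
        for df in simulate_replicates(n_rep, ref_design, vc, None,
                                      SimOptions(seed=rng_seed)):
            if eng is None:
                eng = AnovaEngine(df, ref_design, "percent")
            ms = eng.ms(df["percent"].to_numpy())
            ms_sum = ms if ms_sum is None else ms_sum + ms
        mean_ms = ms_sum / n_rep
        for term in ems.index:
            expected = ems.loc[term, comp] * sigma2
            observed = mean_ms[term]
            df_term = next(t.df for t in eng.terms if t.label == term)
            mc_sd = np.sqrt(2.0 / df_term) * max(expected, 1e-6) / np.sqrt(n_rep)
            assert observed == pytest.approx(expected, abs=6 * mc_sd + 1e-6), \
                f"EMS mismatch for {term} under {comp}"


# ---------------------------------------------------------------------------
# F-ratio construction

def test_exact_f_with_residual_denominator(ref_design):
    ems = expected_mean_squares(ref_design)
    r = build_f_ratio("Ma(Bl) × Fe(Bl) × Te × pH", ems)
    assert r.exact
    assert set(r.denominator) == {RESIDUAL_LABEL}


def test_one_factor_f_and_satterthwaite_df():
    records, design = one_factor_toy()
    eng = AnovaEngine(records, design, "percent")
    r = build_f_ratio("Ma(Bl)", eng.ems)
    assert r.exact and set(r.denominator) == {RESIDUAL_LABEL}
    ms = eng.ms()
    df = pd.Series({t.label: t.df for t in eng.terms})
    assert r.satterthwaite_df(ms, df) == (1.0, 2.0)


def test_quasi_f_cancels_all_nuisance_components(ref_design):
    """For every term, the synthesized numerator/denominator expectations
    differ only by the tested effect (symbolic EMS subtraction)."""
    ems = expected_mean_squares(ref_design)
    for term in ems.index:
        if term == RESIDUAL_LABEL:
            continue
        r = build_f_ratio(term, ems)
        assert r.testable
        own = term if term in ems.columns else f"Q({term})"
        diff = sum(w * ems.loc[k] for k, w in r.numerator.items()) \
            - sum(w * ems.loc[k] for k, w in r.denominator.items())
        expect = pd.Series(0.0, index=ems.columns)
        expect[own] = ems.loc[term, own]
        assert np.allclose(diff, expect, atol=1e-6), term


def test_te_denominator_is_block_by_te(ref_design):
    """With block random, the temperature F uses the block x temperature MS."""
    ems = expected_mean_squares(ref_design)
    r = build_f_ratio("Te", ems)
    assert r.exact and set(r.denominator) == {"Bl × Te"}


# ---------------------------------------------------------------------------
# permutation

def _exhaustive_one_factor_p(values: tuple[float, ...]) -> float:
    """Exhaustive-permutation p for two groups of two (labels fixed)."""
    obs_groups = (values[:2], values[2:])

    def fstat(g1, g2):
        m1, m2 = np.mean(g1), np.mean(g2)
        gm = np.mean(g1 + g2)
        ssb = 2 * ((m1 - gm) ** 2 + (m2 - gm) ** 2)
        ssw = sum((x - m1) ** 2 for x in g1) + sum((x - m2) ** 2 for x in g2)
        return ssb / (ssw / 2) if ssw > 0 else np.inf

    f_obs = fstat(*obs_groups)
    count = total = 0
    for perm in set(itertools.permutations(values)):
        f = fstat(perm[:2], perm[2:])
        total += 1
        count += f >= f_obs - 1e-12
    return count / total


def test_permutation_matches_exhaustive_enumeration():
    records, design = one_factor_toy()
    records = records.assign(percent=[1.0, 2.0, 3.0, 4.0])
    eng = AnovaEngine(records, design, "percent")
    # all 24 orderings collapse onto the same partitions; use many draws so
    # every partition is visited with the exhaustive frequency
    p = eng.permutation_pvalues(n_perm=4 * 24 * 50 - 1, seed=0)["Ma(Bl)"]
    expected = _exhaustive_one_factor_p((1.0, 2.0, 3.0, 4.0))
    assert expected == pytest.approx(1 / 3)
    assert p == pytest.approx(expected, abs=0.02)


def test_constant_response_p_one(ref_design, sim_dataset):
    df = sim_dataset.copy()
    df["percent"] = 5.0
    eng = AnovaEngine(df, ref_design, "percent")
    p = eng.permutation_pvalues(n_perm=99, seed=1)
    assert (p == 1.0).all()


def test_exact_f_permutation_matches_f_distribution():
    """Under a Gaussian null the permutation p of an exact-F term agrees
    with the classical F-distribution p within Monte-Carlo error."""
    from scipy import stats
    design = DesignSpec(n_blocks=1, sires_per_block=6, dams_per_block=1,
                        env_factors=(), n_replicates=4)
    rng = np.random.default_rng(4)
    pp, pc = [], []
    eng = None
    for _ in range(40):
        y = rng.normal(50.0, 10.0, design.total_units())
        records = design.grid()
        records["percent"] = y
        if eng is None:
            eng = AnovaEngine(records, design, "percent")
        ms = eng.ms(y)
        f = eng.f_values(ms)["Ma(Bl)"]
        eng.y = y
        pp.append(eng.permutation_pvalues(n_perm=199, seed=int(rng.integers(2**31)))["Ma(Bl)"])
        pc.append(1 - stats.f.cdf(f, 5, 18))
    # p-values track each other across null datasets
    assert np.corrcoef(pp, pc)[0, 1] > 0.95
    assert abs(np.mean(pp) - np.mean(pc)) < 0.05


# ---------------------------------------------------------------------------
# the assembled table

def test_anova_table_layout_and_determinism(ref_design, sim_dataset):
    tab1 = anova_table(sim_dataset, ref_design, n_perm=199, seed=3)
    tab2 = anova_table(sim_dataset, ref_design, n_perm=199, seed=3)
    pd.testing.assert_frame_equal(tab1, tab2)
    terms = enumerate_terms(ref_design)
    assert list(tab1.index) == [t.label for t in terms]
    assert tab1["df"].tolist() == [t.df for t in terms]
    assert len(tab1) == 20
    assert tab1.loc[RESIDUAL_LABEL, "F"] != tab1.loc[RESIDUAL_LABEL, "F"]  # NaN


def test_large_sire_component_detected(ref_design):
    """Injected sire variance makes the sire term significant."""
    vc = VarianceComponents(sire=400.0, residual=50.0)
    hits = 0
    for df in simulate_replicates(20, ref_design, vc, None,
                                  SimOptions(seed=6)):
        eng = AnovaEngine(df, ref_design, "percent")
        p = eng.permutation_pvalues(n_perm=199, seed=8)["Ma(Bl)"]
        hits += p < 0.05
    assert hits >= 19


def test_restricted_convention_changes_sire_error_term(ref_design):
    """Restricted EMS: the sire error term is the sire x dam MS alone."""
    ems = expected_mean_squares(ref_design, restricted=True)
    r = build_f_ratio("Ma(Bl)", ems)
    assert r.exact and set(r.denominator) == {"Ma(Bl) × Fe(Bl)"}
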