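"""Variance components: method of moments, REML, genetic correlations."""

import shutil
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from ncii import DesignSpec, FixedEffects, SimOptions, VarianceComponents, \
    anova_varcomp, eisen_saxton, reml_fit, simulate_dataset
from ncii.varcomp import default_random_terms

from conftest import one_factor_toy


# ---------------------------------------------------------------------------
# ANOVA method of moments

def test_one_way_closed_form():
    records, design = one_factor_toy()
    vc = anova_varcomp(records, design)
    assert vc.loc["sire", "estimate"] == pytest.approx(7.0)   # (16-2)/2
    assert vc.loc["residual", "estimate"] == pytest.approx(2.0)


def test_residual_only_data(ref_design):
    df = simulate_dataset(ref_design, VarianceComponents(residual=1e-12),
                          FixedEffects(mu=50.0), SimOptions(seed=1))
    rng = np.random.default_rng(0)
    df["percent"] = 50.0 + rng.normal(0, 3.0, len(df))
    vc = anova_varcomp(df, ref_design)
    others = vc.drop(index="residual")
    assert np.all(np.abs(others["estimate"]) < 5.0)
    assert vc.loc["residual", "estimate"] == pytest.approx(9.0, rel=0.5)
    assert (vc["truncated"] >= 0).all()


def test_mom_recovers_sire_component(ref_design):
    from ncii import simulate_replicates
    vc_true = VarianceComponents(sire=25.0, residual=100.0)
    ests = [anova_varcomp(df, ref_design).loc["sire", "estimate"]
            for df in simulate_replicates(200, ref_design, vc_true, None,
                                          SimOptions(seed=12))]
    mean, se = np.mean(ests), np.std(ests, ddof=1) / np.sqrt(len(ests))
    assert abs(mean - 25.0) < 3 * se + 1e-9


# ---------------------------------------------------------------------------
# REML

def test_reml_equals_anova_on_balanced_one_way():
    records, design = one_factor_toy()
    fit = reml_fit(records, random_terms=["sire"], fixed_terms=(),
                   ll_tol=1e-14, grad_tol=1e-12)
    assert fit.converged
    assert fit.components["sire"] == pytest.approx(7.0, rel=1e-6)
    assert fit.components["residual"] == pytest.approx(2.0, rel=1e-6)


def test_reml_boundary_flagged(ref_design):
    """A truly-zero component lands on the boundary and is flagged."""
    vc = VarianceComponents(sire=40.0, residual=30.0)
    df = simulate_dataset(ref_design, vc, None, SimOptions(seed=31))
    fit = reml_fit(df, ref_design)
    assert fit.converged
    # most of the twelve zero-variance terms should hit the bound
    assert len(fit.boundary) >= 5
    assert all(fit.components[b] == 0.0 for b in fit.boundary)


def test_reml_matches_lme4_on_full_model(ref_design, sim_dataset,
                                         tmp_path):
    """Independent cross-check of the full 13-term REML fit against lme4."""
    if shutil.which("Rscript") is None:
        pytest.skip("Rscript not available")
    csv = tmp_path / "records.csv"
    sim_dataset.to_csv(csv, index=False)
    out = tmp_path / "vc.csv"
    rcode = textwrap.dedent(f"""
      suppressMessages(library(lme4))
      d <- read.csv("{csv}")
      d$temperature <- factor(d$temperature); d$ph <- factor(d$ph)
      d$sd <- interaction(d$sire, d$dam, drop=TRUE)
      d$st <- interaction(d$sire, d$temperature, drop=TRUE)
      d$sp <- interaction(d$sire, d$ph, drop=TRUE)
      d$stp <- interaction(d$sire, d$temperature, d$ph, drop=TRUE)
      d$dt <- interaction(d$dam, d$temperature, drop=TRUE)
      d$dp <- interaction(d$dam, d$ph, drop=TRUE)
      d$dtp <- interaction(d$dam, d$temperature, d$ph, drop=TRUE)
      d$sdt <- interaction(d$sd, d$temperature, drop=TRUE)
      d$sdp <- interaction(d$sd, d$ph, drop=TRUE)
      d$sdtp <- interaction(d$sd, d$temperature, d$ph, drop=TRUE)
      m <- lmer(percent ~ temperature*ph + (1|block) + (1|sire) + (1|dam) +
                (1|sd) + (1|st) + (1|sp) + (1|stp) + (1|dt) + (1|dp) +
                (1|dtp) + (1|sdt) + (1|sdp) + (1|sdtp), data=d, REML=TRUE,
                control=lmerControl(check.conv.singular="ignore"))
      vc <- as.data.frame(VarCorr(m))
      write.csv(vc[,c("grp","vcov")], "{out}", row.names=FALSE)
    """)
    res = subprocess.run(["Rscript", "-e", rcode], capture_output=True,
                         text=True, timeout=600)
    assert res.returncode == 0, res.stderr[-2000:]
    lme4 = pd.read_csv(out).set_index("grp")["vcov"]
    mapping = {"block": "block", "sire": "sire", "dam": "dam",
               "sd": "sire_dam", "st": "sire_temperature", "sp": "sire_ph",
               "stp": "sire_temperature_ph", "dt": "dam_temperature",
               "dp": "dam_ph", "dtp": "dam_temperature_ph",
               "sdt": "sire_dam_temperature", "sdp": "sire_dam_ph",
               "sdtp": "sire_dam_temperature_ph", "Residual": "residual"}
    fit = reml_fit(sim_dataset, ref_design)
    scale = fit.components["residual"]
    for grp, val in lme4.items():
        ours = fit.components[mapping[grp]]
        assert ours == pytest.approx(val, rel=0.03, abs=0.02 * scale), grp


def test_reml_equals_mom_at_interior_solution(ref_design):
    """On balanced data whose moment solution is componentwise positive,
    REML (with the full ANOVA random structure) reproduces it."""
    vc = VarianceComponents(block=60.0, sire=80.0, dam=80.0, sire_dam=60.0,
                            sire_temperature=60.0, sire_ph=60.0,
                            sire_temperature_ph=60.0, dam_temperature=60.0,
                            dam_ph=60.0, dam_temperature_ph=60.0,
                            sire_dam_temperature=60.0, sire_dam_ph=60.0,
                            sire_dam_temperature_ph=60.0, residual=40.0)
    design = DesignSpec(n_blocks=2, sires_per_block=5, dams_per_block=4,
                        n_replicates=3)
    from ncii import simulate_replicates
    found = False
    for df in simulate_replicates(12, design, vc, None, SimOptions(seed=2024)):
        mom = anova_varcomp(df, design)
        if (mom["estimate"] > 0).all():
            found = True
            break
    assert found, "no interior moment solution among the simulated datasets"
    fit = reml_fit(df, design,
                   random_terms=default_random_terms(include_block_env=True),
                   ll_tol=1e-12, grad_tol=1e-9)
    for label, est in mom["estimate"].items():
        assert fit.components[label] == pytest.approx(est, rel=1e-5,
                                                      abs=1e-5 * 40), label


def test_reml_loglik_reported_and_finite(ref_design, sim_dataset):
    fit = reml_fit(sim_dataset, ref_design)
    assert np.isfinite(fit.loglik)
    assert fit.n_iter >= 1
    assert set(fit.components.index) == set(default_random_terms()) | {"residual"}


# ---------------------------------------------------------------------------
# Eisen-Saxton correlations

def test_no_gxe_gives_unit_correlations():
    gc = eisen_saxton({"sire": 1.0, "sire_temperature": 0.0, "sire_ph": 0.0,
                       "sire_temperature_ph": 0.0})
    assert (gc.r_G, gc.r_G_T, gc.r_G_pH) == (1.0, 1.0, 1.0)


def test_equal_components_arithmetic():
    gc = eisen_saxton({"sire": 1.0, "sire_temperature": 1.0, "sire_ph": 1.0,
                       "sire_temperature_ph": 1.0})
    assert gc.r_G == pytest.approx(0.25)
    assert gc.r_G_T == pytest.approx(0.5)
    assert gc.r_G_pH == pytest.approx(0.5)


def test_reference_triple_satisfies_identity():
    """A literature correlation triple (0.10, 0.47, 0.63) is internally
    consistent with these formulas: r_G(T) + r_G(pH) - r_G = 1."""
    assert 0.47 + 0.63 - 0.10 == pytest.approx(1.0, abs=0.005)


@given(st.tuples(*[st.floats(0.0, 1e3) for _ in range(4)])
       .filter(lambda t: sum(t) > 1e-6))
def test_identity_holds_for_all_components(comps):
    """The exact algebraic identity of the correlation formulas:
    r_G(T) + r_G(pH) - r_G = 1 - sTpH/D, hence exactly 1 whenever the
    three-way sire x temperature x pH component vanishes."""
    s, st_, sp, stp = comps
    D = s + st_ + sp + stp
    gc = eisen_saxton({"sire": s, "sire_temperature": st_, "sire_ph": sp,
                       "sire_temperature_ph": stp})
    assert gc.r_G_T + gc.r_G_pH - gc.r_G == pytest.approx(1.0 - stp / D,
                                                          abs=1e-9)
    assert max(gc.r_G, gc.r_G_T, gc.r_G_pH) <= 1.0 + 1e-12
    gc0 = eisen_saxton({"sire": s, "sire_temperature": st_, "sire_ph": sp,
                        "sire_temperature_ph": 0.0}) if D - stp > 1e-6 else gc
    if D - stp > 1e-6:
        assert gc0.r_G_T + gc0.r_G_pH - gc0.r_G == pytest.approx(1.0,
                                                                 abs=1e-9)


def test_degenerate_denominator_raises():
    with pytest.raises(ValueError, match="undefined"):
        eisen_saxton({"sire": 0.0, "sire_temperature": 0.0, "sire_ph": 0.0,
                      "sire_temperature_ph": 0.0})
    with pytest.raises(ValueError, match=">= 0"):
        eisen_saxton({"sire": -1.0, "sire_temperature": 2.0, "sire_ph": 0.0,
                      "sire_temperature_ph": 0.0})


def test_accepts_reml_result(ref_design, sim_dataset):
    fit = reml_fit(sim_dataset, ref_design)
    gc = eisen_saxton(fit)
    assert 0.0 <= gc.r_G <= 1.0
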