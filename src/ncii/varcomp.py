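"""Variance components and cross-environment genetic correlations.

Two estimators are provided for the full random-effects structure of the
blocked NC II model (block, sire(block), dam(block), sire x dam and all
parent x environment interactions, fitted in one analysis):

* :func:`anova_varcomp` — method-of-moments solution of the expected-mean-
  square equations.  Unbiased and closed-form on balanced data, but may
  return negative estimates; a zero-truncated copy is reported alongside.
* :func:`reml_fit` — restricted maximum likelihood for the Gaussian linear
  mixed model, maximized by average-information (AI) updates with EM
  fallback and variance components bounded below at zero.  On balanced data
  with an interior optimum REML reproduces the ANOVA solution.

Cross-environment genetic correlations for a trait measured under two
crossed environmental factors are ratios of the sire-associated components
(sire variance = additive-variance signal in a half-sib design):

    r*_G       = s / (s + sT + spH + sTpH)          (over both factor types)
    r*_G(T)    = (s + sT) / (s + sT + spH + sTpH)   (within a temperature class)
    r*_G(pH)   = (s + spH) / (s + sT + spH + sTpH)  (within a pH class)

which obey the identity r*_G(T) + r*_G(pH) - r*_G = 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg

from .anova import AnovaEngine
from .design import RESIDUAL_LABEL, DesignSpec

__all__ = ["RandomTerm", "RemlResult", "GeneticCorrelations",
           "anova_varcomp", "reml_fit", "eisen_saxton",
           "default_random_terms", "design_matrices"]

#: map from simulator/API component keys to ANOVA term factor sets.
#: block x environment keys are recognized so the full ANOVA random
#: structure can be fitted, but they are not part of the default model.
COMPONENT_FACTORS = {
    "block": ("block",),
    "block_temperature": ("block", "temperature"),
    "block_ph": ("block", "ph"),
    "block_temperature_ph": ("block", "temperature", "ph"),
    "sire": ("sire",),
    "dam": ("dam",),
    "sire_dam": ("sire", "dam"),
    "sire_temperature": ("sire", "temperature"),
    "sire_ph": ("sire", "ph"),
    "sire_temperature_ph": ("sire", "temperature", "ph"),
    "dam_temperature": ("dam", "temperature"),
    "dam_ph": ("dam", "ph"),
    "dam_temperature_ph": ("dam", "temperature", "ph"),
    "sire_dam_temperature": ("sire", "dam", "temperature"),
    "sire_dam_ph": ("sire", "dam", "ph"),
    "sire_dam_temperature_ph": ("sire", "dam", "temperature", "ph"),
}


def component_key(factors: frozenset[str]) -> str | None:
    for key, facs in COMPONENT_FACTORS.items():
        if frozenset(facs) == factors:
            return key
    return None


# ---------------------------------------------------------------------------
# ANOVA (method of moments)

def anova_varcomp(records: pd.DataFrame, design: DesignSpec,
                  response: str = "percent",
                  restricted: bool = False) -> pd.DataFrame:
    """Solve E[MS] = C @ components for the variance components.

    Rows of the EMS table belonging to random terms (plus the residual) form
    a square invertible system in the variance components.  Returns a frame
    with the unconstrained solution (possibly negative) and its
    zero-truncated counterpart, indexed by component key.
    """
    eng = AnovaEngine(records, design, response, restricted=restricted)
    ems = eng.ems
    random_rows = [t.label for t in eng.terms if t.is_random]
    vc_cols = [c for c in ems.columns if not c.startswith("Q(")]
    C = ems.loc[random_rows, vc_cols].to_numpy()
    ms = eng.ms().loc[random_rows].to_numpy()
    try:
        est = np.linalg.solve(C, ms)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "EMS coefficient matrix is singular; variance components are "
            "not identifiable for this design") from exc
    label_to_key = {}
    for t in eng.terms:
        if t.is_residual:
            label_to_key[RESIDUAL_LABEL] = "residual"
        elif t.is_random:
            label_to_key[t.label] = component_key(t.factors) or t.label
    idx = [label_to_key[c] for c in vc_cols]
    return pd.DataFrame({"estimate": est, "truncated": np.maximum(est, 0.0)},
                        index=idx)


# ---------------------------------------------------------------------------
# REML

@dataclass
class RandomTerm:
    """One random term of the mixed model: label, incidence and covariance.

    ``Z`` is the n x q incidence matrix; if ``cov`` (q x q, e.g. a pedigree
    relationship matrix) is given, the effect vector has covariance
    sigma^2 * cov.  Internally ``Z @ chol(cov)`` is used so every term
    reduces to an i.i.d. effect.
    """

    label: str
    Z: np.ndarray
    cov: np.ndarray | None = None

    def effective_Z(self) -> np.ndarray:
        if self.cov is None:
            return self.Z
        return self.Z @ np.linalg.cholesky(self.cov)


@dataclass
class RemlResult:
    """REML estimates with asymptotic standard errors and diagnostics."""

    components: pd.Series            # variance estimates incl. residual
    se: pd.Series                    # sqrt(diag(AI^-1)) at the optimum
    cov: pd.DataFrame                # inverse average-information matrix
    loglik: float
    converged: bool
    n_iter: int
    boundary: list[str] = field(default_factory=list)
    fixed_effects: pd.Series | None = None

    def __getitem__(self, key: str) -> float:
        return float(self.components[key])


def _fixed_design(records: pd.DataFrame, fixed_terms: tuple[str, ...]) -> np.ndarray:
    """Treatment-coded fixed-effect design matrix with intercept.

    ``fixed_terms`` entries are column names or ':'-joined interactions.
    """
    n = len(records)
    blocks = [np.ones((n, 1))]
    for term in fixed_terms:
        cols = term.split(":")
        key = (pd.MultiIndex.from_frame(records[cols]) if len(cols) > 1
               else records[cols[0]])
        codes, levels = pd.factorize(key, sort=True)
        if len(levels) < 2:
            continue
        D = np.zeros((n, len(levels) - 1))
        for j in range(1, len(levels)):
            D[codes == j, j - 1] = 1.0
        blocks.append(D)
    X = np.hstack(blocks)
    # drop linearly dependent columns (interaction coding redundancies)
    q, r = np.linalg.qr(X)
    keep = np.abs(np.diag(r)) > 1e-8 * np.abs(r).max()
    return X[:, keep]


def design_matrices(records: pd.DataFrame, design: DesignSpec,
                    random_terms: list[str] | None = None,
                    fixed_terms: tuple[str, ...] = ("temperature", "ph",
                                                    "temperature:ph"),
                    ) -> tuple[np.ndarray, list[RandomTerm]]:
    """Build X and the Z matrices for the declared model terms."""
    if random_terms is None:
        random_terms = default_random_terms()
    X = _fixed_design(records, fixed_terms)
    rts = []
    for key in random_terms:
        cols = list(COMPONENT_FACTORS.get(key, (key,)))
        mi = (pd.MultiIndex.from_frame(records[cols]) if len(cols) > 1
              else records[cols[0]])
        codes, levels = pd.factorize(mi, sort=True)
        Z = np.zeros((len(records), len(levels)))
        Z[np.arange(len(records)), codes] = 1.0
        rts.append(RandomTerm(key, Z))
    return X, rts


def default_random_terms(include_block_env: bool = False) -> list[str]:
    """Random structure fitted in a single analysis with all factors.

    The default follows the convention that block interacts with nothing:
    block, sire(block), dam(block), sire x dam and every parent x
    environment interaction.  ``include_block_env`` adds the block x
    environment terms so the model matches the full ANOVA decomposition.
    """
    keys = list(COMPONENT_FACTORS)
    if not include_block_env:
        keys = [k for k in keys if not k.startswith("block_")]
    return keys


def reml_fit(records: pd.DataFrame, design: DesignSpec | None = None,
             response: str = "percent",
             random_terms: list[str] | list[RandomTerm] | None = None,
             fixed_terms: tuple[str, ...] = ("temperature", "ph",
                                             "temperature:ph"),
             max_iter: int = 200, ll_tol: float = 1e-8,
             grad_tol: float = 1e-6, verbose: bool = False) -> RemlResult:
    """Average-information REML for a variance-components mixed model.

    The model is y = X b + sum_k Z_k u_k + e with u_k ~ N(0, sigma_k^2 I)
    (or sigma_k^2 * cov for structured terms) and e ~ N(0, sigma_e^2 I).
    AI steps are line-searched so the restricted log-likelihood never
    decreases; when an AI step fails, a monotone EM step is taken.
    Components are bounded below at zero; estimates pinned at the bound are
    reported in ``boundary``.
    """
    y = records[response].to_numpy(float)
    n = len(y)
    if random_terms and isinstance(random_terms[0], RandomTerm):
        rts = list(random_terms)
        X = _fixed_design(records, fixed_terms)
    else:
        X, rts = design_matrices(records, design, random_terms, fixed_terms)
    Zs = [rt.effective_Z() for rt in rts]
    labels = [rt.label for rt in rts] + ["residual"]
    k = len(Zs)
    p = X.shape[1]

    vary = float(np.var(y, ddof=1))
    if vary == 0.0:
        comps = pd.Series(0.0, index=labels)
        comps["residual"] = 0.0
        zero = pd.Series(0.0, index=labels)
        return RemlResult(comps, zero, pd.DataFrame(0.0, index=labels,
                                                    columns=labels),
                          loglik=np.nan, converged=True, n_iter=0,
                          boundary=labels[:])
    theta = np.full(k + 1, vary / (k + 1))
    floor = 1e-10 * vary
    q_total = sum(Z.shape[1] for Z in Zs)
    use_woodbury = q_total < n      # many observations, few effect levels

    def build(theta):
        """Factor V = sum theta_j Z_j Z_j' + theta_e I; return an operator
        ``Vi`` applying V^{-1}, tr(V^{-1}), log|V| and the GLS pieces."""
        s2e = theta[-1]
        if use_woodbury:
            U = np.hstack([np.sqrt(theta[j]) * Zs[j] for j in range(k)
                           if theta[j] > 0] or [np.zeros((n, 0))])
            q = U.shape[1]
            if q == 0:
                logdetV = n * np.log(s2e)

                def Vi(M):
                    return M / s2e

                trVi = n / s2e
            else:
                T = U.T @ U / s2e
                cho_m = linalg.cho_factor(np.eye(q) + T, lower=True)
                logdetV = n * np.log(s2e) + 2.0 * np.sum(
                    np.log(np.diag(cho_m[0])))

                def Vi(M):
                    return (M - U @ linalg.cho_solve(cho_m, U.T @ M) / s2e) \
                        / s2e

                trVi = (n - float(np.trace(linalg.cho_solve(cho_m, T)))) / s2e
        else:
            V = s2e * np.eye(n)
            for j in range(k):
                if theta[j] > 0:
                    V += theta[j] * (Zs[j] @ Zs[j].T)
            cho = linalg.cho_factor(V, lower=True)
            Vi_mat = linalg.cho_solve(cho, np.eye(n))
            logdetV = 2.0 * np.sum(np.log(np.diag(cho[0])))

            def Vi(M):
                return Vi_mat @ M

            trVi = float(np.trace(Vi_mat))
        ViX = Vi(X)
        XtViX = X.T @ ViX
        cho_x = linalg.cho_factor(XtViX)
        logdetX = 2.0 * np.sum(np.log(np.diag(cho_x[0])))
        Viy = Vi(np.ascontiguousarray(y))
        beta = linalg.cho_solve(cho_x, X.T @ Viy)
        Py = Viy - ViX @ beta
        ll = -0.5 * (logdetV + logdetX + float(y @ Py))
        return Vi, ViX, cho_x, Py, ll, beta, trVi

    def score_ai(theta, Vi, ViX, cho_x, Py, trVi):
        # score_j = -0.5 [tr(P G_j) - y'P G_j P y];  AI_jl = 0.5 (G_j Py)' P (G_l Py)
        score = np.zeros(k + 1)
        f = []                       # G_j @ Py
        for j in range(k + 1):
            if j < k:
                ZtPy = Zs[j].T @ Py
                f_j = Zs[j] @ ZtPy
                ViZ = Vi(Zs[j])
                trViG = float(np.sum(ViZ * Zs[j]))
                M = X.T @ ViZ
                trPG = trViG - float(np.sum(linalg.cho_solve(cho_x, M) * M))
                quad = float(ZtPy @ ZtPy)
            else:
                f_j = Py.copy()
                trPG = trVi - float(
                    np.trace(linalg.cho_solve(cho_x, ViX.T @ ViX)))
                quad = float(Py @ Py)
            score[j] = -0.5 * (trPG - quad)
            f.append(f_j)
        F = np.column_stack(f)
        PF = Vi(F) - ViX @ linalg.cho_solve(cho_x, (ViX.T @ F))
        AI = 0.5 * (F.T @ PF)
        return score, AI

    Vi, ViX, cho_x, Py, ll, beta, trVi = build(theta)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        score, AI = score_ai(theta, Vi, ViX, cho_x, Py, trVi)
        free = (theta > floor) | (score > 0)
        if np.linalg.norm(score[free]) < grad_tol * (1 + abs(ll)):
            converged = True
            break
        # AI step on the free set, line-searched
        step = np.zeros(k + 1)
        idx = np.where(free)[0]
        try:
            step[idx] = np.linalg.solve(AI[np.ix_(idx, idx)] +
                                        1e-10 * np.eye(len(idx)), score[idx])
        except np.linalg.LinAlgError:
            step[idx] = score[idx] / np.maximum(np.diag(AI)[idx], 1e-12)
        improved = False
        alpha = 1.0
        for _ in range(30):
            cand = np.maximum(theta + alpha * step, 0.0)
            cand[~free & (cand < floor)] = 0.0
            if cand[-1] <= 0:
                cand[-1] = max(theta[-1] * 0.1, floor)
            try:
                new = build(cand)
            except np.linalg.LinAlgError:
                alpha *= 0.5
                continue
            if new[4] >= ll - 1e-12:
                improved = new[4] > ll + ll_tol * (1 + abs(ll))
                theta, (Vi, ViX, cho_x, Py, ll_new, beta, trVi) = cand, new
                if not improved:
                    converged = True
                ll = ll_new
                break
            alpha *= 0.5
        else:
            # EM fallback (monotone)
            cand = theta.copy()
            for j in range(k):
                if theta[j] <= floor and score[j] <= 0:
                    cand[j] = 0.0
                    continue
                q_j = Zs[j].shape[1]
                ZtPy = Zs[j].T @ Py
                ViZ = Vi(Zs[j])
                M = X.T @ ViZ
                trPG = float(np.sum(ViZ * Zs[j])) - float(
                    np.sum(linalg.cho_solve(cho_x, M) * M))
                cand[j] = max(theta[j] + theta[j] ** 2 / q_j *
                              (float(ZtPy @ ZtPy) - trPG), 0.0)
            trP = trVi - float(
                np.trace(linalg.cho_solve(cho_x, ViX.T @ ViX)))
            cand[-1] = max(theta[-1] + theta[-1] ** 2 / (n - p) *
                           (float(Py @ Py) - trP), floor)
            new = build(cand)
            if new[4] < ll + ll_tol * (1 + abs(ll)):
                theta, (Vi, ViX, cho_x, Py, ll, beta, trVi) = cand, new
                converged = True
                break
            theta, (Vi, ViX, cho_x, Py, ll, beta, trVi) = cand, new
        if converged:
            break

    score, AI = score_ai(theta, Vi, ViX, cho_x, Py, trVi)
    try:
        cov = np.linalg.pinv(AI)
    except np.linalg.LinAlgError:
        cov = np.full((k + 1, k + 1), np.nan)
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    comps = pd.Series(np.maximum(theta, 0.0), index=labels)
    boundary = [labels[j] for j in range(k) if theta[j] <= max(floor, 0.0) + 0.0
                and theta[j] < 1e-8 * vary]
    return RemlResult(components=comps, se=pd.Series(se, index=labels),
                      cov=pd.DataFrame(cov, index=labels, columns=labels),
                      loglik=ll, converged=converged, n_iter=it,
                      boundary=boundary,
                      fixed_effects=pd.Series(beta))


# ---------------------------------------------------------------------------
# Eisen-Saxton cross-environment genetic correlations

@dataclass(frozen=True)
class GeneticCorrelations:
    """Cross-environment genetic correlations from sire-side components."""

    r_G: float
    r_G_T: float
    r_G_pH: float

    def as_dict(self) -> dict[str, float]:
        return {"r_G": self.r_G, "r_G_T": self.r_G_T, "r_G_pH": self.r_G_pH}


def eisen_saxton(vc) -> GeneticCorrelations:
    """Genetic correlations across two crossed environmental factors.

    ``vc`` supplies the four sire-associated components (keys ``sire``,
    ``sire_temperature``, ``sire_ph``, ``sire_temperature_ph``); it may be a
    mapping, a :class:`~ncii.simulate.VarianceComponents`, or a
    :class:`RemlResult`.
    """
    if hasattr(vc, "components"):
        vc = vc.components
    if hasattr(vc, "sire_terms"):
        vc = vc.sire_terms()
    s = float(vc["sire"])
    st = float(vc["sire_temperature"])
    sp = float(vc["sire_ph"])
    stp = float(vc["sire_temperature_ph"])
    if min(s, st, sp, stp) < 0:
        raise ValueError("sire-side variance components must be >= 0")
    D = s + st + sp + stp
    if D <= 0:
        raise ValueError("all sire-side components are zero: genetic "
                         "correlations are undefined")
    return GeneticCorrelations(r_G=s / D, r_G_T=(s + st) / D,
                               r_G_pH=(s + sp) / D)
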