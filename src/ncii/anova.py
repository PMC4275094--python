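"""Balanced mixed-model ANOVA with expected mean squares, quasi-F ratios and
raw-data permutation p-values.

Sums of squares use the classical balanced-design decomposition over cell
means.  Expected mean squares follow the Cornfield-Tukey rules; by default
the *unrestricted* mixed-model convention is used (random interactions
involving fixed factors are not sum-constrained), which matches the variance
component definitions of REML.  When no single mean square provides a valid
error term, a quasi-F ratio is synthesized from the unique linear
combination of mean squares whose expectations differ only by the tested
effect, with degrees of freedom by Satterthwaite's approximation.

Significance is assessed by unrestricted permutation of the raw response
values over all observations, recomputing the (quasi-)F statistic for each
permutation; p = (1 + #{F_perm >= F_obs}) / (1 + n_perm).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import (RESIDUAL_LABEL, DesignSpec, ModelTerm, enumerate_terms,
                     validate_dataset)

__all__ = [
    "AnovaEngine",
    "FRatio",
    "sums_of_squares",
    "expected_mean_squares",
    "build_f_ratio",
    "permutation_test",
    "anova_table",
]

_REL_TOL = 1e-9


def _q_label(term: ModelTerm) -> str:
    return f"Q({term.label})"


def expected_mean_squares(design: DesignSpec,
                          terms: list[ModelTerm] | None = None,
                          restricted: bool = False) -> pd.DataFrame:
    """EMS coefficient table: rows = model terms, columns = variance
    components (random-term labels + residual) and fixed-effect quadratic
    forms ``Q(term)``.

    For a balanced design the multiplier of component ``u`` in the row of
    term ``t`` is N divided by the number of subclasses indexed by ``u``,
    whenever ``u`` contains ``t`` (unrestricted convention).  Under the
    restricted convention a component only contributes if every factor it
    adds to ``t`` is random.  The residual component has coefficient 1 in
    every row.
    """
    if terms is None:
        terms = enumerate_terms(design)
    facs = {f.name: f for f in design.factors()}
    N = design.total_units()

    def levels_product(term: ModelTerm) -> int:
        p = 1
        for m in term.subscripts:
            p *= facs[m].n_levels
        return p

    nonres = [t for t in terms if not t.is_residual]
    vc_cols = [t.label for t in nonres if t.is_random] + [RESIDUAL_LABEL]
    q_cols = [_q_label(t) for t in nonres if not t.is_random]
    ems = pd.DataFrame(0.0, index=[t.label for t in terms],
                       columns=vc_cols + q_cols)
    ems[RESIDUAL_LABEL] = 1.0
    for t in terms:
        if t.is_residual:
            continue
        coef = N / levels_product(t)
        for row in terms:
            if row.is_residual or not (t.subscripts >= row.subscripts):
                continue
            if row.label != t.label:
                added = t.factors - row.factors
                if not added:          # t adds only nesting levels, not a superset
                    continue
                if restricted and any(not facs[m].is_random for m in added):
                    continue
                if not t.is_random:
                    continue           # fixed quadratics appear in own row only
            if t.is_random:
                ems.loc[row.label, t.label] = coef
            else:
                ems.loc[row.label, _q_label(t)] = coef
    return ems


@dataclass(frozen=True)
class FRatio:
    """A (quasi-)F ratio as weighted combinations of mean squares."""

    term: str
    numerator: dict[str, float]
    denominator: dict[str, float]
    exact: bool
    testable: bool = True

    def value(self, ms: pd.Series) -> float:
        num = sum(w * ms[k] for k, w in self.numerator.items())
        den = sum(w * ms[k] for k, w in self.denominator.items())
        return num / den if den > 0 else np.nan

    def satterthwaite_df(self, ms: pd.Series, df: pd.Series) -> tuple[float, float]:
        out = []
        for combo in (self.numerator, self.denominator):
            total = sum(w * ms[k] for k, w in combo.items())
            denom = sum((w * ms[k]) ** 2 / df[k] for k, w in combo.items())
            out.append(total ** 2 / denom if denom > 0 else np.nan)
        return tuple(out)


def build_f_ratio(term: str | ModelTerm, ems: pd.DataFrame) -> FRatio:
    """Construct the F (or quasi-F) ratio testing ``term``.

    Solves the linear system over all mean squares for the unique weight
    vector whose expected value isolates the tested effect (the term's own
    variance component, or its fixed-effect quadratic form); positive
    weights form the numerator, negative weights the denominator.
    """
    label = term.label if isinstance(term, ModelTerm) else term
    own = label if label in ems.columns else _q_label_str(label, ems)
    if own is None:
        raise KeyError(f"term {label!r} has no testable effect column")
    target = np.zeros(ems.shape[1])
    target[ems.columns.get_loc(own)] = ems.loc[label, own]
    S = ems.to_numpy()
    # rows of S span the column space; solve S^T x = target
    x, residuals, rank, _ = np.linalg.lstsq(S.T, target, rcond=None)
    if not np.allclose(S.T @ x, target, rtol=1e-8, atol=1e-8):
        return FRatio(label, {label: 1.0}, {}, exact=False, testable=False)
    x = np.where(np.abs(x) < 1e-10, 0.0, x)
    labels = list(ems.index)
    num = {labels[i]: float(x[i]) for i in range(len(x)) if x[i] > 0}
    den = {labels[i]: float(-x[i]) for i in range(len(x)) if x[i] < 0}
    exact = (set(num) == {label} and abs(num[label] - 1.0) < 1e-9
             and len(den) == 1
             and abs(next(iter(den.values())) - 1.0) < 1e-9)
    return FRatio(label, num, den, exact=exact)


def _q_label_str(label: str, ems: pd.DataFrame) -> str | None:
    q = f"Q({label})"
    return q if q in ems.columns else None


class AnovaEngine:
    """Precomputed machinery for repeated SS/F evaluation on one design.

    Group index vectors for every term's subclassification are built once;
    sums of squares for (batches of) response vectors then reduce to a few
    indicator-matrix products, which makes raw-data permutation cheap.
    """

    def __init__(self, records: pd.DataFrame, design: DesignSpec,
                 response: str, restricted: bool = False,
                 check_balance: bool = True):
        if check_balance:
            report = validate_dataset(records, design)
            if not report.balanced:
                raise ValueError(
                    "dataset is not balanced/complete; see validation report:\n"
                    f"{report}")
        self.design = design
        self.response = response
        self.terms = enumerate_terms(design)
        self.ems = expected_mean_squares(design, self.terms,
                                         restricted=restricted)
        self.y = records[response].to_numpy(float)
        self.N = len(self.y)

        env_names = [n for n, _ in design.env_factors]
        cols = {"block": "block", "sire": "sire", "dam": "dam"}
        cols.update({n: n for n in env_names})
        # order terms by subscript-set size so the SS recursion is valid
        self._order = sorted(range(len(self.terms)),
                             key=lambda i: len(self.terms[i].subscripts))
        self._Z: dict[str, np.ndarray] = {}
        self._ncell: dict[str, int] = {}
        for t in self.terms:
            if t.is_residual:
                continue
            key = [cols[m] for m in sorted(t.subscripts)]
            codes = records.groupby(key, sort=True).ngroup().to_numpy()
            G = codes.max() + 1
            Z = np.zeros((self.N, G))
            Z[np.arange(self.N), codes] = 1.0
            self._Z[t.label] = Z
            self._ncell[t.label] = self.N // G

    # -- sums of squares -------------------------------------------------

    def ss(self, y: np.ndarray) -> pd.Series:
        """SS per term (including residual) for response matrix y (..., N)."""
        y = np.atleast_2d(y)
        cf = y.sum(axis=1) ** 2 / self.N
        total = (y ** 2).sum(axis=1) - cf
        out = {}
        for i in self._order:
            t = self.terms[i]
            if t.is_residual:
                continue
            Z = self._Z[t.label]
            U = ((y @ Z) ** 2).sum(axis=1) / self._ncell[t.label]
            ss = U - cf
            for j in self._order:
                u = self.terms[j]
                if u.label != t.label and not u.is_residual \
                        and u.subscripts < t.subscripts:
                    ss = ss - out[u.label]
            out[t.label] = ss
        out[RESIDUAL_LABEL] = total - sum(out.values())
        return pd.DataFrame(out).iloc[0] if y.shape[0] == 1 else pd.DataFrame(out)

    def ms(self, y: np.ndarray | None = None):
        ss = self.ss(self.y if y is None else y)
        df = pd.Series({t.label: t.df for t in self.terms})
        return ss / df[ss.index if isinstance(ss, pd.Series) else ss.columns]

    # -- F ratios --------------------------------------------------------

    def f_ratios(self) -> dict[str, FRatio]:
        return {t.label: build_f_ratio(t.label, self.ems)
                for t in self.terms if not t.is_residual}

    def f_values(self, ms) -> pd.Series | pd.DataFrame:
        ratios = self.f_ratios()
        if isinstance(ms, pd.Series):
            return pd.Series({k: r.value(ms) for k, r in ratios.items()})
        vals = {}
        for k, r in ratios.items():
            num = sum(w * ms[m] for m, w in r.numerator.items())
            den = sum(w * ms[m] for m, w in r.denominator.items())
            with np.errstate(divide="ignore", invalid="ignore"):
                vals[k] = np.asarray(num) / np.asarray(den)
        return pd.DataFrame(vals)

    # -- permutation -----------------------------------------------------

    def exhaustive_permutation_pvalues(self) -> pd.Series:
        """Exact permutation p-values from complete enumeration of all N!
        orderings (only feasible for N <= 9); p = #{F_perm >= F_obs} / N!.

        The identity permutation is part of the enumeration, so p is never
        zero, matching the add-one convention of the sampled version.
        """
        import itertools
        import math
        if self.N > 9:
            raise ValueError("exhaustive enumeration limited to N <= 9 "
                             f"observations (got {self.N})")
        f_obs = self.f_values(self.ms())
        defined = f_obs.notna() & np.isfinite(f_obs)
        perms = np.array(list(itertools.permutations(self.y)))
        f_perm = self.f_values(self.ms(perms))
        p = pd.Series(1.0, index=f_obs.index)
        for k in f_obs.index:
            if defined[k]:
                fp = f_perm[k].to_numpy()
                p[k] = np.sum(fp >= f_obs[k] - 1e-12) / math.factorial(self.N)
        return p

    def permutation_pvalues(self, n_perm: int = 9999,
                            seed: int | np.random.Generator | None = None,
                            batch: int = 512) -> pd.Series:
        """Unrestricted raw-data permutation p-values for every model term."""
        rng = (seed if isinstance(seed, np.random.Generator)
               else np.random.default_rng(seed))
        ms_obs = self.ms()
        f_obs = self.f_values(ms_obs)
        counts = pd.Series(0, index=f_obs.index, dtype=int)
        defined = f_obs.notna() & np.isfinite(f_obs)
        done = 0
        while done < n_perm:
            b = min(batch, n_perm - done)
            perms = np.stack([rng.permutation(self.y) for _ in range(b)])
            f_perm = self.f_values(self.ms(perms))
            for k in f_obs.index:
                if defined[k]:
                    fp = f_perm[k].to_numpy()
                    counts[k] += int(np.sum(fp >= f_obs[k] - 1e-12))
            done += b
        p = (1 + counts) / (1 + n_perm)
        p[~defined] = 1.0
        return p


def sums_of_squares(records: pd.DataFrame, design: DesignSpec,
                    response: str = "percent") -> pd.DataFrame:
    """Classical balanced-design SS/df/MS for every model term."""
    eng = AnovaEngine(records, design, response)
    ss = eng.ss(eng.y)
    df = pd.Series({t.label: t.df for t in eng.terms})
    return pd.DataFrame({"SS": ss, "df": df[ss.index], "MS": ss / df[ss.index]})


def permutation_test(records: pd.DataFrame, design: DesignSpec, term: str,
                     response: str = "percent", n_perm: int = 9999,
                     seed: int | None = None, exhaustive: bool = False) -> float:
    """Permutation p-value for one term (see :meth:`AnovaEngine.permutation_pvalues`).

    With ``exhaustive=True`` all orderings are enumerated (N <= 9 only) and
    the p-value is exact.
    """
    eng = AnovaEngine(records, design, response)
    if exhaustive:
        return float(eng.exhaustive_permutation_pvalues()[term])
    return float(eng.permutation_pvalues(n_perm=n_perm, seed=seed)[term])


def anova_table(records: pd.DataFrame, design: DesignSpec,
                response: str = "percent", n_perm: int = 9999,
                seed: int | None = None,
                restricted: bool = False) -> pd.DataFrame:
    """Full ANOVA table in canonical order: Source, df, SS, MS, F, P(perm).

    F ratios are exact where a single error mean square exists and
    Satterthwaite-synthesized quasi-F ratios otherwise; p-values come from
    unrestricted raw-data permutation.
    """
    eng = AnovaEngine(records, design, response, restricted=restricted)
    ss = eng.ss(eng.y)
    df = pd.Series({t.label: t.df for t in eng.terms})[ss.index]
    ms = ss / df
    ratios = eng.f_ratios()
    p = eng.permutation_pvalues(n_perm=n_perm, seed=seed)

    rows = []
    for t in eng.terms:
        k = t.label
        if t.is_residual:
            rows.append({"Source": k, "df": int(df[k]), "SS": ss[k],
                         "MS": ms[k], "F": np.nan, "P": np.nan,
                         "exact_F": None, "df_num": np.nan, "df_den": np.nan})
            continue
        r = ratios[k]
        dnum, dden = r.satterthwaite_df(ms, df)
        rows.append({"Source": k, "df": int(df[k]), "SS": ss[k], "MS": ms[k],
                     "F": r.value(ms), "P": p[k], "exact_F": r.exact,
                     "df_num": dnum, "df_den": dden})
    out = pd.DataFrame(rows).set_index("Source")
    out.attrs["n_perm"] = n_perm
    out.attrs["seed"] = seed
    return out
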