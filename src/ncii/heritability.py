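"""Heritability and repeatability from intra-family, sire, dam and animal models.

The experimental unit is a jar holding a sample of one full-sib family, so
the "genotype" carrying repeated measurements is the family: each jar is one
repeated observation of its family, and the intra-family (repeatability)
model fits a family random effect whose intraclass correlation is the
repeatability t.

Jar records are family means over tens of embryos, so Mendelian-sampling
variance is averaged away and the additive value of a family is the parental
average 0.5(a_sire + a_dam).  The animal model therefore carries one additive
effect per founder parent with incidence 0.5(Z_sire + Z_dam): this is the
numerator-relationship structure expressed at the family level (variance
0.5 sigma_A^2 per record, covariance 0.25 sigma_A^2 between half-sib
families) and it estimates the population additive variance sigma_A^2
directly.  A family permanent-environment effect absorbs non-additive
family variance.  The sire and dam models fit both parental main effects
plus the family effect and differ only in which parental component is
quadrupled.  Heritabilities are

    sire model    h^2 = 4 sigma_s^2 / sigma_P^2
    dam model     h^2 = 4 sigma_d^2 / sigma_P^2
    animal model  h^2 = sigma_A^2 / sigma_P^2

with sigma_P^2 the phenotypic variance of a record: the sum of every fitted
component's per-observation variance contribution (0.5 sigma_A^2 for the
additive term) plus the residual, optionally excluding block.  Standard
errors follow by the delta method from the inverse average-information
matrix of the REML fit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


from .varcomp import RandomTerm, RemlResult, reml_fit

__all__ = ["Pedigree", "amatrix", "build_pedigree", "HeritabilityEstimate",
           "fit_heritability", "per_treatment_heritability", "MODELS"]

MODELS = ("intra-family", "animal", "sire", "dam")


@dataclass(frozen=True)
class Pedigree:
    """Ordered pedigree entries (id, sire or None, dam or None)."""

    entries: tuple[tuple[str, str | None, str | None], ...]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for ind, s, d in self.entries:
            if ind in (s, d):
                raise ValueError(f"{ind!r} is its own parent")
            for parent in (s, d):
                if parent is not None and parent not in seen:
                    raise ValueError(
                        f"parent {parent!r} of {ind!r} not defined earlier in "
                        "the pedigree (parents must precede offspring)")
            if ind in seen:
                raise ValueError(f"duplicate pedigree id {ind!r}")
            seen.add(ind)

    @property
    def ids(self) -> list[str]:
        return [e[0] for e in self.entries]


def amatrix(ped: Pedigree) -> pd.DataFrame:
    """Numerator relationship matrix by the tabular method.

    Founders are taken as unrelated and non-inbred.
    """
    ids = ped.ids
    pos = {ind: i for i, ind in enumerate(ids)}
    n = len(ids)
    A = np.zeros((n, n))
    for i, (ind, s, d) in enumerate(ped.entries):
        si = pos[s] if s is not None else None
        di = pos[d] if d is not None else None
        for j in range(i):
            a = 0.0
            if si is not None:
                a += 0.5 * A[j, si]
            if di is not None:
                a += 0.5 * A[j, di]
            A[i, j] = A[j, i] = a
        if si is not None and di is not None:
            A[i, i] = 1.0 + 0.5 * A[si, di]
        else:
            A[i, i] = 1.0
    return pd.DataFrame(A, index=ids, columns=ids)


def build_pedigree(records: pd.DataFrame) -> Pedigree:
    """Pedigree with founder parents and one individual per full-sib family."""
    sires = sorted(records["sire"].unique())
    dams = sorted(records["dam"].unique())
    fams = sorted(set(zip(records["sire"], records["dam"])))
    entries = [(s, None, None) for s in sires] + [(d, None, None) for d in dams]
    entries += [(family_id(s, d), s, d) for s, d in fams]
    return Pedigree(tuple(entries))


def family_id(sire: str, dam: str) -> str:
    return f"{sire}x{dam}"


@dataclass(frozen=True)
class HeritabilityEstimate:
    """Point estimate with delta-method SE for a ratio parameter."""

    model: str                     # intra-family | animal | sire | dam
    parameter: str                 # heritability | repeatability
    estimate: float                # truncated to [0, 1]
    se: float
    raw: float                     # untruncated ratio
    components: pd.Series | None = None
    converged: bool = True

    def as_row(self) -> dict:
        return {"Model": self.model, "Parameter": self.parameter,
                "Estimate": self.estimate, "SE": self.se, "Raw": self.raw}


def _ratio_and_se(result: RemlResult, numerator: str, multiplier: float,
                  include: list[str],
                  weights: dict[str, float] | None = None
                  ) -> tuple[float, float]:
    """Delta-method SE for multiplier * sigma_num^2 / sigma_P^2 where
    sigma_P^2 = sum of per-observation variance contributions w_k sigma_k^2.
    """
    weights = weights or {}
    w = pd.Series({k: weights.get(k, 1.0) for k in include})
    total = float((result.components[include] * w).sum())
    if total <= 0:
        return np.nan, np.nan
    num = float(result.components[numerator])
    ratio = multiplier * num / total
    grad = pd.Series(0.0, index=result.cov.index)
    for k in include:
        grad[k] = -multiplier * num * w[k] / total ** 2
    grad[numerator] += multiplier / total
    g = grad.to_numpy()
    var = float(g @ result.cov.to_numpy() @ g)
    return ratio, np.sqrt(max(var, 0.0))


def _one_hot(records: pd.DataFrame, key) -> tuple[np.ndarray, list]:
    codes, levels = pd.factorize(key, sort=True)
    Z = np.zeros((len(records), len(levels)))
    Z[np.arange(len(records)), codes] = 1.0
    return Z, list(levels)


#: per-observation variance contribution of each random term (sigma_P weights)
_OBS_WEIGHTS = {"additive": 0.5}


def _model_terms(records: pd.DataFrame, model: str) -> list[RandomTerm]:
    fam_key = pd.Index([family_id(s, d) for s, d in
                        zip(records["sire"], records["dam"])])
    Z_block, _ = _one_hot(records, records["block"])
    Z_fam, fam_levels = _one_hot(records, fam_key)
    Z_s, _ = _one_hot(records, records["sire"])
    Z_d, _ = _one_hot(records, records["dam"])
    terms = [RandomTerm("block", Z_block)]
    if model == "intra-family":
        terms.append(RandomTerm("family", Z_fam))
    elif model in ("sire", "dam"):
        terms += [RandomTerm("sire", Z_s), RandomTerm("dam", Z_d),
                  RandomTerm("family", Z_fam)]
    elif model == "animal":
        # parental-average breeding values: one additive effect per founder,
        # each family record loads 0.5 on its sire and 0.5 on its dam
        terms += [RandomTerm("additive", 0.5 * np.hstack([Z_s, Z_d])),
                  RandomTerm("family", Z_fam)]
    else:
        raise ValueError(f"unknown model {model!r}; choose from {MODELS}")
    return terms


def fit_heritability(records: pd.DataFrame, model: str,
                     response: str = "percent",
                     fixed_terms: tuple[str, ...] = ("temperature", "ph"),
                     include_block: bool = True,
                     **reml_kwargs) -> HeritabilityEstimate:
    """Fit one of the four genetic models and return its ratio parameter.

    ``include_block`` controls whether the block component enters the
    phenotypic variance in the denominator (it is always fitted).
    """
    terms = _model_terms(records, model)
    result = reml_fit(records, response=response, random_terms=terms,
                      fixed_terms=fixed_terms, **reml_kwargs)
    include = [t.label for t in terms] + ["residual"]
    if not include_block:
        include = [lbl for lbl in include if lbl != "block"]
    spec = {"intra-family": ("family", 1.0, "repeatability"),
            "sire": ("sire", 4.0, "heritability"),
            "dam": ("dam", 4.0, "heritability"),
            "animal": ("additive", 1.0, "heritability")}[model]
    numerator, mult, parameter = spec
    raw, se = _ratio_and_se(result, numerator, mult, include, _OBS_WEIGHTS)
    est = float(np.clip(raw, 0.0, 1.0)) if np.isfinite(raw) else np.nan
    return HeritabilityEstimate(model=model, parameter=parameter,
                                estimate=est, se=se, raw=raw,
                                components=result.components,
                                converged=result.converged)


def per_treatment_heritability(records: pd.DataFrame,
                               temperature, ph,
                               models: tuple[str, ...] = MODELS,
                               response: str = "percent",
                               **kwargs) -> list[HeritabilityEstimate]:
    """Heritability/repeatability restricted to one treatment cell.

    Within a cell there are no environmental fixed effects left, so only the
    intercept is fitted.  Standard errors are expected to be wide.
    """
    cell = records[(records["temperature"] == temperature)
                   & (records["ph"] == ph)]
    if cell["sire"].nunique() < 2 or cell["dam"].nunique() < 2:
        raise ValueError("treatment cell is degenerate: needs >= 2 sires and "
                         ">= 2 dams")
    return [fit_heritability(cell, m, response=response, fixed_terms=(),
                             **kwargs) for m in models]


def heritability_table(records: pd.DataFrame, traits: dict[str, str],
                       **kwargs) -> pd.DataFrame:
    """Estimates for every trait x model, one row each (Table-style output)."""
    rows = []
    for trait, column in traits.items():
        for model in MODELS:
            est = fit_heritability(records, model, response=column, **kwargs)
            rows.append({"Trait": trait, **est.as_row()})
    return pd.DataFrame(rows)
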