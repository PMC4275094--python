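"""Simulation of jar-level NC II datasets.

The study whose design this package analyses did not deposit raw phenotype
records, so all downstream machinery is exercised on simulated data.  The
generator draws one Gaussian effect per level of every declared random term
(block; sire and dam within block; sire x dam; and every parent x
environment interaction), adds fixed treatment effects, and emits one record
per family x treatment x replicate jar.

Two response models are available:

* ``gaussian-percent`` (default): the latent value is reported directly as a
  percentage, clipped to [0, 100].  This mirrors an analysis of raw
  percentage data with normal residuals and keeps the balanced-ANOVA theory
  exact.
* ``latent-binomial``: the latent percentage is mapped to a probability and
  the number of normally developed embryos is drawn binomially from the
  number scored, for robustness studies with realistic counting noise.

Randomness is disciplined: every random term draws from its own named
substream derived from the user seed, so adding or removing one term never
perturbs the draws of the others.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import DesignSpec

__all__ = ["VarianceComponents", "FixedEffects", "SimOptions",
           "simulate_dataset", "simulate_replicates", "PARENTAL_TERMS"]

#: canonical random-term keys, in substream order (stable across versions;
#: the optional block x environment terms are appended so that enabling them
#: never perturbs the draws of the core terms)
VC_KEYS = (
    "block",
    "sire",
    "dam",
    "sire_dam",
    "sire_temperature",
    "sire_ph",
    "sire_temperature_ph",
    "dam_temperature",
    "dam_ph",
    "dam_temperature_ph",
    "sire_dam_temperature",
    "sire_dam_ph",
    "sire_dam_temperature_ph",
    "residual",
    "block_temperature",
    "block_ph",
    "block_temperature_ph",
)

#: purely parental terms shared (scaled by rho_stage) across traits
PARENTAL_TERMS = ("sire", "dam", "sire_dam")


@dataclass(frozen=True)
class VarianceComponents:
    """Variances (on the percent scale, squared units) for every random term."""

    block: float = 0.0
    sire: float = 0.0
    dam: float = 0.0
    sire_dam: float = 0.0
    sire_temperature: float = 0.0
    sire_ph: float = 0.0
    sire_temperature_ph: float = 0.0
    dam_temperature: float = 0.0
    dam_ph: float = 0.0
    dam_temperature_ph: float = 0.0
    sire_dam_temperature: float = 0.0
    sire_dam_ph: float = 0.0
    sire_dam_temperature_ph: float = 0.0
    residual: float = 100.0
    #: block x treatment interactions; zero by default (the standard model
    #: lets block interact with nothing) but available for full-structure
    #: simulation studies
    block_temperature: float = 0.0
    block_ph: float = 0.0
    block_temperature_ph: float = 0.0

    def __post_init__(self) -> None:
        for k in VC_KEYS:
            if getattr(self, k) < 0:
                raise ValueError(f"variance component {k!r} must be >= 0")

    def as_dict(self) -> dict[str, float]:
        return {k: float(getattr(self, k)) for k in VC_KEYS}

    @classmethod
    def from_dict(cls, d: dict) -> "VarianceComponents":
        unknown = set(d) - set(VC_KEYS)
        if unknown:
            raise ValueError(f"unknown variance component(s): {sorted(unknown)}")
        return cls(**{k: float(v) for k, v in d.items()})

    def sire_terms(self) -> dict[str, float]:
        """The four sire-associated components entering cross-environment
        genetic correlations."""
        return {k: getattr(self, k)
                for k in ("sire", "sire_temperature", "sire_ph",
                          "sire_temperature_ph")}


@dataclass(frozen=True)
class FixedEffects:
    """Grand mean and sum-to-zero treatment effects on the percent scale."""

    mu: float = 63.5
    temperature: tuple[float, ...] = (0.0, 0.0)
    ph: tuple[float, ...] = (0.0, 0.0, 0.0)
    temperature_ph: tuple[tuple[float, ...], ...] | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.mu <= 100.0:
            raise ValueError("grand mean must lie in [0, 100] percent")
        for name in ("temperature", "ph"):
            eff = np.asarray(getattr(self, name), float)
            if abs(eff.sum()) > 1e-8:
                raise ValueError(f"{name} effects must sum to zero")
        if self.temperature_ph is not None:
            tp = np.asarray(self.temperature_ph, float)
            if tp.shape != (len(self.temperature), len(self.ph)):
                raise ValueError("temperature_ph must be (n_temp, n_ph)")
            if (np.abs(tp.sum(axis=0)) > 1e-8).any() or \
               (np.abs(tp.sum(axis=1)) > 1e-8).any():
                raise ValueError("interaction effects must sum to zero over "
                                 "each margin")

    def interaction(self) -> np.ndarray:
        if self.temperature_ph is None:
            return np.zeros((len(self.temperature), len(self.ph)))
        return np.asarray(self.temperature_ph, float)

    @classmethod
    def from_dict(cls, d: dict) -> "FixedEffects":
        d = dict(d)
        for k in ("temperature", "ph"):
            if k in d:
                d[k] = tuple(float(x) for x in d[k])
        if d.get("temperature_ph") is not None:
            d["temperature_ph"] = tuple(tuple(float(x) for x in row)
                                        for row in d["temperature_ph"])
        return cls(**d)


@dataclass(frozen=True)
class SimOptions:
    """Response model, seed and trait structure of a simulation run."""

    model: str = "gaussian-percent"
    seed: int = 0
    traits: tuple[str, ...] = ("phenotype",)
    rho_stage: float = 0.0

    def __post_init__(self) -> None:
        if self.model not in ("gaussian-percent", "latent-binomial"):
            raise ValueError(f"unknown response model {self.model!r}")
        if not -1.0 <= self.rho_stage <= 1.0:
            raise ValueError("rho_stage must lie in [-1, 1]")
        if len(self.traits) == 0:
            raise ValueError("at least one trait required")


def _term_columns(key: str) -> list[str]:
    # keys are underscore-joined factor names; every factor name is a column
    return key.split("_")


def _substream(seed_key: tuple, name: str) -> np.random.Generator:
    idx = (VC_KEYS.index(name) if name in VC_KEYS
           else len(VC_KEYS) + {"n_scored": 0, "binomial": 1}[name])
    return np.random.default_rng(np.random.SeedSequence(list(seed_key) + [idx]))


def _level_codes(grid: pd.DataFrame, key: str) -> tuple[np.ndarray, int]:
    cols = _term_columns(key)
    codes, levels = pd.factorize(
        pd.MultiIndex.from_frame(grid[cols]) if len(cols) > 1 else grid[cols[0]],
        sort=True)
    return codes, len(levels)


def simulate_dataset(design: DesignSpec,
                     vc: VarianceComponents | None = None,
                     fx: FixedEffects | None = None,
                     opts: SimOptions | None = None,
                     _seed_key: tuple | None = None) -> pd.DataFrame:
    """Simulate one complete jar-level dataset for the design.

    Returns one row per jar with identifier columns, ``n_scored`` and, per
    trait, percent and success-count columns.  With a single trait the
    columns are named ``percent``/``n_success``; with several traits each
    trait name is used for the percent column with matching
    ``n_success_<trait>`` counts.
    """
    vc = vc or VarianceComponents()
    fx = fx or FixedEffects(
        temperature=tuple(0.0 for _ in range(design.factor("temperature").n_levels)),
        ph=tuple(0.0 for _ in range(design.factor("ph").n_levels)))
    opts = opts or SimOptions()
    if len(fx.temperature) != design.factor("temperature").n_levels or \
       len(fx.ph) != design.factor("ph").n_levels:
        raise ValueError("fixed-effect vectors must match design level counts")

    seed_key = _seed_key if _seed_key is not None else (int(opts.seed),)
    grid = design.grid()
    n = len(grid)

    # fixed part
    t_idx = grid["temperature"].to_numpy() - 1
    p_idx = grid["ph"].to_numpy() - 1
    inter = fx.interaction()
    latent_fixed = (fx.mu + np.asarray(fx.temperature)[t_idx]
                    + np.asarray(fx.ph)[p_idx] + inter[t_idx, p_idx])

    rng_scored = _substream(seed_key, "n_scored")
    lo, hi = design.embryos_scored_range
    n_scored = rng_scored.integers(lo, hi + 1, size=n)
    out = grid.copy()
    out["n_scored"] = n_scored

    shared_effects: dict[str, dict] = {}
    clip_events = 0
    for ti, trait in enumerate(opts.traits):
        latent = latent_fixed.astype(float).copy()
        for key in VC_KEYS:
            var = getattr(vc, key)
            if key == "residual":
                rng = _substream(seed_key + (ti,), key)
                latent += np.sqrt(var) * rng.standard_normal(n)
                continue
            if var == 0.0:
                continue
            codes, n_levels = _level_codes(grid, key)
            rng = _substream(seed_key + (ti,), key)
            z = rng.standard_normal(n_levels)
            if key in PARENTAL_TERMS and len(opts.traits) > 1:
                # parental effects shared across developmental stages
                if ti == 0:
                    shared_effects[key] = z
                else:
                    rho = opts.rho_stage
                    z = rho * shared_effects[key] \
                        + np.sqrt(max(0.0, 1 - rho ** 2)) * z
            latent += np.sqrt(var) * z[codes]

        if opts.model == "gaussian-percent":
            clip_events += int(((latent < 0) | (latent > 100)).sum())
            percent = np.clip(latent, 0.0, 100.0)
            n_success = np.rint(percent / 100.0 * n_scored).astype(int)
        else:
            p = np.clip(latent / 100.0, 1e-9, 1 - 1e-9)
            rng_bin = _substream(seed_key + (ti,), "binomial")
            n_success = rng_bin.binomial(n_scored, p)
            percent = 100.0 * n_success / n_scored

        if len(opts.traits) == 1:
            out["n_success"] = n_success
            out["percent"] = percent
        else:
            out[f"n_success_{trait}"] = n_success
            out[trait] = percent

    if clip_events:
        warnings.warn(f"{clip_events} latent value(s) clipped to [0, 100]; "
                      "heavy clipping invalidates the Gaussian response model",
                      stacklevel=2)
    out.attrs["seed_key"] = seed_key
    return out


def simulate_replicates(k: int, design: DesignSpec,
                        vc: VarianceComponents | None = None,
                        fx: FixedEffects | None = None,
                        opts: SimOptions | None = None):
    """Yield ``k`` independent datasets from seed-derived substreams.

    Dataset ``i`` is reproducible in isolation: it depends only on
    ``(opts.seed, i)``.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    opts = opts or SimOptions()
    for i in range(k):
        yield simulate_dataset(design, vc, fx, opts,
                               _seed_key=(int(opts.seed), i))
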