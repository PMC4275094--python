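"""End-to-end pipeline: simulate -> validate -> ANOVA -> variance components
-> genetic correlations -> heritability -> stage link, with TSV/JSON outputs.

Every artifact is stamped with the configuration hash and seed so a run can
be reproduced byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .anova import anova_table
from .design import DesignSpec, read_records, validate_dataset
from .heritability import heritability_table
from .simulate import FixedEffects, SimOptions, VarianceComponents, simulate_dataset
from .stagelink import stage_link_table
from .varcomp import anova_varcomp, eisen_saxton, reml_fit

log = logging.getLogger("ncii")

__all__ = ["PipelineConfig", "run_pipeline", "reaction_norm_plot"]


@dataclass
class PipelineConfig:
    """Serializable description of one full analysis run."""

    design: DesignSpec = field(default_factory=DesignSpec)
    variance_components: dict = field(default_factory=dict)
    fixed_effects: dict = field(default_factory=dict)
    traits: tuple[str, ...] = ("fertilization", "gastrulation")
    response_model: str = "gaussian-percent"
    rho_stage: float = 0.0
    n_perm: int = 9999
    seed: int = 0
    input_csv: str | None = None     # analyse an existing dataset instead
    outdir: str = "ncii_out"
    stages: tuple[str, ...] = ("simulate", "anova", "varcomp", "heritability",
                               "stagelink")

    @classmethod
    def from_dict(cls, doc: dict) -> "PipelineConfig":
        doc = dict(doc)
        if "design" in doc:
            doc["design"] = DesignSpec.from_dict(doc["design"])
        for k in ("traits", "stages"):
            if k in doc:
                doc[k] = tuple(doc[k])
        return cls(**doc)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in (
            "variance_components", "fixed_effects", "response_model",
            "rho_stage", "n_perm", "seed", "input_csv", "outdir")}
        d["design"] = self.design.to_dict()
        d["traits"] = list(self.traits)
        d["stages"] = list(self.stages)
        return d

    def config_hash(self) -> str:
        """Hash of the scientific configuration (output location excluded)."""
        doc = {k: v for k, v in self.to_dict().items() if k != "outdir"}
        blob = json.dumps(doc, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _stamp(config: PipelineConfig) -> str:
    return (f"# ncii {__version__}  config={config.config_hash()}  "
            f"seed={config.seed}\n")


def _write_tsv(df: pd.DataFrame, path: Path, config: PipelineConfig,
               index: bool = True) -> None:
    with open(path, "w") as fh:
        fh.write(_stamp(config))
        df.to_csv(fh, sep="\t", index=index)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages; returns a run report dictionary."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    design = config.design
    report: dict = {"config_hash": config.config_hash(), "seed": config.seed,
                    "outputs": [], "warnings": []}

    def emit(name: str) -> Path:
        p = out / name
        report["outputs"].append(str(p))
        return p

    # --- obtain data
    if config.input_csv:
        records = read_records(config.input_csv)
        traits = [t for t in config.traits if t in records.columns]
        if not traits and "percent" in records.columns:
            traits = ["percent"]
    elif "simulate" in config.stages:
        vc = VarianceComponents.from_dict(config.variance_components)
        fx = FixedEffects.from_dict(config.fixed_effects) \
            if config.fixed_effects else FixedEffects()
        opts = SimOptions(model=config.response_model, seed=config.seed,
                          traits=tuple(config.traits),
                          rho_stage=config.rho_stage)
        records = simulate_dataset(design, vc, fx, opts)
        traits = list(config.traits) if len(config.traits) > 1 else ["percent"]
        _write_tsv(records, emit("simulated.tsv"), config, index=False)
    else:
        raise ValueError("no input_csv given and 'simulate' stage disabled")

    vrep = validate_dataset(records, design)
    (out / "validation.txt").write_text(_stamp(config) + str(vrep) + "\n")
    report["outputs"].append(str(out / "validation.txt"))
    report["balanced"] = vrep.balanced
    if not vrep.balanced:
        raise ValueError(f"dataset fails validation:\n{vrep}")

    summary: list[str] = [f"ncii pipeline run (config {config.config_hash()}, "
                          f"seed {config.seed})",
                          f"{len(records)} records, traits: {', '.join(traits)}"]

    if "anova" in config.stages:
        for i, trait in enumerate(traits):
            log.info("ANOVA (%s), %d permutations", trait, config.n_perm)
            tab = anova_table(records, design, trait, n_perm=config.n_perm,
                              seed=config.seed + i)
            _write_tsv(tab, emit(f"anova_{trait}.tsv"), config)
            sig = tab.index[(tab["P"] < 0.05).fillna(False)].tolist()
            summary.append(f"ANOVA {trait}: {len(tab)} rows; "
                           f"P<0.05 terms: {', '.join(sig) or 'none'}")

    if "varcomp" in config.stages:
        gc_all = {}
        for trait in traits:
            mom = anova_varcomp(records, design, trait)
            fit = reml_fit(records, design, trait)
            comp = pd.DataFrame({"REML": fit.components, "SE": fit.se,
                                 "ANOVA_unconstrained":
                                     mom["estimate"].reindex(fit.components.index)})
            _write_tsv(comp, emit(f"varcomp_{trait}.tsv"), config)
            try:
                gc_all[trait] = eisen_saxton(fit).as_dict()
            except ValueError as exc:
                report["warnings"].append(f"{trait}: {exc}")
            summary.append(f"varcomp {trait}: REML "
                           f"{'converged' if fit.converged else 'DID NOT converge'}"
                           f" in {fit.n_iter} iter; boundary: "
                           f"{', '.join(fit.boundary) or 'none'}")
        with open(emit("genetic_correlations.json"), "w") as fh:
            json.dump({"config_hash": config.config_hash(),
                       "seed": config.seed, "correlations": gc_all}, fh,
                      indent=1)
        for trait, gc in gc_all.items():
            summary.append(f"genetic correlations {trait}: "
                           + ", ".join(f"{k}={v:.3f}" for k, v in gc.items()))

    if "heritability" in config.stages:
        h2 = heritability_table(records, {t: t for t in traits})
        _write_tsv(h2, emit("heritability.tsv"), config, index=False)
        for _, r in h2.iterrows():
            summary.append(f"h2 {r['Trait']}/{r['Model']}: {r['Parameter']} = "
                           f"{r['Estimate']:.3f} (SE {r['SE']:.3f})")

    if "stagelink" in config.stages:
        if len(traits) >= 2:
            sl = stage_link_table(records, traits[0], traits[1])
            _write_tsv(sl, emit("stage_link.tsv"), config, index=False)
            best = sl[sl["direction"] == "gast_on_fert"]
            summary.append("stage link R2 by cell: "
                           + ", ".join(f"T{int(r.temperature)}/pH{int(r.ph)}:"
                                       f"{r.R2:.2f}"
                                       for r in best.itertuples()))
        else:
            msg = "stage_link skipped: needs two traits"
            report["warnings"].append(msg)
            summary.append(msg)

    (out / "summary.txt").write_text("\n".join([_stamp(config).rstrip()]
                                               + summary) + "\n")
    report["outputs"].append(str(out / "summary.txt"))
    report["summary"] = summary
    return report


def reaction_norm_plot(records: pd.DataFrame, parent: str = "sire",
                       env_factor: str = "temperature",
                       response: str = "percent", path=None):
    """Reaction norms: per-parent progeny mean +/- SE across one environmental
    factor, pooled over the other treatment factor and replicates.

    Returns the matplotlib figure; writes to ``path`` if given.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if records[env_factor].nunique() < 2:
        raise ValueError("need at least 2 environment levels to draw norms")
    g = records.groupby([parent, env_factor])[response]
    stats = g.agg(["mean", "sem"]).reset_index()
    fig, ax = plt.subplots(figsize=(5, 4))
    for pid, sub in stats.groupby(parent):
        ax.errorbar(sub[env_factor], sub["mean"], yerr=sub["sem"],
                    marker="o", capsize=2, label=str(pid))
    ax.set_xlabel(env_factor)
    ax.set_ylabel(f"mean {response} (+/- SE)")
    ax.set_xticks(sorted(records[env_factor].unique()))
    ax.legend(fontsize=6, ncol=2, title=parent)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
    return fig
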