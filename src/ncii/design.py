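"""North Carolina II experimental design: layout, model terms, degrees of freedom.

The design crosses every sire with every dam within an experimental block
(paternal/maternal half-sib structure), exposes each full-sib family to a
factorial set of environmental treatments, and replicates each family ×
treatment cell.  Sires and dams are nested within block: parent identifiers
are never reused across blocks.

The model-term enumeration follows the rules for balanced factorial designs
with nesting: a term is any combination of factors in which no factor
co-occurs with a factor it is nested in; its degrees of freedom are the
product of (levels - 1) over member factors times the number of levels of
every nesting factor not itself in the term.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import pandas as pd
import yaml

__all__ = [
    "Factor",
    "DesignSpec",
    "ModelTerm",
    "ValidationReport",
    "enumerate_terms",
    "total_units",
    "validate_dataset",
    "read_records",
    "write_records",
]

#: default short labels used in rendered ANOVA tables
_SHORT_LABELS = {
    "block": "Bl",
    "sire": "Ma",
    "dam": "Fe",
    "temperature": "Te",
    "ph": "pH",
}

RESIDUAL_LABEL = "Res"


@dataclass(frozen=True)
class Factor:
    """One classification factor of the design."""

    name: str
    n_levels: int
    is_random: bool
    nested_in: str | None = None


@dataclass(frozen=True)
class DesignSpec:
    """Layout of a blocked NC II cross with crossed environmental treatments.

    Defaults reproduce a 2-block design with 4 sires x 2 dams per block,
    2 temperature x 3 pH treatment levels and 3 replicate jars per family x
    treatment cell (288 jars in total, 144 per block).
    """

    n_blocks: int = 2
    sires_per_block: int = 4
    dams_per_block: int = 2
    env_factors: tuple[tuple[str, int], ...] = (("temperature", 2), ("ph", 3))
    n_replicates: int = 3
    embryos_scored_range: tuple[int, int] = (30, 50)

    def __post_init__(self) -> None:
        counts = [self.n_blocks, self.sires_per_block, self.dams_per_block,
                  self.n_replicates]
        counts += [n for _, n in self.env_factors]
        if any(int(c) != c or c < 1 for c in counts):
            raise ValueError("all design counts must be integers >= 1")
        lo, hi = self.embryos_scored_range
        if not (1 <= lo <= hi):
            raise ValueError("embryos_scored_range must satisfy 1 <= lo <= hi")
        names = [name for name, _ in self.env_factors]
        if len(set(names)) != len(names) or set(names) & {"block", "sire", "dam"}:
            raise ValueError("environmental factor names must be unique and "
                             "distinct from block/sire/dam")

    # -- structure -------------------------------------------------------

    def factors(self) -> list[Factor]:
        """All classification factors, parental factors nested in block."""
        out = [
            Factor("block", self.n_blocks, True),
            Factor("sire", self.sires_per_block, True, nested_in="block"),
            Factor("dam", self.dams_per_block, True, nested_in="block"),
        ]
        out += [Factor(name, n, False) for name, n in self.env_factors]
        return out

    def factor(self, name: str) -> Factor:
        for f in self.factors():
            if f.name == name:
                return f
        raise KeyError(f"unknown factor {name!r}")

    def short_label(self, name: str) -> str:
        return _SHORT_LABELS.get(name, name)

    @property
    def n_families(self) -> int:
        return self.n_blocks * self.sires_per_block * self.dams_per_block

    @property
    def n_treatments(self) -> int:
        n = 1
        for _, k in self.env_factors:
            n *= k
        return n

    def total_units(self, per_block: bool = False) -> int:
        n = self.sires_per_block * self.dams_per_block * self.n_treatments \
            * self.n_replicates
        return n if per_block else n * self.n_blocks

    # -- identifiers -----------------------------------------------------

    def sire_ids(self, block: int) -> list[str]:
        return [f"B{block}S{i}" for i in range(1, self.sires_per_block + 1)]

    def dam_ids(self, block: int) -> list[str]:
        return [f"B{block}D{i}" for i in range(1, self.dams_per_block + 1)]

    def block_ids(self) -> list[int]:
        return list(range(1, self.n_blocks + 1))

    def env_levels(self, name: str) -> list[int]:
        for fname, n in self.env_factors:
            if fname == name:
                return list(range(1, n + 1))
        raise KeyError(name)

    def grid(self) -> pd.DataFrame:
        """Full factorial grid of jars (one row per experimental unit)."""
        rows = []
        env_names = [n for n, _ in self.env_factors]
        env_levels = [self.env_levels(n) for n in env_names]
        for b in self.block_ids():
            for s, d in itertools.product(self.sire_ids(b), self.dam_ids(b)):
                for combo in itertools.product(*env_levels):
                    for r in range(1, self.n_replicates + 1):
                        rows.append((b, s, d, *combo, r))
        return pd.DataFrame(rows,
                            columns=["block", "sire", "dam", *env_names,
                                     "replicate"])

    # -- serialization ---------------------------------------------------

    @classmethod
    def from_dict(cls, d: dict) -> "DesignSpec":
        d = dict(d)
        if "env_factors" in d:
            d["env_factors"] = tuple((str(k), int(v)) for k, v in d["env_factors"])
        if "embryos_scored_range" in d:
            d["embryos_scored_range"] = tuple(d["embryos_scored_range"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "DesignSpec":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls.from_dict(doc.get("design", doc))

    def to_dict(self) -> dict:
        return {
            "n_blocks": self.n_blocks,
            "sires_per_block": self.sires_per_block,
            "dams_per_block": self.dams_per_block,
            "env_factors": [list(t) for t in self.env_factors],
            "n_replicates": self.n_replicates,
            "embryos_scored_range": list(self.embryos_scored_range),
        }


@dataclass(frozen=True)
class ModelTerm:
    """One source of variation in the balanced mixed-model ANOVA."""

    label: str
    factors: frozenset[str]
    nested_in: frozenset[str]
    is_random: bool
    df: int

    @property
    def subscripts(self) -> frozenset[str]:
        """Factor set indexing the term's cells (members plus nests)."""
        return self.factors | self.nested_in

    @property
    def is_residual(self) -> bool:
        return self.label == RESIDUAL_LABEL


def total_units(design: DesignSpec, per_block: bool = False) -> int:
    """Number of experimental units (jars): blocks x families x treatments x reps."""
    return design.total_units(per_block=per_block)


def _term_label(design: DesignSpec, members: tuple[str, ...]) -> str:
    parts = []
    for name in members:
        f = design.factor(name)
        lab = design.short_label(name)
        if f.nested_in is not None:
            lab = f"{lab}({design.short_label(f.nested_in)})"
        parts.append(lab)
    return " × ".join(parts)


def _display_order(design: DesignSpec) -> list[str]:
    return ["block", "sire", "dam"] + [n for n, _ in design.env_factors]


def _sort_key(design: DesignSpec, members: frozenset[str]):
    # Canonical table order: by term size; within a size, terms without
    # parental factors first (block/env precedence), then parental terms in
    # sire < dam < env precedence.
    parental = members & {"sire", "dam"}
    if parental:
        prec = ["sire", "dam"] + [n for n, _ in design.env_factors]
    else:
        prec = ["block"] + [n for n, _ in design.env_factors]
    idx = sorted(prec.index(m) for m in members)
    return (len(members), 1 if parental else 0, idx)


def enumerate_terms(design: DesignSpec,
                    fixed: set[str] | None = None,
                    random: set[str] | None = None,
                    drop_zero_df: bool = True,
                    include_residual: bool = True) -> list[ModelTerm]:
    """Enumerate ANOVA model terms for the design in canonical table order.

    ``fixed`` and ``random`` partition the factor names; defaults declare the
    environmental factors fixed and block/sire/dam random.  Terms whose
    degrees of freedom are zero (degenerate designs) are dropped so that
    rendered tables stay aligned with conventional ANOVA output.
    """
    facs = {f.name: f for f in design.factors()}
    if fixed is None and random is None:
        random = {"block", "sire", "dam"}
        fixed = {n for n, _ in design.env_factors}
    fixed = set(fixed or ())
    random = set(random or ())
    if fixed & random:
        raise ValueError(f"factors declared both fixed and random: "
                         f"{sorted(fixed & random)}")
    unknown = (fixed | random) - set(facs)
    if unknown:
        raise ValueError(f"unknown factor name(s): {sorted(unknown)}")
    if set(facs) - (fixed | random):
        raise ValueError("fixed and random together must cover all factors")

    names = list(facs)
    candidates: list[frozenset[str]] = []
    for r in range(1, len(names) + 1):
        for combo in itertools.combinations(names, r):
            s = frozenset(combo)
            # a factor never co-occurs with its nesting factor
            if any(facs[m].nested_in in s for m in s):
                continue
            candidates.append(s)
    candidates.sort(key=lambda s: _sort_key(design, s))

    order = _display_order(design)
    N = design.total_units()
    terms: list[ModelTerm] = []
    for members in candidates:
        nests = frozenset(facs[m].nested_in for m in members
                          if facs[m].nested_in is not None)
        df = 1
        for m in members:
            df *= facs[m].n_levels - 1
        for g in nests - members:
            df *= facs[g].n_levels
        if drop_zero_df and df == 0:
            continue
        ordered = tuple(sorted(members, key=order.index))
        terms.append(ModelTerm(
            label=_term_label(design, ordered),
            factors=members,
            nested_in=nests - members,
            is_random=bool(members & random),
            df=df,
        ))
    if include_residual:
        df_res = N - 1 - sum(t.df for t in terms)
        terms.append(ModelTerm(RESIDUAL_LABEL, frozenset(), frozenset(),
                               True, df_res))
    return terms


# ---------------------------------------------------------------------------
# dataset validation and IO

RECORD_COLUMNS = ["block", "sire", "dam", "temperature", "ph",
                  "replicate", "n_scored", "n_success"]


@dataclass
class ValidationReport:
    """Outcome of checking a jar-level dataset against a design."""

    balanced: bool
    n_records: int
    issues: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return self.balanced and not self.issues

    def __str__(self) -> str:
        head = (f"{self.n_records} records, "
                f"{'balanced' if self.balanced else 'UNBALANCED'}, "
                f"{len(self.issues)} issue(s)")
        return "\n".join([head] + [f"  - {m}" for m in self.issues])


def validate_dataset(records: pd.DataFrame, design: DesignSpec) -> ValidationReport:
    """Check completeness, key uniqueness, count ranges and parent scoping."""
    issues: list[str] = []
    env_names = [n for n, _ in design.env_factors]
    keycols = ["block", "sire", "dam", *env_names, "replicate"]
    missing_cols = [c for c in keycols if c not in records.columns]
    if missing_cols:
        return ValidationReport(False, len(records),
                                [f"missing columns: {missing_cols}"])

    dup = records.duplicated(subset=keycols)
    for _, row in records.loc[dup, keycols].iterrows():
        issues.append(f"duplicate unit key {tuple(row)}")

    expected = design.grid()
    merged = expected.merge(records[keycols].drop_duplicates(), on=keycols,
                            how="left", indicator=True)
    n_missing = int((merged["_merge"] == "left_only").sum())
    for _, row in merged.loc[merged["_merge"] == "left_only", keycols].head(20).iterrows():
        issues.append(f"missing cell {tuple(row)}")
    if n_missing > 20:
        issues.append(f"... and {n_missing - 20} more missing cells")
    extraneous = records[keycols].merge(expected, on=keycols, how="left",
                                        indicator=True)
    for _, row in extraneous.loc[extraneous["_merge"] == "left_only",
                                 keycols].iterrows():
        issues.append(f"unexpected unit {tuple(row)} not in design grid")

    if {"n_scored", "n_success"} <= set(records.columns):
        bad = records["n_success"] > records["n_scored"]
        for i in records.index[bad]:
            issues.append(f"record {i}: n_success > n_scored")
        neg = (records["n_scored"] < 1) | (records["n_success"] < 0)
        for i in records.index[neg]:
            issues.append(f"record {i}: counts out of range")

    # parent identifiers must not leak across blocks
    for col in ("sire", "dam"):
        by_block = records.groupby("block")[col].agg(lambda s: set(s))
        seen: set = set()
        for b, ids in by_block.items():
            reused = ids & seen
            if reused:
                issues.append(f"{col} id(s) reused across blocks: {sorted(reused)}")
            seen |= ids

    balanced = (n_missing == 0 and not dup.any()
                and len(records) == design.total_units())
    return ValidationReport(balanced, len(records), issues)


def add_percent(records: pd.DataFrame, trait: str = "percent") -> pd.DataFrame:
    """Derive a percent column from success counts if absent."""
    if trait not in records.columns:
        records = records.copy()
        records[trait] = 100.0 * records["n_success"] / records["n_scored"]
    return records


def read_records(path, trait: str = "percent") -> pd.DataFrame:
    """Read a jar-level CSV (headered, one row per jar) and derive percents."""
    df = pd.read_csv(path)
    df.columns = [c.strip().lower() for c in df.columns]
    return add_percent(df, trait)


def write_records(records: pd.DataFrame, path) -> None:
    records.to_csv(path, index=False)
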