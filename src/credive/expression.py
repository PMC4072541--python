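"""Reporter-expression scoring tables and per-transgene summaries.

The raw data model mirrors single-cell-resolution GFP scoring of reporter
transgenes in *C. elegans*: one row per (gene, CRE species, host species,
strain, individual, cell) with either a presence/absence flag (binary cells
and cell groups) or an integer count of expressing cells (counted classes
such as the D-type neurons or the ventral nerve cord).  Summaries report,
per transgene, the frequency of expression per binary cell — and per named
group, the frequency of expression in at least one member cell — plus the
median expressing-cell count per counted class, overall and per strain.

Scoring-policy minima follow the survey design: at least fifty individuals
from no fewer than two independent strains per transgene, with
discrepancies counted only when observed in two or more strains (the
consistency rule lives in :mod:`credive.divergence`).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from statistics import median
from typing import Iterable, Mapping

import pandas as pd

OBS_COLUMNS = [
    "gene",
    "cre_species",
    "host_species",
    "strain",
    "individual",
    "cell",
    "value",
]

__all__ = [
    "CellDef",
    "CellOntology",
    "Observation",
    "ScoringPolicy",
    "CellSummary",
    "ExpressionSummary",
    "read_observations",
    "write_observations",
    "observations_to_frame",
    "validate_dataset",
    "summarize_transgene",
    "summarize_dataset",
    "summary_frame",
]


@dataclass(frozen=True)
class CellDef:
    """One scorable unit: a binary cell or a counted class."""

    name: str
    mode: str  # "binary" | "counted"
    tissue: str = "neuron"
    n_members: int = 1  # counted classes: number of member cells

    def __post_init__(self):
        if self.mode not in ("binary", "counted"):
            raise ValueError(f"{self.name}: unknown counting mode {self.mode!r}")
        if self.n_members < 1:
            raise ValueError(f"{self.name}: n_members must be >= 1")


@dataclass
class CellOntology:
    """Cells (binary xor counted) plus named groups aggregated as
    "expressed in at least one member"."""

    cells: dict[str, CellDef]
    groups: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self):
        for gname, members in self.groups.items():
            if not members:
                raise ValueError(f"group {gname!r} has no members")
            for m in members:
                if m not in self.cells:
                    raise ValueError(f"group {gname!r} member {m!r} not in ontology")
                if self.cells[m].mode != "binary":
                    raise ValueError(f"group {gname!r} member {m!r} must be binary")

    def mode(self, cell: str) -> str:
        return self.cells[cell].mode

    @property
    def binary_cells(self) -> list[str]:
        return [c for c, d in self.cells.items() if d.mode == "binary"]

    @property
    def counted_cells(self) -> list[str]:
        return [c for c, d in self.cells.items() if d.mode == "counted"]

    @classmethod
    def from_dict(cls, d: Mapping) -> "CellOntology":
        cells = {
            name: CellDef(
                name=name,
                mode=spec.get("mode", "binary"),
                tissue=spec.get("tissue", "neuron"),
                n_members=int(spec.get("n_members", 1)),
            )
            for name, spec in d["cells"].items()
        }
        return cls(cells=cells, groups={g: list(m) for g, m in d.get("groups", {}).items()})

    def to_dict(self) -> dict:
        return {
            "cells": {
                name: {"mode": d.mode, "tissue": d.tissue, "n_members": d.n_members}
                for name, d in self.cells.items()
            },
            "groups": {g: list(m) for g, m in self.groups.items()},
        }

    @classmethod
    def from_json(cls, path) -> "CellOntology":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass(frozen=True)
class Observation:
    """One scored individual-cell datum."""

    gene: str
    cre_species: str
    host_species: str
    strain: str
    individual: str
    cell: str
    value: int  # 0/1 for binary cells, count for counted classes


@dataclass(frozen=True)
class ScoringPolicy:
    min_individuals: int = 50
    min_strains: int = 2
    consistency_min_strains: int = 2
    reference_inclusion_freq: float = 0.5
    strict_loss_max_freq: float = 0.10
    liberal_reduction_ratio: float = 0.5
    gain_min_freq: float = 0.10

    def __post_init__(self):
        for name in (
            "reference_inclusion_freq",
            "strict_loss_max_freq",
            "liberal_reduction_ratio",
            "gain_min_freq",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass(frozen=True)
class CellSummary:
    label: str
    stat: str  # "frequency" | "median"
    value: float
    n: int  # individuals in the denominator
    per_strain: Mapping[str, tuple[float, int]]  # strain -> (value, n)


@dataclass
class ExpressionSummary:
    gene: str
    cre_species: str
    host_species: str
    n_individuals: int
    n_strains: int
    cells: dict[str, CellSummary]

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.gene, self.cre_species, self.host_species)


# ---------------------------------------------------------------------------
# I/O


def observations_to_frame(observations: Iterable[Observation]) -> pd.DataFrame:
    rows = [
        (o.gene, o.cre_species, o.host_species, o.strain, o.individual, o.cell, o.value)
        for o in observations
    ]
    return pd.DataFrame(rows, columns=OBS_COLUMNS)


def write_observations(observations: Iterable[Observation], path) -> None:
    observations_to_frame(observations).to_csv(path, sep="\t", index=False)


def read_observations(path, ontology: CellOntology) -> list[Observation]:
    """Read and validate a scoring-table TSV; errors name the offending line."""
    out: list[Observation] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != OBS_COLUMNS:
            raise ValueError(f"{path}: bad header {header!r}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != len(OBS_COLUMNS):
                raise ValueError(f"{path}:{lineno}: expected {len(OBS_COLUMNS)} fields")
            gene, cre_sp, host_sp, strain, individual, cell, raw = parts
            if cell not in ontology.cells:
                raise ValueError(f"{path}:{lineno}: unknown cell label {cell!r}")
            try:
                value = int(raw)
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-integer value {raw!r}") from None
            if value < 0:
                raise ValueError(f"{path}:{lineno}: negative value")
            if ontology.mode(cell) == "binary" and value not in (0, 1):
                raise ValueError(
                    f"{path}:{lineno}: count {value} on binary cell {cell!r}"
                )
            out.append(
                Observation(gene, cre_sp, host_sp, strain, individual, cell, value)
            )
    return out


# ---------------------------------------------------------------------------
# Validation and summaries


def validate_dataset(
    observations: Iterable[Observation] | pd.DataFrame,
    policy: ScoringPolicy | None = None,
) -> pd.DataFrame:
    """Per-transgene pass/fail against the scoring-policy minima.

    Report-only: columns n_strains, n_individuals, pass_strains,
    pass_individuals, passed.
    """
    policy = policy or ScoringPolicy()
    df = (
        observations
        if isinstance(observations, pd.DataFrame)
        else observations_to_frame(observations)
    )
    if df.empty:
        return pd.DataFrame(
            columns=[
                "gene", "cre_species", "host_species",
                "n_strains", "n_individuals",
                "pass_strains", "pass_individuals", "passed",
            ]
        )
    rows = []
    for (gene, cre_sp, host_sp), sub in df.groupby(
        ["gene", "cre_species", "host_species"], sort=True
    ):
        n_strains = sub["strain"].nunique()
        n_ind = sub.groupby("strain")["individual"].nunique().sum()
        ok_s = n_strains >= policy.min_strains
        ok_i = n_ind >= policy.min_individuals
        rows.append((gene, cre_sp, host_sp, n_strains, int(n_ind), ok_s, ok_i, ok_s and ok_i))
    return pd.DataFrame(
        rows,
        columns=[
            "gene", "cre_species", "host_species",
            "n_strains", "n_individuals",
            "pass_strains", "pass_individuals", "passed",
        ],
    )


def _drop_gfp_negative(df: pd.DataFrame) -> pd.DataFrame:
    # individuals with no expression anywhere are assumed to have lost the
    # extrachromosomal transgene and are excluded from scoring
    totals = df.groupby(["strain", "individual"])["value"].transform("sum")
    return df[totals > 0]


def summarize_transgene(
    observations: Iterable[Observation] | pd.DataFrame,
    ontology: CellOntology,
    drop_negative: bool = True,
) -> ExpressionSummary:
    """Summarize one transgene's scoring rows.

    Binary cell frequency = expressing individuals / individuals scored for
    that cell (missing rows drop out of the denominator).  Group frequency
    counts an individual once if any member cell expresses.  Counted classes
    are summarized by the median count over scored individuals.
    """
    df = (
        observations.copy()
        if isinstance(observations, pd.DataFrame)
        else observations_to_frame(observations)
    )
    if df.empty:
        raise ValueError("no observations for transgene")
    keys = df[["gene", "cre_species", "host_species"]].drop_duplicates()
    if len(keys) != 1:
        raise ValueError("summarize_transgene expects rows from a single transgene")
    gene, cre_sp, host_sp = keys.iloc[0]
    if drop_negative:
        df = _drop_gfp_negative(df)
        if df.empty:
            raise ValueError("all individuals GFP-negative")

    strains = sorted(df["strain"].unique())
    n_individuals = int(df.groupby("strain")["individual"].nunique().sum())

    cells: dict[str, CellSummary] = {}

    def freq_and_n(sub: pd.DataFrame) -> tuple[float, int]:
        per_ind = sub.groupby(["strain", "individual"])["value"].max()
        n = len(per_ind)
        return (float((per_ind > 0).mean()) if n else float("nan"), n)

    for cell in ontology.binary_cells:
        sub = df[df["cell"] == cell]
        if sub.empty:
            continue  # unscored cell: excluded from downstream calls
        value, n = freq_and_n(sub)
        per_strain = {}
        for strain in strains:
            ssub = sub[sub["strain"] == strain]
            if not ssub.empty:
                per_strain[strain] = freq_and_n(ssub)
        cells[cell] = CellSummary(cell, "frequency", value, n, per_strain)

    for gname, members in ontology.groups.items():
        sub = df[df["cell"].isin(members)]
        if sub.empty:
            continue
        value, n = freq_and_n(sub)
        per_strain = {}
        for strain in strains:
            ssub = sub[sub["strain"] == strain]
            if not ssub.empty:
                per_strain[strain] = freq_and_n(ssub)
        cells[gname] = CellSummary(gname, "frequency", value, n, per_strain)

    for cell in ontology.counted_cells:
        sub = df[df["cell"] == cell]
        if sub.empty:
            continue
        per_ind = sub.groupby(["strain", "individual"])["value"].sum()
        value = float(median(per_ind.tolist()))
        per_strain = {}
        for strain in strains:
            vals = per_ind.loc[strain].tolist() if strain in per_ind.index.get_level_values(0) else []
            if vals:
                per_strain[strain] = (float(median(vals)), len(vals))
        cells[cell] = CellSummary(cell, "median", value, len(per_ind), per_strain)

    return ExpressionSummary(
        gene=gene,
        cre_species=cre_sp,
        host_species=host_sp,
        n_individuals=n_individuals,
        n_strains=len(strains),
        cells=cells,
    )


def summarize_dataset(
    observations: Iterable[Observation] | pd.DataFrame,
    ontology: CellOntology,
    drop_negative: bool = True,
) -> dict[tuple[str, str, str], ExpressionSummary]:
    """Summaries for every transgene in a dataset, keyed by
    (gene, cre_species, host_species)."""
    df = (
        observations
        if isinstance(observations, pd.DataFrame)
        else observations_to_frame(observations)
    )
    out = {}
    for key, sub in df.groupby(["gene", "cre_species", "host_species"], sort=True):
        out[key] = summarize_transgene(sub, ontology, drop_negative=drop_negative)
    return out


def summary_frame(summaries: Mapping | ExpressionSummary) -> pd.DataFrame:
    """Flatten summaries to one row per (transgene, cell/group/class)."""
    if isinstance(summaries, ExpressionSummary):
        summaries = {summaries.key: summaries}
    rows = []
    for s in summaries.values():
        for label, cs in sorted(s.cells.items()):
            per_strain = ";".join(
                f"{strain}={val:.4f}/{n}" for strain, (val, n) in sorted(cs.per_strain.items())
            )
            rows.append(
                (s.gene, s.cre_species, s.host_species, label, cs.stat, cs.value, cs.n, per_strain)
            )
    return pd.DataFrame(
        rows,
        columns=[
            "gene", "cre_species", "host_species",
            "label", "stat", "value", "n", "per_strain",
        ],
    )
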