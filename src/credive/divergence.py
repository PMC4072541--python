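"""Gain/loss classification of heterologous CRE expression patterns.

Each heterologous transgene (a CRE from another species assayed in the
*C. elegans* trans-regulatory environment) is compared cell-by-cell against
the reference pattern driven by the *C. elegans* ortholog:

* a cell in the reference pattern is a strict "loss" when its observed
  frequency falls to at most ``strict_loss_max_freq``, a "reduction" when it
  drops below ``liberal_reduction_ratio`` times the reference frequency, and
  "conserved" otherwise;
* a scored cell outside the reference pattern is a "gain" (ectopic
  expression) when its observed frequency reaches ``gain_min_freq``;
* counted classes are compared on medians: a zero median is a strict loss, a
  median below the reduction ratio of the reference median is a reduction.

To stay conservative about extrachromosomal-array artifacts, any
non-conserved call must be supported by the discrepancy in at least
``consistency_min_strains`` independent strains, otherwise it is demoted
(to conserved) and flagged.  "Gain" and "loss" are labels relative to the
reference-species CRE pattern, not claims about endogenous expression.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .expression import ExpressionSummary, ScoringPolicy

CALLS = ("conserved", "gain", "loss_strict", "reduction", "unscored")

__all__ = [
    "ReferenceEntry",
    "ReferencePattern",
    "DivergenceCall",
    "TallyReport",
    "SweepCurve",
    "build_reference_pattern",
    "classify_transgene",
    "tally",
    "sweep_curve",
    "recurrent_gains",
    "calls_to_frame",
]


@dataclass(frozen=True)
class ReferenceEntry:
    label: str
    stat: str  # "frequency" | "median"
    in_pattern: bool
    ref_value: float
    n: int
    override: str | None = None  # "include" | "exclude" | None


@dataclass
class ReferencePattern:
    """The set of cells/groups/classes the reference-species CRE reliably
    drives, with reference frequencies/medians."""

    gene: str
    entries: dict[str, ReferenceEntry]

    @property
    def in_pattern_labels(self) -> list[str]:
        return [k for k, e in self.entries.items() if e.in_pattern]

    @property
    def complexity(self) -> int:
        """Number of endogenously expressing cell types."""
        return len(self.in_pattern_labels)


@dataclass(frozen=True)
class DivergenceCall:
    gene: str
    cre_species: str
    host_species: str
    label: str
    stat: str
    call: str  # one of CALLS
    ref_value: float
    obs_value: float
    n_strains_supporting: int
    in_reference_pattern: bool = False
    demoted: bool = False
    note: str = ""

    def __post_init__(self):
        if self.call not in CALLS:
            raise ValueError(f"unknown call {self.call!r}")


@dataclass
class TallyReport:
    n_gains: int
    n_losses_strict: int
    n_losses_liberal: int  # strict + reductions
    per_transgene: pd.DataFrame
    per_species: pd.DataFrame
    calls: list[DivergenceCall] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "n_gains": self.n_gains,
            "n_losses_strict": self.n_losses_strict,
            "n_losses_liberal": self.n_losses_liberal,
            "per_transgene": self.per_transgene.to_dict(orient="records"),
            "per_species": self.per_species.to_dict(orient="records"),
        }


@dataclass
class SweepCurve:
    """Sorted gain/loss event frequencies and per-threshold counts.

    Loss frequency of an endogenous-pattern cell is the frequency of
    individuals *not* expressing it (1 - observed frequency); gain frequency
    of a non-endogenous cell is its observed frequency.  Counted classes are
    excluded (their medians are not frequencies).
    """

    gain_freqs: np.ndarray  # sorted descending
    loss_freqs: np.ndarray  # sorted descending
    thresholds: np.ndarray
    n_gains_above: np.ndarray
    n_losses_above: np.ndarray
    dominant: bool  # gains >= losses at every threshold < 100%

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold": self.thresholds,
                "n_gains": self.n_gains_above,
                "n_losses": self.n_losses_above,
            }
        )


# ---------------------------------------------------------------------------


def build_reference_pattern(
    summary: ExpressionSummary,
    policy: ScoringPolicy | None = None,
    overrides: Sequence[Mapping] | None = None,
) -> ReferencePattern:
    """Derive the reference pattern from the reference-species transgene.

    Binary cells/groups join the pattern at frequency >=
    ``reference_inclusion_freq``; counted classes at median > 0.  Explicit
    include/exclude overrides (declarative judgment calls) are applied last
    and recorded on the entry.
    """
    policy = policy or ScoringPolicy()
    over = {
        (o["cell"]): o["action"]
        for o in (overrides or [])
        if o.get("gene") in (None, summary.gene)
    }
    entries: dict[str, ReferenceEntry] = {}
    for label, cs in summary.cells.items():
        if cs.stat == "frequency":
            in_pat = cs.value >= policy.reference_inclusion_freq
        else:
            in_pat = cs.value > 0
        applied = None
        if over.get(label) == "include":
            in_pat, applied = True, "include"
        elif over.get(label) == "exclude":
            in_pat, applied = False, "exclude"
        entries[label] = ReferenceEntry(
            label=label,
            stat=cs.stat,
            in_pattern=in_pat,
            ref_value=cs.value,
            n=cs.n,
            override=applied,
        )
    return ReferencePattern(gene=summary.gene, entries=entries)


def _strains_supporting(per_strain, predicate) -> int:
    return sum(1 for val, n in per_strain.values() if n > 0 and predicate(val))


def classify_transgene(
    summary: ExpressionSummary,
    reference: ReferencePattern,
    policy: ScoringPolicy | None = None,
) -> list[DivergenceCall]:
    """Classify every scored cell of a heterologous transgene against the
    reference pattern.  See the module docstring for the rules."""
    policy = policy or ScoringPolicy()
    if summary.gene != reference.gene:
        raise ValueError(
            f"gene mismatch: summary {summary.gene!r} vs reference {reference.gene!r}"
        )
    calls: list[DivergenceCall] = []
    labels = sorted(set(reference.entries) | set(summary.cells))
    for label in labels:
        ref_entry = reference.entries.get(label)
        cs = summary.cells.get(label)
        in_pattern = ref_entry.in_pattern if ref_entry is not None else False
        ref_value = ref_entry.ref_value if ref_entry is not None else 0.0

        if cs is None or cs.n == 0 or math.isnan(cs.value):
            if in_pattern:
                calls.append(
                    DivergenceCall(
                        summary.gene, summary.cre_species, summary.host_species,
                        label, ref_entry.stat if ref_entry else "frequency",
                        "unscored", ref_value, float("nan"), 0,
                        in_reference_pattern=True,
                        note="no scored individuals",
                    )
                )
            continue

        stat = cs.stat
        obs = cs.value
        call = "conserved"
        support = 0
        demoted = False
        note = ""

        if in_pattern:
            if stat == "frequency":
                if obs <= policy.strict_loss_max_freq:
                    call = "loss_strict"
                    support = _strains_supporting(
                        cs.per_strain, lambda v: v <= policy.strict_loss_max_freq
                    )
                elif obs < policy.liberal_reduction_ratio * ref_value:
                    call = "reduction"
                    support = _strains_supporting(
                        cs.per_strain,
                        lambda v: v < policy.liberal_reduction_ratio * ref_value,
                    )
            else:  # counted class, compare medians
                if obs == 0:
                    call = "loss_strict"
                    support = _strains_supporting(cs.per_strain, lambda v: v == 0)
                elif obs < policy.liberal_reduction_ratio * ref_value:
                    call = "reduction"
                    support = _strains_supporting(
                        cs.per_strain,
                        lambda v: v < policy.liberal_reduction_ratio * ref_value,
                    )
        else:
            if stat == "frequency":
                if obs >= policy.gain_min_freq:
                    call = "gain"
                    support = _strains_supporting(cs.per_strain, lambda v: v > 0)
            else:
                if obs > 0:
                    call = "gain"
                    support = _strains_supporting(cs.per_strain, lambda v: v > 0)

        if call != "conserved" and support < policy.consistency_min_strains:
            note = f"demoted {call}: seen in {support} strain(s)"
            call = "conserved"
            demoted = True

        calls.append(
            DivergenceCall(
                summary.gene, summary.cre_species, summary.host_species,
                label, stat, call, ref_value, obs, support,
                in_reference_pattern=in_pattern, demoted=demoted, note=note,
            )
        )
    return calls


def calls_to_frame(calls: Iterable[DivergenceCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (
                c.gene, c.cre_species, c.host_species, c.label, c.stat,
                c.call, c.ref_value, c.obs_value, c.n_strains_supporting,
                c.in_reference_pattern, c.demoted, c.note,
            )
            for c in calls
        ],
        columns=[
            "gene", "cre_species", "host_species", "label", "stat",
            "call", "ref_value", "obs_value", "n_strains_supporting",
            "in_reference_pattern", "demoted", "note",
        ],
    )


def tally(
    calls: Sequence[DivergenceCall],
    gene_universe: Sequence[str] | None = None,
    species_universe: Sequence[str] | None = None,
) -> TallyReport:
    """Count gains / strict losses / liberal losses (strict + reductions)
    per transgene, per CRE species and overall, optionally restricted to a
    gene and/or species subset (e.g. genes tested from all four
    non-reference species)."""
    kept = [
        c
        for c in calls
        if (gene_universe is None or c.gene in gene_universe)
        and (species_universe is None or c.cre_species in species_universe)
    ]
    rows = []
    by_transgene: dict[tuple[str, str], dict[str, int]] = {}
    for c in kept:
        key = (c.gene, c.cre_species)
        d = by_transgene.setdefault(key, {"gain": 0, "loss_strict": 0, "reduction": 0})
        if c.call in d:
            d[c.call] += 1
    for (gene, sp), d in sorted(by_transgene.items()):
        rows.append(
            (
                gene, sp, d["gain"], d["loss_strict"],
                d["loss_strict"] + d["reduction"],
            )
        )
    per_transgene = pd.DataFrame(
        rows,
        columns=["gene", "cre_species", "n_gains", "n_losses_strict", "n_losses_liberal"],
    )
    if per_transgene.empty:
        per_species = pd.DataFrame(
            columns=["cre_species", "n_gains", "n_losses_strict", "n_losses_liberal"]
        )
        totals = (0, 0, 0)
    else:
        per_species = (
            per_transgene.groupby("cre_species", as_index=False)[
                ["n_gains", "n_losses_strict", "n_losses_liberal"]
            ].sum()
        )
        totals = (
            int(per_transgene["n_gains"].sum()),
            int(per_transgene["n_losses_strict"].sum()),
            int(per_transgene["n_losses_liberal"].sum()),
        )
    return TallyReport(
        n_gains=totals[0],
        n_losses_strict=totals[1],
        n_losses_liberal=totals[2],
        per_transgene=per_transgene,
        per_species=per_species,
        calls=list(kept),
    )


def sweep_curve(
    calls: Sequence[DivergenceCall],
    n_thresholds: int = 100,
) -> SweepCurve:
    """Threshold-sweep of called gain and loss event frequencies.

    Each called gain contributes its observed frequency; each called loss or
    reduction contributes the frequency of endogenous-pattern cells *not*
    expressing (1 - observed frequency).  Re-counting both sides at every
    threshold shows whether gains outnumber losses independent of the policy
    cutoffs.  Dominance (#gains >= #losses strictly above t for every t in
    [0, 1)) is evaluated exactly at every breakpoint, not just on the
    reporting grid.
    """
    gains: list[float] = []
    losses: list[float] = []
    for c in calls:
        if c.stat != "frequency" or math.isnan(c.obs_value):
            continue  # counted classes (medians) never enter the sweep
        if c.call == "gain":
            gains.append(c.obs_value)
        elif c.call in ("loss_strict", "reduction"):
            losses.append(1.0 - c.obs_value)
    gain_arr = np.sort(np.array(gains, dtype=float))[::-1]
    loss_arr = np.sort(np.array(losses, dtype=float))[::-1]

    thresholds = np.linspace(0.0, 1.0, n_thresholds, endpoint=False)
    n_gains_above = np.array([(gain_arr > t).sum() for t in thresholds])
    n_losses_above = np.array([(loss_arr > t).sum() for t in thresholds])

    breakpoints = np.unique(np.concatenate(([0.0], gain_arr, loss_arr)))
    breakpoints = breakpoints[breakpoints < 1.0]
    dominant = all(
        (gain_arr > t).sum() >= (loss_arr > t).sum() for t in breakpoints
    )
    return SweepCurve(
        gain_freqs=gain_arr,
        loss_freqs=loss_arr,
        thresholds=thresholds,
        n_gains_above=n_gains_above,
        n_losses_above=n_losses_above,
        dominant=bool(dominant),
    )


def recurrent_gains(
    calls: Sequence[DivergenceCall],
) -> list[tuple[str, list[tuple[str, str]]]]:
    """Cells gaining expression from >= 2 distinct (gene, species) CREs,
    sorted by decreasing support (ties alphabetically)."""
    by_cell: dict[str, set[tuple[str, str]]] = {}
    for c in calls:
        if c.call == "gain":
            by_cell.setdefault(c.label, set()).add((c.gene, c.cre_species))
    out = [
        (label, sorted(supp))
        for label, supp in by_cell.items()
        if len(supp) >= 2
    ]
    out.sort(key=lambda item: (-len(item[1]), item[0]))
    return out


def write_tally_json(report: TallyReport, path) -> None:
    with open(path, "w") as fh:
        json.dump(report.as_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
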