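"""Synthetic ortholog families and reporter-expression datasets.

Ground-truth generators emulating the statistical structure the analysis
assumes, so the whole pipeline runs with no external data:

* ortholog CRE families: several species' upstream regions derived from a
  common ancestor by per-site substitution (uniform over the three
  alternative bases, Jukes–Cantor-like per branch) and geometric-length
  indels, with planted low-divergence blocks embedded in the background —
  the "blocks of high similarity" a conservation profile should recover.
  Indels never land inside planted blocks, which model constrained
  elements, so a zero-divergence planted block is exactly identical across
  species.
* reporter-expression datasets: per transgene, per strain, per individual,
  one Bernoulli draw per binary cell at that transgene's cell probability
  (the reference pattern modified by planted gain/loss/reduction events)
  and one binomial draw over member cells per counted class.  Optional
  strain-private artifacts (expression confined to a single strain) probe
  the >= 2-strain consistency rule.

Adequacy for testing, not molecular realism, is the goal.  All randomness
derives from a single integer seed per config.
"""

from __future__ import annotations

import json
from bisect import bisect_right
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .expression import CellDef, CellOntology, Observation, write_observations
from .seqcons import SequenceRecord, write_fasta

BASES = "ACGT"

__all__ = [
    "SpeciesBranch",
    "PlantedBlock",
    "OrthologFamilyConfig",
    "PlantedEvent",
    "ExpressionSimConfig",
    "SimTruth",
    "simulate_ortholog_family",
    "simulate_expression_dataset",
    "write_fixtures",
    "study_ontology",
    "study_cohort",
]


@dataclass(frozen=True)
class SpeciesBranch:
    name: str
    substitution_prob: float = 0.0  # per-site, on this branch
    indel_rate: float = 0.0  # per-site probability of starting an indel

    def __post_init__(self):
        if not 0 <= self.substitution_prob <= 1:
            raise ValueError(f"{self.name}: substitution_prob outside [0, 1]")
        if not 0 <= self.indel_rate <= 1:
            raise ValueError(f"{self.name}: indel_rate outside [0, 1]")


@dataclass(frozen=True)
class PlantedBlock:
    ancestor_start: int
    length: int
    substitution_prob: float = 0.0

    @property
    def ancestor_end(self) -> int:
        return self.ancestor_start + self.length


@dataclass
class OrthologFamilyConfig:
    gene_id: str
    ancestor_length: int
    species: list[SpeciesBranch]
    planted_blocks: list[PlantedBlock] = field(default_factory=list)
    indel_mean_len: float = 3.0
    seed: int = 0

    def __post_init__(self):
        if self.ancestor_length < 1:
            raise ValueError("ancestor_length must be positive")
        if not self.species:
            raise ValueError("at least one species required")
        blocks = sorted(self.planted_blocks, key=lambda b: b.ancestor_start)
        prev_end = 0
        min_bg = min(b.substitution_prob for b in self.species)
        for b in blocks:
            if b.length < 1:
                raise ValueError("planted block length must be positive")
            if b.ancestor_start < prev_end:
                raise ValueError("planted blocks overlap")
            if b.ancestor_end > self.ancestor_length:
                raise ValueError("planted block outside ancestor")
            if b.substitution_prob > min_bg:
                raise ValueError(
                    "block_substitution_prob exceeds background substitution probability"
                )
            prev_end = b.ancestor_end
        self.planted_blocks = blocks


@dataclass(frozen=True)
class PlantedEvent:
    cell: str
    event: str  # "gain" | "loss" | "reduction" | "artifact"
    probability: float
    strain: str | None = None  # artifacts only

    def __post_init__(self):
        if self.event not in ("gain", "loss", "reduction", "artifact"):
            raise ValueError(f"unknown event {self.event!r}")
        if not 0 <= self.probability <= 1:
            raise ValueError("event probability outside [0, 1]")


@dataclass
class ExpressionSimConfig:
    gene_id: str
    ontology: CellOntology
    reference_pattern: dict[str, float]  # cell -> expression probability
    per_species_edits: dict[str, list[PlantedEvent]] = field(default_factory=dict)
    reference_species: str = "C_elegans"
    host_species: str = "C_elegans"
    n_strains: int = 2
    n_individuals_per_strain: int = 25
    strain_noise: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_strains < 2:
            raise ValueError("n_strains must be >= 2")
        if self.n_strains * self.n_individuals_per_strain < 50:
            raise ValueError("need at least 50 individuals across strains")
        if not 0 <= self.strain_noise <= 1:
            raise ValueError("strain_noise outside [0, 1]")
        for cell, p in self.reference_pattern.items():
            if cell not in self.ontology.cells:
                raise ValueError(f"reference pattern cell {cell!r} not in ontology")
            if not 0 <= p <= 1:
                raise ValueError(f"probability for {cell!r} outside [0, 1]")
        for sp, events in self.per_species_edits.items():
            for ev in events:
                if ev.cell not in self.ontology.cells:
                    raise ValueError(
                        f"{sp}: event cell {ev.cell!r} not in ontology"
                    )


@dataclass
class SimTruth:
    """Ground truth of a simulation: realized planted-block intervals per
    species (0-based half-open, in that species' coordinates) and planted
    expression events per transgene."""

    planted_blocks: dict[str, list[tuple[int, int]]] = field(default_factory=dict)
    planted_events: dict[tuple[str, str], list[PlantedEvent]] = field(default_factory=dict)

    def merge(self, other: "SimTruth") -> "SimTruth":
        merged = SimTruth(
            planted_blocks={**self.planted_blocks, **other.planted_blocks},
            planted_events={**self.planted_events, **other.planted_events},
        )
        return merged

    def to_dict(self) -> dict:
        return {
            "planted_blocks": {
                sp: [list(iv) for iv in ivs] for sp, ivs in self.planted_blocks.items()
            },
            "planted_events": {
                f"{gene}|{sp}": [
                    {
                        "cell": ev.cell,
                        "event": ev.event,
                        "probability": ev.probability,
                        "strain": ev.strain,
                    }
                    for ev in evs
                ]
                for (gene, sp), evs in self.planted_events.items()
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SimTruth":
        return cls(
            planted_blocks={
                sp: [tuple(iv) for iv in ivs]
                for sp, ivs in d.get("planted_blocks", {}).items()
            },
            planted_events={
                tuple(key.split("|", 1)): [
                    PlantedEvent(
                        cell=ev["cell"],
                        event=ev["event"],
                        probability=ev["probability"],
                        strain=ev.get("strain"),
                    )
                    for ev in evs
                ]
                for key, evs in d.get("planted_events", {}).items()
            },
        )


# ---------------------------------------------------------------------------
# Sequence simulation


def simulate_ortholog_family(
    cfg: OrthologFamilyConfig,
) -> tuple[dict[str, SequenceRecord], SimTruth]:
    """Evolve one ancestor into one DNA record per species.

    Per-site substitutions replace a base with one of the three alternatives
    uniformly; indels start at ``indel_rate`` per site outside planted
    blocks, equiprobably an insertion or a deletion, with geometric length
    of mean ``indel_mean_len``.  Deletions truncate at the next planted
    block.  The returned truth maps each species to the realized interval of
    every planted block in that species' own coordinates.
    """
    rng = np.random.default_rng(cfg.seed)
    L = cfg.ancestor_length
    ancestor = rng.integers(0, 4, size=L)
    block_at = {b.ancestor_start: b for b in cfg.planted_blocks}
    block_starts = [b.ancestor_start for b in cfg.planted_blocks]

    geom_p = 1.0 / max(cfg.indel_mean_len, 1.0)
    records: dict[str, SequenceRecord] = {}
    truth = SimTruth()

    for branch in cfg.species:
        out: list[int] = []
        intervals: list[tuple[int, int]] = []
        i = 0
        while i < L:
            block = block_at.get(i)
            if block is not None:
                start_out = len(out)
                for k in range(block.length):
                    c = int(ancestor[i + k])
                    if block.substitution_prob > 0 and rng.random() < block.substitution_prob:
                        c = (c + 1 + int(rng.integers(0, 3))) % 4
                    out.append(c)
                intervals.append((start_out, len(out)))
                i += block.length
                continue
            if branch.indel_rate > 0 and rng.random() < branch.indel_rate:
                length = int(rng.geometric(geom_p))
                if rng.random() < 0.5:  # insertion before this site
                    out.extend(int(x) for x in rng.integers(0, 4, size=length))
                else:  # deletion, stopping short of the next planted block
                    nxt = bisect_right(block_starts, i)
                    limit = (
                        block_starts[nxt] - i if nxt < len(block_starts) else L - i
                    )
                    i += min(length, limit)
                    continue
            c = int(ancestor[i])
            if branch.substitution_prob > 0 and rng.random() < branch.substitution_prob:
                c = (c + 1 + int(rng.integers(0, 3))) % 4
            out.append(c)
            i += 1
        residues = "".join(BASES[c] for c in out)
        records[branch.name] = SequenceRecord(
            id=f"{cfg.gene_id}|{branch.name}",
            species=branch.name,
            gene=cfg.gene_id,
            alphabet="dna",
            residues=residues,
        )
        truth.planted_blocks[branch.name] = intervals
    return records, truth


# ---------------------------------------------------------------------------
# Expression simulation


def _effective_probs(cfg: ExpressionSimConfig, species: str) -> dict[str, float]:
    probs = {c: 0.0 for c in cfg.ontology.cells}
    probs.update(cfg.reference_pattern)
    for ev in cfg.per_species_edits.get(species, []):
        if ev.event == "gain":
            probs[ev.cell] = ev.probability
        elif ev.event == "loss":
            probs[ev.cell] = ev.probability  # typically 0
        elif ev.event == "reduction":
            probs[ev.cell] = ev.probability
    return probs


def simulate_expression_dataset(
    cfg: ExpressionSimConfig,
) -> tuple[list[Observation], SimTruth]:
    """Simulate scoring tables for one gene: the reference-species transgene
    plus one transgene per edited species, each scored over
    ``n_strains`` x ``n_individuals_per_strain`` individuals.

    With ``strain_noise`` > 0 one silent binary cell per heterologous
    transgene expresses at that rate in exactly one strain (a strain-private
    artifact); the artifact is recorded in the truth so the consistency
    filter can be audited against it.
    """
    rng = np.random.default_rng(cfg.seed)
    species_list = [cfg.reference_species] + sorted(cfg.per_species_edits)
    observations: list[Observation] = []
    truth = SimTruth()

    for species in species_list:
        probs = _effective_probs(cfg, species)
        events = list(cfg.per_species_edits.get(species, []))

        artifact_cell = None
        artifact_strain = None
        if cfg.strain_noise > 0 and species != cfg.reference_species:
            silent = [
                c
                for c in cfg.ontology.binary_cells
                if probs.get(c, 0.0) == 0.0
                and cfg.reference_pattern.get(c, 0.0) == 0.0
            ]
            if silent:
                artifact_cell = silent[int(rng.integers(0, len(silent)))]
                artifact_strain = int(rng.integers(0, cfg.n_strains))

        for s in range(cfg.n_strains):
            strain = f"{cfg.gene_id}_{species}_st{s + 1}"
            if artifact_cell is not None and s == artifact_strain:
                events = events + [
                    PlantedEvent(
                        cell=artifact_cell,
                        event="artifact",
                        probability=cfg.strain_noise,
                        strain=strain,
                    )
                ]
            for k in range(cfg.n_individuals_per_strain):
                individual = f"ind{k + 1:03d}"
                for cell, cdef in cfg.ontology.cells.items():
                    p = probs.get(cell, 0.0)
                    if (
                        artifact_cell is not None
                        and cell == artifact_cell
                        and s == artifact_strain
                    ):
                        p = cfg.strain_noise
                    if cdef.mode == "binary":
                        value = int(rng.random() < p)
                    else:
                        value = int(rng.binomial(cdef.n_members, p))
                    observations.append(
                        Observation(
                            gene=cfg.gene_id,
                            cre_species=species,
                            host_species=cfg.host_species,
                            strain=strain,
                            individual=individual,
                            cell=cell,
                            value=value,
                        )
                    )
        truth.planted_events[(cfg.gene_id, species)] = events
    return observations, truth


# ---------------------------------------------------------------------------
# Fixture bundles


def write_fixtures(
    families: dict[str, dict[str, SequenceRecord]],
    observations: list[Observation],
    truth: SimTruth,
    out_dir,
    ontology: CellOntology | None = None,
) -> list[Path]:
    """Write a self-contained fixture bundle: one FASTA per gene, a single
    observations TSV, truth and ontology JSON.  Returns the paths written."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for gene, records in sorted(families.items()):
        path = out_dir / f"{gene}.fasta"
        write_fasta(records.values(), path)
        written.append(path)
    obs_path = out_dir / "observations.tsv"
    write_observations(observations, obs_path)
    written.append(obs_path)
    truth_path = out_dir / "truth.json"
    with open(truth_path, "w") as fh:
        json.dump(truth.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    written.append(truth_path)
    if ontology is not None:
        onto_path = out_dir / "ontology.json"
        with open(onto_path, "w") as fh:
            json.dump(ontology.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")
        written.append(onto_path)
    return written


# ---------------------------------------------------------------------------
# The default study-shaped cohort


#: shared single-cell ontology used by the default cohort: a pool of
#: identified neurons/tissues, two bilateral groups and one counted class,
#: mirroring the structure (not the identities) of the survey's scoring units
_STUDY_CELLS = [
    "AVAL", "AVAR", "RMED", "RMEV", "RIS", "DVB", "AWAL", "AWAR",
    "CEPDL", "CEPDR", "PVNL", "PVNR", "ADEL", "PDEL", "head_muscle",
    "hypodermis", "gonadal_sheath", "intestine",
]
_STUDY_GROUPS = {
    "HSNs": ["HSNL", "HSNR"],
    "SDQs": ["SDQL", "SDQR"],
}


def study_ontology() -> CellOntology:
    cells = {name: CellDef(name=name, mode="binary") for name in _STUDY_CELLS}
    for members in _STUDY_GROUPS.values():
        for m in members:
            cells[m] = CellDef(name=m, mode="binary")
    cells["VNC"] = CellDef(name="VNC", mode="counted", n_members=12)
    return CellOntology(cells=cells, groups=dict(_STUDY_GROUPS))


def study_cohort(
    seed: int = 0,
    n_genes: int = 8,
    het_species: tuple[str, ...] = ("C_briggsae", "C_remanei", "C_brenneri", "C_japonica"),
    n_strains: int = 2,
    n_individuals_per_strain: int = 25,
    n_gains: int = 44,
    n_losses: int = 12,
    n_reductions: int = 4,
    ref_prob: float = 0.9,
    gain_prob: float = 0.8,
    reduction_prob: float = 0.25,
    strain_noise: float = 0.0,
    ancestor_length: int = 400,
    background_sub: float = 0.2,
    indel_rate: float = 0.02,
) -> tuple[
    dict[str, dict[str, SequenceRecord]],
    list[Observation],
    SimTruth,
    CellOntology,
    list[ExpressionSimConfig],
]:
    """Build a full survey-shaped cohort with known ground truth.

    Defaults mirror the study design: 8 genes x (reference + 4 heterologous
    species), scored over 2 strains x 25 individuals per transgene, with 44
    planted gains, 12 strict losses and 4 reductions spread over the
    heterologous transgenes (liberal losses therefore 16), reference cells
    expressing at 0.9, gains at 0.8 and reductions at 0.25.  Sequence
    families carry two planted conserved blocks per gene in a moderately
    diverged background.
    """
    rng = np.random.default_rng(seed)
    ontology = study_ontology()
    genes = [f"gene{g + 1:02d}" for g in range(n_genes)]
    binary = ontology.binary_cells
    group_members = {m for ms in _STUDY_GROUPS.values() for m in ms}
    pool = [c for c in binary if c not in group_members]

    # per-gene reference patterns: 4 binary cells + one bilateral group,
    # counted VNC class for every other gene
    ref_patterns: dict[str, dict[str, float]] = {}
    for gi, gene in enumerate(genes):
        cells = list(rng.choice(pool, size=4, replace=False))
        pattern = {c: ref_prob for c in cells}
        gname = list(_STUDY_GROUPS)[gi % len(_STUDY_GROUPS)]
        for m in _STUDY_GROUPS[gname]:
            pattern[m] = ref_prob
        if gi % 2 == 0:
            pattern["VNC"] = ref_prob
        ref_patterns[gene] = pattern

    # distribute planted events over heterologous transgenes
    transgenes = [(g, sp) for g in genes for sp in het_species]
    edits: dict[tuple[str, str], list[PlantedEvent]] = {t: [] for t in transgenes}

    def plant(event: str, count: int):
        for _ in range(count):
            for _attempt in range(1000):
                g, sp = transgenes[int(rng.integers(0, len(transgenes)))]
                pattern = ref_patterns[g]
                taken = {ev.cell for ev in edits[(g, sp)]}
                if event == "gain":
                    candidates = [
                        c for c in pool if c not in pattern and c not in taken
                    ]
                    if not candidates:
                        continue
                    cell = candidates[int(rng.integers(0, len(candidates)))]
                    edits[(g, sp)].append(PlantedEvent(cell, "gain", gain_prob))
                else:
                    candidates = [
                        c
                        for c in pattern
                        if c not in taken and ontology.cells[c].mode == "binary"
                        and c not in group_members
                    ]
                    if not candidates:
                        continue
                    cell = candidates[int(rng.integers(0, len(candidates)))]
                    prob = 0.0 if event == "loss" else reduction_prob
                    edits[(g, sp)].append(PlantedEvent(cell, event, prob))
                break
            else:  # pragma: no cover - would need a saturated cohort
                raise RuntimeError(f"could not place planted {event}")

    plant("gain", n_gains)
    plant("loss", n_losses)
    plant("reduction", n_reductions)

    families: dict[str, dict[str, SequenceRecord]] = {}
    observations: list[Observation] = []
    truth = SimTruth()
    configs: list[ExpressionSimConfig] = []
    all_species = ["C_elegans", *het_species]

    for gene in genes:
        fam_seed = int(rng.integers(0, 2**31 - 1))
        b1 = int(rng.integers(20, ancestor_length // 2 - 70))
        b2 = int(rng.integers(ancestor_length // 2 + 10, ancestor_length - 50))
        fam_cfg = OrthologFamilyConfig(
            gene_id=gene,
            ancestor_length=ancestor_length,
            species=[
                SpeciesBranch(
                    sp,
                    substitution_prob=0.0 if sp == "C_elegans" else background_sub,
                    indel_rate=0.0 if sp == "C_elegans" else indel_rate,
                )
                for sp in all_species
            ],
            planted_blocks=[
                PlantedBlock(b1, 50, 0.0),
                PlantedBlock(b2, 30, 0.0),
            ],
            seed=fam_seed,
        )
        records, fam_truth = simulate_ortholog_family(fam_cfg)
        families[gene] = records
        truth.planted_blocks.update(
            {f"{gene}|{sp}": ivs for sp, ivs in fam_truth.planted_blocks.items()}
        )

        expr_cfg = ExpressionSimConfig(
            gene_id=gene,
            ontology=ontology,
            reference_pattern=ref_patterns[gene],
            per_species_edits={
                sp: edits[(gene, sp)] for sp in het_species
            },
            n_strains=n_strains,
            n_individuals_per_strain=n_individuals_per_strain,
            strain_noise=strain_noise,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        obs, expr_truth = simulate_expression_dataset(expr_cfg)
        observations.extend(obs)
        truth.planted_events.update(expr_truth.planted_events)
        configs.append(expr_cfg)

    return families, observations, truth, ontology, configs
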