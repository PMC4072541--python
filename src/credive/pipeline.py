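"""End-to-end orchestration: simulate -> conserve -> summarize -> classify
-> correlate, with a run manifest for reproducibility.

Every stage is a plain function over the library modules so stages are
independently callable (and independently testable).  Identical config and
seed produce byte-identical output bundles: no timestamps enter any
artifact, and all randomness flows from the config seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .correlate import divergence_metrics, panel_frames, rank_correlation
from .divergence import (
    DivergenceCall,
    build_reference_pattern,
    calls_to_frame,
    classify_transgene,
    recurrent_gains,
    sweep_curve,
    tally,
    write_tally_json,
)
from .expression import (
    CellOntology,
    ScoringPolicy,
    read_observations,
    summarize_dataset,
    validate_dataset,
)
from .seqcons import (
    ConservationParams,
    align_global,
    block_metrics,
    conserved_segments,
    perfect_blocks,
    read_fasta,
    window_identity,
    write_blocks_bed,
    write_profile_tsv,
)
from .synthetic import study_cohort, write_fixtures

log = logging.getLogger("credive")

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "load_config"]


class PipelineError(RuntimeError):
    """A stage failure, named after the stage that raised it."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    out_dir: str = "credive_out"
    fasta_dir: str | None = None
    observations: str | None = None
    ontology: str | None = None
    overrides: str | None = None
    reference_species: str = "C_elegans"
    host_species: str = "C_elegans"
    simulate: bool = False
    seed: int = 0
    conservation: ConservationParams = field(default_factory=ConservationParams)
    policy: ScoringPolicy = field(default_factory=ScoringPolicy)

    def to_dict(self) -> dict:
        return asdict(self)


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    cons = ConservationParams(**raw.pop("conservation", {}))
    policy = ScoringPolicy(**raw.pop("policy", {}))
    return PipelineConfig(conservation=cons, policy=policy, **raw)


def _load_overrides(path) -> list[dict]:
    if path is None:
        return []
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if data is None:
        return []
    if not isinstance(data, list):
        raise ValueError("overrides file must be a list of {gene, cell, action, note}")
    return data


def stage_simulate(config: PipelineConfig) -> dict[str, str]:
    """Generate the default study-shaped synthetic cohort as fixtures."""
    out = Path(config.out_dir) / "fixtures"
    families, observations, truth, ontology, _ = study_cohort(seed=config.seed)
    write_fixtures(families, observations, truth, out, ontology=ontology)
    log.info(
        "simulate: %d gene families, %d observations", len(families), len(observations)
    )
    return {
        "fasta_dir": str(out),
        "observations": str(out / "observations.tsv"),
        "ontology": str(out / "ontology.json"),
    }


def stage_conserve(config: PipelineConfig) -> dict:
    """Align heterologous CREs to the reference and emit profiles, blocks
    and block metrics."""
    if config.fasta_dir is None:
        raise PipelineError("conserve", "no FASTA directory configured")
    fasta_dir = Path(config.fasta_dir)
    if not fasta_dir.is_dir():
        raise PipelineError("conserve", f"missing FASTA directory {fasta_dir}")
    out = Path(config.out_dir) / "conservation"
    out.mkdir(parents=True, exist_ok=True)
    params = config.conservation

    metrics_rows = []
    per_pair_metrics = {}
    lengths = {}
    n_aln = 0
    for fasta in sorted(fasta_dir.glob("*.fasta")):
        records = {r.species: r for r in read_fasta(fasta)}
        ref = records.get(config.reference_species)
        if ref is None:
            raise PipelineError(
                "conserve", f"{fasta.name}: reference species {config.reference_species!r} absent"
            )
        gene = ref.gene
        lengths[(gene, "reference")] = len(ref)
        for species, qry in sorted(records.items()):
            if species == config.reference_species:
                continue
            aln = align_global(ref, qry)
            n_aln += 1
            profile = window_identity(aln, params)
            segments = conserved_segments(profile, params)
            perfect = perfect_blocks(aln)
            bm = block_metrics([*perfect, *segments], len(ref), params)
            per_pair_metrics[(gene, species)] = bm
            lengths[(gene, species)] = len(qry)
            write_profile_tsv(profile, out / f"{gene}.{species}.profile.tsv")
            write_blocks_bed(
                [*segments, *perfect], out / f"{gene}.{species}.blocks.bed", gene, species
            )
            metrics_rows.append(
                (
                    gene, species, len(ref), len(qry),
                    bm.longest_perfect_block,
                    bm.nt_in_perfect_blocks_ge_short,
                    bm.fraction_in_blocks_ge_long,
                )
            )
    frame = pd.DataFrame(
        metrics_rows,
        columns=[
            "gene", "cre_species", "ref_len", "qry_len",
            "longest_perfect_block", "nt_in_perfect_blocks_ge7",
            "fraction_in_blocks_ge20",
        ],
    )
    frame.to_csv(out / "block_metrics.tsv", sep="\t", index=False)
    log.info("conserve: %d alignments across %d genes", n_aln, frame["gene"].nunique())
    return {"metrics": per_pair_metrics, "lengths": lengths, "table": frame}


def stage_summarize(config: PipelineConfig) -> dict:
    """Read observations, check the scoring-policy minima and summarize."""
    if config.observations is None or config.ontology is None:
        raise PipelineError("summarize", "observations and ontology paths required")
    for p in (config.observations, config.ontology):
        if not Path(p).exists():
            raise PipelineError("summarize", f"missing input file {p}")
    ontology = CellOntology.from_json(config.ontology)
    observations = read_observations(config.observations, ontology)
    out = Path(config.out_dir) / "expression"
    out.mkdir(parents=True, exist_ok=True)
    report = validate_dataset(observations, config.policy)
    report.to_csv(out / "validation.tsv", sep="\t", index=False)
    failing = set(
        map(tuple, report.loc[~report["passed"], ["gene", "cre_species", "host_species"]].values)
    )
    summaries = summarize_dataset(observations, ontology)
    kept = {k: s for k, s in summaries.items() if k not in failing}
    if failing:
        log.warning("summarize: %d transgene(s) fail policy minima, excluded", len(failing))
    from .expression import summary_frame

    summary_frame(kept).to_csv(out / "summaries.tsv", sep="\t", index=False)
    log.info(
        "summarize: %d observations, %d transgenes kept", len(observations), len(kept)
    )
    return {"summaries": kept, "ontology": ontology, "n_observations": len(observations)}


def stage_classify(config: PipelineConfig, summaries: dict) -> dict:
    """Build reference patterns, classify heterologous transgenes, tally."""
    out = Path(config.out_dir) / "divergence"
    out.mkdir(parents=True, exist_ok=True)
    overrides = _load_overrides(config.overrides)
    references = {}
    calls: list[DivergenceCall] = []
    for key, summary in sorted(summaries.items()):
        gene, cre_sp, host_sp = key
        if cre_sp == config.reference_species and host_sp == config.host_species:
            references[gene] = build_reference_pattern(summary, config.policy, overrides)
    if not references:
        raise PipelineError("classify", "no reference-species transgene found")
    for key, summary in sorted(summaries.items()):
        gene, cre_sp, host_sp = key
        if cre_sp == config.reference_species:
            continue
        ref = references.get(gene)
        if ref is None:
            log.warning("classify: no reference pattern for %s, skipped", gene)
            continue
        calls.extend(classify_transgene(summary, ref, config.policy))

    calls_to_frame(calls).to_csv(out / "calls.tsv", sep="\t", index=False)
    report = tally(calls)
    write_tally_json(report, out / "tally.json")
    curve = sweep_curve(calls)
    curve.frame().to_csv(out / "sweep.tsv", sep="\t", index=False)
    recur = recurrent_gains(calls)
    with open(out / "recurrent_gains.tsv", "w") as fh:
        fh.write("cell\tn_cres\tsupporting_cres\n")
        for cell, supporters in recur:
            names = ",".join(f"{g}|{sp}" for g, sp in supporters)
            fh.write(f"{cell}\t{len(supporters)}\t{names}\n")
    log.info(
        "classify: %d calls -> %d gains, %d strict losses, %d liberal",
        len(calls), report.n_gains, report.n_losses_strict, report.n_losses_liberal,
    )
    return {
        "references": references,
        "calls": calls,
        "tally": report,
        "sweep": curve,
        "recurrent_gains": recur,
    }


def stage_correlate(config: PipelineConfig, classify_out: dict, conserve_out: dict) -> dict:
    """Emit the divergence-vs-metric scatter panels and rank correlations."""
    out = Path(config.out_dir) / "correlate"
    out.mkdir(parents=True, exist_ok=True)
    metrics = divergence_metrics(
        classify_out["references"],
        classify_out["calls"],
        conserve_out["metrics"],
        conserve_out["lengths"],
    )
    metrics.to_csv(out / "metrics.tsv", sep="\t", index=False)
    stats_out = {}
    for panel, frame in panel_frames(metrics).items():
        frame.to_csv(out / f"scatter_{panel}.tsv", sep="\t", index=False)
        if len(frame) >= 3:
            rho, pval = rank_correlation(
                frame["x"].values, frame["y"].values, seed=config.seed
            )
            # undefined (constant-series) correlations serialize as null
            stats_out[panel] = {
                "spearman_rho": None if rho != rho else rho,
                "permutation_p": None if pval != pval else pval,
                "n": len(frame),
            }
        else:
            stats_out[panel] = {"spearman_rho": None, "permutation_p": None, "n": len(frame)}
    with open(out / "correlations.json", "w") as fh:
        json.dump(stats_out, fh, indent=2, sort_keys=True)
        fh.write("\n")
    log.info("correlate: %d CRE points", len(metrics))
    return {"metrics": metrics, "stats": stats_out}


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; any failure aborts with a stage-named error."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    if config.simulate:
        paths = stage_simulate(config)
        config.fasta_dir = paths["fasta_dir"]
        config.observations = paths["observations"]
        config.ontology = paths["ontology"]

    conserve_out = stage_conserve(config)
    summarize_out = stage_summarize(config)
    classify_out = stage_classify(config, summarize_out["summaries"])
    correlate_out = stage_correlate(config, classify_out, conserve_out)

    manifest = {
        "config": config.to_dict(),
        "config_sha256": _config_hash(config),
        "seed": config.seed,
        "credive_version": __version__,
        "n_observations": summarize_out["n_observations"],
        "tally": {
            "n_gains": classify_out["tally"].n_gains,
            "n_losses_strict": classify_out["tally"].n_losses_strict,
            "n_losses_liberal": classify_out["tally"].n_losses_liberal,
        },
        "sweep_dominant": classify_out["sweep"].dominant,
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return {
        "conserve": conserve_out,
        "summarize": summarize_out,
        "classify": classify_out,
        "correlate": correlate_out,
        "manifest": manifest,
    }
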