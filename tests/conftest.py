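"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from credive.expression import (
    CellDef,
    CellOntology,
    CellSummary,
    ExpressionSummary,
    Observation,
)
from credive.seqcons import PairwiseAlignment


# ---------------------------------------------------------------------------
# Alignment helpers / oracles


def make_alignment(ref_aligned: str, qry_aligned: str, score: int = 0) -> PairwiseAlignment:
    """Build a PairwiseAlignment directly from gapped strings."""
    ref_map = []
    pos = 0
    for c in ref_aligned:
        if c == "-":
            ref_map.append(-1)
        else:
            ref_map.append(pos)
            pos += 1
    return PairwiseAlignment(
        ref_aligned=ref_aligned, qry_aligned=qry_aligned, score=score, ref_map=np.array(ref_map)
    )


def gap_cost(length: int, open_: int, extend: int) -> int:
    """Affine cost of one gap run: first column pays open, rest extend."""
    if length == 0:
        return 0
    return open_ + (length - 1) * extend


def oracle_best_score(
    ref: str,
    qry: str,
    match: int = 1,
    mismatch: int = -1,
    gap_open: int = -4,
    gap_extend: int = -1,
) -> int:
    """Independent optimal global alignment score by exhaustive enumeration
    of monotone residue matchings.

    Any global alignment corresponds to a monotone matching of residues;
    with |open| >= |extend| the optimal gap arrangement between consecutive
    matched pairs groups unmatched residues of each sequence into a single
    run, so maximizing over matchings with grouped gap runs attains the
    optimum.  Completely independent of the DP implementation.
    """
    m, n = len(ref), len(qry)
    best = gap_cost(m, gap_open, gap_extend) + gap_cost(n, gap_open, gap_extend)
    for k in range(1, min(m, n) + 1):
        for ri in itertools.combinations(range(m), k):
            for qi in itertools.combinations(range(n), k):
                score = 0
                prev_r, prev_q = -1, -1
                for a, b in zip(ri, qi):
                    score += gap_cost(a - prev_r - 1, gap_open, gap_extend)
                    score += gap_cost(b - prev_q - 1, gap_open, gap_extend)
                    score += match if ref[a] == qry[b] else mismatch
                    prev_r, prev_q = a, b
                score += gap_cost(m - prev_r - 1, gap_open, gap_extend)
                score += gap_cost(n - prev_q - 1, gap_open, gap_extend)
                if score > best:
                    best = score
    return best


def scan_perfect_runs(ref_aligned: str, qry_aligned: str) -> list[tuple[int, int]]:
    """Brute-force identical-column run scan; returns (ref_start, ref_end)
    intervals.  Independent of the package implementation."""
    runs = []
    ref_pos = 0
    run_start = None
    run_last = None
    for a, b in zip(ref_aligned, qry_aligned):
        identical = a != "-" and a == b and a not in "NX"
        if identical:
            if run_start is None:
                run_start = ref_pos
            run_last = ref_pos
        else:
            if run_start is not None:
                runs.append((run_start, run_last + 1))
                run_start = None
        if a != "-":
            ref_pos += 1
    if run_start is not None:
        runs.append((run_start, run_last + 1))
    return runs


def random_gapped_pair(rng: np.random.Generator, ncols: int = 60) -> tuple[str, str]:
    """A random valid alignment (no gap-gap columns) over ACGT."""
    bases = "ACGT"
    ref, qry = [], []
    for _ in range(ncols):
        kind = rng.integers(0, 4)
        if kind == 0:  # forced match
            c = bases[rng.integers(0, 4)]
            ref.append(c)
            qry.append(c)
        elif kind == 1:
            ref.append(bases[rng.integers(0, 4)])
            qry.append(bases[rng.integers(0, 4)])
        elif kind == 2:
            ref.append(bases[rng.integers(0, 4)])
            qry.append("-")
        else:
            ref.append("-")
            qry.append(bases[rng.integers(0, 4)])
    # global alignments never start as gap-gap; also guarantee one residue each
    if all(c == "-" for c in ref):
        ref[0] = "A"
    if all(c == "-" for c in qry):
        qry[0] = "A"
    return "".join(ref), "".join(qry)


# ---------------------------------------------------------------------------
# Expression helpers


@pytest.fixture
def toy_ontology() -> CellOntology:
    cells = {
        name: CellDef(name=name, mode="binary")
        for name in ("ASI", "AVA", "HSNL", "HSNR", "RIS")
    }
    cells["VNC"] = CellDef(name="VNC", mode="counted", n_members=12)
    return CellOntology(cells=cells, groups={"HSNs": ["HSNL", "HSNR"]})


def make_observations(
    gene: str,
    cre_species: str,
    per_cell: dict[str, list[int]],
    strains: tuple[str, ...] = ("st1", "st2"),
    host_species: str = "C_elegans",
) -> list[Observation]:
    """Build observations from per-cell value lists (split evenly over
    strains, one entry per individual)."""
    obs = []
    for cell, values in per_cell.items():
        half = (len(values) + 1) // 2
        for i, v in enumerate(values):
            strain = strains[0] if i < half else strains[1 % len(strains)]
            obs.append(
                Observation(
                    gene=gene,
                    cre_species=cre_species,
                    host_species=host_species,
                    strain=strain,
                    individual=f"ind{i:03d}",
                    cell=cell,
                    value=v,
                )
            )
    return obs


def make_summary(
    gene: str,
    cre_species: str,
    cells: dict[str, tuple[str, float, dict[str, tuple[float, int]]]],
    host_species: str = "C_elegans",
) -> ExpressionSummary:
    """Construct an ExpressionSummary directly: cells maps label ->
    (stat, value, per_strain)."""
    summaries = {}
    n_total = 0
    strains = set()
    for label, (stat, value, per_strain) in cells.items():
        n = sum(n for _, n in per_strain.values())
        summaries[label] = CellSummary(label, stat, value, n, per_strain)
        n_total = max(n_total, n)
        strains.update(per_strain)
    return ExpressionSummary(
        gene=gene,
        cre_species=cre_species,
        host_species=host_species,
        n_individuals=n_total,
        n_strains=len(strains),
        cells=summaries,
    )
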