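"""Scatter analyses relating functional divergence of CREs to pattern
complexity, primary sequence conservation, and CRE length difference.

Each point is one heterologous CRE compared to the reference-species
ortholog: functional divergence is the number of non-conserved calls
(gains + strict losses + reductions), complexity the number of cell types
in the gene's reference pattern, conservation the fraction of the reference
CRE covered by conserved blocks of >= 20 nt, and the length metric the
absolute difference in CRE length.  Association is measured by Spearman
rank correlation with a seeded permutation p-value; the survey's point is
the *absence* of correlation, so the permutation null is the primary
readout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .divergence import DivergenceCall, ReferencePattern
from .seqcons import BlockMetrics

PANELS = ("complexity", "conservation", "length_difference")

__all__ = ["ScatterPoint", "divergence_metrics", "rank_correlation", "panel_frames"]


@dataclass(frozen=True)
class ScatterPoint:
    gene: str
    cre_species: str
    x: float
    y: float
    x_label: str
    y_label: str


def divergence_metrics(
    references: Mapping[str, ReferencePattern],
    calls: Sequence[DivergenceCall],
    block_metrics: Mapping[tuple[str, str], BlockMetrics],
    lengths: Mapping[tuple[str, str], int],
) -> pd.DataFrame:
    """Per-CRE metrics table feeding the three scatter panels.

    ``block_metrics`` and ``lengths`` are keyed by (gene, species); lengths
    must include the reference species of each gene under the key
    (gene, "reference").  CREs missing an upstream result are omitted.
    """
    by_transgene: dict[tuple[str, str], int] = {}
    for c in calls:
        key = (c.gene, c.cre_species)
        by_transgene.setdefault(key, 0)
        if c.call in ("gain", "loss_strict", "reduction"):
            by_transgene[key] += 1

    rows = []
    for (gene, species), n_div in sorted(by_transgene.items()):
        ref = references.get(gene)
        if ref is None:
            continue
        bm = block_metrics.get((gene, species))
        ref_len = lengths.get((gene, "reference"))
        qry_len = lengths.get((gene, species))
        rows.append(
            (
                gene,
                species,
                n_div,
                ref.complexity,
                bm.fraction_in_blocks_ge_long if bm is not None else math.nan,
                abs(ref_len - qry_len)
                if ref_len is not None and qry_len is not None
                else math.nan,
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "gene",
            "cre_species",
            "functional_divergence",
            "complexity",
            "conservation",
            "length_difference",
        ],
    )


def panel_frames(metrics: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """The three paired series: divergence vs complexity, conservation and
    length difference (rows with a missing metric are dropped per panel)."""
    out = {}
    for panel in PANELS:
        sub = metrics[["gene", "cre_species", panel, "functional_divergence"]].dropna()
        out[panel] = sub.rename(columns={panel: "x", "functional_divergence": "y"})
    return out


def rank_correlation(
    xs: Sequence[float],
    ys: Sequence[float],
    n_permutations: int = 10_000,
    seed: int = 0,
) -> tuple[float, float]:
    """Spearman rho (midranks for ties) with a two-sided permutation p-value.

    Returns ``(nan, nan)`` for constant series, where rank correlation is
    undefined.
    """
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    if xs.shape != ys.shape:
        raise ValueError("series length mismatch")
    n = xs.shape[0]
    if n < 3:
        raise ValueError("need at least 3 paired points")
    if np.all(xs == xs[0]) or np.all(ys == ys[0]):
        return (math.nan, math.nan)

    rx = stats.rankdata(xs)
    ry = stats.rankdata(ys)
    rho = float(stats.spearmanr(xs, ys).statistic)

    rng = np.random.default_rng(seed)
    rx_c = rx - rx.mean()
    ry_c = ry - ry.mean()
    denom = math.sqrt(float((rx_c**2).sum() * (ry_c**2).sum()))
    observed = abs(float((rx_c * ry_c).sum()) / denom)
    hits = 0
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        r = abs(float((rx_c[perm] * ry_c).sum()) / denom)
        if r >= observed - 1e-12:
            hits += 1
    pval = (hits + 1) / (n_permutations + 1)
    return rho, float(pval)
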