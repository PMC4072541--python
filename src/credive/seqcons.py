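"""Pairwise conservation analysis of orthologous noncoding (CRE) sequences.

Implements the sequence side of the comparative analysis: end-to-end global
alignment of orthologous upstream intergenic regions, a VISTA-style sliding-
window percent-identity profile (default: 20 bp window, 70% threshold),
perfect-conservation block extraction, and the derived block metrics
(longest perfect block, nucleotides in perfect blocks >= 7 bp, fraction of
the CRE covered by conserved blocks >= 20 bp).  Protein orthologs are
scored as a BLOSUM-based similarity relative to the reference self-score.

Coordinates are 0-based half-open throughout, so BED export is direct.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Align import substitution_matrices
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

from ._gotoh import gotoh_align

DNA_ALPHABET = "ACGTN"
PROTEIN_ALPHABET = "ACDEFGHIKLMNPQRSTVWYBZX*"
AMBIGUOUS = frozenset("NX")

__all__ = [
    "SequenceRecord",
    "ScoringScheme",
    "DNA_SCORING",
    "PROTEIN_SCORING",
    "PairwiseAlignment",
    "ConservationParams",
    "ConservationProfile",
    "ConservedBlock",
    "BlockMetrics",
    "read_fasta",
    "write_fasta",
    "align_global",
    "window_identity",
    "conserved_segments",
    "perfect_blocks",
    "block_metrics",
    "protein_relative_score",
    "write_blocks_bed",
    "write_profile_tsv",
]


@dataclass(frozen=True)
class SequenceRecord:
    """A species/gene-labelled DNA (CRE) or protein sequence."""

    id: str
    species: str
    gene: str
    alphabet: str  # "dna" | "protein"
    residues: str

    def __post_init__(self):
        if self.alphabet not in ("dna", "protein"):
            raise ValueError(f"unknown alphabet {self.alphabet!r}")
        res = self.residues.upper()
        object.__setattr__(self, "residues", res)
        if not res:
            raise ValueError(f"{self.id}: empty sequence")
        allowed = set(DNA_ALPHABET if self.alphabet == "dna" else PROTEIN_ALPHABET)
        bad = set(res) - allowed
        if bad:
            raise ValueError(f"{self.id}: invalid {self.alphabet} characters {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class ScoringScheme:
    """Alignment scoring: simple match/mismatch or a named substitution matrix.

    The first column of a gap run scores ``gap_open``; each further column
    scores ``gap_extend``.
    """

    match: int = 1
    mismatch: int = -1
    gap_open: int = -4
    gap_extend: int = -1
    matrix: str | None = None  # e.g. "BLOSUM62"; overrides match/mismatch


DNA_SCORING = ScoringScheme(match=1, mismatch=-1, gap_open=-4, gap_extend=-1)
PROTEIN_SCORING = ScoringScheme(gap_open=-11, gap_extend=-1, matrix="BLOSUM62")


@dataclass
class PairwiseAlignment:
    """A global pairwise alignment; ``ref_map[k]`` is the 0-based reference
    coordinate of column ``k`` or -1 where the reference is gapped."""

    ref_aligned: str
    qry_aligned: str
    score: int
    ref_map: np.ndarray

    def __post_init__(self):
        if len(self.ref_aligned) != len(self.qry_aligned):
            raise ValueError("gapped strings differ in length")
        for a, b in zip(self.ref_aligned, self.qry_aligned):
            if a == "-" and b == "-":
                raise ValueError("gap-gap column")
        self.ref_map = np.asarray(self.ref_map, dtype=np.int64)
        if self.ref_map.shape[0] != len(self.ref_aligned):
            raise ValueError("ref_map length mismatch")

    @property
    def ncols(self) -> int:
        return len(self.ref_aligned)

    @property
    def ref_len(self) -> int:
        return sum(1 for c in self.ref_aligned if c != "-")

    def identical_columns(self) -> np.ndarray:
        """Boolean per column: both residues present, equal, unambiguous."""
        out = np.zeros(self.ncols, dtype=bool)
        for k, (a, b) in enumerate(zip(self.ref_aligned, self.qry_aligned)):
            out[k] = a != "-" and a == b and a not in AMBIGUOUS
        return out


@dataclass(frozen=True)
class ConservationParams:
    window_len: int = 20
    identity_threshold: float = 0.70
    min_block_short: int = 7
    min_block_long: int = 20
    blosum_name: str = "BLOSUM62"

    def __post_init__(self):
        if self.window_len < 1:
            raise ValueError("window_len must be >= 1")
        if not 0 < self.identity_threshold <= 1:
            raise ValueError("identity_threshold must be in (0, 1]")
        if self.min_block_short > self.min_block_long:
            raise ValueError("min_block_short must be <= min_block_long")


@dataclass
class ConservationProfile:
    """Per-reference-position windowed identity, values in [0, 1]."""

    identity: np.ndarray

    def __post_init__(self):
        self.identity = np.asarray(self.identity, dtype=float)
        if self.identity.size and (
            self.identity.min() < 0 or self.identity.max() > 1
        ):
            raise ValueError("identity values outside [0, 1]")

    def __len__(self) -> int:
        return self.identity.shape[0]


@dataclass(frozen=True)
class ConservedBlock:
    ref_start: int
    ref_end: int  # half-open
    kind: str  # "windowed" | "perfect"

    def __post_init__(self):
        if self.ref_start >= self.ref_end:
            raise ValueError("empty block")
        if self.kind not in ("windowed", "perfect"):
            raise ValueError(f"unknown block kind {self.kind!r}")

    @property
    def length(self) -> int:
        return self.ref_end - self.ref_start


@dataclass(frozen=True)
class BlockMetrics:
    longest_perfect_block: int
    nt_in_perfect_blocks_ge_short: int
    fraction_in_blocks_ge_long: float


# ---------------------------------------------------------------------------
# FASTA I/O


def read_fasta(path, alphabet: str = "dna") -> list[SequenceRecord]:
    """Read FASTA; record ids of the form ``gene|species`` populate the
    gene/species fields, otherwise both default to the raw id."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        gene, _, species = rec.id.partition("|")
        records.append(
            SequenceRecord(
                id=rec.id,
                species=species or rec.id,
                gene=gene,
                alphabet=alphabet,
                residues=str(rec.seq),
            )
        )
    return records


def write_fasta(records: Iterable[SequenceRecord], path) -> None:
    bio = [
        _BioSeqRecord(Seq(r.residues), id=f"{r.gene}|{r.species}", description="")
        for r in records
    ]
    with open(path, "w") as fh:
        SeqIO.write(bio, fh, "fasta")


# ---------------------------------------------------------------------------
# Alignment


def _encode(seq: str, alphabet: str) -> np.ndarray:
    table = DNA_ALPHABET if alphabet == "dna" else PROTEIN_ALPHABET
    try:
        return np.array([table.index(c) for c in seq], dtype=np.int64)
    except ValueError:
        bad = sorted(set(seq) - set(table))
        raise ValueError(f"invalid characters for {alphabet}: {bad}") from None


def _substitution_matrix(alphabet: str, scoring: ScoringScheme) -> np.ndarray:
    if scoring.matrix is not None:
        blosum = substitution_matrices.load(scoring.matrix)
        table = PROTEIN_ALPHABET if alphabet == "protein" else DNA_ALPHABET
        n = len(table)
        sub = np.zeros((n, n), dtype=np.int64)
        for i, a in enumerate(table):
            for j, b in enumerate(table):
                sub[i, j] = int(blosum[a][b])
        return sub
    table = DNA_ALPHABET if alphabet == "dna" else PROTEIN_ALPHABET
    n = len(table)
    sub = np.full((n, n), scoring.mismatch, dtype=np.int64)
    np.fill_diagonal(sub, scoring.match)
    for i, a in enumerate(table):
        if a in AMBIGUOUS:  # ambiguity codes never score as a match
            sub[i, i] = scoring.mismatch
    return sub


def _as_record(seq, alphabet: str, role: str) -> SequenceRecord:
    if isinstance(seq, SequenceRecord):
        return seq
    return SequenceRecord(id=role, species=role, gene=role, alphabet=alphabet, residues=str(seq))


def align_global(ref, qry, scoring: ScoringScheme | None = None) -> PairwiseAlignment:
    """Optimal end-to-end alignment of ``ref`` and ``qry``.

    Accepts :class:`SequenceRecord` or plain strings (treated as DNA unless a
    protein scoring matrix is supplied).  Raises on alphabet mismatch.
    """
    default_alpha = "protein" if scoring is not None and scoring.matrix else "dna"
    ref = _as_record(ref, default_alpha, "ref")
    qry = _as_record(qry, default_alpha, "qry")
    if ref.alphabet != qry.alphabet:
        raise ValueError(f"alphabet mismatch: {ref.alphabet} vs {qry.alphabet}")
    if scoring is None:
        scoring = DNA_SCORING if ref.alphabet == "dna" else PROTEIN_SCORING

    sub = _substitution_matrix(ref.alphabet, scoring)
    score, col_ref, col_qry = gotoh_align(
        _encode(ref.residues, ref.alphabet),
        _encode(qry.residues, qry.alphabet),
        sub,
        scoring.gap_open,
        scoring.gap_extend,
    )
    ref_aligned = "".join(
        ref.residues[i] if i >= 0 else "-" for i in col_ref
    )
    qry_aligned = "".join(
        qry.residues[j] if j >= 0 else "-" for j in col_qry
    )
    return PairwiseAlignment(
        ref_aligned=ref_aligned,
        qry_aligned=qry_aligned,
        score=score,
        ref_map=col_ref,
    )


# ---------------------------------------------------------------------------
# Conservation profile and blocks


def window_identity(
    aln: PairwiseAlignment, params: ConservationParams | None = None
) -> ConservationProfile:
    """Sliding-window identity per reference position.

    The window of ``window_len`` reference positions is centred on each
    position; near the edges it slides inward so it always covers exactly
    ``min(window_len, ref_len)`` positions without padding.  Gap-in-query
    columns count as non-identical; gap-in-reference columns carry no
    reference coordinate and are ignored.  A window at least as long as the
    reference therefore collapses to a single full-length window, making the
    profile equal the overall alignment identity at every position.
    """
    params = params or ConservationParams()
    ident_cols = aln.identical_columns()
    L = aln.ref_len
    # per-reference-position identity indicator (each ref position occurs in
    # exactly one column)
    ind = np.zeros(L, dtype=float)
    for k in range(aln.ncols):
        r = aln.ref_map[k]
        if r >= 0:
            ind[r] = 1.0 if ident_cols[k] else 0.0
    w = min(params.window_len, L)
    half = w // 2
    csum = np.concatenate(([0.0], np.cumsum(ind)))
    profile = np.empty(L, dtype=float)
    for i in range(L):
        a = min(max(0, i - half), L - w)
        b = a + w
        profile[i] = (csum[b] - csum[a]) / w
    return ConservationProfile(identity=profile)


def conserved_segments(
    profile: ConservationProfile, params: ConservationParams | None = None
) -> list[ConservedBlock]:
    """Maximal runs of positions with windowed identity >= the threshold."""
    params = params or ConservationParams()
    above = profile.identity >= params.identity_threshold
    blocks: list[ConservedBlock] = []
    start = None
    for i, flag in enumerate(above):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            blocks.append(ConservedBlock(start, i, "windowed"))
            start = None
    if start is not None:
        blocks.append(ConservedBlock(start, len(above), "windowed"))
    return blocks


def perfect_blocks(aln: PairwiseAlignment) -> list[ConservedBlock]:
    """Maximal gapless runs of identical columns, in reference coordinates.

    A gap column (either strand) or a mismatch terminates a run, so an indel
    splits an otherwise-identical stretch.
    """
    ident = aln.identical_columns()
    blocks: list[ConservedBlock] = []
    start_ref = None
    last_ref = None
    for k in range(aln.ncols):
        if ident[k]:
            r = int(aln.ref_map[k])
            if start_ref is None:
                start_ref = r
            last_ref = r
        else:
            if start_ref is not None:
                blocks.append(ConservedBlock(start_ref, last_ref + 1, "perfect"))
                start_ref = None
    if start_ref is not None:
        blocks.append(ConservedBlock(start_ref, last_ref + 1, "perfect"))
    return blocks


def block_metrics(
    blocks: Sequence[ConservedBlock],
    cre_len: int,
    params: ConservationParams | None = None,
) -> BlockMetrics:
    """Summary divergence metrics for one reference/query pair.

    ``longest_perfect_block`` and the >= ``min_block_short`` total are taken
    over perfect blocks; the covered fraction merges every supplied block of
    length >= ``min_block_long`` (windowed or perfect) before measuring
    coverage, so overlapping calls are not double-counted.
    """
    params = params or ConservationParams()
    if cre_len <= 0:
        raise ValueError("cre_len must be positive")
    perfect = [b for b in blocks if b.kind == "perfect"]
    longest = max((b.length for b in perfect), default=0)
    nt_short = sum(b.length for b in perfect if b.length >= params.min_block_short)

    long_ivals = sorted(
        (b.ref_start, b.ref_end) for b in blocks if b.length >= params.min_block_long
    )
    covered = 0
    cur_s, cur_e = None, None
    for s, e in long_ivals:
        if cur_e is None or s > cur_e:
            if cur_e is not None:
                covered += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    if cur_e is not None:
        covered += cur_e - cur_s
    return BlockMetrics(
        longest_perfect_block=longest,
        nt_in_perfect_blocks_ge_short=nt_short,
        fraction_in_blocks_ge_long=covered / cre_len,
    )


def protein_relative_score(
    qry: SequenceRecord,
    ref: SequenceRecord,
    params: ConservationParams | None = None,
    scoring: ScoringScheme | None = None,
) -> float:
    """BLOSUM similarity of ``qry`` to ``ref``, normalised by the reference
    self-score; equals 1.0 for identical proteins."""
    params = params or ConservationParams()
    if scoring is None:
        scoring = replace(PROTEIN_SCORING, matrix=params.blosum_name)
    for rec in (qry, ref):
        if rec.alphabet != "protein":
            raise ValueError("protein_relative_score requires protein records")
    sub = _substitution_matrix("protein", scoring)
    codes = _encode(ref.residues, "protein")
    self_score = int(sub[codes, codes].sum())
    if self_score <= 0:
        raise ValueError("reference self-score is not positive")
    aln = align_global(ref, qry, scoring=scoring)
    return aln.score / self_score


# ---------------------------------------------------------------------------
# Tabular output


def write_blocks_bed(blocks: Sequence[ConservedBlock], path, gene: str, species: str) -> None:
    """BED3+name; name = gene|species|kind (0-based half-open coordinates)."""
    with open(path, "w") as fh:
        for b in sorted(blocks, key=lambda b: (b.ref_start, b.ref_end)):
            fh.write(f"{gene}\t{b.ref_start}\t{b.ref_end}\t{gene}|{species}|{b.kind}\n")


def write_profile_tsv(profile: ConservationProfile, path) -> None:
    with open(path, "w") as fh:
        fh.write("pos\tidentity\n")
        for i, v in enumerate(profile.identity):
            fh.write(f"{i}\t{v:.6f}\n")
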