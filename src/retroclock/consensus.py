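"""Multiple alignments and majority-rule consensus sequences.

Externally produced alignments (e.g. MAFFT) are first-class input via
``read_aligned_fasta``; the built-in star aligner is a deterministic
fallback adequate for the ≤20% divergences this pipeline deals with.
"""
from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
from Bio import Align

from .errors import FormatError, InputError
from .io import write_fasta

_ALPHABET = "ACGTN-"
_ROW_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _c in enumerate(_ALPHABET):
    _ROW_CODE[ord(_c)] = _i
    _ROW_CODE[ord(_c.lower())] = _i


def _encode_row(row: str) -> np.ndarray:
    codes = _ROW_CODE[np.frombuffer(row.encode("ascii"), dtype=np.uint8)]
    if np.any(codes == 255):
        bad = row[int(np.argmax(codes == 255))]
        raise InputError(f"alignment row contains invalid character {bad!r}")
    return codes


@dataclass
class MultipleAlignment:
    """Equal-length gapped rows over A/C/G/T/N/-; uppercase-normalized."""

    member_ids: list[str]
    rows: list[str]
    score: float | None = None
    # alignment column -> reference position (star alignment only); -1 for
    # columns holding member-specific insertions
    reference_columns: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not self.rows:
            raise InputError("alignment needs at least one row")
        if len(self.member_ids) != len(self.rows):
            raise InputError("member_ids and rows differ in length")
        self.rows = [r.upper() for r in self.rows]
        n = len(self.rows[0])
        for mid, r in zip(self.member_ids, self.rows):
            if len(r) != n:
                raise FormatError(f"ragged alignment: row {mid!r} has length "
                                  f"{len(r)}, expected {n}")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0])

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    def row(self, member_id: str) -> str:
        try:
            return self.rows[self.member_ids.index(member_id)]
        except ValueError:
            raise LookupError(f"member {member_id!r} not in alignment") from None

    def matrix(self) -> np.ndarray:
        """(n_rows, n_columns) uint8 codes over A=0,C=1,G=2,T=3,N=4,-=5."""
        return np.vstack([_encode_row(r) for r in self.rows])


@dataclass
class ConsensusSequence:
    """Ungapped majority-rule consensus with per-column bookkeeping.

    ``column_map[i]`` is the alignment column that produced consensus
    position ``i``; gap-plurality columns are omitted from the sequence but
    remain accounted for by the gaps in ``column_map``. ``support[i]`` is the
    winning-base fraction among non-N rows in that column.
    """

    sequence: str
    column_map: np.ndarray
    support: np.ndarray
    n_columns: int = 0

    def __post_init__(self) -> None:
        if not (len(self.sequence) == len(self.column_map) == len(self.support)):
            raise InputError("sequence, column_map and support must be parallel")

    def as_row(self) -> str:
        """The consensus laid out as a gapped alignment row."""
        row = np.full(self.n_columns, ord("-"), dtype=np.uint8)
        row[self.column_map] = np.frombuffer(self.sequence.encode("ascii"),
                                             dtype=np.uint8)
        return row.tobytes().decode("ascii")


def _aligner(match: float, mismatch: float, gap_open: float,
             gap_extend: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    return aligner


def global_align(a: str, b: str, match: float = 1, mismatch: float = -1,
                 gap_open: float = -4, gap_extend: float = -1,
                 ids: tuple[str, str] = ("a", "b")) -> MultipleAlignment:
    """Optimal affine-gap global alignment of two sequences.

    A gap of length k costs ``-(gap_open + (k-1)*gap_extend)``; the first
    optimal traceback reported by the aligner is used, so output is
    deterministic.
    """
    if not a or not b:
        raise InputError("sequences must be non-empty")
    aligner = _aligner(match, mismatch, gap_open, gap_extend)
    best = aligner.align(a.upper(), b.upper())[0]
    return MultipleAlignment(member_ids=list(ids), rows=[best[0], best[1]],
                             score=best.score)


def star_align(members: list[tuple[str, str]], reference: str,
               **align_kwargs) -> MultipleAlignment:
    """Align every member pairwise to a reference and merge on reference
    coordinates.

    Member-specific insertions relative to the reference get dedicated
    columns (shared slots sized to the longest insertion at that reference
    position, left-justified). Adequate for divergences up to ~20%.
    """
    if not reference:
        raise InputError("reference must be non-empty")
    if not members:
        raise InputError("at least one member required")
    ref_len = len(reference)
    # per member: ins[r] = insertion immediately before ref position r
    # (r == ref_len: trailing), aligned[r] = member char at ref position r
    per_member = []
    for mid, seq in members:
        pair = global_align(reference, seq, **align_kwargs)
        ref_row, mem_row = pair.rows
        ins: dict[int, list[str]] = {}
        aligned = ["-"] * ref_len
        r = 0
        for rc, mc in zip(ref_row, mem_row):
            if rc == "-":
                ins.setdefault(r, []).append(mc)
            else:
                if mc != "-":
                    aligned[r] = mc
                r += 1
        per_member.append((mid, {k: "".join(v) for k, v in ins.items()}, aligned))
    slot = np.zeros(ref_len + 1, dtype=int)
    for _, ins, _a in per_member:
        for r, s in ins.items():
            slot[r] = max(slot[r], len(s))
    rows = []
    ref_cols: list[int] = []
    for which, (mid, ins, aligned) in enumerate(per_member):
        parts = []
        for r in range(ref_len + 1):
            if slot[r]:
                s = ins.get(r, "")
                parts.append(s + "-" * (slot[r] - len(s)))
                if which == 0:
                    ref_cols.extend([-1] * slot[r])
            if r < ref_len:
                parts.append(aligned[r])
                if which == 0:
                    ref_cols.append(r)
        rows.append("".join(parts))
    return MultipleAlignment(member_ids=[m for m, _, _ in per_member], rows=rows,
                             reference_columns=np.asarray(ref_cols, dtype=int))


def read_aligned_fasta(path: str | os.PathLike) -> MultipleAlignment:
    """Read an aligned FASTA; rejects ragged input naming the bad record."""
    from Bio import SeqIO
    ids, rows = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        ids.append(rec.id)
        rows.append(str(rec.seq).upper())
    if not ids:
        raise FormatError(f"{path}: no records")
    n = len(rows[0])
    for mid, r in zip(ids, rows):
        if len(r) != n:
            raise FormatError(f"{path}: record {mid!r} has length {len(r)}, "
                              f"expected {n}")
    return MultipleAlignment(member_ids=ids, rows=rows)


def write_aligned_fasta(aln: MultipleAlignment, path: str | os.PathLike) -> None:
    write_fasta(zip(aln.member_ids, aln.rows), path)


def majority_consensus(aln: MultipleAlignment) -> ConsensusSequence:
    """Majority-rule (plurality) consensus.

    Per column, A/C/G/T and gap are counted (N is ignored); the plurality
    symbol wins. Base ties break deterministically in the order A<C<G<T and
    a gap loses every tie. Gap-winner columns are omitted from the consensus
    string. Support is the winner count over the non-N rows of the column.
    """
    if aln.n_columns == 0:
        raise InputError("zero-column alignment has no consensus")
    mat = aln.matrix()
    counts = np.stack([(mat == b).sum(axis=0) for b in range(6)])  # A C G T N -
    base_counts = counts[:4]
    best_base = base_counts.argmax(axis=0)  # first max -> A<C<G<T tie-break
    best_count = base_counts.max(axis=0)
    gap_wins = counts[5] > best_count  # gap loses ties
    keep = ~gap_wins & (best_count > 0)  # all-N/all-gap columns are omitted
    non_n = (mat != 4).sum(axis=0)
    column_map = np.nonzero(keep)[0]
    winners = best_base[keep]
    support = best_count[keep] / np.maximum(non_n[keep], 1)
    sequence = "".join(_ALPHABET[b] for b in winners)
    return ConsensusSequence(sequence=sequence, column_map=column_map,
                             support=support, n_columns=aln.n_columns)
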