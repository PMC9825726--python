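"""Similarity-hit mining: turn hits against a genome into classified loci.

Coordinates are 0-based half-open everywhere inside the package; the
12-column tabular hit format's 1-based inclusive coordinates are converted
only at the I/O boundary. The built-in ``naive_search`` (exact k-mer
seeding + ungapped X-drop extension) stands in for an external aligner so
the whole pipeline runs self-contained; externally produced hit tables are
equally accepted via ``read_hit_table``.
"""
from __future__ import annotations

import math
import os
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from ._seq import encode, kmer_codes, revcomp
from .errors import FormatError, InputError

DEFAULT_FLANK = 10_000


@dataclass(frozen=True)
class HitRecord:
    """One similarity hit, mirroring the 12-column tabular hit format.

    Query/subject coordinates are 1-based inclusive as in the format; hits
    on the minus strand are normalized so ``subject_start < subject_end``
    with ``strand == '-'``.
    """

    query_id: str
    subject_id: str
    percent_identity: float
    align_length: int
    mismatches: int
    gap_opens: int
    query_start: int
    query_end: int
    subject_start: int
    subject_end: int
    evalue: float
    bitscore: float
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.align_length <= 0:
            raise InputError("align_length must be > 0")
        if not 0 <= self.percent_identity <= 100:
            raise InputError("percent_identity must be in [0, 100]")


@dataclass(frozen=True)
class Cluster:
    """Merged same-scaffold, same-strand hit interval (0-based half-open)."""

    scaffold: str
    start: int
    end: int
    strand: str
    n_hits: int
    bitscore: float  # best single-hit bitscore in the cluster
    query_id: str = ""


@dataclass(frozen=True)
class ExtractedLocus:
    scaffold: str
    start: int  # 0-based half-open, flanks included
    end: int
    strand: str
    sequence: str  # element-forward orientation (revcomp'd for '-' clusters)
    flank_used: tuple[int, int]  # actual (left, right) flank after clamping
    core: tuple[int, int]  # the originating cluster interval


@dataclass(frozen=True)
class LocusStructure:
    """Candidate proviral anatomy of one extracted locus."""

    sequence: str
    candidates: tuple[tuple[int, int, float], ...]  # (start, end, score), score-sorted
    ltr5: tuple[int, int] | None = None
    ltr3: tuple[int, int] | None = None
    internal: tuple[int, int] | None = None
    tsd: str | None = None


@dataclass(frozen=True)
class ProviralLocus:
    classification: str  # provirus | solo_ltr | fragment
    family_id: str
    ltr5: tuple[int, int] | None = None
    ltr3: tuple[int, int] | None = None
    internal: tuple[int, int] | None = None
    tsd: str | None = None
    locus: ExtractedLocus | None = None
    element_id: str = ""


def read_hit_table(path: str | os.PathLike) -> list[HitRecord]:
    """Parse a tab-separated 12-column hit table.

    Minus-strand hits (subject start > end) are normalized to start < end
    with strand '-'. Malformed lines raise a format error naming the line.
    """
    records: list[HitRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 12:
                raise FormatError(f"{path}: line {lineno}: expected >= 12 "
                                  f"tab-separated columns, got {len(parts)}")
            try:
                pident = float(parts[2])
                length = int(parts[3])
                mismatches = int(parts[4])
                gap_opens = int(parts[5])
                qstart, qend = int(parts[6]), int(parts[7])
                sstart, send = int(parts[8]), int(parts[9])
                evalue = float(parts[10])
                bitscore = float(parts[11])
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: {exc}") from None
            strand = "+"
            if sstart > send:
                sstart, send = send, sstart
                strand = "-"
            records.append(HitRecord(
                query_id=parts[0], subject_id=parts[1], percent_identity=pident,
                align_length=length, mismatches=mismatches, gap_opens=gap_opens,
                query_start=qstart, query_end=qend, subject_start=sstart,
                subject_end=send, evalue=evalue, bitscore=bitscore,
                strand=strand))
    return records


def write_hit_table(records: Sequence[HitRecord], path: str | os.PathLike) -> None:
    """Write hits back in the tabular format (minus strand as start > end)."""
    with open(path, "w") as fh:
        for r in records:
            ss, se = r.subject_start, r.subject_end
            if r.strand == "-":
                ss, se = se, ss
            fh.write("\t".join([
                r.query_id, r.subject_id, f"{r.percent_identity:.3f}",
                str(r.align_length), str(r.mismatches), str(r.gap_opens),
                str(r.query_start), str(r.query_end), str(ss), str(se),
                f"{r.evalue:.2e}", f"{r.bitscore:.1f}",
            ]) + "\n")


class GenomeIndex:
    """Exact k-mer index over a set of scaffolds, reusable across queries."""

    def __init__(self, genome: Mapping[str, str], k: int = 12):
        if not 8 <= k <= 32:
            raise InputError("k must be in [8, 32]")
        self.k = k
        self.names = list(genome)
        self.codes = {n: encode(genome[n]) for n in self.names}
        self.total_length = sum(c.size for c in self.codes.values())
        kmers_all, pos_all, scaf_all = [], [], []
        for si, n in enumerate(self.names):
            km = kmer_codes(self.codes[n], k)
            keep = km >= 0
            kmers_all.append(km[keep])
            pos_all.append(np.nonzero(keep)[0].astype(np.int64))
            scaf_all.append(np.full(int(keep.sum()), si, dtype=np.int32))
        kmers = np.concatenate(kmers_all) if kmers_all else np.empty(0, np.int64)
        order = np.argsort(kmers, kind="stable")
        self._kmers = kmers[order]
        self._pos = (np.concatenate(pos_all) if pos_all else np.empty(0, np.int64))[order]
        self._scaf = (np.concatenate(scaf_all) if scaf_all else np.empty(0, np.int32))[order]

    def lookup(self, query_kmers: np.ndarray):
        """For each query k-mer, the (scaffold_idx, position) matches."""
        lo = np.searchsorted(self._kmers, query_kmers, side="left")
        hi = np.searchsorted(self._kmers, query_kmers, side="right")
        return lo, hi, self._scaf, self._pos


def _xdrop_extend(q: np.ndarray, g: np.ndarray, diag: int, qpos: int, k: int,
                  match: int, mismatch: int, xdrop: int) -> tuple[int, int, float, int]:
    """Ungapped X-drop extension of a seed on one diagonal.

    Returns (q_start, q_end, score, n_matches) in query coordinates.
    """
    qs = max(0, -diag)
    qe = min(q.size, g.size - diag)
    eq = (q[qs:qe] == g[qs + diag:qe + diag]) & (q[qs:qe] < 4) & (g[qs + diag:qe + diag] < 4)
    sc = np.where(eq, match, mismatch).astype(np.int64)
    s0 = qpos - qs
    s1 = s0 + k - 1  # seed occupies [s0, s1]
    # right extension from the base after the seed
    right = sc[s1 + 1:]
    best_r = 0
    if right.size:
        cum = np.cumsum(right)
        runmax = np.maximum.accumulate(cum)
        dropped = np.nonzero(runmax - cum > xdrop)[0]
        limit = dropped[0] if dropped.size else right.size
        if limit > 0:
            prefix = cum[:limit]
            best_idx = int(np.argmax(prefix))
            if prefix[best_idx] > 0:
                best_r = best_idx + 1
    # left extension (mirror)
    left = sc[:s0][::-1]
    best_l = 0
    if left.size:
        cum = np.cumsum(left)
        runmax = np.maximum.accumulate(cum)
        dropped = np.nonzero(runmax - cum > xdrop)[0]
        limit = dropped[0] if dropped.size else left.size
        if limit > 0:
            prefix = cum[:limit]
            best_idx = int(np.argmax(prefix))
            if prefix[best_idx] > 0:
                best_l = best_idx + 1
    a = s0 - best_l
    b = s1 + 1 + best_r
    seg_eq = eq[a:b]
    return qs + a, qs + b, float(sc[a:b].sum()), int(seg_eq.sum())


def naive_search(query: str, genome: Mapping[str, str] | str | GenomeIndex,
                 k: int = 12, min_identity: float = 60.0,
                 query_id: str = "query", xdrop: int = 20,
                 match: int = 1, mismatch: int = -2,
                 max_evalue: float = 10.0) -> list[HitRecord]:
    """Self-contained similarity search: exact k-mer seeds on both strands,
    ungapped X-drop extension, per-diagonal deduplication.

    Reported hits have percent identity >= ``min_identity`` over an aligned
    length >= k and an expectation <= ``max_evalue``. Bitscore is the raw
    ungapped score; the e-value is the Karlin-Altschul-style expectation
    m*n*2^-score, which suppresses the chance seed matches any k-mer scan
    produces on a genome-scale subject.
    """
    if not query:
        raise InputError("query must be non-empty")
    if isinstance(genome, str):
        genome = {"subject": genome}
    index = genome if isinstance(genome, GenomeIndex) else GenomeIndex(genome, k)
    if index.k != k:
        raise InputError(f"index built with k={index.k}, requested k={k}")
    hits: list[HitRecord] = []
    n = len(query)
    for strand in "+-":
        qseq = query.upper() if strand == "+" else revcomp(query.upper())
        q = encode(qseq)
        qk = kmer_codes(q, k)
        valid = np.nonzero(qk >= 0)[0]
        lo, hi, scafs, positions = index.lookup(qk[valid])
        covered: dict[tuple[int, int], list[tuple[int, int]]] = {}
        for vi in range(valid.size):
            if lo[vi] == hi[vi]:
                continue
            qpos = int(valid[vi])
            for j in range(lo[vi], hi[vi]):
                si = int(scafs[j])
                gpos = int(positions[j])
                diag = gpos - qpos
                key = (si, diag)
                spans = covered.get(key)
                if spans and any(a <= qpos and qpos + k <= b for a, b in spans):
                    continue
                g = index.codes[index.names[si]]
                qa, qb, score, matches = _xdrop_extend(
                    q, g, diag, qpos, k, match, mismatch, xdrop)
                covered.setdefault(key, []).append((qa, qb))
                length = qb - qa
                identity = 100.0 * matches / length
                evalue = index.total_length * n * math.pow(2.0, -score)
                if length < k or identity < min_identity or evalue > max_evalue:
                    continue
                ga, gb = qa + diag, qb + diag
                if strand == "+":
                    q1, q2 = qa + 1, qb
                else:
                    q1, q2 = n - qb + 1, n - qa
                hits.append(HitRecord(
                    query_id=query_id, subject_id=index.names[si],
                    percent_identity=identity, align_length=length,
                    mismatches=length - matches, gap_opens=0,
                    query_start=q1, query_end=q2,
                    subject_start=ga + 1, subject_end=gb,
                    evalue=evalue, bitscore=score, strand=strand))
    hits.sort(key=lambda h: (-h.bitscore, h.subject_id, h.subject_start))
    return hits


def merge_hits(hits: Sequence[HitRecord], max_gap: int) -> list[Cluster]:
    """Merge same-scaffold, same-strand hits whose gaps are <= max_gap into
    maximal clusters, sorted by (scaffold, start)."""
    by_key: dict[tuple[str, str], list[HitRecord]] = {}
    for h in hits:
        by_key.setdefault((h.subject_id, h.strand), []).append(h)
    clusters: list[Cluster] = []
    for (scaf, strand), group in by_key.items():
        group.sort(key=lambda h: (h.subject_start, h.subject_end))
        cur_start = group[0].subject_start - 1
        cur_end = group[0].subject_end
        cur_n = 1
        cur_score = group[0].bitscore
        cur_query = group[0].query_id
        for h in group[1:]:
            s0, e0 = h.subject_start - 1, h.subject_end
            if s0 - cur_end <= max_gap:
                cur_end = max(cur_end, e0)
                cur_n += 1
                cur_score = max(cur_score, h.bitscore)
            else:
                clusters.append(Cluster(scaf, cur_start, cur_end, strand,
                                        cur_n, cur_score, cur_query))
                cur_start, cur_end, cur_n = s0, e0, 1
                cur_score, cur_query = h.bitscore, h.query_id
        clusters.append(Cluster(scaf, cur_start, cur_end, strand,
                                cur_n, cur_score, cur_query))
    clusters.sort(key=lambda c: (c.scaffold, c.start, c.end))
    return clusters


def extract_locus(genome: Mapping[str, str], cluster: Cluster,
                  flank: int = DEFAULT_FLANK) -> ExtractedLocus:
    """Extract a cluster ± flank, clamped to scaffold bounds; minus-strand
    clusters are reverse-complemented to element-forward orientation."""
    if cluster.scaffold not in genome:
        raise LookupError(f"scaffold {cluster.scaffold!r} not in genome")
    scaffold = genome[cluster.scaffold]
    start = max(0, cluster.start - flank)
    end = min(len(scaffold), cluster.end + flank)
    seq = scaffold[start:end].upper()
    if cluster.strand == "-":
        seq = revcomp(seq)
    return ExtractedLocus(scaffold=cluster.scaffold, start=start, end=end,
                          strand=cluster.strand, sequence=seq,
                          flank_used=(cluster.start - start, end - cluster.end),
                          core=(cluster.start, cluster.end))


def _project_candidates(locus_seq: str, ltr_ref: str, min_identity: float,
                        k: int) -> list[tuple[int, int, float]]:
    """LTR-reference matches in the locus, projected to full reference span.

    Each merged hit cluster is extended along its best hit's diagonal to
    cover the complete reference length (clamped at locus bounds), so
    boundary fraying of the X-drop extension does not truncate the LTR.
    """
    ref_len = len(ltr_ref)
    hits = [h for h in naive_search(ltr_ref, {"locus": locus_seq}, k=k,
                                    min_identity=min_identity, query_id="ltr")
            if h.strand == "+"]
    if not hits:
        return []
    clusters = merge_hits(hits, max_gap=max(50, ref_len // 2))
    out = []
    for c in clusters:
        best = max((h for h in hits
                    if h.subject_start - 1 >= c.start - 1 and h.subject_end <= c.end + 1),
                   key=lambda h: h.bitscore)
        diag = (best.subject_start - 1) - (best.query_start - 1)
        start = max(0, diag)
        end = min(len(locus_seq), diag + ref_len)
        out.append((start, end, c.bitscore))
    out.sort(key=lambda t: (-t[2], t[0]))
    # drop overlapping projections, keeping the best-scoring one
    kept: list[tuple[int, int, float]] = []
    for cand in out:
        if all(cand[1] <= kk[0] or cand[0] >= kk[1] for kk in kept):
            kept.append(cand)
    return kept


def detect_ltr_pair(locus_sequence: str, family_ltr_reference: str,
                    min_identity: float = 60.0, k: int = 11,
                    min_separation: int = 1000,
                    max_separation: int | None = None) -> LocusStructure:
    """Locate up to two LTR-reference matches in a locus.

    Two same-orientation matches separated by at least ``min_separation``
    define a (5' LTR, internal, 3' LTR) structure; a single match defines a
    lone-LTR structure. The 4-6 nt immediately outside both LTRs are
    compared and reported as the target-site duplication when identical.
    """
    if len(family_ltr_reference) < 100:
        raise InputError("family LTR reference must be >= 100 nt")
    cands = _project_candidates(locus_sequence, family_ltr_reference,
                                min_identity, k)
    best_pair = None
    best_score = -1.0
    for i in range(len(cands)):
        for j in range(len(cands)):
            if i == j:
                continue
            a, b = cands[i], cands[j]
            if a[0] > b[0]:
                continue
            gap = b[0] - a[1]
            if gap < min_separation:
                continue
            if max_separation is not None and gap > max_separation:
                continue
            score = a[2] + b[2]
            if score > best_score:
                best_score = score
                best_pair = (a, b)
    ltr5 = ltr3 = internal = None
    tsd = None
    if best_pair:
        a, b = best_pair
        ltr5, ltr3 = (a[0], a[1]), (b[0], b[1])
        internal = (a[1], b[0])
        tsd = _find_tsd(locus_sequence, ltr5, ltr3)
    elif cands:
        ltr5 = (cands[0][0], cands[0][1])
    return LocusStructure(sequence=locus_sequence,
                          candidates=tuple(cands), ltr5=ltr5, ltr3=ltr3,
                          internal=internal, tsd=tsd)


def _find_tsd(seq: str, ltr5: tuple[int, int], ltr3: tuple[int, int],
              lengths: tuple[int, ...] = (6, 5, 4)) -> str | None:
    for t in lengths:
        left = seq[max(0, ltr5[0] - t):ltr5[0]]
        right = seq[ltr3[1]:ltr3[1] + t]
        if len(left) == len(right) == t and left == right:
            return left
    return None


def _internal_coverage(region: str, internal_reference: str,
                       min_identity: float, k: int) -> float:
    """Fraction of the internal reference covered by matches in a region."""
    if len(region) < k:
        return 0.0
    hits = naive_search(internal_reference, {"r": region}, k=k,
                        min_identity=min_identity, query_id="internal")
    if not hits:
        return 0.0
    intervals = sorted((h.query_start - 1, h.query_end) for h in hits)
    covered = 0
    cur_s, cur_e = intervals[0]
    for s, e in intervals[1:]:
        if s <= cur_e:
            cur_e = max(cur_e, e)
        else:
            covered += cur_e - cur_s
            cur_s, cur_e = s, e
    covered += cur_e - cur_s
    return covered / len(internal_reference)


def classify_locus(structure: LocusStructure, family_internal_reference: str,
                   family_id: str = "", min_internal_fraction: float = 0.3,
                   solo_free_window: int = 1000, min_identity: float = 60.0,
                   k: int = 11, locus: ExtractedLocus | None = None,
                   element_id: str = "") -> ProviralLocus:
    """Classify a locus structure as provirus, solo LTR, or fragment.

    Provirus: an LTR pair with the region between them matching at least
    ``min_internal_fraction`` of the internal reference. All candidate LTR
    pairs are evaluated and the pair with the best internal support wins
    (score breaks ties), which guards against pairing a solo LTR with a
    neighbouring element's LTR. Solo LTR: a single LTR with no
    internal-reference match within ``solo_free_window`` on either side.
    Everything else is a fragment.
    """
    seq = structure.sequence
    best_pair = None
    best_key = None
    ref_len = len(family_internal_reference)
    cands = structure.candidates
    for i in range(len(cands)):
        for j in range(len(cands)):
            a, b = cands[i], cands[j]
            if i == j or a[0] >= b[0]:
                continue
            if b[0] - a[1] < 1000:
                continue
            region = seq[a[1]:b[0]]
            cov = _internal_coverage(region, family_internal_reference,
                                     min_identity, k)
            if cov < min_internal_fraction:
                continue
            # ties on coverage go to the pair whose spacing fits the
            # internal reference, then to the better-scoring pair
            key = (cov, -abs(len(region) - ref_len), a[2] + b[2])
            if best_key is None or key > best_key:
                best_key = key
                best_pair = (a, b)
    if best_pair:
        a, b = best_pair
        ltr5, ltr3 = (a[0], a[1]), (b[0], b[1])
        return ProviralLocus(classification="provirus", family_id=family_id,
                             ltr5=ltr5, ltr3=ltr3, internal=(a[1], b[0]),
                             tsd=_find_tsd(seq, ltr5, ltr3),
                             locus=locus, element_id=element_id)
    # fall back to the best single LTR interpretation
    if structure.candidates:
        s, e, _score = structure.candidates[0]
        left = seq[max(0, s - solo_free_window):s]
        right = seq[e:e + solo_free_window]
        near_internal = max(
            _internal_coverage(left, family_internal_reference, min_identity, k),
            _internal_coverage(right, family_internal_reference, min_identity, k))
        if near_internal * len(family_internal_reference) < 100:
            return ProviralLocus(classification="solo_ltr", family_id=family_id,
                                 ltr5=(s, e), locus=locus, element_id=element_id)
        return ProviralLocus(classification="fragment", family_id=family_id,
                             ltr5=(s, e), locus=locus, element_id=element_id)
    return ProviralLocus(classification="fragment", family_id=family_id,
                         locus=locus, element_id=element_id)
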