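"""Cross-genome presence/absence screening and locus annotation.

Presence calls summarize similarity hits of a family consensus against a
target genome; ORF scanning gauges residual protein-coding potential of
mined loci; PBS identification matches the 18 nt downstream of the 5' LTR
against the 3' ends of a tRNA library to name the priming tRNA.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from Bio.Seq import Seq

from ._seq import revcomp
from .errors import InputError
from .mining import HitRecord, ProviralLocus

PBS_LENGTH = 18


@dataclass(frozen=True)
class PresenceCall:
    family_id: str
    genome_id: str
    present: bool
    best_percent_identity: float  # identity of the top-bitscore qualifying hit
    best_hit_length: int
    n_hits: int


@dataclass(frozen=True)
class ORFReport:
    element_id: str
    gene: str
    frame: int  # 0, 1 or 2
    longest_orf_fraction: float  # longest stop-free stretch / gene length
    intact: bool


@dataclass(frozen=True)
class PBSMatch:
    element_id: str
    trna_id: str
    mismatches: int  # over the 18 nt PBS
    position: int  # PBS start offset relative to the 5' LTR end


def screen_genome(consensus_id: str, hit_records: Sequence[HitRecord],
                  genome_id: str = "genome", min_identity: float = 60.0,
                  min_length: int = 300) -> PresenceCall:
    """Presence call for one family consensus against one genome.

    Present iff at least one hit reaches ``min_identity`` percent identity
    over at least ``min_length`` aligned positions; the reported identity is
    that of the top-bitscore qualifying hit. Raising ``min_identity`` can
    only remove qualifying hits, so presence is monotone in the threshold.
    """
    qualifying = [h for h in hit_records
                  if h.percent_identity >= min_identity
                  and h.align_length >= min_length]
    if not qualifying:
        return PresenceCall(family_id=consensus_id, genome_id=genome_id,
                            present=False, best_percent_identity=0.0,
                            best_hit_length=0, n_hits=0)
    best = max(qualifying, key=lambda h: h.bitscore)
    return PresenceCall(family_id=consensus_id, genome_id=genome_id,
                        present=True, best_percent_identity=best.percent_identity,
                        best_hit_length=best.align_length, n_hits=len(qualifying))


def _longest_stop_free(aa: str) -> int:
    best = cur = 0
    for c in aa:
        if c == "*":
            cur = 0
        else:
            cur += 1
            best = max(best, cur)
    return best


def orf_scan(locus_sequence: str, gene_intervals: Mapping[str, tuple[int, int]],
             element_id: str = "", intact_fraction: float = 0.9) -> list[ORFReport]:
    """Assess each annotated gene region for residual coding potential.

    All three forward frames of the gene region are translated; the longest
    stop-free stretch (in nt) over the gene length gives the ORF fraction.
    A gene is called intact when that fraction reaches ``intact_fraction``
    and an ATG lies, in the winning frame, within the first 10% of the gene.
    """
    reports = []
    for gene, (start, end) in gene_intervals.items():
        if start < 0 or end > len(locus_sequence) or start >= end:
            raise InputError(f"gene {gene!r} interval outside locus")
        region = locus_sequence[start:end].upper()
        gene_len = end - start
        best_frame, best_fraction = 0, -1.0
        for frame in range(3):
            sub = region[frame:]
            sub = sub[:len(sub) - len(sub) % 3]
            if not sub:
                continue
            aa = str(Seq(sub).translate())
            fraction = min(1.0, 3 * _longest_stop_free(aa) / gene_len)
            if fraction > best_fraction:
                best_frame, best_fraction = frame, fraction
        head = region[:max(3, int(gene_len * 0.1))]
        has_start = any(head[i:i + 3] == "ATG"
                        for i in range(best_frame, len(head) - 2, 3))
        intact = best_fraction >= intact_fraction and has_start
        reports.append(ORFReport(element_id=element_id, gene=gene,
                                 frame=best_frame,
                                 longest_orf_fraction=max(0.0, best_fraction),
                                 intact=intact))
    return reports


def pbs_identify(locus: ProviralLocus | None, locus_sequence: str,
                 trna_library: Mapping[str, str], search_window: int = 30,
                 max_mismatch: int = 3, element_id: str = "") -> PBSMatch | None:
    """Identify the tRNA priming reverse transcription at a locus.

    Every 18-nt window starting within ``search_window`` nt downstream of
    the annotated 5' LTR end is compared with the reverse complement of each
    tRNA's 3'-terminal 18 nt; the fewest-mismatch match within
    ``max_mismatch`` wins, ties breaking by library order.
    """
    if not trna_library:
        raise InputError("tRNA library is empty")
    if locus is None or locus.ltr5 is None:
        raise InputError("locus needs an annotated 5' LTR")
    ltr_end = locus.ltr5[1]
    probes = []
    for trna_id, trna in trna_library.items():
        if len(trna) < PBS_LENGTH:
            raise InputError(f"tRNA {trna_id!r} shorter than {PBS_LENGTH} nt")
        probes.append((trna_id, revcomp(trna.upper()[-PBS_LENGTH:])))
    best: PBSMatch | None = None
    for offset in range(search_window):
        start = ltr_end + offset
        window = locus_sequence[start:start + PBS_LENGTH].upper()
        if len(window) < PBS_LENGTH:
            break
        for trna_id, probe in probes:
            mm = sum(1 for a, b in zip(window, probe) if a != b)
            if mm <= max_mismatch and (best is None or mm < best.mismatches):
                best = PBSMatch(element_id=element_id or locus.element_id,
                                trna_id=trna_id, mismatches=mm, position=offset)
    return best
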