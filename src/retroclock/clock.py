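"""Molecular-clock dating of provirus integrations.

Three dating methods are implemented, all based on Kimura two-parameter
(K2P) distances with CpG dinucleotide columns excluded:

1. ``ltr_consensus`` — divergence of each LTR copy from the family's
   majority-rule LTR consensus;
2. ``gene_consensus`` — divergence of each proviral gene from the gene
   consensus;
3. ``ltr_pair`` — divergence between a provirus's own 5' and 3' LTR, which
   were identical at integration, giving T = D / (2*rate).

The consensus approximates the ancestral state, so for methods 1-2 the
default conversion is T = D / rate (divergence accrued along a single
lineage); a ``denominator`` switch of 2 is provided for the alternative
reading. CpG columns are defined on the consensus (or on the pairwise
consensus of the two LTRs for method 3) because deamination of methylated
cytosine makes them hypermutable and off-clock.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .consensus import ConsensusSequence, MultipleAlignment, global_align, majority_consensus
from .errors import InputError, SaturationError, UndefinedDistanceError

logger = logging.getLogger(__name__)

DEFAULT_RATE = 0.0017  # substitutions / nucleotide / Myr (mouse lemur germline)

_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")
_VALID = frozenset("ACGT")


@dataclass(frozen=True)
class K2PResult:
    P: float  # transition proportion
    Q: float  # transversion proportion
    d: float  # K2P distance, substitutions/site
    n_sites: int  # usable (unmasked, ungapped, unambiguous) columns


@dataclass(frozen=True)
class AgeEstimate:
    element_id: str
    method: str  # ltr_consensus | gene_consensus | ltr_pair
    divergence: float
    age_myr: float
    rate: float
    n_sites: int = 0
    family_id: str = ""


@dataclass(frozen=True)
class FamilyAgeSummary:
    family_id: str
    method: str
    n: int
    mean_age_myr: float
    sd_age_myr: float

    def display(self) -> str:
        """Table formatting like ``60 (±28)``: rounded for display only."""
        return f"{self.mean_age_myr:.0f} (±{self.sd_age_myr:.0f})"


def cpg_mask(aln: MultipleAlignment, consensus: ConsensusSequence) -> np.ndarray:
    """Boolean alignment-column mask of CpG positions.

    ``mask[j]`` is True iff column ``j`` maps to a consensus position that is
    the C or the G of a CG dinucleotide in the consensus sequence.
    """
    if consensus.n_columns != aln.n_columns:
        raise InputError("consensus column bookkeeping does not match alignment")
    if consensus.column_map.size and consensus.column_map.max() >= aln.n_columns:
        raise InputError("consensus column_map exceeds alignment width")
    mask = np.zeros(aln.n_columns, dtype=bool)
    s = consensus.sequence
    for i in range(len(s) - 1):
        if s[i] == "C" and s[i + 1] == "G":
            mask[consensus.column_map[i]] = True
            mask[consensus.column_map[i + 1]] = True
    return mask


def k2p_distance(row_a: str, row_b: str,
                 mask: np.ndarray | None = None) -> K2PResult:
    """K2P distance between two aligned (gapped) rows with pairwise deletion.

    Columns holding a gap, an N (or any ambiguity), or a True mask entry are
    excluded. d = -1/2 ln(1-2P-Q) - 1/4 ln(1-2Q) with P the transition and Q
    the transversion proportion over the remaining sites.
    """
    if len(row_a) != len(row_b):
        raise InputError("rows must be equal length")
    if mask is not None and len(mask) != len(row_a):
        raise InputError("mask must match row length")
    n_sites = 0
    ts = 0
    tv = 0
    for j, (x, y) in enumerate(zip(row_a.upper(), row_b.upper())):
        if mask is not None and mask[j]:
            continue
        if x not in _VALID or y not in _VALID:
            continue
        n_sites += 1
        if x != y:
            if (x in _PURINES) == (y in _PURINES):
                ts += 1
            else:
                tv += 1
    if n_sites == 0:
        raise UndefinedDistanceError("no usable sites after masking/deletion")
    P = ts / n_sites
    Q = tv / n_sites
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0 or w2 <= 0:
        raise SaturationError(
            f"K2P correction undefined at P={P:.4f}, Q={Q:.4f} (saturated)")
    d = -0.5 * math.log(w1) - 0.25 * math.log(w2)
    return K2PResult(P=P, Q=Q, d=d, n_sites=n_sites)


def age_from_consensus(aln: MultipleAlignment, consensus: ConsensusSequence,
                       rate: float = DEFAULT_RATE,
                       method_label: str = "ltr_consensus",
                       denominator: int = 1,
                       family_id: str = "") -> list[AgeEstimate]:
    """Date each alignment row by its CpG-masked K2P divergence from the
    consensus: age = d / (denominator * rate).

    Rows whose distance is saturated or undefined are skipped with a log
    message rather than clamped, so family means stay unbiased.
    """
    if rate <= 0:
        raise InputError("rate must be > 0")
    if method_label not in ("ltr_consensus", "gene_consensus"):
        raise InputError(f"unknown method label {method_label!r}")
    if denominator not in (1, 2):
        raise InputError("denominator must be 1 or 2")
    mask = cpg_mask(aln, consensus)
    cons_row = consensus.as_row()
    estimates = []
    for mid, row in zip(aln.member_ids, aln.rows):
        try:
            res = k2p_distance(row, cons_row, mask)
        except (SaturationError, UndefinedDistanceError) as exc:
            logger.warning("skipping %s: %s", mid, exc)
            continue
        estimates.append(AgeEstimate(
            element_id=mid, method=method_label, divergence=res.d,
            age_myr=res.d / (denominator * rate), rate=rate,
            n_sites=res.n_sites, family_id=family_id))
    return estimates


def age_ltr_pair(ltr5: str, ltr3: str, rate: float = DEFAULT_RATE,
                 element_id: str = "", family_id: str = "",
                 align: bool | None = None) -> AgeEstimate:
    """Date a provirus from its own LTR pair: T = D / (2*rate).

    Gapped inputs are treated as pre-aligned rows (equal length required).
    Ungapped equal-length sequences are compared position-wise — the usual
    case for LTRs projected onto a common reference frame — while unequal
    lengths are globally aligned first; pass ``align=True`` to force
    alignment of equal-length sequences that may contain indels. The CpG
    mask is taken over the pairwise consensus of the two rows, which makes
    the estimate symmetric.
    """
    if not ltr5 or not ltr3:
        raise InputError("both LTR sequences are required")
    if rate <= 0:
        raise InputError("rate must be > 0")
    if "-" in ltr5 or "-" in ltr3:
        if len(ltr5) != len(ltr3):
            raise InputError("pre-aligned LTR rows must be equal length")
        aln = MultipleAlignment(member_ids=["ltr5", "ltr3"], rows=[ltr5, ltr3])
    elif len(ltr5) == len(ltr3) and not align:
        aln = MultipleAlignment(member_ids=["ltr5", "ltr3"], rows=[ltr5, ltr3])
    else:
        aln = global_align(ltr5, ltr3, ids=("ltr5", "ltr3"))
    mask = cpg_mask(aln, majority_consensus(aln))
    res = k2p_distance(aln.rows[0], aln.rows[1], mask)
    return AgeEstimate(element_id=element_id, method="ltr_pair",
                       divergence=res.d, age_myr=res.d / (2.0 * rate),
                       rate=rate, n_sites=res.n_sites, family_id=family_id)


def summarize_family(estimates: list[AgeEstimate]) -> FamilyAgeSummary:
    """Arithmetic mean and sample SD (n-1; 0 when n=1) of per-locus ages."""
    if not estimates:
        raise InputError("at least one estimate required")
    methods = {e.method for e in estimates}
    if len(methods) > 1:
        raise InputError(f"mixed methods in summary: {sorted(methods)}")
    families = {e.family_id for e in estimates}
    if len(families) > 1:
        raise InputError(f"mixed families in summary: {sorted(families)}")
    ages = np.array([e.age_myr for e in estimates], dtype=float)
    sd = float(ages.std(ddof=1)) if ages.size > 1 else 0.0
    return FamilyAgeSummary(family_id=estimates[0].family_id,
                            method=methods.pop(), n=ages.size,
                            mean_age_myr=float(ages.mean()), sd_age_myr=sd)
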