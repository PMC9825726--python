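"""Synthetic provirus endogenization simulator.

Builds ancestral provirus templates (LTR - PBS - gag/pro/pol/env - LTR),
evolves them forward in time under a Kimura two-parameter substitution
process with optional CpG transition hypermutability, and implants the
evolved elements into a random host genome with target-site duplications,
emitting a ground-truth table for downstream benchmarking.

Time is measured in million years (Myr); the substitution rate is per
nucleotide per Myr. Both LTR copies of an implanted provirus start
character-identical and diverge independently, which is the premise of
LTR-pair molecular-clock dating. The default simulator introduces
substitutions only (no indels), so positional homology between an evolved
element and its template is exact.
"""
from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._seq import decode, encode, random_sequence, revcomp
from .errors import FormatError, InputError, PlacementError

GENE_ORDER = ("gag", "pro", "pol", "env")
PBS_LENGTH = 18

# code transition partner: A<->G, C<->T
_TS = np.array([2, 3, 0, 1], dtype=np.uint8)
# the two transversion targets per base code
_TV1 = np.array([1, 0, 1, 0], dtype=np.uint8)
_TV2 = np.array([3, 2, 3, 2], dtype=np.uint8)

# sense codons that keep a reading frame open (no TAA/TAG/TGA)
_STOPS = {"TAA", "TAG", "TGA"}
_SENSE_CODONS = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"
                 if a + b + c not in _STOPS]


@dataclass(frozen=True)
class EvolutionParams:
    """Parameters of the per-site substitution process.

    rate
        Total substitution rate per site per Myr (default 0.0017, the
        mouse lemur germline rate used for all dating).
    kappa
        Transition/transversion rate ratio (alpha/beta); kappa = 2 means a
        transition is as likely as the two transversions combined.
    cpg_multiplier
        Multiplicative factor applied to the *transition* rate at sites
        currently inside a CpG dinucleotide; 1 disables hypermutability.
    """

    rate: float = 0.0017
    kappa: float = 2.0
    cpg_multiplier: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rate <= 0:
            raise InputError("rate must be > 0")
        if self.kappa <= 0:
            raise InputError("kappa must be > 0")
        if self.cpg_multiplier < 1:
            raise InputError("cpg_multiplier must be >= 1")

    @property
    def beta(self) -> float:
        """Per-target transversion rate; total rate = alpha + 2*beta."""
        return self.rate / (self.kappa + 2.0)

    @property
    def alpha(self) -> float:
        """Transition rate."""
        return self.kappa * self.rate / (self.kappa + 2.0)


@dataclass(frozen=True)
class ProvirusTemplate:
    """Ancestral full-length element used both to simulate and as reference.

    ``internal`` is the region between the two identical LTR copies; its
    first 18 nt are the primer binding site (PBS), followed by the gene
    regions annotated in ``genes`` (intervals relative to ``internal``,
    0-based half-open).
    """

    family_id: str
    ltr: str
    internal: str
    genes: dict[str, tuple[int, int]]
    pbs: str
    genus: str = "gamma"
    element_type: str = "provirus"
    donor_family: str | None = None
    donor_interval: tuple[int, int] | None = None

    @property
    def sequence(self) -> str:
        return self.ltr + self.internal + self.ltr

    @property
    def l_ltr(self) -> int:
        return len(self.ltr)

    def __len__(self) -> int:
        return 2 * len(self.ltr) + len(self.internal)

    def gene_sequence(self, gene: str) -> str:
        start, end = self.genes[gene]
        return self.internal[start:end]


@dataclass(frozen=True)
class InsertionSpec:
    """How many copies of a family to implant, at what age, as what."""

    family_id: str
    age_myr: float
    element_type: str = "provirus"
    count: int = 1
    tsd_length: int | None = None  # None: draw uniformly in [4, 6]

    def __post_init__(self) -> None:
        if self.age_myr < 0:
            raise InputError("age_myr must be >= 0")
        if self.count < 1:
            raise InputError("count must be >= 1")
        if self.element_type not in ("provirus", "solo_ltr", "recombinant"):
            raise InputError(f"unknown element_type {self.element_type!r}")
        if self.tsd_length is not None and not 4 <= self.tsd_length <= 6:
            raise InputError("tsd_length must be in [4, 6]")


@dataclass(frozen=True)
class TruthRecord:
    element_id: str
    family_id: str
    scaffold: str
    start: int  # 0-based, half-open; element only, TSD excluded
    end: int
    strand: str
    element_type: str
    age_myr: float
    tsd: str


@dataclass
class TruthTable:
    records: list[TruthRecord] = field(default_factory=list)

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([dataclasses.asdict(r) for r in self.records])

    def write_bed(self, path: str | os.PathLike) -> None:
        """BED6+3: chrom start end name score strand family type age (tsd in col 10)."""
        with open(path, "w") as fh:
            for r in self.records:
                fh.write("\t".join([
                    r.scaffold, str(r.start), str(r.end), r.element_id, "0",
                    r.strand, r.family_id, r.element_type,
                    repr(r.age_myr), r.tsd or ".",
                ]) + "\n")

    @classmethod
    def read_bed(cls, path: str | os.PathLike) -> "TruthTable":
        records = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                if not line.strip():
                    continue
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 10:
                    raise FormatError(f"{path}: line {lineno}: expected 10 BED columns")
                records.append(TruthRecord(
                    element_id=parts[3], family_id=parts[6], scaffold=parts[0],
                    start=int(parts[1]), end=int(parts[2]), strand=parts[5],
                    element_type=parts[7], age_myr=float(parts[8]),
                    tsd="" if parts[9] == "." else parts[9]))
        return cls(records)


def _codon_fill(length: int, rng: np.random.Generator) -> str:
    """ATG followed by random sense codons, truncated to ``length`` nt."""
    n_codons = max(0, -(-length // 3) - 1)
    idx = rng.integers(0, len(_SENSE_CODONS), size=n_codons)
    seq = "ATG" + "".join(_SENSE_CODONS[i] for i in idx)
    return seq[:length]


def _cpg_positions(seq: str) -> list[int]:
    return [i for i in range(len(seq) - 1) if seq[i] == "C" and seq[i + 1] == "G"]


def _adjust_cpg_density(seq: str, density: float, rng: np.random.Generator,
                        protected: Sequence[tuple[int, int]]) -> str:
    """Plant or remove CG dinucleotides so that ~``density`` of positions
    sit inside a CpG.

    Removal replaces the G with an A; planting writes "CG". Neither edit can
    create a premature stop codon in any reading frame (no stop codon pairs
    C with a following G, or has C at all), so gene regions stay open.
    ``protected`` intervals (PBS, gene start codons) are never edited.
    """
    chars = list(seq)
    is_protected = np.zeros(len(seq), dtype=bool)
    for a, b in protected:
        is_protected[a:b] = True
    target = int(round(density * len(seq) / 2.0))
    current = _cpg_positions(seq)
    editable = [i for i in current if not is_protected[i] and not is_protected[i + 1]]
    if len(current) > target:
        n_remove = len(current) - target
        if n_remove > len(editable):
            raise InputError("cannot reach requested cpg_density: too many protected CpGs")
        for i in rng.permutation(len(editable))[:n_remove]:
            chars[editable[i] + 1] = "A"
    elif len(current) < target:
        need = target - len(current)
        occupied = np.zeros(len(seq), dtype=bool)
        for i in current:
            occupied[max(0, i - 1):i + 3] = True
        candidates = [i for i in range(len(seq) - 1)
                      if not occupied[i] and not occupied[i + 1]
                      and not is_protected[i] and not is_protected[i + 1]]
        if need > len(candidates):
            raise InputError("cannot reach requested cpg_density: sequence too constrained")
        for i in rng.permutation(len(candidates))[:need]:
            pos = candidates[i]
            chars[pos], chars[pos + 1] = "C", "G"
    return "".join(chars)


def make_provirus_template(family_id: str, l_ltr: int,
                           gene_lengths: Mapping[str, int],
                           pbs_source_trna: str, seed: int,
                           genus: str = "gamma",
                           cpg_density: float | None = None) -> ProvirusTemplate:
    """Construct an ancestral provirus template.

    The PBS is the reverse complement of the 3'-terminal 18 nt of the
    priming tRNA, placed immediately 3' of the 5' LTR. Gene regions are
    stop-free in frame 0 and begin with ATG. Total element length is
    ``2*l_ltr + 18 + sum(gene_lengths)``.
    """
    if l_ltr < 100:
        raise InputError("l_ltr must be >= 100")
    if len(pbs_source_trna) < PBS_LENGTH:
        raise InputError(f"pbs_source_trna must be >= {PBS_LENGTH} nt")
    for g, ln in gene_lengths.items():
        if ln <= 0:
            raise InputError(f"gene {g!r} length must be positive")
    rng = np.random.default_rng(seed)
    ltr = random_sequence(l_ltr, rng)
    pbs = revcomp(pbs_source_trna[-PBS_LENGTH:].upper())
    parts = [pbs]
    genes: dict[str, tuple[int, int]] = {}
    pos = PBS_LENGTH
    ordered = [g for g in GENE_ORDER if g in gene_lengths]
    ordered += [g for g in gene_lengths if g not in GENE_ORDER]
    for g in ordered:
        ln = gene_lengths[g]
        parts.append(_codon_fill(ln, rng))
        genes[g] = (pos, pos + ln)
        pos += ln
    internal = "".join(parts)
    if cpg_density is not None:
        protected = [(0, PBS_LENGTH)] + [(s, s + 3) for s, _ in genes.values()]
        internal = _adjust_cpg_density(internal, cpg_density, rng, protected)
        ltr = _adjust_cpg_density(ltr, cpg_density, rng, [])
    return ProvirusTemplate(family_id=family_id, ltr=ltr, internal=internal,
                            genes=genes, pbs=pbs, genus=genus)


def _cpg_flags(codes: np.ndarray) -> np.ndarray:
    """True where a site is the C or the G of a CG dinucleotide."""
    flags = np.zeros(codes.size, dtype=bool)
    cg = (codes[:-1] == 1) & (codes[1:] == 2)
    flags[:-1] |= cg
    flags[1:] |= cg
    return flags


def _evolve_iid(codes: np.ndarray, age_myr: float, params: EvolutionParams,
                rng: np.random.Generator) -> np.ndarray:
    """Context-free K2P jump chain: per-site Poisson event counts, then
    sequential jumps (transition w.p. kappa/(kappa+2))."""
    p_ts = params.kappa / (params.kappa + 2.0)
    n_events = rng.poisson(params.rate * age_myr, size=codes.size)
    out = codes.copy()
    rounds = int(n_events.max()) if codes.size else 0
    for r in range(rounds):
        idx = np.nonzero(n_events > r)[0]
        cur = out[idx]
        is_ts = rng.random(idx.size) < p_ts
        pick2 = rng.random(idx.size) < 0.5
        out[idx] = np.where(is_ts, _TS[cur], np.where(pick2, _TV1[cur], _TV2[cur]))
    return out


def _evolve_cpg(codes: np.ndarray, age_myr: float, params: EvolutionParams,
                rng: np.random.Generator) -> np.ndarray:
    """Gillespie simulation with CpG-context-dependent transition rates.

    The CpG context is evaluated on the *current* sequence at each event,
    so hypermutability is ongoing and self-extinguishing (the first hit at
    a CpG usually destroys the context).
    """
    out = codes.copy()
    n = out.size
    alpha, beta = params.alpha, params.beta
    mult = params.cpg_multiplier
    flags = _cpg_flags(out)
    ts_rate = np.where(flags, alpha * mult, alpha)
    site_rate = ts_rate + 2.0 * beta
    t = 0.0
    while True:
        total = site_rate.sum()
        t += rng.exponential(1.0 / total)
        if t > age_myr:
            break
        cum = np.cumsum(site_rate)
        i = int(np.searchsorted(cum, rng.random() * total, side="right"))
        i = min(i, n - 1)
        if rng.random() < ts_rate[i] / site_rate[i]:
            out[i] = _TS[out[i]]
        else:
            out[i] = _TV1[out[i]] if rng.random() < 0.5 else _TV2[out[i]]
        lo, hi = max(0, i - 1), min(n, i + 2)
        seg = out[max(0, lo - 1):min(n, hi + 1)]
        seg_flags = _cpg_flags(seg)
        off = max(0, lo - 1)
        for j in range(lo, hi):
            flags[j] = seg_flags[j - off]
            ts_rate[j] = alpha * mult if flags[j] else alpha
            site_rate[j] = ts_rate[j] + 2.0 * beta
    return out


def evolve_sequence(seq: str, age_myr: float, params: EvolutionParams,
                    rng: np.random.Generator | None = None) -> str:
    """Evolve a sequence for ``age_myr`` under the K2P substitution process.

    Substitutions only; the returned sequence has the same length. With
    ``rng`` omitted a fresh generator is seeded from ``params.seed``, so two
    calls with the same arguments are identical.
    """
    if not seq:
        raise InputError("seq must be non-empty")
    if age_myr < 0:
        raise InputError("age_myr must be >= 0")
    codes = encode(seq)
    if np.any(codes > 3):
        raise InputError("seq must contain only A/C/G/T")
    if rng is None:
        rng = np.random.default_rng(params.seed)
    if age_myr == 0:
        return seq
    if params.cpg_multiplier == 1.0:
        out = _evolve_iid(codes, age_myr, params, rng)
    else:
        out = _evolve_cpg(codes, age_myr, params, rng)
    return decode(out)


def derive_solo_ltr(template: ProvirusTemplate, age_myr: float,
                    params: EvolutionParams,
                    rng: np.random.Generator | None = None) -> tuple[str, dict]:
    """A single evolved LTR copy, the relic of LTR-LTR ectopic recombination.

    Returns ``(sequence, record)`` where record carries the element type and
    age; the sequence length always equals the template LTR length.
    """
    seq = evolve_sequence(template.ltr, age_myr, params, rng=rng)
    record = {"family_id": template.family_id, "element_type": "solo_ltr",
              "age_myr": age_myr}
    return seq, record


def make_recombinant(template_a: ProvirusTemplate, template_b: ProvirusTemplate,
                     breakpoint_interval: tuple[int, int],
                     family_id: str | None = None) -> ProvirusTemplate:
    """Chimeric template: ``template_a`` outside the interval, ``template_b``
    inside it (full-element coordinates, 0-based half-open).

    Unless the interval is empty or covers the whole element, it must lie
    strictly between the LTRs of ``template_a`` so the chimera keeps
    identical LTR copies.
    """
    b1, b2 = breakpoint_interval
    a_seq, b_seq = template_a.sequence, template_b.sequence
    if b1 < 0 or b2 < b1 or b2 > len(a_seq) or b2 > len(b_seq):
        raise InputError("breakpoint interval outside both templates' ranges")
    name = family_id or f"rec{template_a.family_id}"
    if b1 == b2:
        return dataclasses.replace(template_a, family_id=name,
                                   element_type="recombinant",
                                   donor_family=template_b.family_id,
                                   donor_interval=(b1, b2))
    if b1 == 0 and b2 == len(a_seq) == len(b_seq):
        return dataclasses.replace(template_b, family_id=name,
                                   element_type="recombinant",
                                   donor_family=template_b.family_id,
                                   donor_interval=(b1, b2))
    l = template_a.l_ltr
    if b1 < l or b2 > len(a_seq) - l:
        raise InputError("breakpoint interval must lie between the LTRs "
                         "(or cover the whole element exactly)")
    chimera = a_seq[:b1] + b_seq[b1:b2] + a_seq[b2:]
    internal = chimera[l:len(chimera) - l]
    return ProvirusTemplate(family_id=name, ltr=template_a.ltr,
                            internal=internal, genes=dict(template_a.genes),
                            pbs=template_a.pbs, genus=template_a.genus,
                            element_type="recombinant",
                            donor_family=template_b.family_id,
                            donor_interval=(b1, b2))


def implant_elements(host_length: int, n_scaffolds: int,
                     templates: Mapping[str, ProvirusTemplate],
                     specs: Sequence[InsertionSpec],
                     params: EvolutionParams,
                     min_gap: int = 1000,
                     max_retries: int = 200) -> tuple[dict[str, str], TruthTable]:
    """Implant evolved elements into a random host genome.

    The background is i.i.d. uniform A/C/G/T. Each element is the template
    evolved for its age, inserted on a random strand with a duplicated
    target site of 4-6 bp on both sides (the TSD itself also accrues
    substitutions with age). Implants never overlap and keep ``min_gap``
    background nucleotides between neighbours. Returns the genome as an
    {id: sequence} dict plus the exact truth table.
    """
    for spec in specs:
        if spec.family_id not in templates:
            raise InputError(f"spec references unknown template {spec.family_id!r}")
    total_implant = sum(
        (len(templates[s.family_id]) if s.element_type != "solo_ltr"
         else templates[s.family_id].l_ltr) * s.count for s in specs)
    if total_implant >= host_length:
        raise InputError("total implant length must be < host_length")

    root = np.random.default_rng(params.seed)
    place_rng, evo_rng = root.spawn(2)

    scaffold_len = host_length // n_scaffolds
    lengths = [scaffold_len] * (n_scaffolds - 1)
    lengths.append(host_length - scaffold_len * (n_scaffolds - 1))
    names = [f"scaffold_{i + 1}" for i in range(n_scaffolds)]
    backgrounds = {n: random_sequence(ln, place_rng) for n, ln in zip(names, lengths)}

    # plan all insertions first, then splice scaffold by scaffold
    plans: dict[str, list[tuple[int, InsertionSpec, str, int]]] = {n: [] for n in names}
    counter = 0
    for spec in specs:
        for _ in range(spec.count):
            counter += 1
            scaf = names[place_rng.integers(0, n_scaffolds)]
            tsd_len = (spec.tsd_length if spec.tsd_length is not None
                       else int(place_rng.integers(4, 7)))
            for attempt in range(max_retries):
                anchor = int(place_rng.integers(tsd_len + min_gap,
                                                len(backgrounds[scaf]) - tsd_len - min_gap))
                ok = all(abs(anchor - a) >= min_gap + tsd_len
                         for a, *_ in plans[scaf])
                if ok:
                    plans[scaf].append((anchor, spec, f"elem_{counter:04d}", tsd_len))
                    break
            else:
                raise PlacementError(
                    f"could not place element {counter} on {scaf} "
                    f"after {max_retries} retries")

    genome: dict[str, str] = {}
    truth = TruthTable()
    for scaf in names:
        background = backgrounds[scaf]
        pieces: list[str] = []
        cursor = 0
        offset = 0
        records_here: list[TruthRecord] = []
        for anchor, spec, elem_id, tsd_len in sorted(plans[scaf]):
            template = templates[spec.family_id]
            if spec.element_type == "solo_ltr":
                elem = evolve_sequence(template.ltr, spec.age_myr, params, rng=evo_rng)
            else:
                elem = evolve_sequence(template.sequence, spec.age_myr, params,
                                       rng=evo_rng)
            strand = "+" if place_rng.random() < 0.5 else "-"
            if strand == "-":
                elem = revcomp(elem)
            tsd = background[anchor:anchor + tsd_len]
            tsd_left = (evolve_sequence(tsd, spec.age_myr, params, rng=evo_rng)
                        if spec.age_myr > 0 else tsd)
            tsd_right = (evolve_sequence(tsd, spec.age_myr, params, rng=evo_rng)
                         if spec.age_myr > 0 else tsd)
            pieces.append(background[cursor:anchor])
            pieces.append(tsd_left + elem + tsd_right)
            start = offset + anchor + tsd_len
            etype = (template.element_type if spec.element_type == "provirus"
                     else spec.element_type)
            records_here.append(TruthRecord(
                element_id=elem_id, family_id=spec.family_id, scaffold=scaf,
                start=start, end=start + len(elem), strand=strand,
                element_type=etype, age_myr=spec.age_myr, tsd=tsd))
            # splice consumed background[anchor:anchor+tsd_len] and replaced it
            # with tsd_left + elem + tsd_right
            cursor = anchor + tsd_len
            offset += tsd_len + len(elem)
        pieces.append(background[cursor:])
        genome[scaf] = "".join(pieces)
        truth.records.extend(records_here)
    truth.records.sort(key=lambda r: (r.scaffold, r.start))
    return genome, truth
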