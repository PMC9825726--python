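# Methods

## The model

An endogenous retrovirus (ERV) locus is treated as a neutrally evolving
host sequence from the moment of germline integration. The canonical
provirus is 5′LTR – PBS – gag – pro – pol – env – 3′LTR, flanked by a 4–6
bp target-site duplication (TSD); the two LTR copies are character-
identical at integration. Three clock readings follow:

* the divergence `D` of a locus from the family consensus (a proxy for
  the ancestral state) accrues along a single lineage, so `T = D/μ`;
* the divergence between a provirus's own 5′ and 3′ LTR accrues along two
  independent lineages from an identical start, so `T = D/(2μ)`.

Divergences are Kimura 2-parameter (K2P) distances,
`D = −½ ln(1−2P−Q) − ¼ ln(1−2Q)`, with transitions (A↔G, C↔T) and
transversions counted over usable sites only: columns holding a gap, an
ambiguity, or a CpG mask entry are excluded pairwise. CpG dinucleotides
are excluded because deamination of 5-methyl-cytosine elevates their
transition rate far above the clock rate. The rate constant `μ` defaults
to 0.0017 substitutions/nt/Myr, the mouse lemur germline rate used
throughout; it is a configuration value, not a fitted quantity.

Assumptions: a single constant host rate on all lineages, no gene
conversion between LTRs, and a consensus close to the true ancestor.
Dispersion is reported only as the SD of per-locus ages within a family.

### Design choices in the clock

* **Consensus methods use `T = D/μ` by default.** The divisor 2 applies
  when both compared sequences diverge from a common ancestor; a
  majority-rule consensus approximates the ancestor itself, so a locus's
  divergence from it is single-lineage. This is the only reading under
  which the three methods agree on simulated data (the LTR-pair method,
  whose divisor is unambiguous, recovers the same ages). A
  `consensus_age_denominator: 2` switch exposes the alternative reading.
* **The CpG mask is defined on the consensus** (or, for the LTR pair, on
  the pairwise consensus of the two rows): a reference-defined mask is
  reproducible and symmetric in the pair case. CpG dinucleotides that
  arise *after* integration in individual lineages are not masked; the
  simulation experiment below bounds the resulting bias.
* **Saturation (`1−2P−Q ≤ 0` or `1−2Q ≤ 0`) and empty site sets raise
  errors** and the affected locus is skipped with a log message, never
  clamped — clamping would bias family means downward-censored data
  toward the cap.
* Ages are kept at full precision internally; the `60 (±28)`-style
  rounding is display-only.

## Majority-rule consensus

Per column, A/C/G/T and gap are counted (N is ignored); the plurality
symbol wins, base ties break in the fixed order A<C<G<T, and a gap loses
every tie. Columns whose winner is a gap are omitted from the consensus
string but retained in the column bookkeeping, so alignment columns and
consensus positions remain mutually mappable (this is what the CpG mask
and the `as_row` comparison rely on). Plurality rather than strict
majority means no ambiguity codes are ever emitted — downstream K2P
would treat them as missing anyway — and gap-plurality omission keeps
the consensus usable as an ungapped search query and clock reference.

## Mining

The built-in search (`naive_search`) is exact k-mer seeding (default
k = 12) on both strands, ungapped X-drop extension (match +1, mismatch
−2, X = 20), per-diagonal deduplication, and a Karlin–Altschul-style
expectation cutoff (`m·n·2^−score ≤ 10`) that suppresses chance seed
matches on genome-scale subjects. It is a deliberately simple stand-in
for an external aligner — adequate for ≤20% divergence and indel-free
homology — and externally produced 12-column tabular hit files are
accepted on equal terms. Hits are merged into clusters per scaffold and
strand when gaps are at most `max_gap` (default 2× the LTR reference
length: bridges internal drop-outs without fusing neighbouring
elements); loci are extracted with ±10 kb flanks by default, clamped at
scaffold edges and reverse-complemented to element-forward orientation.

LTR detection matches the family LTR reference inside the locus and
projects each match along its diagonal to the full reference span, so
X-drop fraying at diverged termini does not truncate the annotated LTR.
Classification: a locus is a *provirus* when some candidate LTR pair
(same orientation, ≥1 kb apart) brackets a region matching ≥30% of the
internal reference — among such pairs the one with the best internal
coverage wins, ties going to the pair whose spacing best fits the
internal reference length, which prevents pairing a solo LTR with a
neighbouring element's LTR; a *solo LTR* when a single LTR has no
internal match within 1 kb on either side; otherwise a *fragment*.
Overlapping clusters found by different family queries are resolved
greedily by bitscore, then leftmost coordinate, then scaffold id.
Coordinates are 0-based half-open internally; the hit format's 1-based
inclusive coordinates are converted only at the I/O boundary.

## Recombination scan

A query row is compared with each candidate donor row of one alignment
in windows of 200 columns stepped by 50 (enough to resolve a ~1.6 kb
donor segment with ≥8 internal windows). The window statistic is the
identity fraction over shared unambiguous sites; windows with fewer than
10 usable sites are flagged missing rather than scored 0. The nearest
donor per window is the arg-max (ties to input order); a crossover is
called when the challenger stays nearest by a margin of ≥0.05 for ≥3
consecutive windows (hysteresis against jitter between near-equidistant
donors). The reported breakpoint interval spans from the start of the
last window won by the old donor to the end of the first window of the
new donor's run, and is given both in alignment columns and in ungapped
query coordinates.

## Annotation

* **ORF scan**: each annotated gene region is translated in the three
  forward frames; the longest stop-free stretch over the gene length
  gives the ORF fraction, and a gene is *intact* at fraction ≥0.9 with
  an ATG in the winning frame within the first 10% of the gene. This is
  an intentionally coarse coding-potential measure, not protein-domain
  annotation.
* **PBS**: the 18-nt windows starting within 30 nt downstream of the 5′
  LTR end are compared with the reverse complement of each library
  tRNA's 3′-terminal 18 nt; best match with ≤3 mismatches wins, ties by
  library order. The bundled tRNA library is synthetic (deterministic
  random 76-mers labelled tRNA-Pro/Ile/Phe/Lys/…) and serves only to
  define reproducible PBS sequences.
* **Presence screening**: a family is *present* in a genome when at
  least one hit reaches 60% identity over 300 bp (declared defaults);
  the reported identity is that of the top-bitscore qualifying hit, so
  the call is monotone in the threshold.

## The simulator

`simulate` builds ancestral templates — random LTR, PBS equal to the
reverse complement of the priming tRNA's 3′ 18-mer, genes as ATG plus
random sense codons (stop-free in frame 0) — and evolves sequences
forward under a continuous-time K2P process: total rate `μ` per site,
transition/transversion rate ratio κ (default 2), substitutions only.
With `cpg_multiplier > 1` the transition rate at sites currently inside
a CpG is multiplied by that factor, with the context re-evaluated on the
mutating sequence at every event (Gillespie simulation), so
hypermutability is ongoing and self-extinguishing — matching the reason
extant-alignment CpG masking exists. Template CpG density is
controllable (planting or removing CG dinucleotides; the edits provably
cannot create stop codons or touch the PBS or gene start codons):
uniform random sequence carries ~12.5% of positions in CpGs, so reaching
a genome-like 8% means depletion.

Implantation places elements at uniform positions with a minimum
background gap, duplicates the 4–6 bp target site on both sides (both
TSD copies evolve with the element's age), picks strands at random, and
emits the genome as 80-column FASTA plus a BED6+3 truth table (0-based
half-open element coordinates, TSDs outside the interval, family /
element type / age in the extra columns). The background is i.i.d.
uniform A/C/G/T to avoid accidental homology with templates.

What the simulator does **not** model — and hence what green tests do
not certify about real data: indels (positional homology stays exact, so
the star aligner is never stressed), nested insertions, segmental
duplications or repeat context, polymorphic insertions and selection,
lineage rate variation, and LTR gene conversion. Fragmentary loci exist
in real screens; here they arise only as classification edge cases.

## Benchmark scenarios (problem sizes)

* **Three-family recovery**: 3 unrelated families (LTRs 480–520 bp,
  full elements ~6.8–7.4 kb), 50 proviruses + 30 solo LTRs each at 10,
  44 and 60 Myr, in a 6 Mb / 6-scaffold host with ≥2.5 kb implant gaps;
  extraction flanks of 2 kb (synthetic scaffolds are element-dense, and
  clusters already span complete elements, so real-data 10 kb flanks
  would only pull neighbours into each locus). The full mine →
  consensus → date run recovers each family's mean age within a few
  percent for all three methods and classifies every implanted element
  correctly.
* **CpG masking**: the 60-Myr family regime with `cpg_multiplier = 10`
  and 8% CpG density, 50 LTR copies dated against their consensus.
  Unmasked dating overshoots by ~25%; masked dating stays within ~4% of
  truth. The small residual excess comes from post-integration CpGs,
  which no consensus-defined mask can see.
* **Recombination**: 20 gamma-backbone chimeras with beta-donor segments
  of 1–2.5 kb placed uniformly in the internal region (segments shorter
  than ~4 windows cannot sustain the detector's hysteresis — the scale
  is chosen to resolve the ~1.6 kb segments of interest), ages 5–30 Myr,
  plus 100 non-recombinant controls.

`scripts/acceptance.py` recomputes all of these from a single seed.

## Numerical and degenerate-input conventions

Determinism everywhere under a fixed seed (NumPy PCG64; child generators
spawned for placement vs. evolution). Pairwise alignment is Biopython's
`PairwiseAligner` (global, match 1, mismatch −1, gap open −4, extend −1)
taking the first reported optimal traceback. Star alignment merges
member↔reference pairwise alignments on reference coordinates with
member-specific insertions in shared, left-justified slots. Equal-length
ungapped LTR pairs are compared position-wise (they come projected onto
a common reference frame); unequal lengths are aligned first, and
`align=True` forces alignment otherwise. All-N or all-gap alignment
columns are omitted from consensuses; zero-column alignments, empty
sequences, tRNAs shorter than 18 nt, negative ages and non-positive
rates are rejected with input errors.

## Known limitations

The star aligner is inadequate beyond ~20% divergence or for heavily
indel-fragmented loci — use an external multiple aligner and feed the
aligned FASTA in. The ungapped hit search will split hits across indels
rather than gap over them. Family age SDs understate uncertainty when
loci share post-integration history (e.g. segmental duplications). The
presence screen reports best-hit identity, which is not the same
quantity as an average pairwise identity over orthologous loci.
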