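"""Benchmark scenarios: the simulated study conditions used to validate the
pipeline, defined once so tests, scripts and documentation agree.

The headline scenario implants three unrelated ERV families (50 proviruses
plus 30 solo LTRs each) at 10, 44 and 60 Myr into a 6 Mb host, at the
substitution rate (0.0017/nt/Myr) and transition bias (kappa = 2) used for
dating. Companion experiments probe CpG-masking efficacy under 10x CpG
transition hypermutability and breakpoint recovery for inter-family
recombinants.
"""
from __future__ import annotations

import numpy as np

from .clock import age_from_consensus, k2p_distance
from .consensus import MultipleAlignment, majority_consensus
from .pipeline import RunConfig, build_templates, synthetic_trna_library
from .recombination import detect_crossovers, sliding_similarity
from .simulate import (EvolutionParams, TruthTable, evolve_sequence,
                       make_provirus_template, make_recombinant)

BENCHMARK_AGES = (10.0, 44.0, 60.0)
BENCHMARK_RATE = 0.0017


def three_family_config(seed: int, out: str = "benchmark_run",
                        n_proviruses: int = 50, n_solo: int = 30) -> RunConfig:
    """The three-family ground-truth scenario.

    Scaffolds are element-dense compared with a real genome, so extraction
    flanks of 2 kb (enough to span any clipped element edge plus TSD) and a
    2.5 kb implant gap keep neighbouring elements out of each other's loci.
    """
    families = [
        {"family_id": "ERV1", "l_ltr": 500, "genus": "gamma",
         "pbs_trna": "tRNA-Pro"},
        {"family_id": "ERV2", "l_ltr": 480, "genus": "gamma",
         "pbs_trna": "tRNA-Pro",
         "gene_lengths": {"gag": 1450, "pro": 850, "pol": 2300, "env": 1250}},
        {"family_id": "ERV3", "l_ltr": 520, "genus": "beta",
         "pbs_trna": "tRNA-Lys",
         "gene_lengths": {"gag": 1550, "pro": 950, "pol": 2500, "env": 1350}},
    ]
    insertions = []
    for fam, age in zip(families, BENCHMARK_AGES):
        insertions.append({"family_id": fam["family_id"], "age_myr": age,
                           "element_type": "provirus", "count": n_proviruses})
        insertions.append({"family_id": fam["family_id"], "age_myr": age,
                           "element_type": "solo_ltr", "count": n_solo})
    return RunConfig(seed=seed, rate=BENCHMARK_RATE, flank=2000, out=out,
                     simulate={"host_length": 6_000_000, "n_scaffolds": 6,
                               "min_gap": 2500, "families": families,
                               "insertions": insertions})


def score_classification(truth: TruthTable, families: dict) -> dict[str, float]:
    """Recall/precision of provirus and solo-LTR calls against the truth table.

    A call matches a truth record when its originating cluster overlaps the
    record's interval on the same scaffold.
    """
    calls = []
    for fam in families.values():
        for classified, _structure in fam.loci:
            locus = classified.locus
            calls.append((locus.scaffold, locus.core[0], locus.core[1],
                          classified.classification))
    scores = {}
    for etype in ("provirus", "solo_ltr"):
        truth_recs = [r for r in truth if r.element_type == etype]
        n_called = sum(1 for c in calls if c[3] == etype)
        matched = 0
        for r in truth_recs:
            if any(c[0] == r.scaffold and c[1] < r.end and r.start < c[2]
                   and c[3] == etype for c in calls):
                matched += 1
        scores[f"{etype}_recall"] = matched / len(truth_recs) if truth_recs else 1.0
        scores[f"{etype}_precision"] = matched / n_called if n_called else 1.0
    return scores


def consensus_accuracy(families: dict, cfg: RunConfig) -> float:
    """Fraction of template sites recovered by the family consensuses
    (LTR and internal pooled over all families)."""
    templates = build_templates(cfg)
    total = same = 0
    for fid, fam in families.items():
        t = templates[fid]
        for cons_seq, truth_seq in ((fam.ltr_consensus, t.ltr),
                                    (fam.internal_consensus, t.internal)):
            if cons_seq is None:
                continue
            s = cons_seq.sequence
            n = min(len(s), len(truth_seq))
            same += sum(1 for a, b in zip(s[:n], truth_seq[:n]) if a == b)
            total += max(len(s), len(truth_seq))
    return same / total if total else 0.0


def cpg_masking_experiment(seed: int, n_members: int = 50, age_myr: float = 60.0,
                           cpg_multiplier: float = 10.0,
                           cpg_density: float = 0.08,
                           rate: float = BENCHMARK_RATE) -> dict[str, float]:
    """Date one LTR family evolved under CpG transition hypermutability,
    with and without the CpG column mask.

    Returns the mean recovered age for both treatments; truth is ``age_myr``.
    """
    trnas = synthetic_trna_library()
    template = make_provirus_template(
        "CPG", 500, {"gag": 1500, "pro": 900, "pol": 2400, "env": 1300},
        trnas["tRNA-Pro"], seed=seed, cpg_density=cpg_density)
    params = EvolutionParams(rate=rate, kappa=2.0,
                             cpg_multiplier=cpg_multiplier, seed=seed)
    rng = np.random.default_rng(seed + 1)
    rows = [evolve_sequence(template.ltr, age_myr, params, rng=rng)
            for _ in range(n_members)]
    aln = MultipleAlignment(member_ids=[f"ltr_{i}" for i in range(n_members)],
                            rows=rows)
    cons = majority_consensus(aln)
    masked = age_from_consensus(aln, cons, rate=rate,
                                method_label="ltr_consensus")
    cons_row = cons.as_row()
    unmasked_ages = [k2p_distance(r, cons_row).d / rate for r in rows]
    return {"masked_mean_age_myr": float(np.mean([e.age_myr for e in masked])),
            "unmasked_mean_age_myr": float(np.mean(unmasked_ages)),
            "true_age_myr": age_myr,
            "n": n_members}


def recombination_experiment(seed: int, n_chimeras: int = 20,
                             n_controls: int = 100, max_age_myr: float = 30.0,
                             window: int = 200, step: int = 50
                             ) -> dict[str, float]:
    """Breakpoint recovery for inter-family chimeras plus a false-positive
    control on non-recombinant proviruses.

    Chimeric templates carry a donor segment of 1-2.5 kb placed uniformly in
    the internal region (segments shorter than ~4 windows cannot sustain the
    detector's hysteresis, matching the ~1.6 kb scale of interest). Returns
    the fraction of true breakpoints inside called intervals and the total
    number of events called on the controls.
    """
    trnas = synthetic_trna_library()
    gl = {"gag": 1500, "pro": 900, "pol": 2400, "env": 1500}
    A = make_provirus_template("GAMMA", 500, gl, trnas["tRNA-Pro"], seed=seed)
    B = make_provirus_template("BETA", 500, gl, trnas["tRNA-Lys"],
                               seed=seed + 1, genus="beta")
    rng = np.random.default_rng(seed + 2)
    params = EvolutionParams(rate=BENCHMARK_RATE, kappa=2.0, seed=seed)
    internal_lo, internal_hi = A.l_ltr, len(A) - A.l_ltr
    covered = 0
    total_bp = 0
    refs = {"A": A.sequence, "B": B.sequence}
    for _ in range(n_chimeras):
        seg = int(rng.integers(1000, 2501))
        b1 = int(rng.integers(internal_lo, internal_hi - seg))
        b2 = b1 + seg
        chim = make_recombinant(A, B, (b1, b2))
        age = float(rng.uniform(5.0, max_age_myr))
        q = evolve_sequence(chim.sequence, age, params, rng=rng)
        aln = MultipleAlignment(member_ids=["q", "A", "B"],
                                rows=[q, refs["A"], refs["B"]])
        events = detect_crossovers(sliding_similarity(aln, "q", ["A", "B"],
                                                      window=window, step=step))
        total_bp += 2
        for bp, before, inside in ((b1, "A", "B"), (b2, "B", "A")):
            if any(e.donor_before == before and e.donor_inside == inside
                   and e.breakpoint_start <= bp <= e.breakpoint_end
                   for e in events):
                covered += 1
    false_events = 0
    for _ in range(n_controls):
        age = float(rng.uniform(5.0, max_age_myr))
        q = evolve_sequence(A.sequence, age, params, rng=rng)
        aln = MultipleAlignment(member_ids=["q", "A", "B"],
                                rows=[q, refs["A"], refs["B"]])
        false_events += len(detect_crossovers(
            sliding_similarity(aln, "q", ["A", "B"], window=window, step=step)))
    return {"breakpoint_coverage": covered / total_bp,
            "n_true_breakpoints": total_bp,
            "false_events": float(false_events),
            "n_controls": n_controls}
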