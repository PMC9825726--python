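"""End-to-end orchestration: simulate -> mine -> consensus -> date
(-> recombination scan -> cross-genome screen), with a YAML run
configuration, per-stage artifacts, and a family-level summary report.

Artifacts are written under plain stage directories (``out/simulate``,
``out/mine``, ...) with a single JSON manifest capturing every parameter and
seed, so a run is reproducible from the manifest alone.
"""
from __future__ import annotations

import dataclasses
import difflib
import json
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .clock import (AgeEstimate, age_from_consensus, age_ltr_pair,
                    summarize_family)
from .consensus import (MultipleAlignment, majority_consensus, star_align,
                        write_aligned_fasta)
from .errors import InputError, StageError
from .io import read_fasta, write_fasta
from .mining import (GenomeIndex, classify_locus, detect_ltr_pair,
                     extract_locus, merge_hits, naive_search, write_hit_table)
from .recombination import detect_crossovers, sliding_similarity, write_profile
from .screen import screen_genome
from .simulate import (EvolutionParams, InsertionSpec, ProvirusTemplate,
                       implant_elements, make_provirus_template,
                       make_recombinant)

_TOP_KEYS = {"seed", "rate", "flank", "methods", "consensus_age_denominator",
             "window", "step", "kmer", "min_identity", "out", "simulate",
             "inputs", "recomb", "screen"}
_SIM_KEYS = {"host_length", "n_scaffolds", "kappa", "cpg_multiplier",
             "min_gap", "families", "insertions", "recombinants"}
_FAMILY_KEYS = {"family_id", "l_ltr", "gene_lengths", "genus", "cpg_density",
                "pbs_trna"}
_INSERTION_KEYS = {"family_id", "age_myr", "element_type", "count", "tsd_length"}
_INPUT_KEYS = {"genome", "queries", "ltr_refs", "internal_refs", "hits"}

DEFAULT_GENE_LENGTHS = {"gag": 1500, "pro": 900, "pol": 2400, "env": 1300}
ALL_METHODS = ("ltr_consensus", "gene_consensus", "ltr_pair")


def synthetic_trna_library(seed: int = 7) -> dict[str, str]:
    """A small deterministic library of synthetic tRNA stand-in sequences.

    These are random 76-nt sequences labelled with the amino-acid names used
    for PBS assignment; they are synthetic placeholders, not real tRNA
    genes, and serve only to define reproducible PBS sequences.
    """
    from ._seq import random_sequence
    rng = np.random.default_rng(seed)
    return {name: random_sequence(76, rng)
            for name in ("tRNA-Pro", "tRNA-Ile", "tRNA-Phe", "tRNA-Lys",
                         "tRNA-Trp", "tRNA-Gly")}


@dataclass
class RunConfig:
    seed: int = 0
    rate: float = 0.0017
    flank: int = 10_000
    methods: list[str] = field(default_factory=lambda: list(ALL_METHODS))
    consensus_age_denominator: int = 1
    window: int = 200
    step: int = 50
    kmer: int = 12
    min_identity: float = 60.0
    out: str = "retroclock_run"
    simulate: dict | None = None
    inputs: dict | None = None
    recomb: dict | None = None
    screen: dict | None = None


def _check_keys(mapping: dict, allowed: set[str], where: str) -> None:
    for key in mapping:
        if key not in allowed:
            hint = difflib.get_close_matches(key, allowed, n=1)
            suffix = f" (did you mean {hint[0]!r}?)" if hint else ""
            raise InputError(f"unknown key {key!r} in {where}{suffix}")


def validate_config(path: str | os.PathLike) -> RunConfig:
    """Load, schema-check and default-fill a YAML run configuration."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise InputError("config must be a YAML mapping")
    _check_keys(raw, _TOP_KEYS, "config")
    cfg = RunConfig(**{k: v for k, v in raw.items() if v is not None})
    if cfg.rate <= 0:
        raise InputError("rate must be > 0")
    if cfg.flank < 0:
        raise InputError("flank must be >= 0")
    for m in cfg.methods:
        if m not in ALL_METHODS:
            raise InputError(f"unknown dating method {m!r}")
    if cfg.consensus_age_denominator not in (1, 2):
        raise InputError("consensus_age_denominator must be 1 or 2")
    if cfg.simulate is None and cfg.inputs is None:
        raise InputError("config needs either a 'simulate' scenario or 'inputs'")
    if cfg.simulate is not None:
        _check_keys(cfg.simulate, _SIM_KEYS, "simulate")
        if "host_length" not in cfg.simulate:
            raise InputError("simulate: missing required key 'host_length'")
        if "families" not in cfg.simulate or not cfg.simulate["families"]:
            raise InputError("simulate: missing required key 'families'")
        for fam in cfg.simulate["families"]:
            _check_keys(fam, _FAMILY_KEYS, "simulate.families")
            if "family_id" not in fam:
                raise InputError("simulate.families: missing 'family_id'")
        for ins in cfg.simulate.get("insertions", []):
            _check_keys(ins, _INSERTION_KEYS, "simulate.insertions")
    if cfg.inputs is not None:
        _check_keys(cfg.inputs, _INPUT_KEYS, "inputs")
        base = Path(path).parent
        for key in ("genome",):
            if key not in cfg.inputs:
                raise InputError(f"inputs: missing required key {key!r}")
            p = Path(cfg.inputs[key])
            if not p.is_absolute():
                p = base / p
            if not p.exists():
                raise InputError(f"inputs.{key}: path {p} does not exist")
            cfg.inputs[key] = str(p)
    return cfg


@dataclass
class FamilyData:
    """Everything the pipeline accumulates for one family."""

    family_id: str
    query: str
    ltr_ref: str
    internal_ref: str
    genes: dict[str, tuple[int, int]] = field(default_factory=dict)
    n_hits: int = 0
    loci: list = field(default_factory=list)
    ltr_aln: MultipleAlignment | None = None
    ltr_consensus: Any = None
    internal_aln: MultipleAlignment | None = None
    internal_consensus: Any = None
    estimates: dict[str, list[AgeEstimate]] = field(default_factory=dict)


def build_templates(cfg: RunConfig) -> dict[str, ProvirusTemplate]:
    """Materialize the templates of a simulation scenario."""
    sim = cfg.simulate
    trnas = synthetic_trna_library()
    templates: dict[str, ProvirusTemplate] = {}
    for i, fam in enumerate(sim["families"]):
        trna_name = fam.get("pbs_trna", "tRNA-Pro")
        templates[fam["family_id"]] = make_provirus_template(
            family_id=fam["family_id"],
            l_ltr=fam.get("l_ltr", 500),
            gene_lengths=fam.get("gene_lengths", dict(DEFAULT_GENE_LENGTHS)),
            pbs_source_trna=trnas[trna_name],
            seed=cfg.seed * 1000 + i,
            genus=fam.get("genus", "gamma"),
            cpg_density=fam.get("cpg_density"))
    for rec in sim.get("recombinants", []):
        templates[rec["family_id"]] = make_recombinant(
            templates[rec["backbone"]], templates[rec["donor"]],
            tuple(rec["breakpoints"]), family_id=rec["family_id"])
    return templates


def stage_simulate(cfg: RunConfig, out: Path):
    sim = cfg.simulate
    templates = build_templates(cfg)
    params = EvolutionParams(rate=cfg.rate, kappa=sim.get("kappa", 2.0),
                             cpg_multiplier=sim.get("cpg_multiplier", 1.0),
                             seed=cfg.seed)
    specs = [InsertionSpec(**{k: v for k, v in ins.items()})
             for ins in sim.get("insertions", [])]
    genome, truth = implant_elements(
        host_length=sim["host_length"],
        n_scaffolds=sim.get("n_scaffolds", 4),
        templates=templates, specs=specs, params=params,
        min_gap=sim.get("min_gap", 1000))
    out.mkdir(parents=True, exist_ok=True)
    write_fasta(genome, out / "genome.fa")
    truth.write_bed(out / "truth.bed")
    write_fasta({f"{fid}": t.sequence for fid, t in templates.items()},
                out / "templates.fa")
    return genome, truth, templates


def stage_mine(cfg: RunConfig, genome: dict[str, str],
               families: dict[str, FamilyData], out: Path) -> None:
    """Search, cluster, extract and classify loci for every family."""
    out.mkdir(parents=True, exist_ok=True)
    index = GenomeIndex(genome, k=cfg.kmer)
    tagged_clusters = []
    for fid, fam in families.items():
        hits = naive_search(fam.query, index, k=cfg.kmer,
                            min_identity=cfg.min_identity, query_id=fid)
        fam.n_hits = len(hits)
        write_hit_table(hits, out / f"{fid}.hits.tsv")
        max_gap = 2 * len(fam.ltr_ref)
        for cluster in merge_hits(hits, max_gap=max_gap):
            tagged_clusters.append((fid, cluster))
    # greedy overlap resolution across families: best bitscore wins,
    # then leftmost coordinate, then scaffold id
    tagged_clusters.sort(key=lambda t: (-t[1].bitscore, t[1].start, t[1].scaffold))
    kept: list[tuple[str, Any]] = []
    for fid, cluster in tagged_clusters:
        clash = any(k.scaffold == cluster.scaffold
                    and cluster.start < k.end and k.start < cluster.end
                    for _, k in kept)
        if not clash:
            kept.append((fid, cluster))
    kept.sort(key=lambda t: (t[1].scaffold, t[1].start))
    bed_lines = []
    loci_seqs = {}
    for i, (fid, cluster) in enumerate(kept, 1):
        fam = families[fid]
        locus = extract_locus(genome, cluster, flank=cfg.flank)
        structure = detect_ltr_pair(locus.sequence, fam.ltr_ref,
                                    min_identity=cfg.min_identity)
        element_id = f"{fid}_locus_{i:04d}"
        classified = classify_locus(structure, fam.internal_ref,
                                    family_id=fid, locus=locus,
                                    element_id=element_id,
                                    min_identity=cfg.min_identity)
        fam.loci.append((classified, structure))
        bed_lines.append("\t".join([
            cluster.scaffold, str(cluster.start), str(cluster.end),
            element_id, f"{cluster.bitscore:.0f}", cluster.strand, fid,
            classified.classification]))
        loci_seqs[element_id] = locus.sequence
    (out / "loci.bed").write_text("\n".join(bed_lines) + ("\n" if bed_lines else ""))
    write_fasta(loci_seqs, out / "loci.fa")


def stage_consensus(families: dict[str, FamilyData], out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    for fid, fam in families.items():
        ltr_members = []
        internal_members = []
        for classified, _structure in fam.loci:
            seq = classified.locus.sequence
            if classified.classification == "provirus":
                ltr_members.append((f"{classified.element_id}_5p",
                                    seq[classified.ltr5[0]:classified.ltr5[1]]))
                ltr_members.append((f"{classified.element_id}_3p",
                                    seq[classified.ltr3[0]:classified.ltr3[1]]))
                internal_members.append(
                    (classified.element_id,
                     seq[classified.internal[0]:classified.internal[1]]))
            elif classified.classification == "solo_ltr":
                ltr_members.append((classified.element_id,
                                    seq[classified.ltr5[0]:classified.ltr5[1]]))
        if ltr_members:
            fam.ltr_aln = star_align(ltr_members, fam.ltr_ref)
            fam.ltr_consensus = majority_consensus(fam.ltr_aln)
            write_aligned_fasta(fam.ltr_aln, out / f"{fid}.ltr.afa")
            write_fasta({f"{fid}_LTR_consensus": fam.ltr_consensus.sequence},
                        out / f"{fid}.ltr.consensus.fa")
        if internal_members:
            fam.internal_aln = star_align(internal_members, fam.internal_ref)
            fam.internal_consensus = majority_consensus(fam.internal_aln)
            write_aligned_fasta(fam.internal_aln, out / f"{fid}.internal.afa")
            write_fasta(
                {f"{fid}_internal_consensus": fam.internal_consensus.sequence},
                out / f"{fid}.internal.consensus.fa")
            support = fam.internal_consensus.support
            with open(out / f"{fid}.internal.support.tsv", "w") as fh:
                fh.write("consensus_pos\talignment_column\tsupport\n")
                for i, (c, s) in enumerate(
                        zip(fam.internal_consensus.column_map, support)):
                    fh.write(f"{i}\t{c}\t{s:.4f}\n")


def _slice_alignment(aln: MultipleAlignment, columns: np.ndarray) -> MultipleAlignment:
    rows = ["".join(r[c] for c in columns) for r in aln.rows]
    return MultipleAlignment(member_ids=list(aln.member_ids), rows=rows)


def date_gene_consensus(fam: FamilyData, rate: float,
                        denominator: int) -> list[AgeEstimate]:
    """Per-locus age as the mean of per-gene consensus-divergence ages.

    Gene boundaries are taken on the internal reference; insertion columns
    (reference position -1) are excluded. Without gene annotations the whole
    internal region is dated as a single segment.
    """
    aln = fam.internal_aln
    if aln is None:
        return []
    ref_cols = aln.reference_columns
    regions = (fam.genes if fam.genes
               else {"internal": (0, len(fam.internal_ref))})
    per_locus: dict[str, list[AgeEstimate]] = {m: [] for m in aln.member_ids}
    for gene, (gs, ge) in regions.items():
        cols = np.nonzero((ref_cols >= gs) & (ref_cols < ge))[0]
        if cols.size == 0:
            continue
        sub = _slice_alignment(aln, cols)
        cons = majority_consensus(sub)
        for est in age_from_consensus(sub, cons, rate=rate,
                                      method_label="gene_consensus",
                                      denominator=denominator,
                                      family_id=fam.family_id):
            per_locus[est.element_id].append(est)
    merged = []
    for mid, ests in per_locus.items():
        if not ests:
            continue
        merged.append(AgeEstimate(
            element_id=mid, method="gene_consensus",
            divergence=float(np.mean([e.divergence for e in ests])),
            age_myr=float(np.mean([e.age_myr for e in ests])),
            rate=rate, n_sites=sum(e.n_sites for e in ests),
            family_id=fam.family_id))
    return merged


def stage_date(cfg: RunConfig, families: dict[str, FamilyData], out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for fid, fam in families.items():
        if "ltr_consensus" in cfg.methods and fam.ltr_aln is not None \
                and fam.ltr_consensus is not None:
            fam.estimates["ltr_consensus"] = age_from_consensus(
                fam.ltr_aln, fam.ltr_consensus, rate=cfg.rate,
                method_label="ltr_consensus",
                denominator=cfg.consensus_age_denominator, family_id=fid)
        if "gene_consensus" in cfg.methods:
            fam.estimates["gene_consensus"] = date_gene_consensus(
                fam, cfg.rate, cfg.consensus_age_denominator)
        if "ltr_pair" in cfg.methods:
            ests = []
            for classified, _ in fam.loci:
                if classified.classification != "provirus":
                    continue
                seq = classified.locus.sequence
                ests.append(age_ltr_pair(
                    seq[classified.ltr5[0]:classified.ltr5[1]],
                    seq[classified.ltr3[0]:classified.ltr3[1]],
                    rate=cfg.rate, element_id=classified.element_id,
                    family_id=fid))
            fam.estimates["ltr_pair"] = ests
        for method, ests in fam.estimates.items():
            for e in ests:
                rows.append({"element_id": e.element_id, "family_id": fid,
                             "method": method, "n_sites": e.n_sites,
                             "divergence": e.divergence, "age_myr": e.age_myr})
    pd.DataFrame(rows).to_csv(out / "ages.tsv", sep="\t", index=False)


def stage_screen(cfg: RunConfig, families: dict[str, FamilyData],
                 out: Path) -> pd.DataFrame:
    """Presence/absence of each family consensus across target genomes."""
    out.mkdir(parents=True, exist_ok=True)
    calls = []
    scr = cfg.screen or {}
    for genome_id, path in (scr.get("genomes") or {}).items():
        genome = read_fasta(path)
        index = GenomeIndex(genome, k=cfg.kmer)
        for fid, fam in families.items():
            consensus_seq = _family_consensus_sequence(fam)
            hits = naive_search(consensus_seq, index, k=cfg.kmer,
                                min_identity=scr.get("min_identity", 60.0),
                                query_id=fid)
            calls.append(screen_genome(
                fid, hits, genome_id=genome_id,
                min_identity=scr.get("min_identity", 60.0),
                min_length=scr.get("min_length", 300)))
    frame = pd.DataFrame([dataclasses.asdict(c) for c in calls])
    if not frame.empty:
        matrix = frame.pivot(index="family_id", columns="genome_id",
                             values="best_percent_identity")
        matrix.to_csv(out / "presence.tsv", sep="\t")
    return frame


def _family_consensus_sequence(fam: FamilyData) -> str:
    parts = []
    if fam.ltr_consensus is not None:
        parts.append(fam.ltr_consensus.sequence)
    if fam.internal_consensus is not None:
        parts.append(fam.internal_consensus.sequence)
    if fam.ltr_consensus is not None:
        parts.append(fam.ltr_consensus.sequence)
    return "".join(parts) if parts else fam.query


def build_report(cfg: RunConfig, families: dict[str, FamilyData]) -> pd.DataFrame:
    rows = []
    for fid, fam in families.items():
        n_prov = sum(1 for c, _ in fam.loci if c.classification == "provirus")
        n_solo = sum(1 for c, _ in fam.loci if c.classification == "solo_ltr")
        row = {"family_id": fid, "hits": fam.n_hits, "proviruses": n_prov,
               "solo_ltrs": n_solo}
        for method in cfg.methods:
            ests = fam.estimates.get(method, [])
            label = {"ltr_consensus": "ltr_age",
                     "gene_consensus": "gene_age",
                     "ltr_pair": "ltr_pair_age"}[method]
            row[label] = summarize_family(ests).display() if ests else "N/D"
        row["consensus_length"] = len(_family_consensus_sequence(fam))
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class PipelineResult:
    """Report plus the in-memory state of a finished run (for scoring
    against simulator ground truth)."""

    report: pd.DataFrame
    families: dict[str, FamilyData]
    truth: Any = None  # TruthTable when the run simulated its own genome
    out_dir: Path | None = None


def execute_pipeline(cfg: RunConfig, out_dir: str | os.PathLike | None = None
                     ) -> PipelineResult:
    """Run every configured stage and return the full result object.

    A stage failure raises ``StageError`` naming the stage; artifacts of
    completed stages are retained.
    """
    out = Path(out_dir if out_dir is not None else cfg.out)
    out.mkdir(parents=True, exist_ok=True)
    families: dict[str, FamilyData] = {}
    truth = None

    def _run(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise StageError(f"stage {name!r} failed: {exc}") from exc

    if cfg.simulate is not None:
        genome, truth, templates = _run("simulate", stage_simulate, cfg,
                                        out / "simulate")
        for fid, t in templates.items():
            if t.element_type == "recombinant":
                continue  # recombinants are found through their backbone family
            families[fid] = FamilyData(family_id=fid, query=t.sequence,
                                       ltr_ref=t.ltr, internal_ref=t.internal,
                                       genes=dict(t.genes))
    else:
        genome = read_fasta(cfg.inputs["genome"])
        queries = read_fasta(cfg.inputs["queries"]) if "queries" in cfg.inputs else {}
        ltr_refs = read_fasta(cfg.inputs["ltr_refs"])
        internal_refs = read_fasta(cfg.inputs["internal_refs"])
        for fid in ltr_refs:
            families[fid] = FamilyData(
                family_id=fid, query=queries.get(
                    fid, ltr_refs[fid] + internal_refs[fid] + ltr_refs[fid]),
                ltr_ref=ltr_refs[fid], internal_ref=internal_refs[fid])

    _run("mine", stage_mine, cfg, genome, families, out / "mine")
    _run("consensus", stage_consensus, families, out / "consensus")
    _run("date", stage_date, cfg, families, out / "date")
    if cfg.recomb is not None:
        _run("recomb", stage_recomb, cfg, families, out / "recomb")
    if cfg.screen is not None:
        _run("screen", stage_screen, cfg, families, out / "screen")
    report = build_report(cfg, families)
    report.to_csv(out / "report.tsv", sep="\t", index=False)
    manifest = {
        "retroclock_version": __version__,
        "seed": cfg.seed,
        "parameters": {k: v for k, v in dataclasses.asdict(cfg).items()},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  sort_keys=True) + "\n")
    return PipelineResult(report=report, families=families, truth=truth,
                          out_dir=out)


def run_pipeline(cfg: RunConfig, out_dir: str | os.PathLike | None = None
                 ) -> pd.DataFrame:
    """Convenience wrapper around ``execute_pipeline`` returning the report."""
    return execute_pipeline(cfg, out_dir=out_dir).report


def stage_recomb(cfg: RunConfig, families: dict[str, FamilyData],
                 out: Path) -> list:
    """Scan configured queries of a supplied alignment for donor switches."""
    from .consensus import read_aligned_fasta
    out.mkdir(parents=True, exist_ok=True)
    rc = cfg.recomb
    aln = read_aligned_fasta(rc["aln"])
    events = []
    for query_id in rc.get("queries", [rc.get("query")]):
        profile = sliding_similarity(aln, query_id, rc["references"],
                                     window=cfg.window, step=cfg.step)
        write_profile(profile, out / f"{query_id}.profile.tsv")
        events.extend(detect_crossovers(profile))
    with open(out / "events.tsv", "w") as fh:
        fh.write("query_id\tdonor_before\tdonor_inside\tbp_start\tbp_end"
                 "\tquery_bp_start\tquery_bp_end\tsupport\n")
        for e in events:
            fh.write(f"{e.query_id}\t{e.donor_before}\t{e.donor_inside}\t"
                     f"{e.breakpoint_start}\t{e.breakpoint_end}\t"
                     f"{e.query_breakpoint_start}\t{e.query_breakpoint_end}\t"
                     f"{e.support}\n")
    return events
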