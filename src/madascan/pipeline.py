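"""End-to-end orchestration: filter -> align -> tree -> tribes -> motif
discovery -> HMM build -> (optional) calibrate -> scan -> classify ->
positional and summary reporting.

Every stage writes its artifact under the configured output directory
and logs a line with its parameters and counts.  Reruns with the same
configuration and seed are bit-identical (the log carries no
timestamps).
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from . import align, hmm as hmm_mod, motif as motif_mod, nlrome, phylo, report as report_mod
from . import simulate as sim_mod
from . import tribes as tribes_mod
from .records import SequenceRecord, read_fasta, write_fasta

logger = logging.getLogger("madascan")


@dataclass
class PipelineConfig:
    """Configuration for one pipeline run.

    Exactly one of ``input_fasta`` or ``sim`` must be provided.  With
    ``sim``, ground truth is generated alongside the repertoire and the
    NB-ARC offset defaults to the simulator's template offset.
    """

    outdir: str | Path = "madascan_out"
    input_fasta: Optional[str | Path] = None
    sim: Optional[sim_mod.SimConfig] = None
    seed: int = 0
    min_nterm: int = 30
    offset_to_nbarc: Optional[int] = None
    nbarc_window: Optional[int] = None  # residues of NB-ARC used for the tree
    evalue_max: float = 1e-8
    inflation: float = 2.0
    motif_width: int = 21
    n_starts: int = 8
    cutoff: float = 10.0
    madal_floor: float = 0.0
    skip_tree: bool = False
    bootstrap_replicates: int = 100
    support_min: float = 0.7
    clade_anchors: dict[str, list[str]] = field(default_factory=dict)
    tir_anchors: list[str] = field(default_factory=list)
    calibrate_n: int = 0  # 0 disables EVD calibration
    discovery_tribe: Optional[int] = None  # default: largest tribe
    hmm_file: Optional[str | Path] = None  # skip discovery, use this model


@dataclass
class PipelineResult:
    records: list[SequenceRecord]
    truths: Optional[list[sim_mod.SyntheticTruth]]
    kept: list
    dropped: list
    tribes: Optional[tribes_mod.TribeAssignment]
    tree: Optional[phylo.PhyloTree]
    motif_model: Optional[motif_mod.MotifModel]
    occurrences: list
    hmm: hmm_mod.ProfileHMM
    hits: list[hmm_mod.HmmHit]
    all_hits: list[hmm_mod.HmmHit]
    summary: report_mod.SummaryReport
    outdir: Path

    def report_hash(self) -> str:
        return hashlib.sha256(self.summary.to_json().encode()).hexdigest()


def _setup_logging(outdir: Path) -> None:
    logger.setLevel(logging.INFO)
    logger.handlers = [h for h in logger.handlers
                       if not isinstance(h, logging.FileHandler)]
    fmt = logging.Formatter("%(levelname)s %(message)s")
    fh = logging.FileHandler(outdir / "pipeline.log", mode="w")
    fh.setFormatter(fmt)
    logger.addHandler(fh)
    if not any(isinstance(h, logging.StreamHandler)
               and not isinstance(h, logging.FileHandler)
               for h in logger.handlers):
        sh = logging.StreamHandler()
        sh.setFormatter(fmt)
        logger.addHandler(sh)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _setup_logging(outdir)
    stage = "input"
    try:
        truths = None
        if config.sim is not None:
            sim_config = config.sim
            records, truths = sim_mod.generate_repertoire(sim_config)
            write_fasta(records, outdir / "repertoire.fasta")
            sim_mod.write_truth(truths, outdir / "truth.tsv")
            offset = (config.offset_to_nbarc
                      if config.offset_to_nbarc is not None
                      else sim_mod.PLOOP_OFFSET_IN_TEMPLATE)
            nbarc_window = config.nbarc_window or len(sim_config.nbarc_template)
            logger.info("simulate: %d records (seed=%d)", len(records),
                        sim_config.seed)
        elif config.input_fasta is not None:
            records = read_fasta(config.input_fasta)
            offset = config.offset_to_nbarc or 0
            nbarc_window = config.nbarc_window
            logger.info("input: %d records from %s", len(records),
                        config.input_fasta)
        else:
            raise ValueError("config needs input_fasta or sim")

        stage = "filter"
        kept, dropped = nlrome.compile_cc_nlr_db(
            records, min_nterm=config.min_nterm, offset_to_nbarc=offset)
        nlrome.write_dropped_report(dropped, outdir / "dropped.tsv")
        write_fasta([r for r, _ in kept], outdir / "db.fasta")
        logger.info("filter: kept=%d dropped=%d (min_nterm=%d)",
                    len(kept), len(dropped), config.min_nterm)
        if len(kept) < 3:
            raise ValueError("fewer than 3 records pass the database filters")

        tree = None
        if not config.skip_tree:
            stage = "tree"
            nbarc_recs = [
                SequenceRecord(id=rec.id,
                               residues=nlrome.nbarc_sequence(rec, ann, nbarc_window))
                for rec, ann in kept
            ]
            msa = align.progressive_msa(nbarc_recs)
            msa = align.strip_gap_columns(msa, max_gap_fraction=0.5)
            tree = phylo.bootstrap_support(
                msa, n_replicates=config.bootstrap_replicates, seed=config.seed)
            phylo.write_newick(tree, outdir / "nbarc_nj.nwk")
            logger.info("tree: %d taxa, %d bootstrap replicates",
                        len(msa.ids), config.bootstrap_replicates)

        stage = "tribes"
        nterm_seqs = {rec.id: nlrome.nterm_sequence(rec, ann) for rec, ann in kept}
        graph = tribes_mod.all_vs_all_graph(nterm_seqs, evalue_max=config.evalue_max)
        tribes_mod.write_abc(graph, outdir / "similarity.abc")
        assignment = tribes_mod.mcl_cluster(graph, inflation=config.inflation)
        tribes_mod.write_assignment(assignment, outdir / "tribes.tsv")
        logger.info("tribes: %d tribes + %d singletons (evalue<%g, I=%.1f)",
                    assignment.n_tribes_multi, assignment.n_singletons,
                    config.evalue_max, config.inflation)

        motif_model = None
        occurrences: list = []
        if config.hmm_file is not None:
            stage = "hmm_load"
            profile = hmm_mod.read_hmm(config.hmm_file)
            logger.info("hmm: loaded %s (M=%d)", config.hmm_file, profile.n_states)
        else:
            stage = "motif_discovery"
            target_tid = config.discovery_tribe
            if target_tid is None:
                target_tid = min(assignment.tribes,
                                 key=lambda t: (-len(assignment.tribes[t]), t))
            tribe_seqs = {m: nterm_seqs[m] for m in assignment.tribes[target_tid]
                          if len(nterm_seqs[m]) >= config.motif_width}
            results = motif_mod.discover_motifs(
                tribe_seqs, width=config.motif_width, n_motifs=1,
                n_starts=config.n_starts, seed=config.seed)
            if not results:
                raise ValueError("motif discovery returned no motif")
            motif_model, occurrences = results[0]
            motif_mod.write_meme_minimal([motif_model], outdir / "motifs.meme")
            motif_mod.occurrences_to_stockholm(occurrences, outdir / "sites.sto")
            logger.info("motif: tribe %d, %d/%d sites, consensus %s",
                        target_tid, len(occurrences), len(tribe_seqs),
                        motif_mod.consensus_string(motif_model))

            stage = "hmm_build"
            profile = hmm_mod.build_hmm([o.matched for o in occurrences],
                                        name="MADA-like")
            if config.calibrate_n:
                profile = hmm_mod.calibrate(profile, n_random=config.calibrate_n,
                                            seed=config.seed)
            hmm_mod.write_hmm(profile, outdir / "motif.hmm")
            logger.info("hmm: M=%d from %d sites%s", profile.n_states,
                        profile.n_seq,
                        ", calibrated" if config.calibrate_n else "")

        stage = "scan"
        hits = hmm_mod.score_records(profile, [rec for rec, _ in kept])
        for h in hits:
            hmm_mod.classify(h, cutoff=config.cutoff, madal_floor=config.madal_floor)
        hmm_mod.write_hits(hits, outdir / "hits_db.tsv")
        # full input scan (decoys included) for the precision analysis
        all_hits = hmm_mod.score_records(profile, records)
        for h in all_hits:
            hmm_mod.classify(h, cutoff=config.cutoff, madal_floor=config.madal_floor)
        hmm_mod.write_hits(all_hits, outdir / "hits_all.tsv")
        logger.info("scan: %d db hits >= %.1f bits",
                    sum(1 for h in hits if h.score >= config.cutoff),
                    config.cutoff)

        stage = "report"
        clade_labels: dict[str, str] = {}
        if tree is not None and config.clade_anchors:
            for clade_name, anchors in sorted(config.clade_anchors.items()):
                for member in phylo.flag_clade(tree, anchors, config.support_min):
                    clade_labels[member] = clade_name
        summary = report_mod.summarize(kept, assignment, hits, clade_labels)
        try:
            per_species, overall, hist = report_mod.precision_vs_annotation(
                all_hits, records, cutoff=config.cutoff)
            summary.precision = {
                "per_species": {k: list(v) for k, v in per_species.items()},
                "overall": list(overall),
                "histogram": {str(k): [int(v["nlr"]), int(v["non_nlr"])]
                              for k, v in hist.iterrows()},
            }
        except ValueError:
            summary.precision = None  # no annotations available
        summary.write(outdir)
        logger.info("report: MADA=%d MADAL=%d of %d (%.1f%%)",
                    summary.positional["n_mada"], summary.positional["n_madal"],
                    summary.positional["n_db"],
                    summary.positional["pct_mada_madal_of_db"])
    except Exception:
        snapshot = outdir / "failed_stage.txt"
        snapshot.write_text(stage + "\n")
        logger.error("pipeline failed at stage %r (snapshot: %s)", stage, snapshot)
        raise

    return PipelineResult(
        records=records, truths=truths, kept=kept, dropped=dropped,
        tribes=assignment, tree=tree, motif_model=motif_model,
        occurrences=occurrences, hmm=profile, hits=hits, all_hits=all_hits,
        summary=summary, outdir=outdir,
    )


def synthetic_config(outdir: str | Path, seed: int = 0,
                     sim: Optional[sim_mod.SimConfig] = None,
                     **overrides) -> PipelineConfig:
    """Reference synthetic-run configuration: simulate at ``seed``, anchor
    the helper clade on the first two helpers and the sensor clade on the
    first two family-2 sensors."""
    if sim is None:
        sim = sim_mod.SimConfig(seed=seed)
    n = sim.seqs_per_family
    anchors = {
        "helper_clade": ["helper_f1_001", "helper_f1_002"],
        "sensor_clade": ["sensor_f2_001", "sensor_f2_002"],
    }
    cfg = PipelineConfig(outdir=outdir, sim=sim, seed=seed,
                         clade_anchors=anchors if n >= 2 else {}, **overrides)
    return cfg
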