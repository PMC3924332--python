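"""End-to-end workflow: pre-processing, motif mining, model prediction and
model evaluation & selection.

``run()`` executes the four stages on in-memory objects and is the core
API; ``run_pipeline()`` wraps it with file input/output for the CLI.  Given
the same configuration and seed the run is deterministic and its output
files are byte-identical.
"""

from __future__ import annotations

import logging
import os
import statistics
from dataclasses import dataclass, field

from . import hmm as hmm_mod
from . import metrics as metrics_mod
from . import mining, models as models_mod, selection as selection_mod
from .fixtures import FixtureSpec, plant_genome
from .hmm import FamilyAlignment, ProfileHMM
from .seqio import (
    AnnotationModel,
    GenomicSequence,
    extract_orfs,
    read_annotation,
    read_genome,
    six_frame_translate,
    write_fasta,
    write_gff3,
)

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    genome: str | None = None
    families: list[str] = field(default_factory=list)
    annotation: str | None = None
    outdir: str | None = None
    scan_e: float = 10.0  # generous initial scan threshold
    hit_keep_e: float = 0.1  # significance filter on projected hits
    final_e: float = 0.001  # final model E-value cutoff
    window_up: int = 2500
    window_down: int = 1500
    min_orf: int = 15
    min_intron: int = 40
    max_intron: int = 2500
    allow_gc_donor: bool = False
    signal_gate: bool = True
    d_min: float = 0.4
    merge_max_gap: int = mining.DEFAULT_MERGE_GAP
    profile_overlap_tol: int = mining.DEFAULT_PROFILE_OVERLAP_TOL
    max_candidates: int = 50
    decoy_n: int = 4000
    seed: int = 0

    def validate(self) -> None:
        for name in ("scan_e", "hit_keep_e", "final_e", "d_min"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.window_up < 0 or self.window_down < 0:
            raise ValueError("window sizes must be >= 0")

    def header(self) -> str:
        keys = [
            "scan_e", "hit_keep_e", "final_e", "window_up", "window_down",
            "min_orf", "min_intron", "max_intron", "allow_gc_donor",
            "signal_gate", "d_min", "merge_max_gap", "profile_overlap_tol",
            "max_candidates", "decoy_n", "seed",
        ]
        return "\n".join(f"# {k} = {getattr(self, k)}" for k in keys)


@dataclass
class RunResult:
    models: list[selection_mod.SelectedModel]
    extended_hits: list[mining.ExtendedHit]
    n_orfs: int
    n_db: int
    profiles: dict[str, ProfileHMM]
    families: dict[str, FamilyAlignment]
    report: dict
    comparison: dict | None = None


def _scan_database(genome, annotations, min_orf):
    """Six-frame ORFs plus annotated proteins; returns (db, ctx)."""
    orfs = []
    frames = []
    for g in genome:
        for t in six_frame_translate(g):
            frames.append(t)
            orfs.extend(extract_orfs(t, min_len=min_orf))
    ctx = mining.MappingContext(orfs=orfs, frames=frames, annotations=annotations or [])
    db = [(o.orf_id, o.aa) for o in orfs]
    for a in annotations or []:
        if a.protein:
            db.append((a.gene_id, a.protein))
    return db, ctx, len(orfs)


def scan_stage(
    genome: list[GenomicSequence],
    families: list[FamilyAlignment],
    annotations: list[AnnotationModel] | None,
    cfg: PipelineConfig,
):
    """Pre-processing + motif mining: profiles, calibration, search,
    projection, filtering, clustering and merging into extended hits.

    Returns ``(extended_hits, profiles, n_db, stage_report)``.
    """
    db, ctx, n_orfs = _scan_database(genome, annotations, cfg.min_orf)
    n_db = len(db)
    lens = sorted(len(s) for _, s in db) or [60]
    decoy_len = max(15, int(statistics.median(lens)))
    log.info("scan database: %d ORFs, %d total entries", n_orfs, n_db)

    profiles: dict[str, ProfileHMM] = {}
    genomic_hits: list[mining.GenomicHit] = []
    for i, fam in enumerate(families):
        prof = hmm_mod.build_profile(fam)
        hmm_mod.calibrate(
            prof,
            decoy_n=cfg.decoy_n,
            decoy_len=decoy_len,
            seed=(cfg.seed * 1009 + i) % (2**31 - 1),
        )
        profiles[fam.family_id] = prof
        hits = hmm_mod.search(prof, db, e_max=cfg.scan_e, n_db=n_db)
        genomic_hits.extend(mining.project_hits(hits, ctx))
    kept = mining.significance_filter(genomic_hits, cfg.hit_keep_e)
    best = mining.select_best_per_cluster(kept)
    extended = mining.merge_partial_hits(
        best, max_gap=cfg.merge_max_gap, profile_overlap_tol=cfg.profile_overlap_tol
    )
    log.info(
        "hits: %d raw -> %d significant -> %d cluster-best -> %d extended",
        len(genomic_hits), len(kept), len(best), len(extended),
    )
    report = {
        "n_orfs": n_orfs,
        "n_db": n_db,
        "n_raw_hits": len(genomic_hits),
        "n_significant_hits": len(kept),
        "n_cluster_best": len(best),
        "n_extended_hits": len(extended),
    }
    return extended, profiles, n_db, report


def run(
    genome: list[GenomicSequence],
    families: list[FamilyAlignment],
    annotations: list[AnnotationModel] | None = None,
    cfg: PipelineConfig | None = None,
) -> RunResult:
    """Run the full pipeline on in-memory inputs."""
    cfg = cfg or PipelineConfig()
    cfg.validate()
    genome_by_id = {g.id: g for g in genome}
    fam_by_id = {f.family_id: f for f in families}

    extended, profiles, n_db, stage_report = scan_stage(
        genome, families, annotations, cfg
    )
    n_orfs = stage_report["n_orfs"]

    predicted, n_candidates = predict_stage(
        genome, fam_by_id, profiles, extended, n_db, cfg
    )
    final = selection_mod.final_filter(predicted, e_max=cfg.final_e)
    report = dict(stage_report)
    report.update(
        {
            "n_candidates": n_candidates,
            "n_selected": len(predicted),
            "n_final": len(final),
        }
    )
    comparison = None
    if annotations:
        comparison = metrics_mod.compare_annotation(
            [m.model for m in final], annotations
        )
        report["annotation_comparison"] = comparison["counts"]
    return RunResult(
        models=final,
        extended_hits=extended,
        n_orfs=n_orfs,
        n_db=n_db,
        profiles=profiles,
        families=fam_by_id,
        report=report,
        comparison=comparison,
    )


def predict_stage(
    genome,
    fam_by_id: dict[str, FamilyAlignment],
    profiles: dict[str, ProfileHMM],
    extended: list[mining.ExtendedHit],
    n_db: int,
    cfg: PipelineConfig,
):
    """Model prediction, scoring and per-hit selection.

    Returns ``(selected_models, n_candidates)``; the final E-value filter is
    applied by the caller.
    """
    genome_by_id = (
        genome if isinstance(genome, dict) else {g.id: g for g in genome}
    )
    builder_cfg = models_mod.ModelBuilderConfig(
        min_intron=cfg.min_intron,
        max_intron=cfg.max_intron,
        allow_gc_donor=cfg.allow_gc_donor,
        max_candidates=cfg.max_candidates,
    )
    selected: list[selection_mod.SelectedModel] = []
    n_candidates = 0
    for xh in extended:
        w = models_mod.extract_window(
            xh, genome_by_id, up=cfg.window_up, down=cfg.window_down
        )
        cands = models_mod.enumerate_models(w, config=builder_cfg)
        cands.extend(models_mod.external_predictor_seam(w))
        n_candidates += len(cands)
        prof = profiles[xh.family_id]
        fam = fam_by_id[xh.family_id]
        scored = []
        for cand in cands:
            if not cand.protein:
                continue
            sig = selection_mod.active_signal_score(cand.protein)
            structural = (
                cand.has_start and cand.has_stop and not cand.has_internal_stop
            )
            gated = (not cfg.signal_gate) or sig >= cfg.d_min
            if structural and gated:
                score = selection_mod.ModelScore(
                    msa_score=selection_mod.msa_score(cand.protein, fam),
                    hmmprob_score=selection_mod.hmmprob_score(cand.protein, prof),
                    signal_score=sig,
                )
                scored.append((cand, score))
        best_model = selection_mod.select_best(
            scored, signal_gate_on=cfg.signal_gate, d_min=cfg.d_min
        )
        if best_model is None:
            continue
        # final E-value: the completed protein rescored against the family
        # profile, scaled by the size of the scan database
        s = hmm_mod.forward_score(prof, best_model.model.protein)
        best_model.score.final_evalue = hmm_mod.evalue(prof, s, n_db)
        best_model.family_id = xh.family_id
        selected.append(best_model)
    return selected, n_candidates


# ---------------------------------------------------------------------------
# file-level entry point and reporting
# ---------------------------------------------------------------------------

def _model_annotations(result: RunResult) -> list[AnnotationModel]:
    out = []
    for i, m in enumerate(result.models):
        out.append(
            AnnotationModel(
                gene_id=f"fm{i:04d}",
                seq_id=m.model.seq_id,
                strand=m.model.strand,
                exons=list(m.model.exons),
                protein=m.model.protein,
            )
        )
    return out


def write_outputs(result: RunResult, cfg: PipelineConfig, outdir: str) -> None:
    """Write GFF3, FASTA, score TSV and per-family alignments."""
    os.makedirs(outdir, exist_ok=True)
    anns = _model_annotations(result)
    write_gff3(anns, os.path.join(outdir, "models.gff3"))
    write_fasta(
        [(a.gene_id, a.protein) for a in anns], os.path.join(outdir, "proteins.fa")
    )
    write_fasta(
        [(a.gene_id, m.model.cds) for a, m in zip(anns, result.models)],
        os.path.join(outdir, "cds.fa"),
    )
    with open(os.path.join(outdir, "scores.tsv"), "w") as fh:
        fh.write(cfg.header() + "\n")
        fh.write(
            "model_id\tfamily\tseq_id\tstart\tend\tstrand\tn_exons\t"
            "msa_score\thmmprob_score\tsignal_score\tfinal_evalue\n"
        )
        for a, m in zip(anns, result.models):
            lo, hi = m.model.genomic_span
            fh.write(
                f"{a.gene_id}\t{m.family_id}\t{m.model.seq_id}\t{lo}\t{hi}\t"
                f"{m.model.strand}\t{m.model.n_exons}\t{m.score.msa_score:.3f}\t"
                f"{m.score.hmmprob_score:.3f}\t{m.score.signal_score:.3f}\t"
                f"{m.score.final_evalue:.3g}\n"
            )
    # per-family alignment of predictions plus the family consensus
    for fid, fam in sorted(result.families.items()):
        rows = list(fam.members)
        rows.append(("consensus", selection_mod.family_consensus(fam)))
        for a, m in zip(anns, result.models):
            if m.family_id != fid:
                continue
            pairs = selection_mod.align_to_family(m.model.protein, fam)
            row = ["-"] * fam.columns
            for c, r in pairs:
                if c is not None and r is not None:
                    row[c] = m.model.protein[r]
            rows.append((a.gene_id, "".join(row)))
        write_fasta(rows, os.path.join(outdir, f"family_{fid}.afa"))
    if result.comparison is not None:
        with open(os.path.join(outdir, "annotation_comparison.tsv"), "w") as fh:
            fh.write("model_id\tcategory\tannotation_id\n")
            by_model = {
                id(lbl[0]): (lbl[1], lbl[2]) for lbl in result.comparison["labels"]
            }
            for a, m in zip(anns, result.models):
                cat, match = by_model.get(id(m.model), ("unannotated", None))
                fh.write(
                    f"{a.gene_id}\t{cat}\t{match.gene_id if match else '.'}\n"
                )
    with open(os.path.join(outdir, "run_report.txt"), "w") as fh:
        fh.write(cfg.header() + "\n")
        for k, v in result.report.items():
            fh.write(f"{k}\t{v}\n")


def run_pipeline(cfg: PipelineConfig) -> RunResult:
    """File-based entry point: read inputs, run all stages, write outputs."""
    cfg.validate()
    if not cfg.genome or not cfg.families:
        raise ValueError("a genome and at least one family alignment are required")
    genome = read_genome(cfg.genome)
    families = [FamilyAlignment.read(p) for p in cfg.families]
    annotations = (
        read_annotation(cfg.annotation, genome) if cfg.annotation else None
    )
    result = run(genome, families, annotations, cfg)
    if cfg.outdir:
        write_outputs(result, cfg, cfg.outdir)
    return result


def evaluate_against_truth(result: RunResult, truth_models) -> dict:
    """Nucleotide- and exon-level Sn/Sp of a run against truth models."""
    pred = [m.model for m in result.models]
    nt = metrics_mod.nucleotide_metrics(pred, truth_models)
    ex = metrics_mod.exon_metrics(pred, truth_models)
    return {"nucleotide": nt, "exon": ex}


def make_fixture(spec: FixtureSpec, outdir: str | None = None):
    truth = plant_genome(spec)
    if outdir:
        truth.write(outdir)
    return truth
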