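"""Pipeline driver: wiring, external-tool adapters, checkpoints, resume.

The annotation pipeline runs in a fixed stage order::

    align -> hints -> traingenes -> train1 -> chunks -> predict1
          -> support -> train2 -> predict2 -> summary

Spliced alignment, predictor training, metaparameter optimization and gene
prediction are performed by *external* binaries reached through
user-editable command templates; when no template is configured the
pipeline runs in dry-run mode with built-in mock adapters (a no-op trainer
and the deterministic hint-based mock predictor), which exercises every
bespoke stage without any third-party tool.

Every stage writes its outputs plus a ``<stage>.done`` marker into the
work directory; a rerun skips stages whose marker exists, so the work-dir
contents fully determine resume behaviour.  All outputs are written
deterministically — two complete runs from the same inputs are
byte-identical.
"""

from __future__ import annotations

import json
import logging
import math
import subprocess
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import evaluation, fixtures
from .chunking import (
    ChunkPlan,
    merge_chunk_predictions,
    plan_chunks,
    renumber_models,
)
from .formats import (
    parse_alignments,
    read_fasta,
    read_gene_models,
    write_alignments_compact,
    write_gene_models,
    write_hints_gff,
    write_training_genbank,
)
from .hint_scoring import ScoringConfig, classify_evidence, evidence_table
from .training_genes import (
    apply_flanks,
    compute_flank,
    evaluate_support,
    second_round_training_genes,
    select_training_genes,
)

logger = logging.getLogger(__name__)

STAGES = (
    "align",
    "hints",
    "traingenes",
    "train1",
    "chunks",
    "predict1",
    "support",
    "train2",
    "predict2",
    "summary",
)


class AdapterError(RuntimeError):
    """An external tool invocation failed (stage name in ``.stage``)."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage}: {message}")
        self.stage = stage


class InputError(RuntimeError):
    """Unusable pipeline inputs (missing files, bad config)."""


@dataclass
class PipelineConfig:
    genome: str = ""
    proteins: list[str] = field(default_factory=list)
    workdir: str = "exonweave-wd"
    threads: int = 1
    alignments: str | None = None  # precomputed alignments (skip the aligner)
    alignment_dialect: str = "compact"
    skip_optimize: bool = False
    # command templates; all None => dry-run with mock adapters
    aligner_cmd: str | None = None
    trainer_cmd: str | None = None
    predictor_cmd: str | None = None
    optimizer_cmd: str | None = None
    scoring: ScoringConfig = field(default_factory=ScoringConfig)
    chunk_size: int = 5_000_000
    overlap: int = 1_000_000
    batch_target: int = 5_000_000
    flank_floor: int = 500
    flank_cap: int = 10_000
    coverage_threshold: float = 0.8
    min_exons: int = 1

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        scoring = ScoringConfig(**raw.pop("scoring", {})) if isinstance(
            raw.get("scoring"), dict
        ) else raw.pop("scoring", ScoringConfig())
        return cls(scoring=scoring, **raw)

    def validate(self) -> None:
        if not self.genome or not Path(self.genome).exists():
            raise InputError(f"genome file not found: {self.genome!r}")
        if self.alignments is None:
            if not self.proteins:
                raise InputError("at least one proteome is required")
            for p in self.proteins:
                if not Path(p).exists():
                    raise InputError(f"protein file not found: {p!r}")
            if self.aligner_cmd is not None:
                _check_template(self.aligner_cmd, "{genome}", "{proteins}", "{out}")
        elif not Path(self.alignments).exists():
            raise InputError(f"alignment file not found: {self.alignments!r}")


def _check_template(template: str, *placeholders: str) -> None:
    missing = [p for p in placeholders if p not in template]
    if missing:
        raise InputError(
            f"command template {template!r} lacks placeholders {missing}"
        )


def _run_command(stage: str, template: str, mapping: dict[str, str]) -> None:
    cmd = template.format(**mapping)
    logger.info("[%s] running: %s", stage, cmd)
    proc = subprocess.run(
        cmd, shell=True, capture_output=True, text=True
    )
    if proc.returncode != 0:
        raise AdapterError(
            stage, f"command {cmd!r} exited {proc.returncode}: {proc.stderr[-2000:]}"
        )


class _Workdir:
    def __init__(self, path: str | Path):
        self.path = Path(path)
        self.path.mkdir(parents=True, exist_ok=True)

    def file(self, name: str) -> Path:
        return self.path / name

    def done(self, stage: str) -> bool:
        return self.file(f"{stage}.done").exists()

    def mark(self, stage: str) -> None:
        self.file(f"{stage}.done").write_text("")


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute (or resume) the full pipeline; returns paths and stage log."""
    cfg.validate()
    wd = _Workdir(cfg.workdir)
    executed: list[str] = []

    def stage(name: str):
        def deco(fn):
            if wd.done(name):
                logger.info("[%s] checkpoint present, skipping", name)
                return
            logger.info("[%s] running", name)
            fn()
            wd.mark(name)
            executed.append(name)

        return deco

    assembly = read_fasta(cfg.genome)
    seq_lengths = {s.seq_id: s.length for s in assembly}

    @stage("align")
    def _align():
        out = wd.file("alignments.aln")
        if cfg.alignments is not None:
            chains = parse_alignments(cfg.alignments, cfg.alignment_dialect)
        elif cfg.aligner_cmd is not None:
            raw = wd.file("alignments.raw.gff")
            _run_command(
                "align",
                cfg.aligner_cmd,
                {
                    "genome": cfg.genome,
                    "proteins": " ".join(cfg.proteins),
                    "out": str(raw),
                },
            )
            chains = parse_alignments(raw, "miniprot_gff")
        else:
            raise InputError(
                "dry-run mode needs precomputed alignments (--alignments)"
            )
        write_alignments_compact(chains, out)

    @stage("hints")
    def _hints():
        chains = parse_alignments(wd.file("alignments.aln"), "compact")
        evidence, hints = classify_evidence(chains, cfg.scoring)
        write_hints_gff(hints, wd.file("hints.gff"))
        evidence_table(evidence).to_csv(
            wd.file("evidence.tsv"), sep="\t", index=False
        )

    @stage("traingenes")
    def _traingenes():
        chains = parse_alignments(wd.file("alignments.aln"), "compact")
        evidence, _ = classify_evidence(chains, cfg.scoring)
        genes = select_training_genes(chains, evidence, min_exons=cfg.min_exons)
        flank = compute_flank(genes, cap=cfg.flank_cap, floor=cfg.flank_floor)
        apply_flanks(genes, flank, seq_lengths)
        wd.file("flank.txt").write_text(f"{flank}\n")
        write_training_genbank(genes, assembly, wd.file("training.gb"))
        write_gene_models([g.model for g in genes], wd.file("training.gff3"))

    @stage("train1")
    def _train1():
        if cfg.trainer_cmd is not None:
            _run_command(
                "train1",
                cfg.trainer_cmd,
                {"training": str(wd.file("training.gb")), "out": str(wd.file("params1.txt"))},
            )
        else:
            wd.file("params1.txt").write_text("mock-trainer round 1\n")

    @stage("chunks")
    def _chunks():
        plan = plan_chunks(
            assembly,
            chunk_size=cfg.chunk_size,
            overlap=cfg.overlap,
            batch_target=cfg.batch_target,
        )
        plan.to_tsv(wd.file("chunk_plan.tsv"))

    def _predict(round_name: str, out_name: str) -> None:
        plan = ChunkPlan.from_tsv(
            wd.file("chunk_plan.tsv"),
            chunk_size=cfg.chunk_size,
            overlap=cfg.overlap,
            batch_target=cfg.batch_target,
        )
        from .formats import read_hints_gff

        hints = read_hints_gff(wd.file("hints.gff"))
        if cfg.predictor_cmd is not None:
            per_chunk = _external_predict(round_name, cfg, wd, plan, assembly)
        else:
            per_chunk = fixtures.run_mock_predictor_on_plan(assembly, hints, plan)
        merged = merge_chunk_predictions(per_chunk, plan)
        merged = renumber_models(merged)
        write_gene_models(merged, wd.file(out_name))

    @stage("predict1")
    def _predict1():
        _predict("predict1", "predictions1.gff3")

    @stage("support")
    def _support():
        from .formats import read_hints_gff

        predictions = read_gene_models(wd.file("predictions1.gff3"), "gff3")
        hints = read_hints_gff(wd.file("hints.gff"))
        reports = evaluate_support(
            predictions, hints, coverage_threshold=cfg.coverage_threshold
        )
        with open(wd.file("support.tsv"), "w") as fh:
            fh.write(
                "transcript_id\tn_introns\tn_introns_supported\t"
                "cds_coverage\tfully_supported\n"
            )
            for r in reports:
                fh.write(
                    f"{r.transcript_id}\t{r.n_introns}\t{r.n_introns_supported}\t"
                    f"{r.cds_coverage_fraction:.4f}\t{int(r.fully_supported)}\n"
                )
        flank = int(wd.file("flank.txt").read_text().strip())
        training2 = second_round_training_genes(
            predictions, reports, flank, seq_lengths
        )
        write_training_genbank(training2, assembly, wd.file("training2.gb"))

    @stage("train2")
    def _train2():
        if cfg.trainer_cmd is not None:
            _run_command(
                "train2",
                cfg.trainer_cmd,
                {"training": str(wd.file("training2.gb")), "out": str(wd.file("params2.txt"))},
            )
        else:
            wd.file("params2.txt").write_text("mock-trainer round 2\n")
        if not cfg.skip_optimize:
            if cfg.optimizer_cmd is not None:
                _run_command(
                    "train2",
                    cfg.optimizer_cmd,
                    {"training": str(wd.file("training2.gb")), "out": str(wd.file("params2.txt"))},
                )
            else:
                logger.info("[train2] no optimizer configured; skipping optimization")

    @stage("predict2")
    def _predict2():
        _predict("predict2", "annotation.gff3")

    @stage("summary")
    def _summary():
        final = read_gene_models(wd.file("annotation.gff3"), "gff3")
        s = evaluation.summarize_gene_set(final)
        payload = {
            "n_genes": s.n_genes,
            "n_transcripts": s.n_transcripts,
            "mono_mult_ratio": "Inf" if math.isinf(s.mono_mult_ratio) else round(s.mono_mult_ratio, 4),
            "max_exons": s.max_exons,
            "n_incomplete": s.n_incomplete,
        }
        wd.file("summary.json").write_text(
            json.dumps(payload, indent=2, sort_keys=True) + "\n"
        )

    return {
        "workdir": str(wd.path),
        "annotation": str(wd.file("annotation.gff3")),
        "summary": str(wd.file("summary.json")),
        "executed_stages": executed,
    }


def _external_predict(stage_name, cfg, wd, plan, assembly):
    """Run the external predictor per chunk via its command template."""
    from .chunking import remap_predictions, write_chunk_fastas

    _check_template(cfg.predictor_cmd, "{chunk}", "{hints}", "{out}")
    chunk_dir = wd.file(f"{stage_name}_chunks")
    paths = write_chunk_fastas(plan, assembly, chunk_dir)
    per_chunk = {}
    for cid, fa in paths.items():
        out = Path(chunk_dir) / f"chunk_{cid}.gff3"
        _run_command(
            stage_name,
            cfg.predictor_cmd,
            {"chunk": fa, "hints": str(wd.file("hints.gff")), "out": str(out)},
        )
        local = read_gene_models(out, "gff3")
        per_chunk[cid] = remap_predictions(cid, local, plan)
    return per_chunk
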