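"""Gene-set accuracy and summary metrics.

Predictions are compared against a reference annotation at three structural
levels, matching CDS coordinates exactly:

* **exon** — a distinct CDS exon (seq, strand, start, end) present in both
  sets;
* **transcript** — a predicted transcript whose ordered CDS exon list is
  identical to a reference transcript's;
* **gene** — a gene with at least one matched transcript (counted on the
  reference side for sensitivity, on the prediction side for specificity).

Sensitivity = TP / reference count, Specificity = TP / predicted count and
F1 = 2*Sn*Sp / (Sn + Sp) — the harmonic mean, 0 when both are 0.  UTRs are
ignored throughout (predictions carry none) and models are canonicalized
to stop-codon-included CDS at read time, so dialect differences in stop
codon handling cannot create spurious mismatches.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from typing import Sequence

import pandas as pd

from .formats import GeneModel


@dataclass
class LevelAccuracy:
    """Accuracy at one structural level.

    ``tp_ref`` / ``tp_pred`` are the matched counts on the reference and
    prediction side; they differ only at gene level, where one predicted
    gene can match several reference genes and vice versa.
    """

    tp_ref: int
    tp_pred: int
    n_reference: int
    n_predicted: int

    @property
    def sensitivity(self) -> float:
        return self.tp_ref / self.n_reference if self.n_reference else 0.0

    @property
    def specificity(self) -> float:
        return self.tp_pred / self.n_predicted if self.n_predicted else 0.0

    @property
    def f1_score(self) -> float:
        return f1(self.sensitivity, self.specificity)


@dataclass
class AccuracyReport:
    gene: LevelAccuracy
    transcript: LevelAccuracy
    exon: LevelAccuracy

    def as_dict(self) -> dict:
        out = {}
        for level in ("gene", "transcript", "exon"):
            acc: LevelAccuracy = getattr(self, level)
            out[level] = {
                "tp_ref": acc.tp_ref,
                "tp_pred": acc.tp_pred,
                "n_reference": acc.n_reference,
                "n_predicted": acc.n_predicted,
                "sensitivity": acc.sensitivity,
                "specificity": acc.specificity,
                "f1": acc.f1_score,
            }
        return out

    def as_frame(self) -> pd.DataFrame:
        d = self.as_dict()
        return pd.DataFrame(d).T[
            ["tp_ref", "tp_pred", "n_reference", "n_predicted", "sensitivity", "specificity", "f1"]
        ]


@dataclass
class GeneSetSummary:
    """Descriptive statistics of one predicted gene set."""

    n_genes: int
    n_transcripts: int
    mono_mult_ratio: float  # math.inf when no multi-exon first isoform exists
    max_exons: int
    n_incomplete: int


def f1(sn: float, sp: float) -> float:
    """Harmonic mean of sensitivity and specificity; 0 when both are 0."""
    if not (0 <= sn <= 1 and 0 <= sp <= 1):
        raise ValueError("sensitivity and specificity must lie in [0, 1]")
    if sn + sp == 0:
        return 0.0
    return 2 * sn * sp / (sn + sp)


def compare_gene_sets(
    pred: Sequence[GeneModel], ref: Sequence[GeneModel]
) -> AccuracyReport:
    """Exact-coordinate CDS comparison at gene, transcript and exon level.

    Matching is deduplicated: identical transcript structures are paired
    one-to-one (a structure occurring twice in the prediction matches at
    most two reference transcripts, and vice versa); exons are counted over
    distinct coordinates.
    """
    if not ref:
        raise ValueError("empty reference annotation")

    # exon level: distinct CDS exon coordinates
    pred_exons = {(m.seq_id, m.strand, a, b) for m in pred for a, b in m.cds_exons}
    ref_exons = {(m.seq_id, m.strand, a, b) for m in ref for a, b in m.cds_exons}
    exon_tp = len(pred_exons & ref_exons)
    exon = LevelAccuracy(exon_tp, exon_tp, len(ref_exons), len(pred_exons))

    # transcript level: identical ordered CDS exon lists, paired one-to-one
    def structure_counts(models: Sequence[GeneModel]) -> dict[tuple, int]:
        counts: dict[tuple, int] = {}
        for m in models:
            counts[m.structure_key()] = counts.get(m.structure_key(), 0) + 1
        return counts

    pred_struct = structure_counts(pred)
    ref_struct = structure_counts(ref)
    tx_tp = sum(
        min(n, ref_struct[s]) for s, n in pred_struct.items() if s in ref_struct
    )
    transcript = LevelAccuracy(tx_tp, tx_tp, len(ref), len(pred))

    # gene level: >=1 transcript matched, counted per side
    matched_structures = set(pred_struct) & set(ref_struct)
    ref_genes = {m.gene_id for m in ref}
    pred_genes = {m.gene_id for m in pred}
    ref_matched = {m.gene_id for m in ref if m.structure_key() in matched_structures}
    pred_matched = {m.gene_id for m in pred if m.structure_key() in matched_structures}
    gene = LevelAccuracy(
        len(ref_matched), len(pred_matched), len(ref_genes), len(pred_genes)
    )
    return AccuracyReport(gene=gene, transcript=transcript, exon=exon)


def summarize_gene_set(models: Sequence[GeneModel]) -> GeneSetSummary:
    """Gene counts, mono:mult ratio, max exon count, incomplete count.

    The mono:mult ratio considers only the first isoform of each gene
    (lexicographically smallest transcript id); genes whose first isoform
    has a single CDS exon count as mono-exonic.  The ratio is infinite when
    no multi-exonic first isoform exists.
    """
    first_isoform: dict[str, GeneModel] = {}
    for m in sorted(models, key=lambda m: m.transcript_id):
        first_isoform.setdefault(m.gene_id, m)
    mono = sum(1 for m in first_isoform.values() if m.n_exons == 1)
    multi = len(first_isoform) - mono
    ratio = mono / multi if multi else math.inf
    return GeneSetSummary(
        n_genes=len(first_isoform),
        n_transcripts=len(models),
        mono_mult_ratio=ratio,
        max_exons=max((m.n_exons for m in models), default=0),
        n_incomplete=sum(1 for m in models if m.completeness != "complete"),
    )


def reliable_subset(
    ref_a: Sequence[GeneModel], ref_b: Sequence[GeneModel]
) -> list[GeneModel]:
    """Transcripts reported identically by two annotation providers.

    Returns the transcripts of ``ref_a`` whose ordered CDS exon lists also
    occur in ``ref_b`` — a reliability filter for benchmark references of
    uneven curation quality.
    """
    b_structures = {m.structure_key() for m in ref_b}
    return [m for m in ref_a if m.structure_key() in b_structures]


def summarize_f1_table(per_species_f1: Sequence[float]) -> float:
    """Unweighted arithmetic mean of per-species F1 values, 2-decimal rounded."""
    if not len(per_species_f1):
        raise ValueError("empty F1 list")
    return round(sum(per_species_f1) / len(per_species_f1), 2)


def load_benchmark_f1() -> pd.DataFrame:
    """Published 14-species benchmark F1 table bundled with the package.

    Columns: species, pipeline, gene, transcript, exon — percentage
    F1-scores of several annotation pipelines against curated reference
    annotations; used as a worked example for the summary routines.
    """
    with resources.files("exonweave.data").joinpath("species_f1.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")
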