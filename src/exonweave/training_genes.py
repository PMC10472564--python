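"""Training-gene construction for the ab initio gene predictor.

A gene finder needs a set of trustworthy gene structures, each excised from
the genome together with flanking (hopefully intergenic) sequence, to
estimate its parameters.  This module

* turns high-confidence spliced alignments into candidate gene structures
  and keeps, per locus, only the best-scoring one;
* sizes the flanking regions from the observed gene-span distribution;
* supports the iterative refinement round: measuring evidence support of
  predicted genes and shrinking flanks so they contain no part of any
  other predicted gene ("decontamination").
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

from .formats import AlignmentChain, GeneModel, Hint, Interval
from .hint_scoring import IntronEvidence

logger = logging.getLogger(__name__)


class NoTrainingGenesError(RuntimeError):
    """No usable training genes could be derived — the pipeline must abort."""


@dataclass
class TrainingGene:
    """A selected gene structure plus the genomic window to excise."""

    source: str  # alignment|prediction
    model: GeneModel
    score: float
    flank: int = 0
    excised_window: Interval = (0, 0)

    def apply_flank(self, flank: int, seq_length: int | None = None) -> None:
        """Set a symmetric flank, clamped to sequence bounds when known."""
        s, e = self.model.span
        w0, w1 = s - flank, e + flank
        if seq_length is not None:
            if w0 < 0 or w1 > seq_length:
                logger.info(
                    "window of %s clamped to [0,%d)", self.model.transcript_id, seq_length
                )
            w0, w1 = max(0, w0), min(seq_length, w1)
        self.flank = flank
        self.excised_window = (w0, w1)


@dataclass
class SupportReport:
    """Evidence support of one predicted transcript."""

    transcript_id: str
    n_introns: int
    n_introns_supported: int
    cds_coverage_fraction: float
    fully_supported: bool


def chain_to_gene_model(chain: AlignmentChain) -> GeneModel:
    """Interpret an alignment chain as a CDS-level gene model."""
    return GeneModel(
        gene_id=f"{chain.protein_id}.g",
        transcript_id=f"{chain.protein_id}.t",
        seq_id=chain.seq_id,
        strand=chain.strand,
        cds_exons=list(chain.blocks),
    )


def _has_valid_orf(chain: AlignmentChain) -> bool:
    """Frame-consistent and free of homology-breaking events.

    The implied CDS must have length divisible by 3 and the alignment must
    record neither frameshifts nor in-frame stop codons anywhere.
    """
    cds_len = sum(b - a for a, b in chain.blocks)
    return cds_len % 3 == 0 and not chain.frameshifts and not chain.inframe_stops


def select_training_genes(
    chains: Sequence[AlignmentChain],
    evidence: Sequence[IntronEvidence],
    min_exons: int = 1,
) -> list[TrainingGene]:
    """Pick the best high-confidence alignment-derived gene per locus.

    Candidates are chains whose every intron is classified high-confidence,
    with a valid ORF and at least ``min_exons`` blocks.  A locus is a
    connected component of candidates whose CDS spans overlap on the same
    strand; within a locus exactly the chain with the highest alignment
    score survives (ties: longer CDS, then lexicographically smaller
    protein id).  Raises :class:`NoTrainingGenesError` when nothing
    qualifies, which mirrors the practical pipeline failure mode.
    """
    high = {
        (e.seq_id, e.strand, e.interval)
        for e in evidence
        if e.confidence == "high"
    }
    candidates = [
        c
        for c in chains
        if len(c.blocks) >= min_exons
        and _has_valid_orf(c)
        and all(
            (c.seq_id, c.strand, iv) in high for iv in c.intron_intervals
        )
    ]
    if not candidates:
        raise NoTrainingGenesError("no training genes")

    # sweep per (seq, strand) to build overlap components over CDS spans
    winners: list[AlignmentChain] = []
    by_group: dict[tuple[str, str], list[AlignmentChain]] = {}
    for c in candidates:
        by_group.setdefault((c.seq_id, c.strand), []).append(c)
    for group in by_group.values():
        group.sort(key=lambda c: c.span)
        locus: list[AlignmentChain] = []
        locus_end = -1
        for c in group:
            s, e = c.span
            if locus and s >= locus_end:
                winners.append(_best_of_locus(locus))
                locus, locus_end = [], -1
            locus.append(c)
            locus_end = max(locus_end, e)
        if locus:
            winners.append(_best_of_locus(locus))

    genes = [
        TrainingGene(source="alignment", model=chain_to_gene_model(c), score=c.alignment_score)
        for c in winners
    ]
    genes.sort(key=lambda g: (g.model.seq_id, g.model.span[0], g.model.span[1]))
    return genes


def _best_of_locus(locus: list[AlignmentChain]) -> AlignmentChain:
    def rank(c: AlignmentChain):
        cds_len = sum(b - a for a, b in c.blocks)
        return (-c.alignment_score, -cds_len, c.protein_id)

    return min(locus, key=rank)


def apply_flanks(
    genes: Sequence[TrainingGene],
    flank: int,
    seq_lengths: Mapping[str, int] | None = None,
) -> None:
    """Apply one common flank to all genes (clamped per sequence)."""
    for g in genes:
        seq_len = seq_lengths.get(g.model.seq_id) if seq_lengths else None
        g.apply_flank(flank, seq_len)


def compute_flank(
    genes: Sequence[TrainingGene], cap: int = 10_000, floor: int = 500
) -> int:
    """Common flank size: half the mean gene span, clamped to [floor, cap]."""
    if not genes:
        raise ValueError("compute_flank needs at least one gene")
    spans = [g.model.span[1] - g.model.span[0] for g in genes]
    flank = round(0.5 * sum(spans) / len(spans))
    return max(floor, min(cap, flank))


def evaluate_support(
    predictions: Sequence[GeneModel],
    hints: Sequence[Hint],
    coverage_threshold: float = 0.8,
) -> list[SupportReport]:
    """Measure extrinsic-evidence support of predicted transcripts.

    An intron is supported iff an intron hint matches its exact interval
    and strand.  CDS coverage is the fraction of CDS bases covered by the
    union of ``CDSpart`` hints.  A transcript is *fully supported* when all
    its introns are supported, coverage reaches the threshold, and the
    model is complete.
    """
    intron_hints = {
        (h.seq_id, h.strand, (h.start, h.end))
        for h in hints
        if h.feature == "intron"
    }
    cds_hints: dict[tuple[str, str], list[Interval]] = {}
    for h in hints:
        if h.feature == "CDSpart":
            cds_hints.setdefault((h.seq_id, h.strand), []).append((h.start, h.end))
    for ivs in cds_hints.values():
        ivs.sort()

    reports: list[SupportReport] = []
    for m in predictions:
        introns = m.introns
        n_supported = sum(
            1 for iv in introns if (m.seq_id, m.strand, iv) in intron_hints
        )
        covered = _covered_bp(m.cds_exons, cds_hints.get((m.seq_id, m.strand), []))
        frac = covered / m.cds_length if m.cds_length else 0.0
        fully = (
            n_supported == len(introns)
            and frac >= coverage_threshold
            and m.completeness == "complete"
        )
        reports.append(
            SupportReport(
                transcript_id=m.transcript_id,
                n_introns=len(introns),
                n_introns_supported=n_supported,
                cds_coverage_fraction=frac,
                fully_supported=fully,
            )
        )
    return reports


def _covered_bp(exons: Sequence[Interval], hint_ivs: Sequence[Interval]) -> int:
    """Base pairs of ``exons`` covered by the union of sorted ``hint_ivs``."""
    merged: list[Interval] = []
    for a, b in hint_ivs:
        if merged and a <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], b))
        else:
            merged.append((a, b))
    total = 0
    for a, b in exons:
        for ha, hb in merged:
            if hb <= a:
                continue
            if ha >= b:
                break
            total += min(b, hb) - max(a, ha)
    return total


def refine_flanks(
    training: Sequence[TrainingGene], all_predictions: Sequence[GeneModel]
) -> list[TrainingGene]:
    """Shrink excised windows until they contain no other predicted gene.

    For each training gene, any *other* predicted gene intersecting the
    window pushes the window edge to that gene's near boundary.  Windows
    never shrink below the training gene's own span; a neighbour
    overlapping the gene itself collapses the flank on that side to zero
    (logged as a conflict).
    """
    refined: list[TrainingGene] = []
    by_seq: dict[str, list[GeneModel]] = {}
    for p in all_predictions:
        by_seq.setdefault(p.seq_id, []).append(p)
    for g in training:
        s, e = g.model.span
        w0, w1 = g.excised_window
        for other in by_seq.get(g.model.seq_id, []):
            if other.transcript_id == g.model.transcript_id and other.strand == g.model.strand:
                if other.span == g.model.span:
                    continue  # the training gene's own prediction
            os_, oe = other.span
            if oe <= w0 or os_ >= w1:
                continue
            if oe <= s:  # neighbour in the left flank
                w0 = max(w0, oe)
            elif os_ >= e:  # right flank
                w1 = min(w1, os_)
            else:  # overlaps the training gene itself
                logger.warning(
                    "predicted gene %s overlaps training gene %s; flank collapsed",
                    other.transcript_id,
                    g.model.transcript_id,
                )
                if os_ < s:
                    w0 = s
                if oe > e:
                    w1 = e
        refined.append(
            TrainingGene(
                source=g.source,
                model=g.model,
                score=g.score,
                flank=g.flank,
                excised_window=(min(w0, s), max(w1, e)),
            )
        )
    return refined


def second_round_training_genes(
    predictions: Sequence[GeneModel],
    reports: Sequence[SupportReport],
    flank: int,
    seq_lengths: Mapping[str, int] | None = None,
) -> list[TrainingGene]:
    """Iterative-training round 2: keep fully supported predictions.

    The retained genes become the new training set; *all* predictions (kept
    or not) then delimit the flanking windows via :func:`refine_flanks`, so
    unsupported genes are eliminated only from flanking regions, never used
    for training.
    """
    supported = {r.transcript_id for r in reports if r.fully_supported}
    kept = [
        TrainingGene(source="prediction", model=m, score=1.0)
        for m in predictions
        if m.transcript_id in supported
    ]
    if not kept:
        raise NoTrainingGenesError("no training genes")
    for g in kept:
        seq_len = seq_lengths.get(g.model.seq_id) if seq_lengths else None
        g.apply_flank(flank, seq_len)
    return refine_flanks(kept, predictions)
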