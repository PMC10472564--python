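"""Intron evidence scoring and two-tier confidence classification.

Every candidate intron implied by a spliced protein-to-genome alignment is
scored by two complementary measures:

* **IBA** (intron border alignment): how well the exonic alignment columns
  flanking the intron are conserved, with exponentially larger weights for
  columns close to the donor and acceptor splice sites.  Columns classified
  as identical earn credit 1, positive-scoring substitutions a configurable
  partial credit, mismatches 0; the weighted means of the two sides are
  averaged.  Frameshift or in-frame-stop events inside the scored window
  each apply a multiplicative penalty — both are hallmarks of spurious
  homology.
* **IMC** (intron mapping coverage): the number of *distinct* donor
  proteins whose spliced alignments map the identical intron interval.

Evidence failing both a minimal IBA and a minimal IMC is discarded; the
remainder is split into high-confidence introns (enforced during
prediction, source tag ``M``) and low-confidence introns (suggested as
plain hints, source tag ``P``).  Exonic ``CDSpart`` hints and terminal
``start``/``stop`` hints are emitted alongside.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .formats import (
    COLUMN_CLASSES,
    IDENTICAL,
    MISMATCH,
    SUBSTITUTION,
    AlignmentChain,
    Hint,
    Junction,
)

logger = logging.getLogger(__name__)

IntronKey = tuple[str, str, tuple[int, int]]  # (seq_id, strand, interval)

_CREDIT = {IDENTICAL: 1.0, SUBSTITUTION: None, MISMATCH: 0.0}  # None -> config


@dataclass
class ScoringConfig:
    """Tunable parameters of the evidence scorer.

    ``window`` columns on each side of a junction enter the IBA score, the
    k-th column from the junction weighted ``decay**k``.  ``iba_min_keep``
    / ``imc_min_keep`` gate discarding (evidence is kept if EITHER holds);
    ``iba_min_high`` / ``imc_min_high`` gate the high-confidence class, same
    OR-combination.
    """

    window: int = 15
    decay: float = 0.8
    substitution_credit: float = 0.5
    event_penalty: float = 0.5
    iba_min_keep: float = 0.1
    imc_min_keep: int = 2
    iba_min_high: float = 0.25
    imc_min_high: int = 2
    cdspart_shrink: int = 9

    def __post_init__(self) -> None:
        if not (0 < self.decay <= 1):
            raise ValueError("decay must be in (0, 1]")
        if not (0 <= self.substitution_credit <= 1):
            raise ValueError("substitution_credit must be in [0, 1]")
        if not (0 < self.event_penalty <= 1):
            raise ValueError("event_penalty must be in (0, 1]")
        if self.window < 1:
            raise ValueError("window must be >= 1")
        if self.iba_min_high < self.iba_min_keep:
            raise ValueError("iba_min_high must be >= iba_min_keep")
        if min(self.imc_min_keep, self.imc_min_high) < 1:
            raise ValueError("IMC thresholds must be integers >= 1")


@dataclass
class IntronEvidence:
    """Aggregated evidence for one distinct candidate intron."""

    seq_id: str
    strand: str
    interval: tuple[int, int]
    iba: float
    imc: int
    supporting_proteins: set[str] = field(default_factory=set)
    n_frameshift_near: int = 0
    n_stop_near: int = 0
    confidence: str = "discarded"  # discarded|low|high


def _side_score(cols: Sequence[str], cfg: ScoringConfig) -> float:
    """Decay-weighted mean column credit of one junction side.

    A side with zero aligned columns scores 0 — an intron bordering nothing
    alignable carries no conservation signal.
    """
    total_w = 0.0
    total = 0.0
    for k, cls in enumerate(cols[: cfg.window]):
        if cls not in COLUMN_CLASSES:
            raise ValueError(f"unknown column class {cls!r}")
        credit = _CREDIT[cls]
        if credit is None:
            credit = cfg.substitution_credit
        w = cfg.decay**k
        total += w * credit
        total_w += w
    return total / total_w if total_w else 0.0


def score_iba(junction: Junction, cfg: ScoringConfig | None = None) -> float:
    """Intron border alignment score of one junction, in [0, 1].

    Mean of the two per-side decay-weighted credits, multiplied by
    ``event_penalty`` once per frameshift/in-frame-stop event within the
    scored window on either side.
    """
    cfg = cfg or ScoringConfig()
    score = 0.5 * (_side_score(junction.left_cols, cfg) + _side_score(junction.right_cols, cfg))
    n_events = sum(1 for d in junction.left_event_cols if d < cfg.window) + sum(
        1 for d in junction.right_event_cols if d < cfg.window
    )
    score *= cfg.event_penalty**n_events
    return min(1.0, max(0.0, score))


def compute_imc(
    chains: Iterable[AlignmentChain],
) -> dict[IntronKey, tuple[int, set[str]]]:
    """Count distinct supporting proteins per exactly-mapped intron.

    A protein aligned twice to the same locus with the same intron counts
    once; the same interval on opposite strands forms two separate keys.
    """
    support: dict[IntronKey, set[str]] = {}
    for chain in chains:
        for iv in chain.intron_intervals:
            key = (chain.seq_id, chain.strand, iv)
            support.setdefault(key, set()).add(chain.protein_id)
    return {k: (len(v), v) for k, v in support.items()}


def classify_evidence(
    chains: Sequence[AlignmentChain], cfg: ScoringConfig | None = None
) -> tuple[list[IntronEvidence], list[Hint]]:
    """Score, filter and classify all candidate introns; emit hints.

    Per distinct intron the IBA is the maximum over its supporting
    junctions (chains without residue detail contribute to IMC only).  The
    intron is discarded unless ``iba >= iba_min_keep`` OR
    ``imc >= imc_min_keep``; kept introns are high-confidence if
    ``iba >= iba_min_high`` OR ``imc >= imc_min_high``, else low.

    Hints: one intron hint per kept intron (``mult`` = IMC, score = IBA,
    confidence as classified); one ``CDSpart`` hint per alignment block,
    shrunk by ``cdspart_shrink`` bp on each side with a 1 bp floor; a
    ``start`` (``stop``) hint over the chain-terminal codon where the
    alignment covers the protein's first (last) residue.  Exonic and
    terminal hints are low confidence.
    """
    cfg = cfg or ScoringConfig()
    imc_map = compute_imc(chains)

    best_iba: dict[IntronKey, float] = {}
    fs_near: dict[IntronKey, int] = {}
    stop_near: dict[IntronKey, int] = {}
    for chain in chains:
        if chain.junctions is None:
            continue
        for junction in chain.junctions:
            key = (chain.seq_id, chain.strand, junction.intron)
            iba = score_iba(junction, cfg)
            if iba > best_iba.get(key, -1.0):
                best_iba[key] = iba
                n_fs = sum(
                    1
                    for p in chain.frameshifts
                    if _near_junction(p, junction, chain, cfg)
                )
                n_st = sum(
                    1
                    for p in chain.inframe_stops
                    if _near_junction(p, junction, chain, cfg)
                )
                fs_near[key] = n_fs
                stop_near[key] = n_st

    evidence: list[IntronEvidence] = []
    hints: list[Hint] = []
    for key in sorted(imc_map, key=lambda k: (k[0], k[2][0], k[2][1], k[1])):
        seq_id, strand, iv = key
        imc, proteins = imc_map[key]
        iba = best_iba.get(key, 0.0)
        keep = iba >= cfg.iba_min_keep or imc >= cfg.imc_min_keep
        if not keep:
            conf = "discarded"
        elif iba >= cfg.iba_min_high or imc >= cfg.imc_min_high:
            conf = "high"
        else:
            conf = "low"
        evidence.append(
            IntronEvidence(
                seq_id=seq_id,
                strand=strand,
                interval=iv,
                iba=iba,
                imc=imc,
                supporting_proteins=proteins,
                n_frameshift_near=fs_near.get(key, 0),
                n_stop_near=stop_near.get(key, 0),
                confidence=conf,
            )
        )
        if conf != "discarded":
            hints.append(
                Hint(
                    seq_id=seq_id,
                    feature="intron",
                    start=iv[0],
                    end=iv[1],
                    strand=strand,
                    score=round(iba, 4),
                    mult=imc,
                    confidence=conf,
                )
            )

    hints.extend(_exonic_and_terminal_hints(chains, cfg))
    hints.sort(key=lambda h: (h.seq_id, h.start, h.end, h.feature, h.strand))
    return evidence, hints


def _near_junction(
    pos: int, junction: Junction, chain: AlignmentChain, cfg: ScoringConfig
) -> bool:
    """Is a genomic event position within the scored window of a junction?"""
    s, e = junction.intron
    win_bp = 3 * cfg.window
    return (s - win_bp <= pos < s) or (e <= pos < e + win_bp)


def _exonic_and_terminal_hints(
    chains: Sequence[AlignmentChain], cfg: ScoringConfig
) -> list[Hint]:
    seen: set[tuple] = set()
    out: list[Hint] = []

    def add(h: Hint) -> None:
        key = (h.seq_id, h.feature, h.start, h.end, h.strand)
        if key not in seen:
            seen.add(key)
            out.append(h)

    for chain in chains:
        for a, b in chain.blocks:
            s = a + cfg.cdspart_shrink
            e = b - cfg.cdspart_shrink
            if e - s < 1:  # floor: keep at least the central base
                mid = (a + b) // 2
                s, e = mid, mid + 1
            add(
                Hint(
                    seq_id=chain.seq_id,
                    feature="CDSpart",
                    start=s,
                    end=e,
                    strand=chain.strand,
                    score=round(chain.identity, 4),
                    mult=1,
                    confidence="low",
                )
            )
        first, last = chain.blocks[0], chain.blocks[-1]
        if chain.strand == "+":
            start_iv, stop_iv = (first[0], first[0] + 3), (last[1] - 3, last[1])
        else:
            start_iv, stop_iv = (last[1] - 3, last[1]), (first[0], first[0] + 3)
        if chain.covers_protein_start:
            add(
                Hint(
                    seq_id=chain.seq_id,
                    feature="start",
                    start=start_iv[0],
                    end=start_iv[1],
                    strand=chain.strand,
                    score=round(chain.identity, 4),
                    mult=1,
                    confidence="low",
                )
            )
        if chain.covers_protein_end:
            add(
                Hint(
                    seq_id=chain.seq_id,
                    feature="stop",
                    start=stop_iv[0],
                    end=stop_iv[1],
                    strand=chain.strand,
                    score=round(chain.identity, 4),
                    mult=1,
                    confidence="low",
                )
            )
    return out


def evidence_table(evidence: Sequence[IntronEvidence]) -> pd.DataFrame:
    """Tabulate classified evidence (TSV-ready: one row per intron)."""
    return pd.DataFrame(
        {
            "seq_id": [e.seq_id for e in evidence],
            "start": [e.interval[0] for e in evidence],
            "end": [e.interval[1] for e in evidence],
            "strand": [e.strand for e in evidence],
            "iba": [round(e.iba, 4) for e in evidence],
            "imc": [e.imc for e in evidence],
            "class": [e.confidence for e in evidence],
        }
    )
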