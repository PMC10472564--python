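"""Overlap-chunked parallel prediction planning and duplicate-free merging.

The external gene predictor is single-threaded, so large sequences are
split into overlapping windows that are predicted independently and small
sequences are batched into joint jobs.  Overlaps prevent the truncation of
genes near window borders; afterwards the redundant predictions from
overlapping windows must be removed deterministically.  Each window owns a
*responsibility interval*; the responsibility intervals of one sequence
partition it exactly, splitting every overlap at its centre, and a
transcript is kept by the window whose responsibility contains its
midpoint.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .formats import GeneModel, GenomeSequence, Interval

logger = logging.getLogger(__name__)


def max_intron_size(genome_size: int) -> int:
    """Genome-size-dependent intron length cap: floor(3.6 * sqrt(size)).

    Used by the spliced aligner to bound intron search; chunk overlaps
    should be at least twice this value so no gene is split by a window
    border that the aligner could have bridged.
    """
    if genome_size <= 0:
        raise ValueError("genome_size must be positive")
    return math.floor(3.6 * math.sqrt(genome_size))


@dataclass
class ChunkEntry:
    chunk_id: int
    seq_id: str
    window: Interval
    responsibility: Interval


@dataclass
class ChunkPlan:
    entries: list[ChunkEntry] = field(default_factory=list)
    chunk_size: int = 5_000_000
    overlap: int = 1_000_000
    batch_target: int = 5_000_000

    def entries_for_chunk(self, chunk_id: int) -> list[ChunkEntry]:
        return [e for e in self.entries if e.chunk_id == chunk_id]

    @property
    def n_chunks(self) -> int:
        return len({e.chunk_id for e in self.entries})

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("chunk_id\tseq_id\twin_start\twin_end\tresp_start\tresp_end\n")
            for e in self.entries:
                fh.write(
                    f"{e.chunk_id}\t{e.seq_id}\t{e.window[0]}\t{e.window[1]}\t"
                    f"{e.responsibility[0]}\t{e.responsibility[1]}\n"
                )

    @classmethod
    def from_tsv(cls, path, **cfg) -> "ChunkPlan":
        plan = cls(**cfg)
        with open(path) as fh:
            next(fh)
            for line in fh:
                cid, sid, w0, w1, r0, r1 = line.rstrip("\n").split("\t")
                plan.entries.append(
                    ChunkEntry(int(cid), sid, (int(w0), int(w1)), (int(r0), int(r1)))
                )
        return plan


def plan_chunks(
    assembly: Sequence[GenomeSequence],
    chunk_size: int = 5_000_000,
    overlap: int = 1_000_000,
    batch_target: int = 5_000_000,
    genome_size: int | None = None,
) -> ChunkPlan:
    """Plan prediction windows over an assembly.

    Sequences longer than ``chunk_size`` are tiled with stride
    ``chunk_size - overlap``; the final window is clamped to the sequence
    end and its start pulled back to preserve the full chunk size when
    possible (so boundary genes see maximal context).  Sequences up to
    ``chunk_size`` are greedily packed, in input order, into batches whose
    total length stays within ``batch_target``; each batch is one chunk and
    every member sequence is its own responsibility interval.
    """
    if overlap >= chunk_size:
        raise ValueError("overlap must be smaller than chunk_size")
    if overlap < 0:
        raise ValueError("overlap must be non-negative")
    total = genome_size or sum(s.length for s in assembly)
    cap = max_intron_size(total) if total > 0 else 0
    if overlap < 2 * cap:
        logger.warning(
            "overlap %d is below twice the intron cap %d; genes spanning "
            "window borders may be truncated",
            overlap,
            cap,
        )

    plan = ChunkPlan(chunk_size=chunk_size, overlap=overlap, batch_target=batch_target)
    next_id = 0
    stride = chunk_size - overlap

    # large sequences: overlapping tiling, deterministic by (seq_id, start)
    for seq in sorted(
        (s for s in assembly if s.length > chunk_size), key=lambda s: s.seq_id
    ):
        windows: list[Interval] = []
        start = 0
        while True:
            end = start + chunk_size
            if end >= seq.length:
                end = seq.length
                start = max(0, end - chunk_size)  # final-window pullback
                windows.append((start, end))
                break
            windows.append((start, end))
            start += stride
        # responsibilities: split each overlap at its centre
        bounds = [0]
        for i in range(len(windows) - 1):
            ov_lo, ov_hi = windows[i + 1][0], windows[i][1]
            bounds.append((ov_lo + ov_hi) // 2)
        bounds.append(seq.length)
        for (w, b0, b1) in zip(windows, bounds[:-1], bounds[1:]):
            plan.entries.append(ChunkEntry(next_id, seq.seq_id, w, (b0, b1)))
            next_id += 1

    # small sequences: greedy batching in input order
    batch: list[GenomeSequence] = []
    batch_len = 0

    def flush() -> None:
        nonlocal batch, batch_len, next_id
        if batch:
            for s in batch:
                plan.entries.append(
                    ChunkEntry(next_id, s.seq_id, (0, s.length), (0, s.length))
                )
            next_id += 1
            batch, batch_len = [], 0

    for seq in (s for s in assembly if s.length <= chunk_size):
        if batch and batch_len + seq.length > batch_target:
            flush()
        batch.append(seq)
        batch_len += seq.length
    flush()
    return plan


def write_chunk_fastas(
    plan: ChunkPlan, assembly: Sequence[GenomeSequence], out_dir
) -> dict[int, str]:
    """Emit one ``chunk_{id}.fa`` per chunk; returns chunk_id -> path."""
    from pathlib import Path

    from .formats import write_fasta

    seq_by_id = {s.seq_id: s for s in assembly}
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[int, str] = {}
    for cid in sorted({e.chunk_id for e in plan.entries}):
        members = plan.entries_for_chunk(cid)
        records = []
        for e in members:
            src = seq_by_id[e.seq_id]
            w0, w1 = e.window
            records.append(
                GenomeSequence(e.seq_id, src.residues[w0:w1], src.mask[w0:w1])
            )
        path = out_dir / f"chunk_{cid}.fa"
        write_fasta(records, path)
        paths[cid] = str(path)
    return paths


def remap_predictions(
    chunk_id: int, models: Sequence[GeneModel], plan: ChunkPlan
) -> list[GeneModel]:
    """Shift chunk-local gene models back to genome coordinates.

    For tiled windows all intervals shift by the window start; for batched
    sequences coordinates are already sequence-local and only sanity
    checking applies.  A model exceeding its window bounds is an error.
    """
    entries = plan.entries_for_chunk(chunk_id)
    if not entries:
        raise KeyError(f"chunk {chunk_id} not in plan")
    by_seq = {e.seq_id: e for e in entries}
    out: list[GeneModel] = []
    for m in models:
        e = by_seq.get(m.seq_id)
        if e is None:
            raise ValueError(
                f"chunk {chunk_id}: model {m.transcript_id} on unknown sequence "
                f"{m.seq_id}"
            )
        w0, w1 = e.window
        if m.span[1] > w1 - w0:
            raise ValueError(
                f"chunk {chunk_id}: model {m.transcript_id} exceeds window bounds"
            )
        out.append(
            GeneModel(
                gene_id=m.gene_id,
                transcript_id=m.transcript_id,
                seq_id=m.seq_id,
                strand=m.strand,
                cds_exons=[(a + w0, b + w0) for a, b in m.cds_exons],
                completeness=m.completeness,
            )
        )
    return out


def merge_chunk_predictions(
    per_chunk: Mapping[int, Sequence[GeneModel]], plan: ChunkPlan
) -> list[GeneModel]:
    """Merge remapped per-chunk predictions, removing overlap redundancy.

    A transcript survives with the copy from the chunk whose responsibility
    interval contains its midpoint, provided that chunk's window fully
    contains it; otherwise the copy from the lowest-indexed chunk fully
    containing it is kept.  Transcripts fully contained in no window are
    kept once (lowest chunk index) and flagged truncated.  Exact duplicate
    structures collapse to one.  Output is sorted by (seq_id, start).
    """
    window_of: dict[tuple[int, str], Interval] = {}
    resp: dict[str, list[tuple[Interval, int]]] = {}
    for e in plan.entries:
        window_of[(e.chunk_id, e.seq_id)] = e.window
        resp.setdefault(e.seq_id, []).append((e.responsibility, e.chunk_id))
    for v in resp.values():
        v.sort()

    # group identical structures across emitting chunks
    copies: dict[tuple, list[tuple[int, GeneModel]]] = {}
    for cid in sorted(per_chunk):
        for m in per_chunk[cid]:
            copies.setdefault(m.structure_key(), []).append((cid, m))

    merged: list[GeneModel] = []
    for key in sorted(copies, key=lambda k: (k[0], k[2][0][0], k[2][-1][1], k[1])):
        emitters = copies[key]
        seq_id = key[0]
        span = (key[2][0][0], key[2][-1][1])
        midpoint = (span[0] + span[1]) // 2
        owner = None
        for (r0, r1), cid in resp.get(seq_id, []):
            if r0 <= midpoint < r1:
                owner = cid
                break
        containing = [
            (cid, m)
            for cid, m in emitters
            if _contains(window_of.get((cid, seq_id)), span)
        ]
        chosen: GeneModel | None = None
        if owner is not None:
            owner_win = window_of.get((owner, seq_id))
            if _contains(owner_win, span):
                for cid, m in emitters:
                    if cid == owner:
                        chosen = m
                        break
                if chosen is None and containing:
                    chosen = containing[0][1]
            elif containing:
                chosen = containing[0][1]
        elif containing:
            chosen = containing[0][1]
        if chosen is None:
            cid, m = emitters[0]
            m = GeneModel(
                gene_id=m.gene_id,
                transcript_id=m.transcript_id,
                seq_id=m.seq_id,
                strand=m.strand,
                cds_exons=m.cds_exons,
                completeness=m.completeness,
                truncated=True,
            )
            chosen = m
        merged.append(chosen)
    merged.sort(key=lambda m: (m.seq_id, m.span[0], m.span[1], m.strand))
    return merged


def _contains(window: Interval | None, span: Interval) -> bool:
    return window is not None and window[0] <= span[0] and span[1] <= window[1]


def renumber_models(models: Sequence[GeneModel], prefix: str = "g") -> list[GeneModel]:
    """Assign position-ordered deterministic ids (final-output canonical form)."""
    out: list[GeneModel] = []
    ordered = sorted(models, key=lambda m: (m.seq_id, m.span[0], m.span[1], m.strand))
    for i, m in enumerate(ordered, 1):
        out.append(
            GeneModel(
                gene_id=f"{prefix}{i}",
                transcript_id=f"{prefix}{i}.t1",
                seq_id=m.seq_id,
                strand=m.strand,
                cds_exons=m.cds_exons,
                completeness=m.completeness,
                truncated=m.truncated,
            )
        )
    return out
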