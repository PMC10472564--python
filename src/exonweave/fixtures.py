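"""Synthetic annotation fixtures with known ground truth.

The generator builds toy genomes with planted multi-exon protein-coding
genes (canonical ``GT..AG`` introns, ``ATG`` start, single terminal stop),
derives donor proteomes at a controlled per-residue divergence, and induces
the spliced alignments those donors would produce against the genome —
including frameshift and in-frame-stop corruption at configurable
per-block rates.  A deterministic, window-local mock gene predictor closes
the loop, so hint scoring, training-gene selection, chunked prediction and
merging are all testable end to end without any external binary.

Everything is driven by one seeded :class:`numpy.random.Generator`; the
same seed yields byte-identical outputs.

What the fixtures deliberately do *not* emulate: repeat content, GC
isochores, alternative splicing, spurious alignments to paralogous loci,
and phylogenetic substitution processes (divergence is a flat per-residue
substitution probability).  Alignment induction reproduces the true exon
blocks exactly, so recovery experiments measure the scorer's filtering
behaviour, not aligner errors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from Bio.Seq import Seq

from .formats import (
    IDENTICAL,
    MISMATCH,
    SUBSTITUTION,
    AlignmentChain,
    BlockSummary,
    GeneModel,
    GenomeSequence,
    Hint,
    Interval,
    _build_junctions,
)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: residue similarity groups: substitutions within a group are scored as
#: positive ("S" columns), across groups as mismatches ("X" columns)
SIMILAR_GROUPS = ("ILVM", "KR", "DE", "ST", "FYW", "NQ", "AG", "C", "H", "P")

_GROUP_OF = {aa: g for g in SIMILAR_GROUPS for aa in g}

_STOPS = {"TAA", "TAG", "TGA"}
_CODING_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in _STOPS
]


@dataclass
class FixtureConfig:
    """Geometry and noise model of one synthetic annotation scenario."""

    seed: int = 0
    n_sequences: int = 1
    sequence_length: int = 100_000
    n_genes: int = 10
    exons_per_gene: tuple[int, int] = (2, 4)
    exon_length: tuple[int, int] = (60, 240)  # sampled as multiples of 3
    intron_length: tuple[int, int] = (60, 240)
    # gaps stay above the mock predictor's cluster join distance so planted
    # neighbours never fuse, and above its edge margin so border genes are
    # treated identically in chunked and unchunked runs
    intergenic_length: tuple[int, int] = (1200, 2000)
    protein_divergence: float = 0.0
    frameshift_rate: float = 0.0
    stop_rate: float = 0.0
    n_donor_proteomes: int = 1

    def __post_init__(self) -> None:
        for r in (self.protein_divergence, self.frameshift_rate, self.stop_rate):
            if not (0 <= r <= 1):
                raise ValueError("rates must lie in [0, 1]")


PRESETS: dict[str, FixtureConfig] = {
    "tiny": FixtureConfig(
        n_genes=5, sequence_length=30_000, n_donor_proteomes=2, protein_divergence=0.02
    ),
    "default": FixtureConfig(
        n_genes=50,
        sequence_length=500_000,
        n_donor_proteomes=3,
        protein_divergence=0.05,
        frameshift_rate=0.02,
        stop_rate=0.02,
    ),
    "stress": FixtureConfig(
        n_genes=200,
        n_sequences=4,
        sequence_length=600_000,
        n_donor_proteomes=3,
        protein_divergence=0.15,
        frameshift_rate=0.05,
        stop_rate=0.05,
    ),
}


@dataclass
class Fixture:
    """One generated scenario: genome, truth, donors and induced alignments."""

    config: FixtureConfig
    assembly: list[GenomeSequence]
    truth: list[GeneModel]
    proteins: list[str]  # exact translations, parallel to truth
    donor_proteomes: list[list[str]] = field(default_factory=list)
    chains: list[AlignmentChain] = field(default_factory=list)


_BASES = np.frombuffer(b"ACGT", dtype="S1")


def _random_dna(rng: np.random.Generator, n: int) -> str:
    if n <= 0:
        return ""
    return _BASES[rng.integers(0, 4, size=n)].tobytes().decode()


def _revcomp(s: str) -> str:
    return str(Seq(s).reverse_complement())


def make_genome_with_genes(
    cfg: FixtureConfig,
) -> tuple[list[GenomeSequence], list[GeneModel], list[str]]:
    """Plant protein-coding genes in random intergenic background.

    Every gene has an ``ATG`` start, canonical ``GT..AG`` introns at codon
    boundaries, and a single terminal ``TAA`` stop included in the CDS.
    The returned proteins are the exact translations of the truth models.
    Raises ``ValueError`` when the requested genes do not fit.
    """
    rng = np.random.default_rng(cfg.seed)
    per_seq = [cfg.n_genes // cfg.n_sequences] * cfg.n_sequences
    for i in range(cfg.n_genes % cfg.n_sequences):
        per_seq[i] += 1

    assembly: list[GenomeSequence] = []
    truth: list[GeneModel] = []
    proteins: list[str] = []
    gene_no = 0
    for si in range(cfg.n_sequences):
        seq_id = f"seq{si + 1}"
        parts: list[str] = []
        cursor = 0
        for _ in range(per_seq[si]):
            gap = int(rng.integers(*cfg.intergenic_length, endpoint=True))
            parts.append(_random_dna(rng, gap))
            cursor += gap
            gene_seq, local_exons, protein, strand = _build_gene(cfg, rng)
            exons = [(cursor + a, cursor + b) for a, b in local_exons]
            cursor += len(gene_seq)
            if cursor > cfg.sequence_length:
                raise ValueError(
                    f"infeasible geometry: genes do not fit in "
                    f"sequence_length={cfg.sequence_length}"
                )
            gene_no += 1
            parts.append(gene_seq)
            truth.append(
                GeneModel(
                    gene_id=f"g{gene_no}",
                    transcript_id=f"g{gene_no}.t1",
                    seq_id=seq_id,
                    strand=strand,
                    cds_exons=exons,
                )
            )
            proteins.append(protein)
        tail = cfg.sequence_length - cursor
        parts.append(_random_dna(rng, tail))
        assembly.append(GenomeSequence(seq_id, "".join(parts)))
    return assembly, truth, proteins


def _build_gene(
    cfg: FixtureConfig, rng: np.random.Generator
) -> tuple[str, list[Interval], str, str]:
    """One gene region in genome-forward orientation plus local CDS exons."""
    n_exons = int(rng.integers(*cfg.exons_per_gene, endpoint=True))
    exon_lens = [
        3 * int(rng.integers(cfg.exon_length[0] // 3, cfg.exon_length[1] // 3 + 1))
        for _ in range(n_exons)
    ]
    n_codons = sum(exon_lens) // 3
    codons = ["ATG"] + [
        _CODING_CODONS[int(i)]
        for i in rng.integers(0, len(_CODING_CODONS), size=n_codons - 2)
    ] + ["TAA"]
    cds = "".join(codons)
    protein = str(Seq(cds).translate())[:-1]  # drop the stop symbol

    # assemble exons + canonical introns in biological orientation
    pieces: list[str] = []
    exons_bio: list[Interval] = []
    pos = 0
    offset = 0
    for i, el in enumerate(exon_lens):
        exon = cds[offset : offset + el]
        offset += el
        pieces.append(exon)
        exons_bio.append((pos, pos + el))
        pos += el
        if i < n_exons - 1:
            il = int(rng.integers(*cfg.intron_length, endpoint=True))
            intron = "GT" + _random_dna(rng, il - 4) + "AG"
            pieces.append(intron)
            pos += il
    gene_seq = "".join(pieces)

    strand = "+" if rng.random() < 0.5 else "-"
    if strand == "-":
        gene_seq = _revcomp(gene_seq)
        total = len(gene_seq)
        exons_local = sorted((total - b, total - a) for a, b in exons_bio)
    else:
        exons_local = exons_bio
    return gene_seq, exons_local, protein, strand


def diverge_proteins(
    proteins: Sequence[str], divergence: float, seed_or_rng
) -> list[str]:
    """Substitute each residue with the given probability.

    Replacements come from a fixed table: with probability one half a
    residue from the same similarity group (a positive substitution) when
    the group has one, otherwise a uniformly random different amino acid.
    Deterministic for a given seed.
    """
    if not (0 <= divergence <= 1):
        raise ValueError("divergence must lie in [0, 1]")
    rng = (
        seed_or_rng
        if isinstance(seed_or_rng, np.random.Generator)
        else np.random.default_rng(seed_or_rng)
    )
    out: list[str] = []
    for p in proteins:
        chars = list(p)
        for i, aa in enumerate(chars):
            if rng.random() >= divergence:
                continue
            group = [g for g in _GROUP_OF.get(aa, aa) if g != aa]
            if group and rng.random() < 0.5:
                chars[i] = group[int(rng.integers(len(group)))]
            else:
                others = [a for a in AMINO_ACIDS if a != aa]
                chars[i] = others[int(rng.integers(len(others)))]
        out.append("".join(chars))
    return out


def _column_class(orig: str, donor: str) -> str:
    if orig == donor:
        return IDENTICAL
    if _GROUP_OF.get(orig) is not None and _GROUP_OF.get(orig) == _GROUP_OF.get(donor):
        return SUBSTITUTION
    return MISMATCH


def induce_alignments(
    truth: Sequence[GeneModel],
    proteins: Sequence[str],
    donor_proteomes: Sequence[Sequence[str]],
    cfg: FixtureConfig,
    rng: np.random.Generator | None = None,
) -> list[AlignmentChain]:
    """Build the spliced alignments the donor proteins would induce.

    Chains reproduce the true exon blocks exactly; per-codon column classes
    reflect the realized divergence of each donor residue relative to the
    target translation (start and stop codons anchor as identical).
    Frameshift and in-frame-stop events are injected per block at the
    configured rates, with genomic positions recorded.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed + 1)
    chains: list[AlignmentChain] = []
    for di, proteome in enumerate(donor_proteomes):
        for gi, model in enumerate(truth):
            chains.append(
                _chain_for(model, proteins[gi], proteome[gi], f"d{di + 1}_p{gi + 1}", cfg, rng)
            )
    return chains


def _chain_for(
    model: GeneModel,
    original: str,
    donor: str,
    protein_id: str,
    cfg: FixtureConfig,
    rng: np.random.Generator,
) -> AlignmentChain:
    # per-codon classes in biological order: start, residues..., stop
    classes_bio = (
        [IDENTICAL]
        + [_column_class(o, d) for o, d in zip(original, donor)]
        + [IDENTICAL]
    )
    exons_bio = model.cds_exons if model.strand == "+" else model.cds_exons[::-1]
    block_cols_bio: list[list[str]] = []
    k = 0
    for a, b in exons_bio:
        n = (b - a) // 3
        block_cols_bio.append(classes_bio[k : k + n])
        k += n

    if model.strand == "+":
        blocks = list(model.cds_exons)
        block_cols = block_cols_bio
    else:
        blocks = list(model.cds_exons)
        block_cols = [list(reversed(c)) for c in reversed(block_cols_bio)]

    frameshifts: list[int] = []
    stops: list[int] = []
    for (a, b) in blocks:
        if rng.random() < cfg.frameshift_rate:
            frameshifts.append(int(rng.integers(a, b)))
        if rng.random() < cfg.stop_rate:
            stops.append(int(rng.integers(a, b)))

    summaries = [
        BlockSummary(
            identical=c.count(IDENTICAL),
            positive=c.count(SUBSTITUTION),
            mismatch=c.count(MISMATCH),
        )
        for c in block_cols
    ]
    total = sum(s.total for s in summaries)
    ident = sum(s.identical for s in summaries)
    n_events = len(frameshifts) + len(stops)
    score = (
        2.0 * ident
        + 1.0 * sum(s.positive for s in summaries)
        - 1.0 * sum(s.mismatch for s in summaries)
        - 10.0 * n_events
    )
    junctions = _build_junctions(blocks, block_cols, frameshifts, stops)
    plen = len(original)
    chain = AlignmentChain(
        protein_id=protein_id,
        seq_id=model.seq_id,
        strand=model.strand,
        blocks=blocks,
        block_summaries=summaries,
        frameshifts=sorted(frameshifts),
        inframe_stops=sorted(stops),
        alignment_score=score,
        identity=ident / total if total else 0.0,
        junctions=junctions if len(blocks) > 1 else [],
        protein_start=0,
        protein_end=plen,
        protein_length=plen,
    )
    if len(blocks) == 1:
        chain._single_block_cols = list(block_cols[0])  # round-trip aid
    return chain


def make_fixture(cfg: FixtureConfig) -> Fixture:
    """Generate the full scenario: genome, truth, donors and alignments."""
    assembly, truth, proteins = make_genome_with_genes(cfg)
    # independent streams: corruption events must not depend on how many
    # draws the divergence step consumed, so that recovery curves over a
    # divergence grid see identical event sets (common random numbers)
    rng_div = np.random.default_rng(cfg.seed + 1)
    rng_aln = np.random.default_rng(cfg.seed + 2)
    donors = [
        diverge_proteins(proteins, cfg.protein_divergence, rng_div)
        for _ in range(cfg.n_donor_proteomes)
    ]
    chains = induce_alignments(truth, proteins, donors, cfg, rng_aln)
    return Fixture(cfg, assembly, truth, proteins, donors, chains)


# ---------------------------------------------------------------------------
# mock predictor
# ---------------------------------------------------------------------------


def mock_predictor(
    window: GenomeSequence,
    hints: Sequence[Hint],
    join_distance: int = 500,
    edge_margin: int = 1000,
    cdspart_shrink: int = 9,
) -> list[GeneModel]:
    """Deterministic window-local hint-based gene caller.

    Reconstructs gene models purely from the hints whose (window-local)
    coordinates fall fully inside the window: same-strand intron and
    ``CDSpart`` hints closer than ``join_distance`` are clustered into one
    gene, exon boundaries are recovered by undoing the ``CDSpart`` shrink,
    and any cluster within ``edge_margin`` of a window border is dropped as
    potentially truncated.  The output depends on nothing outside the
    window, which is what makes chunked-versus-unchunked equivalence a
    valid oracle; equivalence is guaranteed when the chunk overlap exceeds
    ``2 * edge_margin`` plus the largest gene span, and ``edge_margin``
    exceeds the largest intron plus exon.
    """
    length = window.length
    local = [
        h
        for h in hints
        if h.seq_id == window.seq_id and 0 <= h.start and h.end <= length
    ]
    out: list[GeneModel] = []
    for strand in "+-":
        items = sorted(
            ((h.start, h.end, h.feature) for h in local if h.strand == strand and h.feature in ("intron", "CDSpart")),
        )
        clusters: list[list[tuple[int, int, str]]] = []
        for item in items:
            if clusters and item[0] - max(e for _, e, _ in clusters[-1]) <= join_distance:
                clusters[-1].append(item)
            else:
                clusters.append([item])
        for cluster in clusters:
            cds_hints = [(s, e) for s, e, f in cluster if f == "CDSpart"]
            introns = sorted({(s, e) for s, e, f in cluster if f == "intron"})
            if not cds_hints:
                continue
            cds_start = min(s for s, _ in cds_hints) - cdspart_shrink
            cds_end = max(e for _, e in cds_hints) + cdspart_shrink
            if cds_start < edge_margin or cds_end > length - edge_margin:
                continue  # potentially truncated at a window border
            bounds = [cds_start]
            ok = True
            for i0, i1 in introns:
                if i0 <= bounds[-1] or i1 >= cds_end:
                    ok = False
                    break
                bounds.extend([i0, i1])
            if not ok:
                continue
            bounds.append(cds_end)
            exons = [(bounds[i], bounds[i + 1]) for i in range(0, len(bounds), 2)]
            if any(b <= a for a, b in exons):
                continue
            out.append(
                GeneModel(
                    gene_id=f"mp_{window.seq_id}_{strand}{cds_start}",
                    transcript_id=f"mp_{window.seq_id}_{strand}{cds_start}.t1",
                    seq_id=window.seq_id,
                    strand=strand,
                    cds_exons=exons,
                )
            )
    out.sort(key=lambda m: (m.span[0], m.span[1], m.strand))
    return out


def run_mock_predictor_on_plan(
    assembly: Sequence[GenomeSequence],
    hints: Sequence[Hint],
    plan,
    **predictor_kwargs,
) -> dict[int, list[GeneModel]]:
    """Run the mock predictor per chunk (hints localized per window)."""
    from .chunking import remap_predictions

    seq_by_id = {s.seq_id: s for s in assembly}
    per_chunk: dict[int, list[GeneModel]] = {}
    for cid in sorted({e.chunk_id for e in plan.entries}):
        models: list[GeneModel] = []
        for e in plan.entries_for_chunk(cid):
            src = seq_by_id[e.seq_id]
            w0, w1 = e.window
            local_seq = GenomeSequence(e.seq_id, src.residues[w0:w1], src.mask[w0:w1])
            local_hints = [
                Hint(
                    seq_id=h.seq_id,
                    feature=h.feature,
                    start=h.start - w0,
                    end=h.end - w0,
                    strand=h.strand,
                    score=h.score,
                    mult=h.mult,
                    confidence=h.confidence,
                )
                for h in hints
                if h.seq_id == e.seq_id and h.start >= w0 and h.end <= w1
            ]
            models.extend(mock_predictor(local_seq, local_hints, **predictor_kwargs))
        per_chunk[cid] = remap_predictions(cid, models, plan)
    return per_chunk


def emit_fixture(fixture: Fixture, out_dir: str | Path) -> dict[str, str]:
    """Write a fixture to disk in the package's external formats."""
    from .formats import (
        write_alignments_compact,
        write_fasta,
        write_gene_models,
    )

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome": str(out / "genome.fa"),
        "truth": str(out / "truth.gff3"),
        "alignments": str(out / "alignments.aln"),
        "proteins": str(out / "proteins.fa"),
    }
    write_fasta(fixture.assembly, paths["genome"])
    write_gene_models(fixture.truth, paths["truth"], dialect="gff3")
    write_alignments_compact(fixture.chains, paths["alignments"])
    with open(paths["proteins"], "w") as fh:
        for di, proteome in enumerate(fixture.donor_proteomes):
            for gi, p in enumerate(proteome):
                fh.write(f">d{di + 1}_p{gi + 1}\n{p}\n")
    return paths
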