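"""Greedy seed-extension transcript assembly.

A deliberately simple assembler for venom-gland merged reads: it takes
quality-filtered reads as seeds and extends each seed end by reads whose
terminal ``overlap`` bases (120 by default) exactly match the contig's
terminal bases. The exact long-overlap requirement is what lets it walk
through highly similar toxin paralogs without collapsing them: at 2%
nucleotide divergence a 120-nt window almost always contains several
diagnostic differences, so reads from a sister paralog simply never match.

Not a general-purpose assembler: no de Bruijn graph, no scaffolding, no
paired-end logic. Conflict handling when candidate reads disagree beyond
the overlap is majority voting per extended position; an exact tie stops
extension at that end and flags the contig rather than fabricating a
chimera.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from venomont.datatypes import ValidationError

DEFAULT_OVERLAP = 120
DEFAULT_MIN_READS = 200

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Read:
    """One merged read with per-base phred qualities."""

    id: str
    sequence: str
    qualities: tuple[int, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "qualities", tuple(self.qualities))
        if len(self.sequence) != len(self.qualities):
            raise ValidationError(
                f"read {self.id!r}: sequence length {len(self.sequence)} != "
                f"{len(self.qualities)} qualities"
            )

    @property
    def min_quality(self) -> int:
        return min(self.qualities) if self.qualities else 0


@dataclass
class Contig:
    sequence: str
    n_reads_assembled: int = 0
    per_base_depth: list[int] = field(default_factory=list)
    flagged: bool = False  # extension stopped on an unresolvable conflict

    def __len__(self) -> int:
        return len(self.sequence)


def filter_high_quality(reads: list[Read], min_phred: int = 30) -> list[Read]:
    """Keep exactly the reads whose every base has phred >= ``min_phred``."""
    return [r for r in reads if r.qualities and r.min_quality >= min_phred]


class _OverlapIndex:
    """Every ``overlap``-mer of every read (both orientations), with position.

    A read extends the right end of a contig when the contig's terminal
    ``overlap``-mer occurs in the read at position p, the read's first
    p + overlap bases exactly match the contig's tail (the whole overlap
    region matches, with the 120-nt window as the minimum), and the read
    continues beyond it.
    """

    def __init__(self, reads: list[Read], overlap: int):
        self.overlap = overlap
        self.kmers: dict[str, list[tuple[str, int]]] = {}
        for r in sorted(reads, key=lambda r: r.id):  # canonical order
            for seq in (r.sequence, revcomp(r.sequence)):
                for p in range(len(seq) - overlap + 1):
                    self.kmers.setdefault(seq[p : p + overlap], []).append((seq, p))

    def extensions(self, contig: str) -> list[str]:
        """Non-empty extensions of reads exactly matching the contig's tail."""
        out = []
        for seq, p in self.kmers.get(contig[-self.overlap :], ()):
            if len(seq) > p + self.overlap and contig.endswith(seq[: p + self.overlap]):
                out.append(seq[p + self.overlap :])
        return out


def _majority_extension(candidates: list[str]) -> tuple[str, bool]:
    """Majority base path over candidate extensions.

    Returns (extension, conflict). Candidates that diverge from the chosen
    path stop voting at later positions; an exact vote tie terminates the
    path and sets the conflict flag.
    """
    out: list[str] = []
    active = list(candidates)
    pos = 0
    while True:
        votes: dict[str, int] = {}
        for c in active:
            if len(c) > pos:
                votes[c[pos]] = votes.get(c[pos], 0) + 1
        if not votes:
            return "".join(out), False
        best = max(votes.values())
        winners = sorted(b for b, v in votes.items() if v == best)
        if len(winners) > 1:
            return "".join(out), True  # exact tie: stop, flag
        base = winners[0]
        out.append(base)
        active = [c for c in active if len(c) <= pos or c[pos] == base]
        pos += 1


def extend_seed(
    seed: str,
    reads: list[Read],
    overlap: int = DEFAULT_OVERLAP,
    max_rounds: int = 10_000,
    _index: _OverlapIndex | None = None,
) -> Contig:
    """Extend both ends of ``seed`` by exact-``overlap`` matching reads.

    At each end, every read (either orientation) that overlaps the contig
    end exactly over at least ``overlap`` bases and continues beyond it
    proposes its overhang as an extension; the majority path is appended.
    Extension stops when no read extends either end, a conflict tie is
    hit, or ``max_rounds`` is reached. ``n_reads_assembled`` counts the
    distinct input reads that map back to the final contig with zero
    mismatches.
    """
    if len(seed) < overlap:
        raise ValidationError(f"seed length {len(seed)} is shorter than overlap {overlap}")
    index = _index if _index is not None else _OverlapIndex(reads, overlap)
    contig = seed
    flagged = False
    for _ in range(max_rounds):
        grew = False
        # right end
        ext, conflict = _majority_extension(index.extensions(contig))
        if ext:
            contig += ext
            grew = True
        flagged = flagged or conflict
        # left end: extend the reverse complement's right end
        rc = revcomp(contig)
        ext, conflict = _majority_extension(index.extensions(rc))
        if ext:
            contig = revcomp(rc + ext)
            grew = True
        flagged = flagged or conflict
        if not grew:
            break
    result = Contig(sequence=contig, flagged=flagged)
    _map_back(result, reads)
    return result


def _map_back(contig: Contig, reads: list[Read]) -> None:
    """Count reads occurring exactly in the contig (either strand) and tally depth."""
    depth = [0] * len(contig.sequence)
    n = 0
    for r in reads:
        pos = contig.sequence.find(r.sequence)
        if pos < 0:
            pos = contig.sequence.find(revcomp(r.sequence))
        if pos >= 0:
            n += 1
            for i in range(pos, pos + len(r.sequence)):
                depth[i] += 1
    contig.n_reads_assembled = n
    contig.per_base_depth = depth


def assemble(
    seeds: list[Read],
    reads: list[Read],
    overlap: int = DEFAULT_OVERLAP,
    min_reads: int = DEFAULT_MIN_READS,
    min_phred: int = 30,
    max_rounds: int = 10_000,
) -> list[Contig]:
    """Extend every seed, deduplicate, and apply the read-support filter.

    Reads (and seeds) are quality-filtered first; contigs identical to or
    wholly contained in another (either strand) are removed; contigs with
    fewer than ``min_reads`` mapped-back reads are discarded. Output is
    deterministic regardless of input order: reads are canonically
    ordered by id and contigs by (length desc, sequence).
    """
    reads = filter_high_quality(sorted(reads, key=lambda r: r.id), min_phred)
    seeds = filter_high_quality(sorted(seeds, key=lambda r: r.id), min_phred)
    index = _OverlapIndex(reads, overlap)
    contigs = [
        extend_seed(s.sequence, reads, overlap, max_rounds, _index=index)
        for s in seeds
        if len(s.sequence) >= overlap
    ]
    contigs.sort(key=lambda c: (-len(c), c.sequence))
    kept: list[Contig] = []
    for c in contigs:
        rc = revcomp(c.sequence)
        if any(c.sequence in k.sequence or rc in k.sequence for k in kept):
            continue
        kept.append(c)
    return [c for c in kept if c.n_reads_assembled >= min_reads]
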