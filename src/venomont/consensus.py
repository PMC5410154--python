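"""Consensus toxin-transcriptome construction.

Assembled toxin transcripts from multiple individuals are merged into a
species-level consensus catalog in two clustering stages: within
individuals at <=1% nucleotide divergence, then across individuals at
<=1.5%. These thresholds operationally define paralogs — venom toxin
families carry many close gene copies, and the divergence cutoffs decide
which assembled variants are allelic/erroneous copies of one locus versus
distinct paralogs.

Divergence is the p-distance of a global pairwise alignment (match +1,
mismatch -1, gap -2): mismatched plus gapped columns over alignment
length. Clustering is single linkage (a connectivity criterion; complete
linkage is available behind a flag). Cluster consensus is the columnwise
majority over members progressively aligned to the longest member, with
IUPAC ambiguity codes on ties; divergence computations treat an ambiguity
code as matching any compatible base.

Chimeric assemblies (artifacts fusing two real transcripts) betray
themselves by an abrupt step in read coverage at the fusion point; the
screen flags transcripts whose adjacent-window median depth ratio exceeds
a threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from Bio import Align

from venomont.assembler import revcomp
from venomont.datatypes import ValidationError

WITHIN_INDIVIDUAL_THRESHOLD = 0.01
CROSS_INDIVIDUAL_THRESHOLD = 0.015

_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_CODE_FOR = {frozenset(v): k for k, v in _IUPAC.items()}


@dataclass
class TranscriptCluster:
    """One cluster of near-identical transcripts and its consensus."""

    member_ids: list[str]
    member_sequences: list[str]
    consensus: str
    max_internal_divergence: float


@dataclass
class DepthProfile:
    """Per-base read coverage over one transcript."""

    transcript_id: str
    depth: np.ndarray

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=float)
        if np.any(self.depth < 0):
            raise ValidationError("depths must be >= 0")


@lru_cache(maxsize=1)
def _aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -2
    return aligner


def _bases_compatible(a: str, b: str) -> bool:
    return bool(set(_IUPAC.get(a, a)) & set(_IUPAC.get(b, b)))


def _gapped_pair(seq_a: str, seq_b: str) -> tuple[str, str]:
    aln = _aligner().align(seq_a, seq_b)[0]
    return str(aln[0]), str(aln[1])


def pairwise_divergence(seq_a: str, seq_b: str) -> float:
    """Global-alignment p-distance between two nucleotide sequences.

    Mismatched columns (incompatible bases) plus gap columns, divided by
    alignment length. IUPAC ambiguity codes match any compatible base.
    """
    if not seq_a or not seq_b:
        raise ValidationError("both sequences must be nonempty")
    ga, gb = _gapped_pair(seq_a.upper(), seq_b.upper())
    diffs = sum(
        1 for x, y in zip(ga, gb) if x == "-" or y == "-" or not _bases_compatible(x, y)
    )
    return diffs / len(ga)


def consensus_sequence(members: list[str]) -> str:
    """Columnwise majority consensus over a progressive alignment.

    Members are aligned pairwise to the longest member (ties broken
    lexicographically); for each reference column the majority base wins
    and exact ties become the IUPAC code of the tied bases. Insertions
    relative to the reference are dropped, so the consensus length never
    exceeds the longest member.
    """
    if not members:
        raise ValidationError("consensus of an empty member list")
    members = [m.upper() for m in members]
    if len(members) == 1:
        return members[0]
    ref = sorted(members, key=lambda s: (-len(s), s))[0]
    votes: list[dict[str, int]] = [{} for _ in ref]
    for m in members:
        if m == ref:
            cols = list(ref)
        else:
            ga, gb = _gapped_pair(ref, m)
            cols = [y for x, y in zip(ga, gb) if x != "-"]
        for i, b in enumerate(cols):
            if b != "-":
                votes[i][b] = votes[i].get(b, 0) + 1
    out = []
    for i, v in enumerate(votes):
        if not v:
            out.append(ref[i])
            continue
        best = max(v.values())
        winners = frozenset(b for b, c in v.items() if c == best)
        out.append(next(iter(winners)) if len(winners) == 1 else _CODE_FOR[winners])
    return "".join(out)


def cluster_transcripts(
    sequences: list[tuple[str, str]], threshold: float, linkage: str = "single"
) -> list[TranscriptCluster]:
    """Cluster (id, sequence) pairs at a nucleotide-divergence threshold.

    Single linkage (default): two sequences are linked iff their pairwise
    divergence is <= threshold and clusters are the connected components,
    so a chain A-B-C can join even when A and C individually exceed the
    threshold. ``linkage="complete"`` instead requires every pair within
    a cluster to satisfy the threshold. Input order never matters:
    members are canonically ordered by id before linkage.
    """
    if not 0 < threshold < 0.5:
        raise ValidationError("threshold must be in (0, 0.5)")
    if linkage not in ("single", "complete"):
        raise ValidationError(f"unknown linkage {linkage!r}")
    items = sorted(sequences, key=lambda kv: kv[0])
    n = len(items)
    if n == 0:
        return []
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dist[i, j] = dist[j, i] = pairwise_divergence(items[i][1], items[j][1])

    if linkage == "single":
        parent = list(range(n))

        def find(i: int) -> int:
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(n):
            for j in range(i + 1, n):
                if dist[i, j] <= threshold:
                    parent[find(i)] = find(j)
        labels = [find(i) for i in range(n)]
    else:
        from scipy.cluster.hierarchy import fcluster, linkage as scipy_linkage
        from scipy.spatial.distance import squareform

        if n == 1:
            labels = [0]
        else:
            z = scipy_linkage(squareform(dist, checks=False), method="complete")
            labels = list(fcluster(z, t=threshold, criterion="distance"))

    clusters = []
    for lab in sorted(set(labels), key=lambda l: labels.index(l)):
        idx = [i for i, l in enumerate(labels) if l == lab]
        ids = [items[i][0] for i in idx]
        seqs = [items[i][1] for i in idx]
        internal = max(
            (dist[i, j] for a, i in enumerate(idx) for j in idx[a + 1 :]), default=0.0
        )
        clusters.append(
            TranscriptCluster(
                member_ids=ids,
                member_sequences=seqs,
                consensus=consensus_sequence(seqs),
                max_internal_divergence=float(internal),
            )
        )
    return clusters


def two_stage_cluster(
    per_individual: dict[str, list[tuple[str, str]]],
    within_threshold: float = WITHIN_INDIVIDUAL_THRESHOLD,
    cross_threshold: float = CROSS_INDIVIDUAL_THRESHOLD,
) -> list[TranscriptCluster]:
    """Within-individual then cross-individual clustering to a species consensus."""
    stage1: list[tuple[str, str]] = []
    for indiv in sorted(per_individual):
        for k, cluster in enumerate(
            cluster_transcripts(per_individual[indiv], within_threshold)
        ):
            stage1.append((f"{indiv}/c{k + 1}", cluster.consensus))
    return cluster_transcripts(stage1, cross_threshold)


def chimera_screen(
    profile: DepthProfile, step_ratio: float = 5.0, window: int = 100
) -> tuple[bool, int | None]:
    """Flag transcripts whose coverage steps sharply between adjacent windows.

    Slides a breakpoint along the profile and compares the median depth of
    the ``window`` bases on each side. Returns (keep, breakpoint):
    keep=False when the larger/smaller median ratio reaches
    ``step_ratio`` with both medians >= 1, with the position of the
    strongest step.
    """
    depth = profile.depth
    if len(depth) < 2 * window:
        raise ValidationError(
            f"profile length {len(depth)} shorter than 2 x window ({2 * window})"
        )
    from numpy.lib.stride_tricks import sliding_window_view

    medians = np.median(sliding_window_view(depth, window), axis=1)
    # breakpoint b: left window ends at b, right window starts at b
    left = medians[: len(medians) - window]
    right = medians[window:]
    lo = np.minimum(left, right)
    hi = np.maximum(left, right)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where((lo >= 1.0), hi / lo, 0.0)
    if len(ratio) == 0 or np.nanmax(ratio) < step_ratio:
        return True, None
    b = int(np.nanargmax(ratio)) + window
    return False, b


def dedupe(sequences: list[str]) -> list[str]:
    """Drop exact duplicates and sequences contained in a longer one (either strand)."""
    ordered = sorted(sequences, key=lambda s: (-len(s), s))
    kept: list[str] = []
    for s in ordered:
        rc = revcomp(s)
        if any(s in k or rc in k for k in kept):
            continue
        kept.append(s)
    return kept
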