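"""Coverage-based transcript presence/absence calling.

A transcript is declared absent from a transcriptome when more than 10%
of its coding sequence has read depth below 5x — a deliberately strict
criterion that approximates whether the transcript could have been
assembled de novo from that sample's reads. Reads contribute to coverage
only if they align end-to-end to a consensus transcript with at most two
mismatches (gaps or nucleotide differences).

The mapper here is a lightweight end-to-end aligner (edit distance
bounded by the mismatch policy, both strands) sufficient for desk-scale
consensus transcriptomes; it emits per-base depth profiles, not
alignments. Reads tying across near-identical paralogs are shared
fractionally between them by default so that neither paralog is
artificially called absent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import edlib
import numpy as np
from scipy import stats

from venomont._rng import substream
from venomont.assembler import Read, revcomp
from venomont.consensus import DepthProfile
from venomont.datatypes import (
    PresenceAbsenceMatrix,
    SampleMeta,
    ValidationError,
)

SUBSAMPLE_READS = 9_500_000  # published per-sample read-count equalization


@dataclass(frozen=True)
class AlignmentPolicy:
    """Read-filter and absence-rule parameters.

    max_mismatches counts gaps plus nucleotide differences over an
    end-to-end alignment; a transcript is absent when the fraction of
    positions with depth below ``min_depth`` exceeds ``max_low_fraction``
    (both inequalities strict, matching the published rule).
    """

    max_mismatches: int = 2
    min_depth: int = 5
    max_low_fraction: float = 0.10
    both_strands: bool = True
    multimap: str = "fraction"  # or "random"

    def __post_init__(self) -> None:
        if self.max_mismatches < 0:
            raise ValidationError("max_mismatches must be >= 0")
        if self.min_depth < 1:
            raise ValidationError("min_depth must be >= 1")
        if not 0 < self.max_low_fraction < 1:
            raise ValidationError("max_low_fraction must be in (0, 1)")
        if self.multimap not in ("fraction", "random"):
            raise ValidationError("multimap must be 'fraction' or 'random'")


@dataclass
class MapResult:
    profiles: dict[str, DepthProfile]
    n_mapped: int = 0
    n_discarded: int = 0  # best alignment exceeded the mismatch budget
    n_skipped_short: int = 0  # reference shorter than read


def map_reads(
    reads: list[Read],
    references: list[tuple[str, str]],
    policy: AlignmentPolicy = AlignmentPolicy(),
    seed: int = 0,
) -> MapResult:
    """Align reads end-to-end against consensus transcripts; accumulate depth.

    Each read is assigned to its best-scoring reference location
    (edit distance, infix alignment so the read must match end-to-end
    within the reference) and discarded when the best alignment has more
    than ``policy.max_mismatches`` edits. Reads tying across several
    references are shared fractionally (weight 1/k) or assigned uniformly
    at random ("random"), per policy; a read matching both strands of the
    same reference counts once on the canonical strand.
    """
    if not references:
        raise ValidationError("references must be nonempty")
    result = MapResult(
        profiles={
            rid: DepthProfile(rid, np.zeros(len(seq))) for rid, seq in references
        }
    )
    rng = substream(seed, "multimap")
    refs = [(rid, seq) for rid, seq in references]
    for read in reads:
        queries = [read.sequence]
        if policy.both_strands:
            queries.append(revcomp(read.sequence))
        best = None  # (distance, [(rid, start, end)])
        skipped_all = True
        for rid, ref_seq in refs:
            if len(ref_seq) < len(read.sequence):
                continue
            skipped_all = False
            hit_here = None
            for q in queries:
                aln = edlib.align(q, ref_seq, mode="HW", task="locations",
                                  k=policy.max_mismatches)
                d = aln["editDistance"]
                if d < 0:
                    continue
                loc = aln["locations"][0]
                if hit_here is None or d < hit_here[0]:
                    hit_here = (d, loc)  # both strands equal: count once
            if hit_here is None:
                continue
            d, (start, end) = hit_here
            if best is None or d < best[0]:
                best = (d, [(rid, start, end)])
            elif d == best[0]:
                best[1].append((rid, start, end))
        if skipped_all:
            result.n_skipped_short += 1
            continue
        if best is None:
            result.n_discarded += 1
            continue
        result.n_mapped += 1
        hits = best[1]
        if policy.multimap == "random" and len(hits) > 1:
            hits = [hits[rng.integers(len(hits))]]
        w = 1.0 / len(hits)
        for rid, start, end in hits:
            result.profiles[rid].depth[start : end + 1] += w
    return result


def call_absent(profile: DepthProfile, policy: AlignmentPolicy = AlignmentPolicy()) -> bool:
    """Absent iff the fraction of positions below ``min_depth`` exceeds the cap.

    Strict inequalities on both sides: depth exactly at ``min_depth``
    counts as covered, and a low fraction exactly at the cap still counts
    as present.
    """
    if len(profile.depth) == 0:
        raise ValidationError("empty depth profile")
    low_fraction = float(np.mean(profile.depth < policy.min_depth))
    return low_fraction > policy.max_low_fraction


def subsample_reads(reads: list[Read], n: int, seed: int = 0) -> list[Read]:
    """Uniform sample of ``n`` reads without replacement, deterministic under seed.

    Output is in canonical (id-sorted) order regardless of input order.
    """
    if n > len(reads):
        raise ValidationError(f"cannot sample {n} of {len(reads)} reads")
    if n < 0:
        raise ValidationError("n must be >= 0")
    rng = substream(seed, "read_subsample")
    ordered = sorted(reads, key=lambda r: r.id)
    idx = rng.choice(len(ordered), size=n, replace=False)
    return [ordered[i] for i in sorted(idx.tolist())]


@dataclass
class AbsenceSummary:
    """Published-style summary of a presence/absence matrix."""

    per_transcriptome_missing: dict[str, int]
    overall_mean_missing: float
    adult_mean: float
    juvenile_mean: float
    n_variable_transcripts: int
    welch_p: float  # NaN when a group has < 2 samples

    @property
    def max_missing(self) -> int:
        return max(self.per_transcriptome_missing.values())


def summarize_absence(
    matrix: PresenceAbsenceMatrix, metadata: list[SampleMeta]
) -> AbsenceSummary:
    """Per-transcriptome missing counts, group means, and a Welch t test.

    ``metadata`` must align with the matrix columns. The Welch two-sample
    t test (two-sided, unequal variances, Welch-Satterthwaite degrees of
    freedom) compares adult vs juvenile missing counts.
    """
    if [m.sample_id for m in metadata] != list(matrix.transcriptome_ids):
        raise ValidationError("metadata sample ids do not match matrix columns")
    counts = matrix.absent_counts
    per = {tid: int(c) for tid, c in zip(matrix.transcriptome_ids, counts)}
    adult = np.array(
        [c for c, m in zip(counts, metadata) if m.age_class == "adult"], dtype=float
    )
    juv = np.array(
        [c for c, m in zip(counts, metadata) if m.age_class == "juvenile"], dtype=float
    )
    if len(adult) >= 2 and len(juv) >= 2:
        welch_p = float(stats.ttest_ind(adult, juv, equal_var=False).pvalue)
    else:
        welch_p = float("nan")
    return AbsenceSummary(
        per_transcriptome_missing=per,
        overall_mean_missing=float(np.mean(counts)),
        adult_mean=float(np.mean(adult)) if len(adult) else float("nan"),
        juvenile_mean=float(np.mean(juv)) if len(juv) else float("nan"),
        n_variable_transcripts=int(((~matrix.present).sum(axis=1) > 0).sum()),
        welch_p=welch_p,
    )


def presence_matrix_from_profiles(
    profiles_by_sample: dict[str, dict[str, DepthProfile]],
    transcript_ids: list[str],
    policy: AlignmentPolicy = AlignmentPolicy(),
) -> PresenceAbsenceMatrix:
    """Apply the absence rule across samples to build a presence matrix."""
    sample_ids = list(profiles_by_sample)
    present = np.zeros((len(transcript_ids), len(sample_ids)), dtype=bool)
    for j, sid in enumerate(sample_ids):
        for i, tid in enumerate(transcript_ids):
            present[i, j] = not call_absent(profiles_by_sample[sid][tid], policy)
    return PresenceAbsenceMatrix(list(transcript_ids), sample_ids, present)


def write_depth_profiles(profiles: dict[str, DepthProfile], path) -> None:
    """3-column TSV: transcript, position (1-based), depth."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("transcript\tposition\tdepth\n")
        for tid in sorted(profiles):
            for pos, d in enumerate(profiles[tid].depth, start=1):
                fh.write(f"{tid}\t{pos}\t{d:g}\n")
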