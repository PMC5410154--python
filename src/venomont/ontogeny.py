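"""Compositional outlier test for adult/juvenile expression change.

TPM expression is compositional: each sample's values sum to one million,
so only relative information is meaningful. The analysis therefore works
on centered log-ratios, clr_i = ln(x_i) - mean_j ln(x_j), after flooring
exact zeros at 1.0 TPM.

For each of the five adult/juvenile population pairs, the per-transcript
clr difference delta = clr(adult) - clr(juvenile) is computed. Nontoxin
transcripts supply an empirical null: the 99th percentile of |delta| over
nontoxins is the outlier threshold for that pair, and toxins with |delta|
strictly larger are flagged up or down. A toxin is called ontogenetically
variable only when it is an outlier in at least 3 of the 5 pairs with a
consistent direction in at least 3 — a majority-consensus rule that keeps
population-specific expression variation from producing false positives.
Calls can then be cross-checked against external differential-expression
detections (DESeq/DESeq2 adjusted p < 0.1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from venomont.datatypes import (
    ConsensusCall,
    DetectionFlags,
    ExpressionMatrix,
    OutlierFlagMatrix,
    SampleMeta,
    TranscriptCatalog,
    ValidationError,
)

DEFAULT_PERCENTILE = 99.0
DEFAULT_MIN_OUTLIER = 3
DEFAULT_MIN_SAME_DIRECTION = 3
MIN_NONTOXINS = 100


@dataclass
class ClrMatrix:
    """Centered log-ratio transformed expression; columns sum to zero."""

    transcript_ids: list[str]
    samples: list[SampleMeta]
    values: np.ndarray

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def column(self, sample_id: str) -> np.ndarray:
        return self.values[:, self.sample_ids.index(sample_id)]


@dataclass
class PairComparison:
    """One adult/juvenile comparison with its nontoxin-derived threshold."""

    population: str
    adult_sample: str
    juvenile_sample: str
    delta: np.ndarray  # adult clr - juvenile clr, all transcripts
    null_threshold: float
    toxin_flags: dict[str, str]  # toxin id -> up/down/none


def replace_zeros(matrix: ExpressionMatrix, floor: float = 1.0) -> ExpressionMatrix:
    """Floor exact 0.0 TPM values at ``floor`` so log-ratios are defined.

    Only exact zeros are replaced; small positive estimates pass through
    unchanged.
    """
    values = matrix.values.copy()
    values[values == 0.0] = floor
    return ExpressionMatrix(list(matrix.transcript_ids), list(matrix.samples), values)


def clr_transform(matrix: ExpressionMatrix) -> ClrMatrix:
    """Per-sample centered log-ratio: clr_i = ln(x_i) - mean_j ln(x_j).

    The geometric-mean centering is over all transcripts in the supplied
    matrix, so the composition basis is whatever the caller provides
    (ideally toxins + nontoxins together).
    """
    if np.any(matrix.values <= 0):
        raise ValidationError(
            "clr_transform requires strictly positive values; apply replace_zeros first"
        )
    logs = np.log(matrix.values)
    values = logs - logs.mean(axis=0, keepdims=True)
    return ClrMatrix(list(matrix.transcript_ids), list(matrix.samples), values)


def empirical_percentile(values: np.ndarray, q: float) -> float:
    """Empirical percentile via linear interpolation between order statistics."""
    return float(np.percentile(np.asarray(values, dtype=float), q, method="linear"))


def pair_outliers(
    clr: ClrMatrix,
    catalog: TranscriptCatalog,
    pairs: list[tuple[str, str, str]],
    percentile: float = DEFAULT_PERCENTILE,
    min_nontoxins: int = MIN_NONTOXINS,
) -> list[PairComparison]:
    """Flag toxin outliers against the nontoxin null for each population pair.

    Parameters
    ----------
    pairs
        (adult_sample_id, juvenile_sample_id, population) triples.
    percentile
        Percentile of |delta| over nontoxins used as the threshold
        (default 99). Flags use strict inequalities: a toxin exactly at
        the threshold is not an outlier.
    min_nontoxins
        Minimum number of nontoxin transcripts required for a stable
        empirical percentile.
    """
    ids = clr.transcript_ids
    tox_mask = catalog.is_toxin_mask(ids)
    n_nontox = int((~tox_mask).sum())
    if n_nontox < min_nontoxins:
        raise ValidationError(
            f"only {n_nontox} nontoxin transcripts in matrix; "
            f"need >= {min_nontoxins} for a stable null percentile"
        )
    toxin_ids = [t for t, m in zip(ids, tox_mask) if m]
    out = []
    for adult_id, juv_id, population in pairs:
        delta = clr.column(adult_id) - clr.column(juv_id)
        threshold = empirical_percentile(np.abs(delta[~tox_mask]), percentile)
        if threshold <= 0:
            raise ValidationError(
                f"degenerate null for pair {population}: nontoxin {percentile}th "
                "percentile is not strictly positive; a zero threshold would flag "
                "every toxin"
            )
        flags = {}
        for t in toxin_ids:
            d = delta[ids.index(t)]
            flags[t] = "up" if d > threshold else ("down" if d < -threshold else "none")
        out.append(
            PairComparison(
                population=population,
                adult_sample=adult_id,
                juvenile_sample=juv_id,
                delta=delta,
                null_threshold=threshold,
                toxin_flags=flags,
            )
        )
    return out


def flags_from_pairs(comparisons: list[PairComparison]) -> OutlierFlagMatrix:
    """Assemble per-pair toxin flags into an OutlierFlagMatrix."""
    toxins = list(comparisons[0].toxin_flags)
    flags = np.array(
        [[c.toxin_flags[t] for c in comparisons] for t in toxins], dtype=object
    )
    return OutlierFlagMatrix(toxins, [c.population for c in comparisons], flags)


def consensus_call(
    flags: OutlierFlagMatrix,
    min_outlier: int = DEFAULT_MIN_OUTLIER,
    min_same_direction: int = DEFAULT_MIN_SAME_DIRECTION,
) -> list[ConsensusCall]:
    """Majority-consensus ontogeny call per toxin.

    A toxin is called up (down) when it is an outlier in at least
    ``min_outlier`` of the population pairs and at least
    ``min_same_direction`` of those outliers agree on the direction.
    Direction counts only use comparisons where the toxin was an outlier,
    so n_up + n_down = n_outlier.
    """
    calls = []
    for i, t in enumerate(flags.transcript_ids):
        row = flags.flags[i]
        n_up = int(np.sum(row == "up"))
        n_down = int(np.sum(row == "down"))
        n_outlier = n_up + n_down
        if n_outlier >= min_outlier and n_up >= min_same_direction:
            call = "up"
        elif n_outlier >= min_outlier and n_down >= min_same_direction:
            call = "down"
        else:
            call = "none"
        calls.append(
            ConsensusCall(
                transcript_id=t, n_outlier=n_outlier, n_up=n_up, n_down=n_down, call=call
            )
        )
    return calls


def intersect_detections(
    calls: list[ConsensusCall], detections: list[DetectionFlags]
) -> list[ConsensusCall]:
    """Mark consensus calls confirmed by at least one external DE method."""
    detected: set[str] = set()
    for d in detections:
        detected |= d.detected_ids
    return [
        ConsensusCall(
            transcript_id=c.transcript_id,
            n_outlier=c.n_outlier,
            n_up=c.n_up,
            n_down=c.n_down,
            call=c.call,
            confirmed=(c.call != "none") and (c.transcript_id in detected),
        )
        for c in calls
    ]


def replicate_concordance(
    clr_a: np.ndarray, clr_b: np.ndarray, subset: np.ndarray | None = None
) -> tuple[float, float]:
    """Spearman's rho and Pearson's r between two replicate clr columns.

    Used to quantify agreement between left- and right-gland abundance
    estimates for the same individual. Returns (nan, nan) for constant
    columns, where neither coefficient is defined.
    """
    a = np.asarray(clr_a, dtype=float)
    b = np.asarray(clr_b, dtype=float)
    if subset is not None:
        a, b = a[subset], b[subset]
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return (float("nan"), float("nan"))
    rho = stats.spearmanr(a, b).statistic
    r = stats.pearsonr(a, b).statistic
    return (float(rho), float(r))


def tpm_from_counts(counts: np.ndarray, lengths: np.ndarray) -> np.ndarray:
    """Naive TPM from read counts and transcript lengths.

    rate_i = counts_i / lengths_i, TPM_i = 1e6 * rate_i / sum(rate).
    A desk-scale stand-in for model-based abundance estimation.
    """
    counts = np.asarray(counts, dtype=float)
    lengths = np.asarray(lengths, dtype=float)
    if np.any(lengths <= 0):
        raise ValidationError("lengths must be positive")
    if not np.any(counts > 0):
        raise ValidationError("all-zero counts: TPM undefined")
    rate = counts / lengths
    return 1e6 * rate / rate.sum()
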