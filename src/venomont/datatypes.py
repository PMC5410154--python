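"""Core data model for the ontogeny pipeline.

Every table the pipeline touches has a typed, validated container here:
expression matrices (TPM), transcript catalogs (toxin/nontoxin labels),
presence/absence matrices, per-population outlier-flag matrices, external
differential-expression detection flags, and dose-response tables.
Containers are thin wrappers around numpy arrays / pandas frames with the
invariants enforced at construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

POPULATIONS = ("ANF", "BR", "CAL", "ENP", "LSG")
AGE_CLASSES = ("adult", "juvenile")
GLANDS = ("left", "right", "pooled")
FLAG_VALUES = ("up", "down", "none")

TPM_TOTAL = 1_000_000.0


class ValidationError(ValueError):
    """Raised when a container's invariants are violated."""


@dataclass(frozen=True)
class SampleMeta:
    """Identity and grouping of one venom-gland RNA-seq sample.

    Samples come from adult/juvenile pairs collected in five named
    populations; left and right glands may be sequenced separately or
    pooled per individual.
    """

    sample_id: str
    population: str
    age_class: str
    gland: str = "pooled"

    def __post_init__(self) -> None:
        if self.population not in POPULATIONS:
            raise ValidationError(
                f"unknown population {self.population!r}; expected one of {POPULATIONS}"
            )
        if self.age_class not in AGE_CLASSES:
            raise ValidationError(
                f"unknown age_class {self.age_class!r}; expected one of {AGE_CLASSES}"
            )
        if self.gland not in GLANDS:
            raise ValidationError(
                f"unknown gland {self.gland!r}; expected one of {GLANDS}"
            )

    @classmethod
    def from_label(cls, label: str, gland: str = "pooled") -> "SampleMeta":
        """Parse a ``POP-A`` / ``POP-J`` style column label (e.g. ``ANF-A``)."""
        pop, _, suffix = label.partition("-")
        age = {"A": "adult", "J": "juvenile"}.get(suffix)
        if pop not in POPULATIONS or age is None:
            raise ValidationError(f"cannot parse sample label {label!r}")
        return cls(sample_id=label, population=pop, age_class=age, gland=gland)


def _check_unique(ids, what: str) -> None:
    seen = set()
    for i in ids:
        if i in seen:
            raise ValidationError(f"duplicate {what}: {i!r}")
        seen.add(i)


@dataclass
class ExpressionMatrix:
    """Transcripts x samples abundance table in transcripts per million.

    For full transcriptomes each sample column sums to one million (the
    compositional closure of TPM); slices restricted to toxins only do not
    close and are used as-is.
    """

    transcript_ids: list[str]
    samples: list[SampleMeta]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.transcript_ids), len(self.samples)):
            raise ValidationError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.transcript_ids)} transcripts x {len(self.samples)} samples"
            )
        _check_unique(self.transcript_ids, "transcript id")
        _check_unique([s.sample_id for s in self.samples], "sample id")
        key = {(s.population, s.age_class, s.gland) for s in self.samples}
        if len(key) != len(self.samples):
            raise ValidationError("(population, age_class, gland) not unique across samples")
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise ValidationError(
                f"non-finite value at transcript {self.transcript_ids[bad[0]]!r}, "
                f"sample {self.samples[bad[1]].sample_id!r}"
            )
        if np.any(self.values < 0):
            bad = np.argwhere(self.values < 0)[0]
            raise ValidationError(
                f"negative value at transcript {self.transcript_ids[bad[0]]!r}, "
                f"sample {self.samples[bad[1]].sample_id!r}"
            )

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.transcript_ids, columns=self.sample_ids)

    def column(self, sample_id: str) -> np.ndarray:
        return self.values[:, self.sample_ids.index(sample_id)]

    def is_closed(self, rtol: float = 1e-6) -> bool:
        """True when every sample column sums to 1e6 within ``rtol``."""
        return bool(np.allclose(self.values.sum(axis=0), TPM_TOTAL, rtol=rtol))


@dataclass
class TranscriptCatalog:
    """Per-transcript labels: toxin/nontoxin, toxin family, CDS length (nt)."""

    table: pd.DataFrame  # columns: transcript_id, is_toxin, family, cds_length

    REQUIRED = ("transcript_id", "is_toxin", "family", "cds_length")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValidationError(f"catalog missing columns: {missing}")
        _check_unique(list(self.table["transcript_id"]), "transcript id")
        if (self.table["cds_length"] < 1).any():
            raise ValidationError("cds_length must be >= 1")
        bad = self.table[self.table["is_toxin"] & (self.table["family"] == "")]
        if len(bad):
            raise ValidationError(
                f"toxin transcripts with empty family: {list(bad['transcript_id'])}"
            )

    @staticmethod
    def family_from_id(transcript_id: str) -> str:
        """Derive the family label by stripping the trailing ``-<number>``."""
        stem, _, tail = transcript_id.rpartition("-")
        return stem if stem and tail.isdigit() else transcript_id

    @classmethod
    def build(cls, transcript_ids, is_toxin, cds_lengths) -> "TranscriptCatalog":
        ids = list(transcript_ids)
        tox = list(is_toxin)
        return cls(
            pd.DataFrame(
                {
                    "transcript_id": ids,
                    "is_toxin": tox,
                    "family": [cls.family_from_id(i) if t else "" for i, t in zip(ids, tox)],
                    "cds_length": list(cds_lengths),
                }
            )
        )

    @property
    def toxin_ids(self) -> list[str]:
        return list(self.table.loc[self.table["is_toxin"], "transcript_id"])

    @property
    def nontoxin_ids(self) -> list[str]:
        return list(self.table.loc[~self.table["is_toxin"], "transcript_id"])

    def is_toxin_mask(self, transcript_ids) -> np.ndarray:
        tox = set(self.toxin_ids)
        return np.array([t in tox for t in transcript_ids], dtype=bool)


@dataclass
class PresenceAbsenceMatrix:
    """Boolean transcripts x transcriptomes matrix; True means present.

    A transcript is absent from a transcriptome when more than 10% of its
    coding sequence has below 5x read coverage (see presence_absence).
    """

    transcript_ids: list[str]
    transcriptome_ids: list[str]
    present: np.ndarray

    def __post_init__(self) -> None:
        self.present = np.asarray(self.present, dtype=bool)
        if self.present.shape != (len(self.transcript_ids), len(self.transcriptome_ids)):
            raise ValidationError("present matrix shape mismatch")
        _check_unique(self.transcript_ids, "transcript id")
        _check_unique(self.transcriptome_ids, "transcriptome id")

    @property
    def absent_counts(self) -> np.ndarray:
        """Number of absent transcripts per transcriptome (column)."""
        return (~self.present).sum(axis=0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.present, index=self.transcript_ids, columns=self.transcriptome_ids
        )


@dataclass
class OutlierFlagMatrix:
    """Per-transcript, per-population outlier direction flags (up/down/none)."""

    transcript_ids: list[str]
    populations: list[str]
    flags: np.ndarray  # dtype object/str, values in FLAG_VALUES

    def __post_init__(self) -> None:
        self.flags = np.asarray(self.flags, dtype=object)
        if self.flags.shape != (len(self.transcript_ids), len(self.populations)):
            raise ValidationError("flags matrix shape mismatch")
        _check_unique(self.transcript_ids, "transcript id")
        bad = set(self.flags.ravel()) - set(FLAG_VALUES)
        if bad:
            raise ValidationError(f"invalid flag values: {sorted(bad)}; expected {FLAG_VALUES}")

    def consensus(self, min_outlier: int = 3, min_same_direction: int = 3):
        """Majority-consensus calls; see :func:`venomont.ontogeny.consensus_call`."""
        from venomont.ontogeny import consensus_call

        return consensus_call(self, min_outlier=min_outlier, min_same_direction=min_same_direction)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.flags, index=self.transcript_ids, columns=self.populations)


@dataclass
class DetectionFlags:
    """External differential-expression detections (e.g. DESeq/DESeq2).

    ``adjusted_p`` is NaN when the method printed no usable value (censored
    ">0.1" entries or NA from all-zero counts); such rows are not detected.
    """

    method: str
    table: pd.DataFrame  # columns: transcript_id, adjusted_p (float, NaN ok)
    fdr_threshold: float = 0.1

    def __post_init__(self) -> None:
        for c in ("transcript_id", "adjusted_p"):
            if c not in self.table.columns:
                raise ValidationError(f"detection table missing column {c!r}")
        _check_unique(list(self.table["transcript_id"]), "transcript id")
        p = self.table["adjusted_p"]
        if ((p < 0) | (p > 1)).any():
            raise ValidationError("adjusted_p outside [0, 1]")

    @property
    def detected(self) -> pd.Series:
        """detected = adjusted_p present and < fdr_threshold, indexed by transcript."""
        p = self.table.set_index("transcript_id")["adjusted_p"]
        return p.notna() & (p < self.fdr_threshold)

    @property
    def detected_ids(self) -> set[str]:
        d = self.detected
        return set(d.index[d])


@dataclass
class DoseResponseTable:
    """Ordered dose series (mg/kg) with group sizes and observed deaths."""

    doses: np.ndarray
    n_per_group: np.ndarray
    deaths: np.ndarray

    def __post_init__(self) -> None:
        self.doses = np.asarray(self.doses, dtype=float)
        self.n_per_group = np.asarray(self.n_per_group, dtype=int)
        self.deaths = np.asarray(self.deaths, dtype=int)
        k = len(self.doses)
        if len(self.n_per_group) != k or len(self.deaths) != k:
            raise ValidationError("doses, n_per_group, deaths must have equal length")
        if np.any(self.doses <= 0):
            raise ValidationError("doses must be positive")
        d = np.diff(self.doses)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise ValidationError("doses must be strictly monotone")
        if np.any(self.n_per_group < 1):
            raise ValidationError("group sizes must be >= 1")
        if np.any(self.deaths < 0) or np.any(self.deaths > self.n_per_group):
            raise ValidationError("deaths must satisfy 0 <= deaths <= n_per_group")

    @property
    def proportions(self) -> np.ndarray:
        return self.deaths / self.n_per_group

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"dose": self.doses, "n": self.n_per_group, "deaths": self.deaths}
        )


@dataclass
class ConsensusCall:
    """Consensus ontogeny call for one toxin across the five population pairs."""

    transcript_id: str
    n_outlier: int
    n_up: int
    n_down: int
    call: str  # up / down / none
    confirmed: bool = False

    def __post_init__(self) -> None:
        if self.n_up + self.n_down != self.n_outlier:
            raise ValidationError("n_up + n_down must equal n_outlier")
        if self.call not in FLAG_VALUES:
            raise ValidationError(f"invalid call {self.call!r}")
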