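"""Synthetic-data generators with the statistical structure the analysis assumes.

Each generator emulates one input of the pipeline so every downstream
stage is testable without external data:

* paired adult/juvenile expression matrices from several populations,
  with a large nontoxin background, log-normal (optionally heavy-tailed)
  sample-pair noise, and planted toxin log-fold-changes whose truth table
  is returned alongside;
* toxin paralog families at controlled nucleotide divergence
  (substitutions from a shared random ancestor, no indels);
* uniform-coverage merged reads with optional transcript dropout and
  per-base substitution errors;
* chimeric transcripts for exercising the coverage-step screen;
* binomial dose-mortality tables under a log-dose logistic tolerance
  curve on a constant-factor dilution series.

Every generator is a pure function of its spec including the seed; a
single global seed fans out to per-component streams (see _rng).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from venomont._rng import substream
from venomont.datatypes import (
    POPULATIONS,
    TPM_TOTAL,
    DoseResponseTable,
    ExpressionMatrix,
    SampleMeta,
    TranscriptCatalog,
    ValidationError,
)

BASES = np.array(list("ACGT"))


# ---------------------------------------------------------------------------
# expression


@dataclass
class ExpressionSimSpec:
    """Study conditions for a synthetic paired adult/juvenile expression set.

    ``log_noise_sd`` is the standard deviation of the natural-log
    adult-juvenile difference for null transcripts. ``planted_effects``
    maps toxin ids to signed natural-log fold-changes (adult minus
    juvenile) applied identically in every population. ``noise_df`` (None
    for Gaussian) switches the null noise to a scaled Student-t, for
    probing the robustness of the empirical-percentile null.
    """

    n_nontoxins: int = 2000
    n_toxins: int = 59
    n_populations: int = 5
    log_noise_sd: float = 0.4
    planted_effects: dict[str, float] = field(default_factory=dict)
    population_effect_sd: float = 0.5
    zero_rate: float = 0.0
    noise_df: float | None = None
    base_log_mean: float = 3.0
    base_log_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nontoxins < 1 or self.n_toxins < 1 or self.n_populations < 1:
            raise ValidationError("counts must be positive")
        if self.log_noise_sd < 0 or self.population_effect_sd < 0:
            raise ValidationError("noise standard deviations must be >= 0")
        if not 0 <= self.zero_rate < 1:
            raise ValidationError("zero_rate must be in [0, 1)")


def _noise(rng: np.random.Generator, sd: float, size, df: float | None) -> np.ndarray:
    if df is None:
        return rng.normal(0.0, sd, size=size)
    # scale so the t draw has standard deviation sd (requires df > 2)
    scale = sd / np.sqrt(df / (df - 2.0)) if df > 2 else sd
    return scale * rng.standard_t(df, size=size)


def gen_expression_dataset(
    spec: ExpressionSimSpec,
) -> tuple[ExpressionMatrix, TranscriptCatalog, pd.DataFrame]:
    """Generate a full expression matrix, catalog, and planted-effect truth table.

    One adult and one juvenile sample per population. Null transcripts
    get adult-juvenile natural-log differences ~ N(0, log_noise_sd);
    planted toxins receive the specified additive log-fold-change in every
    population; toxins drop to zero with probability ``zero_rate`` per
    sample; each column is renormalized to one million TPM.
    """
    toxin_ids = [f"TOX-{i + 1}" for i in range(spec.n_toxins)]
    nontoxin_ids = [f"NT-{i + 1}" for i in range(spec.n_nontoxins)]
    ids = toxin_ids + nontoxin_ids
    unknown = set(spec.planted_effects) - set(toxin_ids)
    if unknown:
        raise ValidationError(f"planted effects on unknown toxin ids: {sorted(unknown)}")

    n = len(ids)
    rng = substream(spec.seed, "expression")
    base = rng.normal(spec.base_log_mean, spec.base_log_sd, size=n)
    lfc = np.array([spec.planted_effects.get(t, 0.0) for t in ids])

    if spec.n_populations > len(POPULATIONS):
        raise ValidationError(
            f"at most {len(POPULATIONS)} populations available: {POPULATIONS}"
        )
    pops = list(POPULATIONS[: spec.n_populations])
    samples: list[SampleMeta] = []
    columns: list[np.ndarray] = []
    for p, pop in enumerate(pops):
        pop_eff = rng.normal(0.0, spec.population_effect_sd, size=n)
        juv_log = base + pop_eff
        diff = _noise(rng, spec.log_noise_sd, n, spec.noise_df)
        adult_log = juv_log + diff + lfc
        for age, logs in (("adult", adult_log), ("juvenile", juv_log)):
            x = np.exp(logs)
            if spec.zero_rate > 0:
                drop = rng.random(spec.n_toxins) < spec.zero_rate
                x[: spec.n_toxins][drop] = 0.0
            columns.append(x * TPM_TOTAL / x.sum())
            samples.append(
                SampleMeta(
                    sample_id=f"{pop}-{'A' if age == 'adult' else 'J'}",
                    population=pop,
                    age_class=age,
                )
            )

    matrix = ExpressionMatrix(ids, samples, np.column_stack(columns))
    catalog = TranscriptCatalog.build(
        ids, [True] * spec.n_toxins + [False] * spec.n_nontoxins, [1000] * n
    )
    truth = pd.DataFrame(
        {
            "transcript_id": ids,
            "is_toxin": [t in set(toxin_ids) for t in ids],
            "true_lfc": lfc,
            "planted": [t in spec.planted_effects for t in ids],
        }
    )
    return matrix, catalog, truth


def default_pairs(matrix: ExpressionMatrix) -> list[tuple[str, str, str]]:
    """(adult_id, juvenile_id, population) triples present in ``matrix``."""
    by_pop: dict[str, dict[str, str]] = {}
    for s in matrix.samples:
        by_pop.setdefault(s.population, {})[s.age_class] = s.sample_id
    return [
        (ages["adult"], ages["juvenile"], pop)
        for pop, ages in by_pop.items()
        if {"adult", "juvenile"} <= set(ages)
    ]


# ---------------------------------------------------------------------------
# sequences and reads


def gen_paralog_family(
    ancestor_length: int, n_paralogs: int, divergence: float, seed: int = 0
) -> list[tuple[str, str]]:
    """Simulate a toxin paralog family by independent substitution.

    Each paralog independently mutates each site of a shared random
    ancestor with probability ``divergence`` (substitutions to a
    different base, no indels), so the expected pairwise divergence
    between paralogs is about twice ``divergence``.
    """
    if not 0 <= divergence <= 0.5:
        raise ValidationError("divergence must be in [0, 0.5]")
    if ancestor_length < 1 or n_paralogs < 1:
        raise ValidationError("ancestor_length and n_paralogs must be positive")
    rng = substream(seed, "paralogs")
    ancestor = rng.choice(4, size=ancestor_length)
    out = []
    for i in range(n_paralogs):
        seq = ancestor.copy()
        hit = rng.random(ancestor_length) < divergence
        # substitute to one of the three other bases, uniformly
        seq[hit] = (seq[hit] + rng.integers(1, 4, size=int(hit.sum()))) % 4
        out.append((f"paralog-{i + 1}", "".join(BASES[seq])))
    return out


def ancestor_sequence(ancestor_length: int, seed: int = 0) -> str:
    """The shared ancestor used by :func:`gen_paralog_family` for this seed."""
    rng = substream(seed, "paralogs")
    return "".join(BASES[rng.choice(4, size=ancestor_length)])


@dataclass
class ReadSimSpec:
    """Uniform-coverage merged-read simulation over a set of transcripts."""

    transcripts: list[tuple[str, str]]
    mean_depth: float = 30.0
    read_length: int = 150
    error_rate: float = 0.0
    dropout_ids: list[str] = field(default_factory=list)
    quality_phred: int = 40
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.transcripts:
            raise ValidationError("need at least one transcript")
        shortest = min(len(s) for _, s in self.transcripts)
        if self.read_length > shortest:
            raise ValidationError(
                f"read_length {self.read_length} exceeds shortest transcript ({shortest} nt)"
            )
        if not 0 <= self.error_rate < 0.5:
            raise ValidationError("error_rate must be in [0, 0.5)")
        if self.mean_depth <= 0:
            raise ValidationError("mean_depth must be positive")


def gen_reads(spec: ReadSimSpec) -> list:
    """Sample error-free (or noisy) merged reads uniformly along transcripts.

    Fragment start positions are uniform over the molecule including
    overhangs at both termini, then clamped to the transcript, which
    reproduces the boundary pileup of real fragments at molecule ends and
    gives uniform expected coverage ``mean_depth`` at every base. Dropout
    transcripts yield no reads. All bases carry the same phred quality.
    Returns :class:`venomont.assembler.Read` objects sorted by id.
    """
    from venomont.assembler import Read

    rng = substream(spec.seed, "reads")
    drop = set(spec.dropout_ids)
    reads = []
    for tid, seq in spec.transcripts:
        if tid in drop:
            continue
        length = len(seq)
        span = length + spec.read_length - 1  # molecule plus terminal overhangs
        n_reads = rng.poisson(spec.mean_depth * span / spec.read_length)
        starts = rng.integers(-(spec.read_length - 1), length, size=n_reads)
        starts = np.clip(starts, 0, length - spec.read_length)
        arr_seq = np.frombuffer(seq.encode(), dtype="S1")
        for j, s in enumerate(sorted(starts.tolist())):
            frag = arr_seq[s : s + spec.read_length].copy()
            if spec.error_rate > 0:
                hit = rng.random(spec.read_length) < spec.error_rate
                if hit.any():
                    idx = "ACGT"
                    cur = np.array([idx.index(b.decode()) for b in frag[hit]])
                    frag[hit] = np.frombuffer(
                        "".join(BASES[(cur + rng.integers(1, 4, size=len(cur))) % 4]).encode(),
                        dtype="S1",
                    )
            reads.append(
                Read(
                    id=f"{tid}:{j}:{s}",
                    sequence=frag.tobytes().decode(),
                    qualities=[spec.quality_phred] * spec.read_length,
                )
            )
    reads.sort(key=lambda r: r.id)
    return reads


def gen_chimeric_transcript(seq_a: str, seq_b: str, breakpoint: float) -> str:
    """Join a prefix of ``seq_a`` to a suffix of ``seq_b`` at ``breakpoint``.

    Emulates an assembly artifact fusing two real transcripts; used to
    exercise the coverage-step chimera screen.
    """
    if not seq_a or not seq_b:
        raise ValidationError("both sequences must be nonempty")
    if not 0 < breakpoint < 1:
        raise ValidationError("breakpoint must be a fraction in (0, 1)")
    cut_a = int(round(len(seq_a) * breakpoint))
    cut_b = int(round(len(seq_b) * breakpoint))
    return seq_a[:cut_a] + seq_b[cut_b:]


# ---------------------------------------------------------------------------
# dose-response


@dataclass
class DoseSimSpec:
    """Binomial mortality under a logistic tolerance curve on log10 dose."""

    true_ld50: float = 3.0  # mg/kg
    slope: float = 4.0  # logistic slope per log10 dose unit
    top_dose: float = 12.0
    n_doses: int = 5
    dilution_factor: float = 2.0
    group_size: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.true_ld50 <= 0 or self.top_dose <= 0 or self.slope <= 0:
            raise ValidationError("true_ld50, top_dose and slope must be positive")
        if self.n_doses < 2:
            raise ValidationError("need at least 2 doses")
        if self.dilution_factor <= 1:
            raise ValidationError("dilution factor must be > 1")
        if self.group_size < 1:
            raise ValidationError("group_size must be >= 1")


def gen_dose_response(spec: DoseSimSpec) -> DoseResponseTable:
    """Simulate one dilution-series mortality table.

    deaths_i ~ Binomial(group_size, expit(slope * (log10 dose_i - log10 LD50))).
    """
    from venomont.toxicity import design_dilution_series

    rng = substream(spec.seed, "dose_response")
    doses = design_dilution_series(spec.top_dose, spec.n_doses, spec.dilution_factor)
    logit = spec.slope * (np.log10(doses) - np.log10(spec.true_ld50))
    p_death = 1.0 / (1.0 + np.exp(-logit))
    deaths = rng.binomial(spec.group_size, p_death)
    return DoseResponseTable(
        doses=doses,
        n_per_group=np.full(spec.n_doses, spec.group_size),
        deaths=deaths,
    )
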