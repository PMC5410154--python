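"""File I/O for every table and sequence format the pipeline touches.

Tabular formats are TSV/CSV (UTF-8, LF, "." decimal separator) so outputs
are bit-stable; nested results go to JSON; sequences to FASTA/FASTQ via
Biopython. Writers and readers round-trip: flags and integers exactly,
reals to 1e-9.
"""

from __future__ import annotations

import json
import os
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from venomont.datatypes import (
    ConsensusCall,
    DetectionFlags,
    DoseResponseTable,
    ExpressionMatrix,
    OutlierFlagMatrix,
    PresenceAbsenceMatrix,
    SampleMeta,
    TranscriptCatalog,
    ValidationError,
)

ABSENT_ROW_LABEL = "# Absent"


def _sep_for(path: str, fmt: str | None = None) -> str:
    if fmt == "tsv":
        return "\t"
    if fmt == "csv":
        return ","
    return "\t" if str(path).endswith((".tsv", ".tab", ".txt")) else ","


# ---------------------------------------------------------------------------
# expression tables


def read_expression_table(
    path, metadata: Sequence[SampleMeta] | None = None
) -> ExpressionMatrix:
    """Read a transcripts x samples TPM table.

    The file must have a header row of sample ids and transcript ids in the
    first column; separator is inferred from the extension (default comma,
    ``.tsv`` tab). When ``metadata`` is omitted, sample ids must follow the
    ``POP-A``/``POP-J`` labelling scheme so population and age class can be
    parsed from the header.
    """
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    if df.shape[0] == 0:
        raise ValidationError(f"{path}: no data rows")
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ValidationError(f"{path}: duplicate transcript id {dup!r}")
    for col in df.columns:
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            row = df.index[vals.isna()][0]
            raise ValidationError(
                f"{path}: missing or non-numeric cell at transcript {row!r}, sample {col!r}"
            )
        if (vals < 0).any():
            row = df.index[vals < 0][0]
            raise ValidationError(
                f"{path}: negative value at transcript {row!r}, sample {col!r}"
            )
    if metadata is None:
        metadata = [SampleMeta.from_label(str(c)) for c in df.columns]
    elif [m.sample_id for m in metadata] != [str(c) for c in df.columns]:
        raise ValidationError(f"{path}: metadata sample ids do not match header columns")
    return ExpressionMatrix(
        transcript_ids=[str(i) for i in df.index],
        samples=list(metadata),
        values=df.to_numpy(dtype=float),
    )


def write_expression_table(matrix: ExpressionMatrix, path, fmt: str | None = None) -> None:
    matrix.to_frame().to_csv(
        path, sep=_sep_for(path, fmt), index_label="transcript_id"
    )


# ---------------------------------------------------------------------------
# presence/absence


def write_presence_absence(
    matrix: PresenceAbsenceMatrix, path, fmt: str | None = None
) -> None:
    """Write +/- presence matrix with a trailing ``# Absent`` summary row."""
    sep = _sep_for(path, fmt)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("Transcript" + sep + sep.join(matrix.transcriptome_ids) + "\n")
        for i, t in enumerate(matrix.transcript_ids):
            symbols = ["+" if p else "-" for p in matrix.present[i]]
            fh.write(t + sep + sep.join(symbols) + "\n")
        counts = matrix.absent_counts
        fh.write(ABSENT_ROW_LABEL + sep + sep.join(str(int(c)) for c in counts) + "\n")


def read_presence_absence(path) -> PresenceAbsenceMatrix:
    sep = _sep_for(path)
    with open(path, encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    header = lines[0].split(sep)
    transcriptome_ids = header[1:]
    ids: list[str] = []
    rows: list[list[bool]] = []
    stored_counts: list[int] | None = None
    for ln in lines[1:]:
        cells = ln.split(sep)
        if cells[0] == ABSENT_ROW_LABEL:
            stored_counts = [int(c) for c in cells[1:]]
            continue
        ids.append(cells[0])
        if len(cells) != len(header):
            raise ValidationError(f"{path}: row {cells[0]!r} has {len(cells) - 1} cells")
        rows.append([c == "+" for c in cells[1:]])
    matrix = PresenceAbsenceMatrix(ids, transcriptome_ids, np.array(rows, dtype=bool))
    if stored_counts is not None and list(matrix.absent_counts) != stored_counts:
        raise ValidationError(
            f"{path}: stored '# Absent' row {stored_counts} does not match "
            f"recomputed counts {list(matrix.absent_counts)}"
        )
    return matrix


# ---------------------------------------------------------------------------
# outlier flags / detections / consensus calls


def write_outlier_flags(matrix: OutlierFlagMatrix, path, fmt: str | None = None) -> None:
    matrix.to_frame().to_csv(path, sep=_sep_for(path, fmt), index_label="transcript_id")


def read_outlier_flags(path) -> OutlierFlagMatrix:
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0, dtype=str)
    return OutlierFlagMatrix(
        transcript_ids=[str(i) for i in df.index],
        populations=[str(c) for c in df.columns],
        flags=df.to_numpy(dtype=object),
    )


def read_detection_flags(path, method: str, fdr_threshold: float = 0.1) -> DetectionFlags:
    """Read a per-transcript adjusted-p table for one DE method.

    Censored entries printed as ``>0.1`` and ``NA`` both parse to missing
    (NaN) and therefore count as not detected.
    """
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str)
    cols = {c.lower(): c for c in df.columns}
    id_col = cols.get("transcript_id") or cols.get("toxin") or df.columns[0]
    p_col = cols.get("adjusted_p") or cols.get("padj") or df.columns[1]

    def parse_p(cell: str) -> float:
        cell = str(cell).strip()
        if cell in ("NA", "nan", "") or cell.startswith(">"):
            return np.nan
        return float(cell)

    out = pd.DataFrame(
        {
            "transcript_id": df[id_col].astype(str),
            "adjusted_p": [parse_p(c) for c in df[p_col]],
        }
    )
    return DetectionFlags(method=method, table=out, fdr_threshold=fdr_threshold)


def write_detection_flags(flags: DetectionFlags, path, fmt: str | None = None) -> None:
    df = flags.table.copy()
    df["detected"] = flags.detected.to_numpy()
    df.to_csv(path, sep=_sep_for(path, fmt), index=False)


def write_consensus_calls(calls: Iterable[ConsensusCall], path, fmt: str | None = None) -> None:
    df = pd.DataFrame(
        [
            {
                "transcript_id": c.transcript_id,
                "n_outlier": c.n_outlier,
                "n_up": c.n_up,
                "n_down": c.n_down,
                "call": c.call,
                "confirmed": c.confirmed,
            }
            for c in calls
        ]
    )
    df.to_csv(path, sep=_sep_for(path, fmt), index=False)


def read_consensus_calls(path) -> list[ConsensusCall]:
    df = pd.read_csv(path, sep=_sep_for(path))
    return [
        ConsensusCall(
            transcript_id=str(r.transcript_id),
            n_outlier=int(r.n_outlier),
            n_up=int(r.n_up),
            n_down=int(r.n_down),
            call=str(r.call),
            confirmed=bool(r.confirmed),
        )
        for r in df.itertuples()
    ]


# ---------------------------------------------------------------------------
# catalogs and dose-response


def read_catalog(path) -> TranscriptCatalog:
    df = pd.read_csv(path, sep=_sep_for(path))
    df["is_toxin"] = df["is_toxin"].astype(bool)
    df["family"] = df["family"].fillna("").astype(str)
    return TranscriptCatalog(df)


def write_catalog(catalog: TranscriptCatalog, path, fmt: str | None = None) -> None:
    catalog.table.to_csv(path, sep=_sep_for(path, fmt), index=False)


def read_dose_response(path) -> DoseResponseTable:
    df = pd.read_csv(path, sep=_sep_for(path))
    cols = {c.lower(): c for c in df.columns}
    return DoseResponseTable(
        doses=df[cols.get("dose", df.columns[0])].to_numpy(dtype=float),
        n_per_group=df[cols.get("n", df.columns[1])].to_numpy(dtype=int),
        deaths=df[cols.get("deaths", df.columns[2])].to_numpy(dtype=int),
    )


def write_dose_response(table: DoseResponseTable, path, fmt: str | None = None) -> None:
    table.to_frame().to_csv(path, sep=_sep_for(path, fmt), index=False)


# ---------------------------------------------------------------------------
# generic dispatch


_WRITERS = {
    ExpressionMatrix: write_expression_table,
    PresenceAbsenceMatrix: write_presence_absence,
    OutlierFlagMatrix: write_outlier_flags,
    DetectionFlags: write_detection_flags,
    DoseResponseTable: write_dose_response,
    TranscriptCatalog: write_catalog,
}


def write_results(obj, path, fmt: str = "tsv") -> None:
    """Serialise any pipeline result to ``path`` in tsv/csv/json.

    Dispatches on the object's type; lists of consensus calls and plain
    dicts are also accepted. JSON output converts numpy scalars.
    """
    if fmt not in ("tsv", "csv", "json"):
        raise ValueError(f"unknown format {fmt!r}; expected tsv, csv or json")
    if fmt == "json":
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            json.dump(_jsonable(obj), fh, indent=2, sort_keys=True)
            fh.write("\n")
        return
    if isinstance(obj, (list, tuple)) and obj and isinstance(obj[0], ConsensusCall):
        write_consensus_calls(obj, path, fmt)
        return
    for klass, writer in _WRITERS.items():
        if isinstance(obj, klass):
            writer(obj, path, fmt)
            return
    raise TypeError(f"do not know how to write {type(obj).__name__} as {fmt}")


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, ConsensusCall):
        return {
            "transcript_id": obj.transcript_id,
            "n_outlier": obj.n_outlier,
            "n_up": obj.n_up,
            "n_down": obj.n_down,
            "call": obj.call,
            "confirmed": obj.confirmed,
        }
    if hasattr(obj, "to_frame"):
        return json.loads(obj.to_frame().to_json(orient="split"))
    return obj


# ---------------------------------------------------------------------------
# sequences


def read_fasta(path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(records: Iterable[tuple[str, str]], path, descriptions=None) -> None:
    descriptions = descriptions or {}
    recs = [
        SeqRecord(Seq(seq), id=rid, description=descriptions.get(rid, ""))
        for rid, seq in records
    ]
    SeqIO.write(recs, str(path), "fasta")


def read_fastq(path) -> list:
    """Read merged reads; returns :class:`venomont.assembler.Read` objects."""
    from venomont.assembler import Read

    out = []
    for rec in SeqIO.parse(str(path), "fastq"):
        out.append(
            Read(
                id=rec.id,
                sequence=str(rec.seq).upper(),
                qualities=list(rec.letter_annotations["phred_quality"]),
            )
        )
    return out


def write_fastq(reads: Iterable, path) -> None:
    recs = []
    for r in reads:
        rec = SeqRecord(Seq(r.sequence), id=r.id, description="")
        rec.letter_annotations["phred_quality"] = list(r.qualities)
        recs.append(rec)
    SeqIO.write(recs, str(path), "fastq")


def ensure_dir(path) -> None:
    os.makedirs(path, exist_ok=True)
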