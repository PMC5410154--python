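"""Packaged transcriptions of the published summary tables.

Six fixtures ship with the package:

``table3``
    59 putative toxin transcripts x 10 individuals, TPM (a toxin-only
    slice, so columns do not close to one million).
``table4_full`` / ``table4_sub``
    Presence/absence matrices over all 59 toxins for the ten
    transcriptomes, from all merged reads and from the 9.5M-read
    subsampling run respectively.
``table5_outliers``
    Per-population adult-vs-juvenile outlier direction flags
    (up/down/none) for each toxin.
``table5_deseq`` / ``table5_deseq2``
    Adjusted p-values from the two external differential-expression
    methods; censored (">0.1") and NA entries are stored as missing and
    count as not detected at the 0.1 FDR threshold.
"""

from __future__ import annotations

from importlib import resources

from venomont import io as vio

_FILES = {
    "table3": "table3_toxin_tpm.tsv",
    "table4_full": "table4_full.csv",
    "table4_sub": "table4_sub.csv",
    "table5_outliers": "table5_outlier_flags.tsv",
    "table5_deseq": "table5_deseq.tsv",
    "table5_deseq2": "table5_deseq2.tsv",
}


def fixture_path(name: str):
    """Filesystem path of a packaged fixture file."""
    if name not in _FILES:
        raise KeyError(f"unknown fixture {name!r}; valid names: {sorted(_FILES)}")
    return resources.files("venomont").joinpath("data", _FILES[name])


def load_fixture(name: str):
    """Load one packaged table by name, as its typed container.

    Valid names: ``table3``, ``table4_full``, ``table4_sub``,
    ``table5_outliers``, ``table5_deseq``, ``table5_deseq2``.
    """
    path = fixture_path(name)
    with resources.as_file(path) as p:
        if name == "table3":
            return vio.read_expression_table(p)
        if name in ("table4_full", "table4_sub"):
            return vio.read_presence_absence(p)
        if name == "table5_outliers":
            return vio.read_outlier_flags(p)
        if name == "table5_deseq":
            return vio.read_detection_flags(p, method="deseq")
        if name == "table5_deseq2":
            return vio.read_detection_flags(p, method="deseq2")
    raise AssertionError("unreachable")
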