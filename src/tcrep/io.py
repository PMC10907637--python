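"""Reading and writing immunoSEQ-style rearrangement tables.

Input files are tab-separated with a single header line, one row per
observed TCR-β rearrangement. Two column-name dialects ship built in
(immunoSEQ v2-style exports and AIRR Rearrangement), and a user-supplied
mapping overrides both. Rows are filtered to productive rearrangements and
aggregated into CDR3β amino-acid clonotypes; V/J labels are carried as
metadata only and never enter clonal identity.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .repertoire import AMINO_ACIDS, EmptyRepertoireError, Repertoire

__all__ = [
    "RearrangementRow",
    "FormatError",
    "read_rearrangements",
    "aggregate_clonotypes",
    "read_repertoire",
    "write_clonotype_table",
    "read_clonotype_table",
    "BUILTIN_DIALECTS",
]

logger = logging.getLogger(__name__)

IN_FRAME = "in"
OUT_OF_FRAME = "out"
STOP = "stop"
UNKNOWN = "unknown"

_VALID_AA = re.compile(rf"^[{AMINO_ACIDS}]+$")


class FormatError(ValueError):
    """Raised when a rearrangement table lacks a mandatory column."""


@dataclass(frozen=True)
class RearrangementRow:
    """One observed rearrangement (one input line) before aggregation."""

    cdr3_nt: str
    cdr3_aa: str
    v_gene: str
    j_gene: str
    templates: int
    frame: str  # one of IN_FRAME / OUT_OF_FRAME / STOP / UNKNOWN

    def is_productive(self) -> bool:
        """In-frame, stop-free rearrangements with a non-empty CDR3β.

        When the source file carried no frame column the call falls back to
        the sequence itself: non-empty and free of the stop character ``*``.
        """
        if self.frame == UNKNOWN:
            return bool(self.cdr3_aa) and "*" not in self.cdr3_aa
        return self.frame == IN_FRAME and bool(self.cdr3_aa) and "*" not in self.cdr3_aa


# Candidate header names per logical field, tried in order. The immunoSEQ
# names come first; AIRR Rearrangement names follow.
BUILTIN_DIALECTS: dict[str, dict[str, Sequence[str]]] = {
    "immunoseq": {
        "cdr3_nt": ("rearrangement", "nucleotide"),
        "cdr3_aa": ("amino_acid", "aminoAcid"),
        "v_gene": ("v_resolved", "v_gene", "vGeneName"),
        "j_gene": ("j_resolved", "j_gene", "jGeneName"),
        "templates": ("templates", "templates/reads"),
        "reads": ("reads", "seq_reads", "count (templates/reads)"),
        "frame": ("frame_type", "sequenceStatus"),
    },
    "airr": {
        "cdr3_nt": ("junction", "cdr3"),
        "cdr3_aa": ("junction_aa", "cdr3_aa"),
        "v_gene": ("v_call",),
        "j_gene": ("j_call",),
        "templates": ("duplicate_count",),
        "reads": ("consensus_count",),
        "frame": ("productive",),
    },
}

_FRAME_ALIASES = {
    "in": IN_FRAME, "in-frame": IN_FRAME, "inframe": IN_FRAME,
    "productive": IN_FRAME, "t": IN_FRAME, "true": IN_FRAME,
    "out": OUT_OF_FRAME, "out-of-frame": OUT_OF_FRAME, "outofframe": OUT_OF_FRAME,
    "f": OUT_OF_FRAME, "false": OUT_OF_FRAME, "unproductive": OUT_OF_FRAME,
    "stop": STOP, "has_stop": STOP,
}


def _normalize_frame(value: object) -> str:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return UNKNOWN
    return _FRAME_ALIASES.get(str(value).strip().lower(), UNKNOWN)


def _resolve_columns(
    header: Sequence[str], dialect: Optional[Mapping[str, str]]
) -> dict[str, Optional[str]]:
    """Map logical field names to actual header columns.

    ``dialect`` maps logical fields (``cdr3_aa``, ``templates``, ...) to
    concrete column names and overrides the built-in candidates.
    """
    present = {c.strip(): c for c in header}
    resolved: dict[str, Optional[str]] = {}
    fields = ("cdr3_nt", "cdr3_aa", "v_gene", "j_gene", "templates", "reads", "frame")
    for field_name in fields:
        col = None
        if dialect and field_name in dialect:
            if dialect[field_name] not in present:
                raise FormatError(
                    f"mapped column {dialect[field_name]!r} for field "
                    f"{field_name!r} not found in header"
                )
            col = present[dialect[field_name]]
        else:
            for d in BUILTIN_DIALECTS.values():
                for candidate in d.get(field_name, ()):
                    if candidate in present:
                        col = present[candidate]
                        break
                if col is not None:
                    break
        resolved[field_name] = col

    if resolved["cdr3_aa"] is None:
        raise FormatError("no CDR3 amino-acid column found (field 'cdr3_aa')")
    if resolved["templates"] is None and resolved["reads"] is None:
        raise FormatError("no template or read count column found (field 'templates')")
    if resolved["templates"] is None:
        logger.warning(
            "no template column; falling back to read counts from column %r",
            resolved["reads"],
        )
    return resolved


def read_rearrangements(
    path: str | Path, dialect: Optional[Mapping[str, str]] = None
) -> list[RearrangementRow]:
    """Read a rearrangement TSV into a list of rows, in file order.

    Parameters
    ----------
    path
        Tab-separated file with a single header line; ``.gz`` transparently
        decompressed.
    dialect
        Optional mapping from logical fields (``cdr3_aa``, ``templates``,
        ``frame``, ...) to column names, overriding the built-in immunoSEQ
        and AIRR dialects.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"rearrangement file not found: {path}")
    table = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    cols = _resolve_columns(list(table.columns), dialect)

    def _col(name: str, default: str = "") -> pd.Series:
        if cols[name] is None:
            return pd.Series([default] * len(table), index=table.index)
        return table[cols[name]]

    count_col = cols["templates"] if cols["templates"] is not None else cols["reads"]
    raw_counts = pd.to_numeric(
        table[count_col].replace("", np.nan), errors="coerce"
    )
    # Rows with a missing count stand for a single observed molecule.
    n_missing = int(raw_counts.isna().sum())
    if n_missing:
        logger.warning("%d rows lack a count in %s; defaulting to 1", n_missing, path)
    counts = raw_counts.fillna(1).astype(np.int64)

    frames = (
        _col("frame").map(_normalize_frame)
        if cols["frame"] is not None
        else pd.Series([UNKNOWN] * len(table), index=table.index)
    )

    rows = [
        RearrangementRow(
            cdr3_nt=str(nt).strip().upper(),
            cdr3_aa=str(aa).strip().upper(),
            v_gene=str(v).strip(),
            j_gene=str(j).strip(),
            templates=int(c),
            frame=f,
        )
        for nt, aa, v, j, c, f in zip(
            _col("cdr3_nt"), _col("cdr3_aa"), _col("v_gene"), _col("j_gene"),
            counts, frames,
        )
    ]
    return rows


def aggregate_clonotypes(
    rows: Iterable[RearrangementRow],
    sample_id: str = "sample",
    subject_id: str = "",
    tissue: str = "other",
    cohort: str = "",
) -> Repertoire:
    """Aggregate rearrangement rows into a productive CDR3β repertoire.

    Keeps productive rows only, groups them by CDR3β amino-acid sequence
    (V/J gene labels are ignored for identity), and sums template counts
    within each group. Sequences containing characters outside the 20-letter
    amino-acid alphabet are dropped with a logged count.

    Raises
    ------
    EmptyRepertoireError
        If no productive rows survive filtering.
    ValueError
        If any row carries a negative template count.
    """
    counts: dict[str, int] = {}
    n_bad_alphabet = 0
    for row in rows:
        if row.templates < 0:
            raise ValueError(
                f"negative template count {row.templates} for {row.cdr3_aa!r}"
            )
        if row.templates == 0 or not row.is_productive():
            continue
        if not _VALID_AA.match(row.cdr3_aa):
            n_bad_alphabet += 1
            continue
        counts[row.cdr3_aa] = counts.get(row.cdr3_aa, 0) + row.templates
    if n_bad_alphabet:
        logger.warning(
            "dropped %d productive rows with non-standard residues in %s",
            n_bad_alphabet, sample_id,
        )
    if not counts:
        raise EmptyRepertoireError(
            f"no productive rearrangements in sample {sample_id!r}"
        )
    return Repertoire.from_counts(
        counts, sample_id=sample_id, subject_id=subject_id, tissue=tissue, cohort=cohort
    )


def read_repertoire(
    path: str | Path,
    sample_id: Optional[str] = None,
    dialect: Optional[Mapping[str, str]] = None,
    **metadata: str,
) -> Repertoire:
    """Read a rearrangement TSV and aggregate it in one call."""
    path = Path(path)
    rows = read_rearrangements(path, dialect=dialect)
    return aggregate_clonotypes(
        rows, sample_id=sample_id or path.stem.removesuffix(".tsv"), **metadata
    )


def write_clonotype_table(repertoire: Repertoire, path: str | Path) -> None:
    """Write a clonotype TSV (cdr3_aa, templates, frequency).

    Rows are sorted by descending template count, ties broken
    lexicographically by sequence; counts round-trip exactly through
    :func:`read_clonotype_table`.
    """
    table = pd.DataFrame(
        list(repertoire.clonotypes()), columns=["cdr3_aa", "templates", "frequency"]
    )
    table.to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_clonotype_table(
    path: str | Path, sample_id: Optional[str] = None, **metadata: str
) -> Repertoire:
    """Read a clonotype TSV written by :func:`write_clonotype_table`."""
    path = Path(path)
    table = pd.read_csv(path, sep="\t", dtype={"cdr3_aa": str, "templates": np.int64})
    if "cdr3_aa" not in table.columns or "templates" not in table.columns:
        raise FormatError(f"{path} is not a clonotype table")
    counts = pd.Series(table["templates"].values, index=table["cdr3_aa"].values)
    return Repertoire(
        sample_id=sample_id or path.stem.removesuffix(".tsv"),
        counts=counts,
        **metadata,
    )
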