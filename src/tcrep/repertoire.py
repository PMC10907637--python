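"""Core containers for TCR-β CDR3 clonotype repertoires.

A *clonotype* is one productive CDR3β amino-acid sequence; its abundance is
the template count (number of input DNA molecules supporting it). A
*repertoire* is one sample's clonotype table plus sample identity (subject,
tissue, cohort). All diversity and overlap statistics in this package run on
these containers.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Mapping, NamedTuple

import numpy as np
import pandas as pd

__all__ = [
    "AMINO_ACIDS",
    "Clonotype",
    "Repertoire",
    "EmptyRepertoireError",
    "RepertoireValidationError",
]

#: The 20 standard amino acids (uppercase one-letter codes).
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


class EmptyRepertoireError(ValueError):
    """Raised when an operation requires at least one productive clonotype."""


class RepertoireValidationError(ValueError):
    """Raised when clonotype counts violate the repertoire invariants."""


class Clonotype(NamedTuple):
    """One productive CDR3β amino-acid sequence within a sample."""

    cdr3_aa: str
    templates: int
    frequency: float


@dataclass(frozen=True)
class Repertoire:
    """One sample's aggregated clonotype table.

    Parameters
    ----------
    sample_id
        Unique sample label.
    counts
        Template counts indexed by CDR3β amino-acid sequence. The index must
        be unique and every count a positive integer.
    subject_id, tissue, cohort
        Sample identity used for pairing and grouping. ``tissue`` is one of
        ``"tumor"``, ``"ntl"`` (adjacent non-tumor liver) or ``"other"``.
    """

    sample_id: str
    counts: pd.Series
    subject_id: str = ""
    tissue: str = "other"
    cohort: str = ""

    def __post_init__(self) -> None:
        counts = self.counts
        if not isinstance(counts, pd.Series):
            counts = pd.Series(counts, dtype=np.int64)
        counts = counts.astype(np.int64)
        counts.name = "templates"
        if len(counts) == 0:
            raise EmptyRepertoireError(
                f"repertoire {self.sample_id!r} has no clonotypes"
            )
        if not counts.index.is_unique:
            raise RepertoireValidationError(
                f"repertoire {self.sample_id!r} has duplicate CDR3 keys"
            )
        if (counts.values <= 0).any():
            raise RepertoireValidationError(
                f"repertoire {self.sample_id!r} has non-positive template counts"
            )
        if self.tissue not in ("tumor", "ntl", "other"):
            raise RepertoireValidationError(
                f"unknown tissue label {self.tissue!r} (expected tumor/ntl/other)"
            )
        object.__setattr__(self, "counts", counts)

    @classmethod
    def from_counts(
        cls,
        counts: Mapping[str, int],
        sample_id: str = "sample",
        **metadata: str,
    ) -> "Repertoire":
        """Build a repertoire from a ``{cdr3_aa: templates}`` mapping."""
        return cls(sample_id=sample_id, counts=pd.Series(counts, dtype=np.int64), **metadata)

    # -- derived quantities -------------------------------------------------

    @property
    def n_unique(self) -> int:
        """Number of distinct clonotypes (``n`` in the diversity formulas)."""
        return int(len(self.counts))

    @property
    def total_templates(self) -> int:
        """Total template count over all clonotypes (``N``)."""
        return int(self.counts.values.sum())

    @property
    def frequencies(self) -> pd.Series:
        """Per-clonotype probabilities ``p_i = templates_i / N``."""
        freq = self.counts / self.total_templates
        freq.name = "frequency"
        return freq

    def clonotypes(self) -> Iterator[Clonotype]:
        """Iterate clonotypes sorted by descending count, then sequence."""
        total = self.total_templates
        order = sorted(self.counts.items(), key=lambda kv: (-kv[1], kv[0]))
        for cdr3, templates in order:
            yield Clonotype(str(cdr3), int(templates), templates / total)

    def with_metadata(self, **metadata: str) -> "Repertoire":
        """Return a copy with updated identity fields."""
        return replace(self, **metadata)

    def __len__(self) -> int:
        return self.n_unique

    def __contains__(self, cdr3_aa: str) -> bool:
        return cdr3_aa in self.counts.index
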