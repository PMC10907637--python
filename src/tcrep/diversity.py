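"""Per-repertoire diversity statistics.

Shannon entropy (in bits), entropy-normalized clonality, Simpson's index,
the rank-abundance clone-size spectrum, and fixed-size clonotype
down-sampling. With clonotype probabilities ``p_i = templates_i / N`` over
``n`` unique clonotypes:

* Shannon entropy  ``H = -Σ p_i log2 p_i``
* Clonality        ``1 + (Σ p_i log2 p_i) / log2 n  =  1 - H / log2 n``
* Simpson's index  ``D = Σ p_i²``

Clonality ranges over [0, 1]: 0 for a perfectly even (maximally diverse)
repertoire and 1 for a monoclonal one. The single-clone case, where the
formula divides by ``log2(1) = 0``, is defined as clonality 1 — a repertoire
of one clone is the monoclonal extreme.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .repertoire import EmptyRepertoireError, Repertoire

__all__ = [
    "DiversitySummary",
    "CloneSizeSpectrum",
    "shannon_entropy",
    "clonality",
    "simpson_index",
    "downsample_clonotypes",
    "clone_size_spectrum",
    "summarize",
]

DEFAULT_DOWNSAMPLE_K = 20_000
DEFAULT_SIZE_CLASS_EDGES = (1, 10, 100)


@dataclass(frozen=True)
class DiversitySummary:
    """Diversity statistics for one sample."""

    sample_id: str
    subject_id: str
    tissue: str
    cohort: str
    n_unique: int
    total_templates: int
    shannon_entropy_bits: float
    clonality: float
    simpson: float


@dataclass(frozen=True)
class CloneSizeSpectrum:
    """Rank-abundance view of a repertoire.

    ``ranks`` holds one row per clonotype, ordered by descending template
    count (ties broken lexicographically by sequence). ``histogram`` counts
    clonotypes per size class; the top class is open-ended.
    """

    sample_id: str
    ranks: pd.DataFrame  # columns: clone_rank, cdr3_aa, templates
    histogram: pd.Series  # index: size-class label, values: clonotype counts


def shannon_entropy(repertoire: Repertoire) -> float:
    """Shannon entropy of the clonotype frequencies, in bits."""
    return float(stats.entropy(repertoire.counts.values, base=2))


def clonality(repertoire: Repertoire) -> float:
    """Entropy-normalized clonality in [0, 1].

    ``1 + (Σ p_i log2 p_i) / log2 n`` for ``n ≥ 2``; 1.0 for a single-clone
    repertoire (monoclonal convention for the ``log2(1) = 0`` degeneracy).
    """
    n = repertoire.n_unique
    if n == 1:
        return 1.0
    value = 1.0 - shannon_entropy(repertoire) / np.log2(n)
    # guard against ~1e-16 float excursions outside [0, 1]
    return float(min(max(value, 0.0), 1.0))


def simpson_index(repertoire: Repertoire) -> float:
    """Simpson's index ``D = Σ p_i²``: the probability that two templates
    drawn at random belong to the same clonotype."""
    p = repertoire.frequencies.values
    return float(np.dot(p, p))


def downsample_clonotypes(
    repertoire: Repertoire,
    k: int = DEFAULT_DOWNSAMPLE_K,
    seed: Optional[int | np.random.Generator] = None,
) -> Repertoire:
    """Down-sample to exactly ``k`` unique clonotypes.

    Clonotypes are drawn uniformly without replacement — unweighted, so the
    clone-size distribution shape is preserved in expectation — and each
    retains its original template count; frequencies renormalize implicitly.
    Repertoires with ``n_unique ≤ k`` are returned unchanged.
    """
    if k <= 0:
        raise ValueError(f"k must be a positive integer, got {k}")
    if repertoire.n_unique <= k:
        return repertoire
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    keep = rng.choice(repertoire.n_unique, size=k, replace=False)
    keep.sort()
    return Repertoire(
        sample_id=repertoire.sample_id,
        counts=repertoire.counts.iloc[keep],
        subject_id=repertoire.subject_id,
        tissue=repertoire.tissue,
        cohort=repertoire.cohort,
    )


def clone_size_spectrum(
    repertoire: Repertoire,
    size_class_edges: Sequence[int] = DEFAULT_SIZE_CLASS_EDGES,
) -> CloneSizeSpectrum:
    """Rank clonotypes by abundance and bin them into size classes.

    ``size_class_edges`` must be strictly increasing; classes are
    ``[e_0, e_1), [e_1, e_2), ..., [e_last, ∞)`` — the top class is open
    (e.g. edges ``(1, 10, 100)`` give classes 1–9, 10–99 and ≥100).
    """
    edges = np.asarray(size_class_edges)
    if len(edges) == 0 or (len(edges) > 1 and not (np.diff(edges) > 0).all()):
        raise ValueError(f"size class edges must be strictly increasing: {size_class_edges}")

    order = sorted(repertoire.counts.items(), key=lambda kv: (-kv[1], kv[0]))
    ranks = pd.DataFrame(
        {
            "clone_rank": np.arange(1, len(order) + 1),
            "cdr3_aa": [k for k, _ in order],
            "templates": [int(v) for _, v in order],
        }
    )

    labels = [
        f"{lo}" if hi == lo + 1 else f"{lo}-{hi - 1}"
        for lo, hi in zip(edges[:-1], edges[1:])
    ] + [f">={edges[-1]}"]
    bin_idx = np.digitize(ranks["templates"].values, edges[1:], right=False)
    hist = pd.Series(
        np.bincount(bin_idx, minlength=len(labels)), index=labels, name="n_clonotypes"
    )
    return CloneSizeSpectrum(sample_id=repertoire.sample_id, ranks=ranks, histogram=hist)


def summarize(repertoire: Repertoire) -> DiversitySummary:
    """Compute the full diversity summary for one repertoire."""
    if repertoire.n_unique < 1:
        raise EmptyRepertoireError("cannot summarize an empty repertoire")
    return DiversitySummary(
        sample_id=repertoire.sample_id,
        subject_id=repertoire.subject_id,
        tissue=repertoire.tissue,
        cohort=repertoire.cohort,
        n_unique=repertoire.n_unique,
        total_templates=repertoire.total_templates,
        shannon_entropy_bits=shannon_entropy(repertoire),
        clonality=clonality(repertoire),
        simpson=simpson_index(repertoire),
    )
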