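"""Pairwise repertoire overlap: Morisita's index and shared clonotypes.

Morisita's overlap index (MOI, the Morisita–Horn form) between repertoires
X and Y with per-clonotype template counts x_i, y_i over the union of their
CDR3β keys (absent keys count 0):

    MOI = 2 Σ x_i y_i / ((D_X + D_Y) N_X N_Y)

where N is each sample's total template count and D its Simpson index
Σ (x_i/N)². MOI is 0 when no sequence is shared and 1 when both samples
have identical clonotype composition.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .repertoire import Repertoire

__all__ = [
    "OverlapMatrix",
    "SharedClonotypePair",
    "CohortOverlapSummary",
    "morisita_overlap",
    "pairwise_overlap_matrix",
    "shared_clonotypes",
    "clonotype_publicity",
    "cohort_overlap_summary",
]


def morisita_overlap(x: Repertoire, y: Repertoire) -> float:
    """Morisita's overlap index between two repertoires, in [0, 1]."""
    xc, yc = x.counts, y.counts
    shared = xc.index.intersection(yc.index)
    if len(shared) == 0:
        return 0.0
    nx, ny = x.total_templates, y.total_templates
    cross = float(np.dot(xc.loc[shared].values.astype(float),
                         yc.loc[shared].values.astype(float)))
    sum_sq_x = float(np.dot(xc.values.astype(float), xc.values.astype(float)))
    sum_sq_y = float(np.dot(yc.values.astype(float), yc.values.astype(float)))
    # (D_X + D_Y) N_X N_Y rewritten so two identical repertoires hit 1.0 exactly
    denom = sum_sq_x * (ny / nx) + sum_sq_y * (nx / ny)
    return 2.0 * cross / denom


@dataclass(frozen=True)
class OverlapMatrix:
    """Symmetric pairwise MOI matrix over a set of samples."""

    sample_ids: tuple[str, ...]
    values: np.ndarray  # square, symmetric, unit diagonal

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.sample_ids)

    def to_long(self) -> pd.DataFrame:
        """Unordered off-diagonal pairs as (sample_a, sample_b, moi) rows."""
        records = [
            (self.sample_ids[i], self.sample_ids[j], self.values[i, j])
            for i, j in itertools.combinations(range(len(self.sample_ids)), 2)
        ]
        return pd.DataFrame(records, columns=["sample_a", "sample_b", "moi"])

    def pair(self, a: str, b: str) -> float:
        i, j = self.sample_ids.index(a), self.sample_ids.index(b)
        return float(self.values[i, j])

    def offdiagonal(self) -> np.ndarray:
        iu = np.triu_indices(len(self.sample_ids), k=1)
        return self.values[iu]


def pairwise_overlap_matrix(repertoires: Sequence[Repertoire]) -> OverlapMatrix:
    """MOI for every unordered pair of repertoires."""
    if len(repertoires) < 2:
        raise ValueError("need at least 2 repertoires for a pairwise matrix")
    ids = [r.sample_id for r in repertoires]
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate sample_ids in overlap matrix input: {ids}")
    n = len(repertoires)
    values = np.eye(n)
    for i, j in itertools.combinations(range(n), 2):
        values[i, j] = values[j, i] = morisita_overlap(repertoires[i], repertoires[j])
    return OverlapMatrix(sample_ids=tuple(ids), values=values)


@dataclass(frozen=True)
class SharedClonotypePair:
    """Clonotypes common to two samples, with both samples' counts."""

    sample_a: str
    sample_b: str
    shared: frozenset[str]
    counts: pd.DataFrame  # index cdr3_aa; columns templates_a, templates_b

    @property
    def n_shared(self) -> int:
        return len(self.shared)


def shared_clonotypes(x: Repertoire, y: Repertoire) -> SharedClonotypePair:
    """Exact CDR3β key intersection of two repertoires."""
    shared = x.counts.index.intersection(y.counts.index).sort_values()
    counts = pd.DataFrame(
        {
            "templates_a": x.counts.loc[shared].astype(int),
            "templates_b": y.counts.loc[shared].astype(int),
        },
        index=shared,
    )
    return SharedClonotypePair(
        sample_a=x.sample_id,
        sample_b=y.sample_id,
        shared=frozenset(shared),
        counts=counts,
    )


def clonotype_publicity(repertoires: Sequence[Repertoire]) -> pd.Series:
    """For each clonotype, the number of distinct subjects carrying it.

    Samples without a subject_id count as distinct subjects. A clonotype
    with publicity ≥ 2 is *public* (seen in more than one individual).
    """
    carriers: dict[str, set[str]] = {}
    for rep in repertoires:
        subject = rep.subject_id or rep.sample_id
        for cdr3 in rep.counts.index:
            carriers.setdefault(cdr3, set()).add(subject)
    pub = pd.Series({k: len(v) for k, v in carriers.items()}, name="publicity")
    return pub.sort_values(ascending=False)


@dataclass(frozen=True)
class CohortOverlapSummary:
    """Within-group pairwise MOI distributions and their paired comparison.

    The paired unit is the subject: each subject contributes the mean MOI of
    its group-A sample against all other subjects' group-A samples, and the
    same quantity within group B. A paired two-sided t-test compares the two
    per-subject vectors. ``degenerate`` flags an all-zero-variance
    difference vector, where the t statistic is undefined.
    """

    group_a_name: str
    group_b_name: str
    values_a: np.ndarray  # within-group pairwise MOI, group A
    values_b: np.ndarray
    mean_a: float
    mean_b: float
    subjects: tuple[str, ...]
    per_subject_a: np.ndarray  # per-subject mean cross-individual MOI
    per_subject_b: np.ndarray
    statistic: float
    p_value: float
    degenerate: bool = False
    test_kind: str = "paired-t"


def _per_subject_mean_moi(matrix: OverlapMatrix, subjects: Sequence[str]) -> dict[str, float]:
    """Mean MOI of each subject's sample against all other samples."""
    vals = matrix.values
    out = {}
    for i, subj in enumerate(subjects):
        others = [j for j in range(len(subjects)) if j != i]
        out[subj] = float(vals[i, others].mean())
    return out


def cohort_overlap_summary(
    group_a: Sequence[Repertoire],
    group_b: Sequence[Repertoire],
    pairing: Optional[Mapping[str, tuple[str, str]]] = None,
    group_a_name: str = "tumor",
    group_b_name: str = "ntl",
) -> CohortOverlapSummary:
    """Compare within-group cross-individual sharing between two groups.

    Parameters
    ----------
    group_a, group_b
        Each a list of ≥2 repertoires, one per subject (e.g. all tumor
        samples vs all adjacent-liver samples).
    pairing
        Optional ``{subject_id: (sample_id_in_a, sample_id_in_b)}``. When
        omitted, samples are paired by their ``subject_id`` field.
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs at least 2 repertoires")

    mat_a = pairwise_overlap_matrix(group_a)
    mat_b = pairwise_overlap_matrix(group_b)

    ids_a = {r.sample_id: r for r in group_a}
    ids_b = {r.sample_id: r for r in group_b}
    if pairing is None:
        subj_a = {r.subject_id: r.sample_id for r in group_a if r.subject_id}
        subj_b = {r.subject_id: r.sample_id for r in group_b if r.subject_id}
        common = sorted(set(subj_a) & set(subj_b))
        pairing = {s: (subj_a[s], subj_b[s]) for s in common}
    for subj, (sa, sb) in pairing.items():
        if sa not in ids_a or sb not in ids_b:
            raise ValueError(f"pairing for subject {subj!r} references missing samples")
    if len(pairing) < 2:
        raise ValueError("need at least 2 paired subjects for the paired comparison")

    subj_means_a = _per_subject_mean_moi(mat_a, [r.subject_id or r.sample_id for r in group_a])
    subj_means_b = _per_subject_mean_moi(mat_b, [r.subject_id or r.sample_id for r in group_b])
    subjects = tuple(sorted(pairing))
    a_vec = np.array([subj_means_a[ids_a[pairing[s][0]].subject_id or pairing[s][0]]
                      for s in subjects])
    b_vec = np.array([subj_means_b[ids_b[pairing[s][1]].subject_id or pairing[s][1]]
                      for s in subjects])

    diffs = a_vec - b_vec
    if np.allclose(diffs.std(ddof=1), 0.0):
        statistic, p_value, degenerate = float("nan"), float("nan"), True
        if np.allclose(diffs, 0.0):
            # identical per-subject sharing: a true null, statistic 0 by convention
            statistic, p_value = 0.0, 1.0
    else:
        res = stats.ttest_rel(a_vec, b_vec)
        statistic, p_value, degenerate = float(res.statistic), float(res.pvalue), False

    return CohortOverlapSummary(
        group_a_name=group_a_name,
        group_b_name=group_b_name,
        values_a=mat_a.offdiagonal(),
        values_b=mat_b.offdiagonal(),
        mean_a=float(mat_a.offdiagonal().mean()),
        mean_b=float(mat_b.offdiagonal().mean()),
        subjects=subjects,
        per_subject_a=a_vec,
        per_subject_b=b_vec,
        statistic=statistic,
        p_value=p_value,
        degenerate=degenerate,
    )
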