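"""Synthetic multi-individual paired tumor / adjacent-liver repertoires.

The generator reproduces, with controllable parameters, the two statistical
features the downstream analysis is built to detect:

1. heavy-tailed (Zipf / power-law) clone-size distributions, with a
   per-tissue exponent α controlling expansion (α = 0 gives near-uniform
   counts and clonality near 0; larger α gives more skew and higher
   clonality);
2. cross-individual clonotype sharing through a single *public pool* of
   CDR3β sequences drawn once per cohort, from which each sample takes a
   tissue-specific fraction ``f`` of its clonotypes. Template counts for
   public clonotypes are drawn independently per sample — sharing is of
   identity, not of abundance.

Tumor and adjacent-liver samples of the same subject additionally share a
small within-subject pool so paired samples are not artificially disjoint.
This is a modeling device for testing the pipeline, not a claim about
T-cell biology: there is no V(D)J recombination model, no generation
probabilities and no sequencing error.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .repertoire import AMINO_ACIDS, Repertoire

__all__ = [
    "SimulationConfig",
    "SyntheticCohort",
    "random_cdr3",
    "zipf_counts",
    "generate_cohort",
    "write_cohort",
    "read_cohort_manifest",
]

logger = logging.getLogger(__name__)

_AA_ARRAY = np.array(list(AMINO_ACIDS))


@dataclass(frozen=True)
class SimulationConfig:
    """All parameters of the synthetic cohort generator.

    Defaults emulate the study conditions of a small liver-tumor cohort:
    paired tumor / adjacent non-tumor liver (NTL) samples per subject, tens
    of thousands of unique clonotypes per sample at roughly 10 templates per
    clonotype, a power-law clone-size skew that is stronger in NTL than in
    tumor (tumor less clonally expanded), and a public-pool sharing fraction
    that is much higher among tumors than among NTL samples.
    """

    n_subjects: int = 6
    unique_clonotypes_per_sample: int = 20_000
    total_templates_per_sample: int = 200_000
    powerlaw_exponent_tumor: float = 1.0
    powerlaw_exponent_ntl: float = 1.5
    public_pool_size: int = 30_000
    public_fraction_tumor: float = 0.30
    public_fraction_ntl: float = 0.02
    within_subject_fraction: float = 0.05
    cdr3_length_range: tuple[int, int] = (9, 18)
    seed: int = 7

    def validate(self) -> None:
        u, t, p = (self.unique_clonotypes_per_sample,
                   self.total_templates_per_sample, self.public_pool_size)
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be ≥ 1")
        if t < u:
            raise ValueError(f"total templates ({t}) must be ≥ unique clonotypes ({u})")
        for name, f in (("public_fraction_tumor", self.public_fraction_tumor),
                        ("public_fraction_ntl", self.public_fraction_ntl),
                        ("within_subject_fraction", self.within_subject_fraction)):
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {f}")
            if name != "within_subject_fraction" and round(f * u) > p:
                raise ValueError(
                    f"{name}={f} requests {round(f * u)} public clonotypes "
                    f"but the pool holds only {p}"
                )
        if self.powerlaw_exponent_tumor < 0 or self.powerlaw_exponent_ntl < 0:
            raise ValueError("power-law exponents must be ≥ 0")
        g = round(self.within_subject_fraction * u)
        for f in (self.public_fraction_tumor, self.public_fraction_ntl):
            if round(f * u) + g > u:
                raise ValueError(
                    "public plus within-subject pool fractions exceed the "
                    "per-sample clonotype budget"
                )
        lo, hi = self.cdr3_length_range
        if lo < 3 or hi < lo:
            raise ValueError(f"invalid CDR3 length range {self.cdr3_length_range}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cdr3_length_range"] = list(self.cdr3_length_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "cdr3_length_range" in d:
            d["cdr3_length_range"] = tuple(d["cdr3_length_range"])
        return cls(**d)


@dataclass(frozen=True)
class SyntheticCohort:
    """A generated cohort: two repertoires (tumor + NTL) per subject.

    ``provenance`` maps each sample to a per-clonotype origin label:
    ``public:<pool index>``, ``subject`` (within-subject shared pool) or
    ``private``.
    """

    repertoires: tuple[Repertoire, ...]
    config: SimulationConfig
    provenance: dict[str, dict[str, str]] = field(repr=False, default_factory=dict)

    def by_tissue(self, tissue: str) -> list[Repertoire]:
        return [r for r in self.repertoires if r.tissue == tissue]

    def pairing(self) -> dict[str, tuple[str, str]]:
        """subject_id → (tumor sample_id, ntl sample_id)."""
        tum = {r.subject_id: r.sample_id for r in self.by_tissue("tumor")}
        ntl = {r.subject_id: r.sample_id for r in self.by_tissue("ntl")}
        return {s: (tum[s], ntl[s]) for s in sorted(tum) if s in ntl}


def random_cdr3(
    rng: np.random.Generator, length_range: tuple[int, int] = (9, 18)
) -> str:
    """One random CDR3β-like amino-acid string.

    Follows the CDR3β convention of a conserved cysteine at the start and
    phenylalanine at the end; the interior is uniform over the 20-letter
    alphabet. Lengths are drawn uniformly from ``length_range`` (inclusive).
    """
    lo, hi = length_range
    if lo < 3:
        raise ValueError(f"minimum CDR3 length must be ≥ 3, got {lo}")
    length = int(rng.integers(lo, hi + 1))
    interior = rng.choice(_AA_ARRAY, size=length - 2)
    return "C" + "".join(interior) + "F"


def _random_cdr3_batch(
    rng: np.random.Generator, n: int, length_range: tuple[int, int]
) -> list[str]:
    """Vectorized batch of CDR3-like strings (not deduplicated)."""
    lo, hi = length_range
    if lo < 3:
        raise ValueError(f"minimum CDR3 length must be ≥ 3, got {lo}")
    lengths = rng.integers(lo, hi + 1, size=n)
    chars = rng.integers(0, len(_AA_ARRAY), size=int(lengths.sum() - 2 * n))
    flat = _AA_ARRAY[chars]
    out, pos = [], 0
    for ln in lengths:
        k = int(ln) - 2
        out.append("C" + "".join(flat[pos:pos + k]) + "F")
        pos += k
    return out


def _draw_unique_cdr3s(
    rng: np.random.Generator,
    n: int,
    length_range: tuple[int, int],
    used: set[str],
) -> list[str]:
    """Draw ``n`` fresh sequences absent from ``used``; collisions re-drawn."""
    out: list[str] = []
    while len(out) < n:
        batch = _random_cdr3_batch(rng, n - len(out), length_range)
        for s in batch:
            if s not in used:
                used.add(s)
                out.append(s)
    return out


def zipf_counts(
    u: int, t: int, alpha: float, rng: np.random.Generator
) -> np.ndarray:
    """Zipf-like clone sizes: ``u`` positive integers summing exactly to ``t``.

    Every clonotype gets one guaranteed template; the residual ``t - u``
    templates are drawn multinomially with rank-``r`` probability
    proportional to ``r^(-alpha)``. ``alpha = 0`` gives near-uniform counts;
    larger ``alpha`` concentrates templates on the leading ranks.
    """
    if u < 1:
        raise ValueError("u must be ≥ 1")
    if t < u:
        raise ValueError(f"t ({t}) must be ≥ u ({u}) so every clonotype gets a template")
    if alpha < 0:
        raise ValueError("alpha must be ≥ 0")
    ranks = np.arange(1, u + 1, dtype=float)
    weights = ranks ** (-alpha)
    probs = weights / weights.sum()
    counts = np.ones(u, dtype=np.int64)
    if t > u:
        counts += rng.multinomial(t - u, probs)
    return counts


def _make_sample(
    rng: np.random.Generator,
    config: SimulationConfig,
    public_pool: list[str],
    subject_pool: list[str],
    used: set[str],
    public_fraction: float,
    alpha: float,
    sample_id: str,
    subject_id: str,
    tissue: str,
    cohort: str,
) -> tuple[Repertoire, dict[str, str]]:
    u = config.unique_clonotypes_per_sample
    n_public = round(public_fraction * u)
    n_subject = min(round(config.within_subject_fraction * u), len(subject_pool))
    n_private = u - n_public - n_subject

    pool_idx = rng.choice(len(public_pool), size=n_public, replace=False)
    members = [public_pool[i] for i in pool_idx]
    origins = {public_pool[i]: f"public:{i}" for i in pool_idx}
    for s in subject_pool[:n_subject]:
        origins[s] = "subject"
    members += subject_pool[:n_subject]
    private = _draw_unique_cdr3s(rng, n_private, config.cdr3_length_range, used)
    for s in private:
        origins[s] = "private"
    members += private

    counts = zipf_counts(u, config.total_templates_per_sample, alpha, rng)
    # random identity→rank assignment: public clones are not systematically
    # the largest, matching abundance-independent sharing
    perm = rng.permutation(u)
    series = pd.Series(counts, index=np.array(members)[perm])
    rep = Repertoire(
        sample_id=sample_id, counts=series,
        subject_id=subject_id, tissue=tissue, cohort=cohort,
    )
    return rep, origins


def generate_cohort(config: SimulationConfig = SimulationConfig()) -> SyntheticCohort:
    """Generate a paired tumor/NTL cohort from a single seed.

    One public pool of ``public_pool_size`` distinct sequences is drawn once
    for the whole cohort. Each sample draws ``round(f·U)`` of its clonotypes
    uniformly from that pool, ``round(g·U)`` from a per-subject shared pool,
    and the remainder as fresh private sequences guaranteed unique across
    the cohort; clone sizes come from :func:`zipf_counts` with the tissue's
    exponent. Fully reproducible from ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    used: set[str] = set()
    public_pool = _draw_unique_cdr3s(
        rng, config.public_pool_size, config.cdr3_length_range, used
    )

    n_subject_pool = round(
        config.within_subject_fraction * config.unique_clonotypes_per_sample
    )
    reps: list[Repertoire] = []
    provenance: dict[str, dict[str, str]] = {}
    for k in range(1, config.n_subjects + 1):
        subject_id = f"S{k:02d}"
        subject_pool = _draw_unique_cdr3s(
            rng, n_subject_pool, config.cdr3_length_range, used
        )
        for tissue, frac, alpha in (
            ("tumor", config.public_fraction_tumor, config.powerlaw_exponent_tumor),
            ("ntl", config.public_fraction_ntl, config.powerlaw_exponent_ntl),
        ):
            sample_id = f"{subject_id}-{tissue}"
            rep, origins = _make_sample(
                rng, config, public_pool, subject_pool, used,
                frac, alpha, sample_id, subject_id, tissue, cohort="synthetic",
            )
            reps.append(rep)
            provenance[sample_id] = origins
    return SyntheticCohort(
        repertoires=tuple(reps), config=config, provenance=provenance
    )


def write_cohort(cohort: SyntheticCohort, directory: str | Path) -> Path:
    """Write one rearrangement-style TSV per sample plus a manifest.

    TSVs use the immunoSEQ-style columns read back by
    :mod:`tcrep.io` (``amino_acid``, ``templates``, ``frame_type``); the
    manifest JSON records the config, seed and per-sample metadata, so the
    cohort can be re-generated byte-identically.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    samples = []
    for rep in cohort.repertoires:
        fname = f"{rep.sample_id}.tsv"
        clones = list(rep.clonotypes())
        table = pd.DataFrame(
            {
                "amino_acid": [c.cdr3_aa for c in clones],
                "templates": [c.templates for c in clones],
                "frame_type": "In",
            }
        )
        table.to_csv(directory / fname, sep="\t", index=False)
        samples.append(
            {
                "sample_id": rep.sample_id,
                "subject_id": rep.subject_id,
                "tissue": rep.tissue,
                "cohort": rep.cohort,
                "file": fname,
            }
        )
    manifest = {"config": cohort.config.to_dict(), "samples": samples}
    manifest_path = directory / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest_path


def read_cohort_manifest(manifest_path: str | Path) -> tuple[SimulationConfig, pd.DataFrame]:
    """Read a cohort manifest back into its config and sample table."""
    manifest_path = Path(manifest_path)
    manifest = json.loads(manifest_path.read_text())
    config = SimulationConfig.from_dict(manifest["config"])
    samples = pd.DataFrame(manifest["samples"])
    samples["file"] = [str(manifest_path.parent / f) for f in samples["file"]]
    return config, samples
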