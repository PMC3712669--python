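"""Shared domain containers.

Conventions used throughout the package:

* genomic positions are 1-based and inclusive;
* genotypes are additive dosages in ``{0, 1, 2}`` of the ALT (effect) allele,
  with hemizygous male X genotypes coded 0/2;
* a *simple feature* is a single SNP lying in no LD block, a *complex
  feature* is the set of SNPs an LD block contributes to a gene or pathway
  window (two or more SNPs).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "SnpRecord",
    "GeneAnnotation",
    "PathwayDefinition",
    "AssocResult",
    "MetaResult",
    "LdBlock",
    "FeatureSet",
    "PathwayArchitecture",
    "PermutationResult",
    "StratumSpec",
]


@dataclass(frozen=True)
class SnpRecord:
    """One genotyped variant."""

    id: str
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    maf: float  # realized ALT-allele frequency in the panel

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"{self.id}: position must be >= 1")


@dataclass(frozen=True)
class GeneAnnotation:
    """Transcript span of a gene, 1-based inclusive."""

    symbol: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.symbol}: start > end")


@dataclass(frozen=True)
class PathwayDefinition:
    """A named gene set analysed as one unit.

    ``flank`` is the distance in bases by which each gene's transcript span
    is extended on both sides when capturing SNPs (closed interval).
    """

    name: str
    genes: Tuple[str, ...]
    flank: int = 50_000

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("pathway gene symbols must be unique")
        if self.flank < 0:
            raise ValueError("flank must be non-negative")


@dataclass(frozen=True)
class AssocResult:
    """Per-SNP case-control association summary.

    ``beta`` is the log odds ratio per copy of ``effect_allele``. A SNP
    that could not be analysed (monomorphic, separation) carries
    ``beta = se = p = nan`` and a non-empty ``note``; such results are
    excluded from feature construction downstream.
    """

    snp: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    p: float
    n: int
    note: str = ""

    @property
    def ok(self) -> bool:
        return self.note == "" and np.isfinite(self.beta) and self.se > 0

    @property
    def odds_ratio(self) -> float:
        return float(np.exp(self.beta))


@dataclass(frozen=True)
class MetaResult:
    """Fixed-effect combination of per-study summaries for one SNP."""

    snp: str
    beta: Optional[float]
    se: Optional[float]
    p: float
    weights: Tuple[float, ...]
    n_studies: int
    n: int


@dataclass(frozen=True)
class LdBlock:
    """A run of physically adjacent SNPs in strong pairwise LD."""

    chrom: str
    snps: Tuple[str, ...]  # ordered by position
    start: int
    end: int

    def __post_init__(self) -> None:
        if len(self.snps) < 2:
            raise ValueError("an LD block needs at least two members")

    def __len__(self) -> int:
        return len(self.snps)


@dataclass(frozen=True)
class FeatureSet:
    """A gene or pathway decomposed into simple and complex features.

    The features partition the mapped SNPs: every mapped SNP appears in
    exactly one simple or complex feature.
    """

    owner: str
    simple: Tuple[str, ...]
    complex: Tuple[Tuple[str, ...], ...]

    def __post_init__(self) -> None:
        for members in self.complex:
            if len(members) < 2:
                raise ValueError("complex features need >= 2 SNPs")
        seen = list(self.simple) + [s for c in self.complex for s in c]
        if len(seen) != len(set(seen)):
            raise ValueError(f"{self.owner}: a SNP appears in two features")

    @property
    def n_simple(self) -> int:
        return len(self.simple)

    @property
    def n_complex(self) -> int:
        return len(self.complex)

    @property
    def n_features(self) -> int:
        return self.n_simple + self.n_complex

    @property
    def snps(self) -> Tuple[str, ...]:
        return tuple(self.simple) + tuple(s for c in self.complex for s in c)

    @property
    def architecture(self) -> "PathwayArchitecture":
        return PathwayArchitecture(
            n_simple=self.n_simple,
            complex_sizes=tuple(sorted(len(c) for c in self.complex)),
        )


@dataclass(frozen=True)
class PathwayArchitecture:
    """Matching key for the permutation null: the number of simple features
    plus the multiset of complex-feature sizes."""

    n_simple: int
    complex_sizes: Tuple[int, ...]  # sorted

    @property
    def size_counts(self) -> Counter:
        return Counter(self.complex_sizes)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PathwayArchitecture):
            return NotImplemented
        return (
            self.n_simple == other.n_simple
            and Counter(self.complex_sizes) == Counter(other.complex_sizes)
        )

    def __hash__(self) -> int:
        return hash((self.n_simple, tuple(sorted(self.complex_sizes))))


@dataclass(frozen=True)
class PermutationResult:
    """Outcome of an architecture-matched permutation test.

    ``p_value`` is the strict-exceedance plug-in estimate
    ``#{null count > observed} / n_perm`` unless the bias-corrected
    ``(k+1)/(n+1)`` estimator was requested.
    """

    owner: str
    observed: int
    null_counts: Tuple[int, ...]
    n_perm: int
    p_value: float
    alpha: float
    seed: Optional[int]
    note: str = ""

    @property
    def testable(self) -> bool:
        return self.n_perm > 0 and self.note != "untestable"

    @property
    def n_exceed(self) -> int:
        return int(sum(c > self.observed for c in self.null_counts))


@dataclass(frozen=True)
class StratumSpec:
    """One analysis stratum: a gender filter crossed with an outcome.

    Outcomes partition cases by intraocular pressure at diagnosis:
    ``hpg`` keeps cases with IOP >= 22 mmHg, ``npg`` cases with IOP < 22;
    ``overall`` keeps every case. Controls are shared across outcomes.
    Cases with no recorded IOP enter only the ``overall`` outcome.
    """

    gender: str = "all"  # all | female | male
    outcome: str = "overall"  # overall | hpg | npg
    iop_cut: float = 22.0

    def __post_init__(self) -> None:
        if self.gender not in ("all", "female", "male"):
            raise ValueError(f"unknown gender filter {self.gender!r}")
        if self.outcome not in ("overall", "hpg", "npg"):
            raise ValueError(f"unknown outcome {self.outcome!r}")

    @property
    def includes_x(self) -> bool:
        """X-linked SNPs are analysed only in the female-only strata."""
        return self.gender == "female"

    @property
    def label(self) -> str:
        g = {"all": "all", "female": "females only", "male": "males only"}[self.gender]
        o = {"overall": "overall", "hpg": "HPG", "npg": "NPG"}[self.outcome]
        return f"{o}, {g}"
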