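"""Identity-by-descent (IBD) machinery for affected sib pairs.

A full sib pair shares 0, 1, or 2 alleles IBD at any autosomal locus with
prior probabilities (1/4, 1/2, 1/4).  Given marker genotypes for the pair
(and optionally the parents), the conditional IBD distribution is computed
exactly by enumerating the 16 equiprobable ordered transmission patterns of
the two parental meioses per sib; untyped parents are marginalized over
ordered parental genotypes with Hardy-Weinberg weights.

Allele indices are 0-based and contiguous internally; file I/O uses the
1-based LINKAGE convention with 0 denoting a missing genotype.
"""
from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Optional

import numpy as np

__all__ = [
    "AlleleFrequencySpec",
    "Genotype",
    "NuclearFamily",
    "IBDPrior",
    "IBDPosterior",
    "MendelianInconsistencyError",
    "prior_ibd_asp",
    "conditional_ibd_posterior",
    "ibd_count_fully_informative",
    "pic",
]


class MendelianInconsistencyError(ValueError):
    """Sib genotypes are impossible given the typed parental genotypes."""


@dataclass(frozen=True)
class AlleleFrequencySpec:
    """Population allele frequencies for a single marker.

    Frequencies must be strictly positive and sum to one; a marker needs at
    least two alleles to be informative.
    """

    frequencies: tuple[float, ...]

    def __post_init__(self) -> None:
        freqs = tuple(float(p) for p in self.frequencies)
        object.__setattr__(self, "frequencies", freqs)
        if len(freqs) < 2:
            raise ValueError("a marker needs at least 2 alleles")
        if any(p <= 0.0 for p in freqs):
            raise ValueError("allele frequencies must be strictly positive")
        if abs(sum(freqs) - 1.0) > 1e-12:
            raise ValueError("allele frequencies must sum to 1 (within 1e-12)")

    @classmethod
    def equifrequent(cls, k: int) -> "AlleleFrequencySpec":
        """k equally frequent alleles (the simulation-study marker models)."""
        if k < 2:
            raise ValueError("need k >= 2 alleles")
        return cls(tuple([1.0 / k] * k))

    @classmethod
    def parse(cls, text: str) -> "AlleleFrequencySpec":
        """Parse ``equal:k`` shorthand or a comma-separated frequency list."""
        text = text.strip()
        if text.startswith("equal:"):
            return cls.equifrequent(int(text.split(":", 1)[1]))
        return cls(tuple(float(tok) for tok in text.replace(",", " ").split()))

    @property
    def n_alleles(self) -> int:
        return len(self.frequencies)


@dataclass(frozen=True)
class Genotype:
    """An unordered pair of allele indices; (a, b) and (b, a) compare equal."""

    allele_a: int
    allele_b: int

    def __post_init__(self) -> None:
        a, b = int(self.allele_a), int(self.allele_b)
        if a < 0 or b < 0:
            raise ValueError("allele indices must be nonnegative")
        if a > b:
            a, b = b, a
        object.__setattr__(self, "allele_a", a)
        object.__setattr__(self, "allele_b", b)

    @property
    def alleles(self) -> tuple[int, int]:
        return (self.allele_a, self.allele_b)


@dataclass(frozen=True)
class NuclearFamily:
    """Two parents (possibly untyped) and two affected, always-typed sibs."""

    sib1_genotype: Genotype
    sib2_genotype: Genotype
    father_genotype: Optional[Genotype] = None
    mother_genotype: Optional[Genotype] = None
    sib1_covariate: Optional[float] = None
    sib2_covariate: Optional[float] = None


@dataclass(frozen=True)
class IBDPrior:
    """Prior probabilities that a relative pair shares 0/1/2 alleles IBD."""

    f0: float
    f1: float
    f2: float

    def __post_init__(self) -> None:
        v = (self.f0, self.f1, self.f2)
        if any(x < 0 for x in v):
            raise ValueError("prior IBD probabilities must be nonnegative")
        if abs(sum(v) - 1.0) > 1e-12:
            raise ValueError("prior IBD probabilities must sum to 1")

    def as_array(self) -> np.ndarray:
        return np.array([self.f0, self.f1, self.f2])


@dataclass(frozen=True)
class IBDPosterior:
    """Marker-conditional probabilities of sharing 0/1/2 alleles IBD."""

    g0: float
    g1: float
    g2: float

    def __post_init__(self) -> None:
        v = (self.g0, self.g1, self.g2)
        if any(x < -1e-12 for x in v):
            raise ValueError("posterior IBD probabilities must be nonnegative")
        if abs(sum(v) - 1.0) > 1e-10:
            raise ValueError("posterior IBD probabilities must sum to 1")

    def as_array(self) -> np.ndarray:
        return np.array([self.g0, self.g1, self.g2])


def prior_ibd_asp() -> IBDPrior:
    """Mendelian full-sib prior (1/4, 1/2, 1/4) on sharing 0/1/2 alleles IBD."""
    return IBDPrior(0.25, 0.5, 0.25)


# The 16 ordered transmission patterns: (a, b, c, d) picks the father's a-th
# and mother's b-th allele for sib 1, and c-th/d-th for sib 2; IBD count is
# (a == c) + (b == d).  Each pattern has probability 1/16.
_PATTERNS = [(a, b, c, d) for a in (0, 1) for b in (0, 1) for c in (0, 1) for d in (0, 1)]


def _tally_typed(
    father: tuple[int, int],
    mother: tuple[int, int],
    sib1: tuple[int, int],
    sib2: tuple[int, int],
) -> np.ndarray:
    """Unnormalized IBD tally (3,) over the 16 transmission patterns."""
    out = np.zeros(3)
    s1 = tuple(sorted(sib1))
    s2 = tuple(sorted(sib2))
    for a, b, c, d in _PATTERNS:
        g1 = tuple(sorted((father[a], mother[b])))
        g2 = tuple(sorted((father[c], mother[d])))
        if g1 == s1 and g2 == s2:
            out[(a == c) + (b == d)] += 1.0 / 16.0
    return out


def _genotype_index(lo: np.ndarray, hi: np.ndarray, k: int) -> np.ndarray:
    """Triangular index of an unordered genotype (lo <= hi), 0..k(k+1)/2-1."""
    return lo * (2 * k - lo + 1) // 2 + (hi - lo)


@lru_cache(maxsize=8)
def _untyped_joint_table(freqs: AlleleFrequencySpec) -> np.ndarray:
    """Joint P(sib1 genotype, sib2 genotype, IBD = i) with untyped parents.

    Built by exact enumeration: all ordered parental genotype pairs weighted
    by Hardy-Weinberg frequencies, times the 16 transmission patterns.
    Shape (3, G, G) with G = k(k+1)/2 unordered genotypes; summing over IBD
    and both genotype axes gives 1, and the IBD margin is (1/4, 1/2, 1/4).
    """
    p = np.asarray(freqs.frequencies)
    k = len(p)
    G = k * (k + 1) // 2
    idx = np.arange(k)
    f1, f2, m1, m2 = np.meshgrid(idx, idx, idx, idx, indexing="ij")
    w = (p[f1] * p[f2] * p[m1] * p[m2]).ravel() / 16.0
    parental = np.stack([f1.ravel(), f2.ravel(), m1.ravel(), m2.ravel()])
    table = np.zeros((3, G, G))
    for a, b, c, d in _PATTERNS:
        g1a, g1b = parental[a], parental[2 + b]
        g2a, g2b = parental[c], parental[2 + d]
        i1 = _genotype_index(np.minimum(g1a, g1b), np.maximum(g1a, g1b), k)
        i2 = _genotype_index(np.minimum(g2a, g2b), np.maximum(g2a, g2b), k)
        ibd = (a == c) + (b == d)
        np.add.at(table[ibd], (i1, i2), w)
    return table


def _check_alleles(freqs: AlleleFrequencySpec, *genotypes: Optional[Genotype]) -> None:
    k = freqs.n_alleles
    for g in genotypes:
        if g is not None and g.allele_b >= k:
            raise ValueError(f"allele index {g.allele_b} out of range for {k} alleles")


def conditional_ibd_posterior(
    family: NuclearFamily, freqs: AlleleFrequencySpec
) -> IBDPosterior:
    """Exact conditional IBD distribution of the sib pair given marker data.

    Both parents typed: enumerate the 16 equiprobable ordered transmission
    patterns and keep those reproducing both sib genotypes.  Both parents
    untyped: marginalize over ordered parental genotype pairs with
    Hardy-Weinberg weights.  One parent typed: marginalize the missing
    parent only.
    """
    s1, s2 = family.sib1_genotype, family.sib2_genotype
    if s1 is None or s2 is None:
        raise ValueError("both sib genotypes are required")
    _check_alleles(freqs, s1, s2, family.father_genotype, family.mother_genotype)

    father, mother = family.father_genotype, family.mother_genotype
    p = np.asarray(freqs.frequencies)
    k = len(p)

    if father is not None and mother is not None:
        tally = _tally_typed(father.alleles, mother.alleles, s1.alleles, s2.alleles)
        if tally.sum() == 0.0:
            raise MendelianInconsistencyError(
                "sib genotypes are inconsistent with the typed parents"
            )
    elif father is None and mother is None:
        table = _untyped_joint_table(freqs)
        i1 = _genotype_index(np.int64(s1.allele_a), np.int64(s1.allele_b), k)
        i2 = _genotype_index(np.int64(s2.allele_a), np.int64(s2.allele_b), k)
        tally = table[:, i1, i2]
    else:
        typed = (father or mother).alleles  # type: ignore[union-attr]
        father_typed = father is not None
        tally = np.zeros(3)
        for i in range(k):
            for j in range(k):
                other = (i, j)
                fa, mo = (typed, other) if father_typed else (other, typed)
                tally += p[i] * p[j] * _tally_typed(fa, mo, s1.alleles, s2.alleles)
        if tally.sum() == 0.0:
            raise MendelianInconsistencyError(
                "sib genotypes are inconsistent with the typed parent"
            )

    post = tally / tally.sum()
    return IBDPosterior(*post)


def ibd_count_fully_informative(family: NuclearFamily) -> int:
    """Observed IBD count when the four parental alleles are pairwise distinct.

    With unique founder alleles every transmission is unambiguous, so the
    conditional IBD distribution is an indicator on the true count: the
    number of parental alleles the two sibs share.
    """
    father, mother = family.father_genotype, family.mother_genotype
    if father is None or mother is None:
        raise ValueError("fully-informative counting requires typed parents")
    founder = father.alleles + mother.alleles
    if len(set(founder)) != 4:
        raise ValueError("parental alleles are not pairwise distinct")
    s1 = set(family.sib1_genotype.alleles)
    s2 = set(family.sib2_genotype.alleles)
    if not (s1 <= set(founder) and s2 <= set(founder)):
        raise MendelianInconsistencyError("sib alleles not found among parents")
    return len(s1 & s2)


def pic(freqs: AlleleFrequencySpec) -> float:
    """Polymorphism information content of a marker.

    PIC = 1 - sum_i p_i^2 - sum_i sum_{j>i} 2 p_i^2 p_j^2.  Equals 0.375 for
    a biallelic marker with equal frequencies and approaches 1 as the number
    of equally frequent alleles grows.
    """
    p = np.asarray(freqs.frequencies)
    p2 = p * p
    cross = (p2.sum() ** 2 - (p2 * p2).sum())  # 2 * sum_{j>i} p_i^2 p_j^2
    return float(1.0 - p2.sum() - cross)


# ---------------------------------------------------------------------------
# Vectorized batch posteriors used by the gene-dropping simulator.
# ---------------------------------------------------------------------------

def posterior_batch_untyped(
    sibs1: np.ndarray, sibs2: np.ndarray, freqs: AlleleFrequencySpec
) -> np.ndarray:
    """Posteriors (N, 3) for N sib pairs with untyped parents.

    ``sibs1``/``sibs2`` are (N, 2) allele-index arrays (order irrelevant).
    """
    k = freqs.n_alleles
    table = _untyped_joint_table(freqs)
    s1 = np.sort(np.asarray(sibs1), axis=1)
    s2 = np.sort(np.asarray(sibs2), axis=1)
    i1 = _genotype_index(s1[:, 0], s1[:, 1], k)
    i2 = _genotype_index(s2[:, 0], s2[:, 1], k)
    joint = table[:, i1, i2].T
    return joint / joint.sum(axis=1, keepdims=True)


def posterior_batch_typed(
    fathers: np.ndarray,
    mothers: np.ndarray,
    sibs1: np.ndarray,
    sibs2: np.ndarray,
) -> np.ndarray:
    """Posteriors (N, 3) for N sib pairs with both parents typed.

    Enumerates the 16 transmission patterns vectorized across families.
    Raises if any family is Mendelian-inconsistent.
    """
    fa = np.asarray(fathers)
    mo = np.asarray(mothers)
    s1 = np.sort(np.asarray(sibs1), axis=1)
    s2 = np.sort(np.asarray(sibs2), axis=1)
    n = fa.shape[0]
    tally = np.zeros((n, 3))
    for a, b, c, d in _PATTERNS:
        g1 = np.sort(np.stack([fa[:, a], mo[:, b]], axis=1), axis=1)
        g2 = np.sort(np.stack([fa[:, c], mo[:, d]], axis=1), axis=1)
        match = np.all(g1 == s1, axis=1) & np.all(g2 == s2, axis=1)
        tally[:, (a == c) + (b == d)] += match / 16.0
    total = tally.sum(axis=1)
    if np.any(total == 0.0):
        raise MendelianInconsistencyError(
            "sib genotypes inconsistent with typed parents in batch"
        )
    return tally / total[:, None]
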