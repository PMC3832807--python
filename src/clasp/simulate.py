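"""Gene-dropping simulation of the no-linkage null for affected sib pairs.

Families consist of two parents and two affected sibs.  Founder marker
genotypes are assigned (unique alleles per founder for a fully informative
marker, or Hardy-Weinberg draws for a k-allele equifrequent marker) and
alleles segregate to the sibs by independent fair meioses.  The marker is
unlinked to the trait, and pairs are ascertained as affected, so no
penetrance model is involved anywhere: the trait enters only through the
all-affected sampling design.

A replicate study repeatedly simulates a sample of families, computes IBD
posteriors, maximizes the LOD under a chosen analysis model, and collects
the maximized LODs into an empirical null distribution, from which
empirical p-values and critical LOD scores are read off by ranking.
"""
from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import ndtri

from .ibd import (
    AlleleFrequencySpec,
    Genotype,
    NuclearFamily,
    posterior_batch_typed,
    posterior_batch_untyped,
)
from .likelihood import (
    AnalysisModel,
    CovariateConvention,
    FitResult,
    ModelTag,
    maximize_lod_arrays,
)
from .mixtures import ChiSquareMixture, asymptotic_pvalue

__all__ = [
    "MarkerKind",
    "MarkerModel",
    "CovariateKind",
    "CovariateSpec",
    "ReplicateStudy",
    "EmpiricalNull",
    "simulate_family",
    "simulate_families",
    "simulate_pair_covariate",
    "run_null_replicates",
    "empirical_pvalues",
    "qq_table",
    "empirical_critical_lods",
]

_PRIOR = np.array([0.25, 0.5, 0.25])


class MarkerKind(enum.Enum):
    FULLY_INFORMATIVE = "fully-informative"
    EQUIFREQUENT = "equifrequent"


@dataclass(frozen=True)
class MarkerModel:
    """Marker informativeness design: unique founder alleles or k equal alleles."""

    kind: MarkerKind
    n_alleles: Optional[int] = None
    parents_typed: bool = True

    def __post_init__(self) -> None:
        if self.kind is MarkerKind.EQUIFREQUENT:
            if self.n_alleles is None or self.n_alleles < 2:
                raise ValueError("equifrequent markers need n_alleles >= 2")
        elif self.n_alleles is not None:
            raise ValueError("fully informative markers take no allele count")

    def frequencies(self) -> Optional[AlleleFrequencySpec]:
        if self.kind is MarkerKind.EQUIFREQUENT:
            return AlleleFrequencySpec.equifrequent(self.n_alleles)
        return None


class CovariateKind(enum.Enum):
    NONE = "none"
    CONTINUOUS_MEAN_CENTERED = "continuous"
    BINARY_MINIMUM_ADJUSTED = "binary"


@dataclass(frozen=True)
class CovariateSpec:
    """Pair covariate design: individual N(0,1) + effect, summed over sibs.

    Binary covariates dichotomize the individual value at the population
    quantile of its generating distribution so that the population
    prevalence equals ``prevalence``.  Under the null the effect offset is
    correlated only with (constant) affection status, so it shifts location
    only; the default is 0.
    """

    kind: CovariateKind = CovariateKind.NONE
    effect: float = 0.0
    prevalence: float = 0.2

    def __post_init__(self) -> None:
        if not (0.0 < self.prevalence < 1.0):
            raise ValueError("prevalence must be in (0, 1)")


@dataclass(frozen=True)
class ReplicateStudy:
    """A replicate design: who is simulated, how often, and under which model."""

    n_families: int
    n_replicates: int
    model: AnalysisModel
    marker: MarkerModel = MarkerModel(MarkerKind.FULLY_INFORMATIVE)
    covariate: CovariateSpec = CovariateSpec()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_families < 1 or self.n_replicates < 1:
            raise ValueError("family and replicate counts must be positive")
        needs_cov = self.model.n_covariates > 0
        has_cov = self.covariate.kind is not CovariateKind.NONE
        if needs_cov != has_cov:
            raise ValueError("covariate spec inconsistent with the analysis model")


@dataclass(frozen=True)
class EmpiricalNull:
    """Maximized LODs across replicates with rank-based empirical p-values."""

    lods: np.ndarray
    empirical_pvalues: np.ndarray
    converged: np.ndarray

    @property
    def n_replicates(self) -> int:
        return len(self.lods)


def _replicate_rng(seed: int, replicate: int) -> np.random.Generator:
    """Counter-based substream: replicate results are order-independent."""
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(replicate,)))


def _simulate_marker_batch(
    marker: MarkerModel, n: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Gene-drop n families; returns (father, mother, sib1, sib2, ibd).

    The segregation indicators are drawn before the founder genotypes, so
    runs with the same seed share the same true IBD pattern across marker
    models (common random numbers for informativeness comparisons).
    """
    pat = rng.integers(0, 2, size=(n, 2))  # paternal meiosis per sib
    mat = rng.integers(0, 2, size=(n, 2))
    if marker.kind is MarkerKind.FULLY_INFORMATIVE:
        father = np.tile([0, 1], (n, 1))
        mother = np.tile([2, 3], (n, 1))
    else:
        p = np.asarray(marker.frequencies().frequencies)
        k = len(p)
        draws = rng.choice(k, size=(n, 4), p=p)
        father, mother = draws[:, :2], draws[:, 2:]
    rows = np.arange(n)
    sib1 = np.stack([father[rows, pat[:, 0]], mother[rows, mat[:, 0]]], axis=1)
    sib2 = np.stack([father[rows, pat[:, 1]], mother[rows, mat[:, 1]]], axis=1)
    ibd = (pat[:, 0] == pat[:, 1]).astype(np.int64) + (mat[:, 0] == mat[:, 1])
    return father, mother, sib1, sib2, ibd


def simulate_family(
    marker: MarkerModel,
    freqs: Optional[AlleleFrequencySpec] = None,
    rng: Optional[np.random.Generator] = None,
) -> NuclearFamily:
    """Simulate one nuclear family under the null (marker unlinked).

    Parental genotypes are reported or masked according to
    ``marker.parents_typed``.  ``freqs`` is ignored for fully informative
    markers and, when given for an equifrequent marker, must match it.
    """
    return simulate_families(marker, 1, rng, freqs=freqs)[0]


def simulate_families(
    marker: MarkerModel,
    n: int,
    rng: Optional[np.random.Generator] = None,
    freqs: Optional[AlleleFrequencySpec] = None,
) -> list[NuclearFamily]:
    """Simulate n families as :class:`NuclearFamily` records."""
    if rng is None:
        rng = np.random.default_rng()
    if freqs is not None and marker.kind is MarkerKind.EQUIFREQUENT:
        if freqs != marker.frequencies():
            raise ValueError("freqs inconsistent with the marker model")
    father, mother, sib1, sib2, _ = _simulate_marker_batch(marker, n, rng)
    out = []
    for i in range(n):
        out.append(
            NuclearFamily(
                sib1_genotype=Genotype(*sib1[i]),
                sib2_genotype=Genotype(*sib2[i]),
                father_genotype=Genotype(*father[i]) if marker.parents_typed else None,
                mother_genotype=Genotype(*mother[i]) if marker.parents_typed else None,
            )
        )
    return out


def simulate_pair_covariate(
    spec: CovariateSpec, rng: np.random.Generator
) -> tuple[float, float, float]:
    """One pair's covariate draw: (sib1 value, sib2 value, unadjusted sum)."""
    v1, v2 = _simulate_covariates_batch(spec, 1, rng)[0]
    return float(v1), float(v2), float(v1 + v2)


def _simulate_covariates_batch(
    spec: CovariateSpec, n: int, rng: np.random.Generator
) -> np.ndarray:
    if spec.kind is CovariateKind.NONE:
        raise ValueError("no covariate is specified")
    vals = rng.normal(size=(n, 2)) + spec.effect
    if spec.kind is CovariateKind.BINARY_MINIMUM_ADJUSTED:
        threshold = spec.effect + ndtri(1.0 - spec.prevalence)
        vals = (vals > threshold).astype(float)
    return vals


def _adjust_pair_covariates(spec: CovariateSpec, pair_values: np.ndarray) -> np.ndarray:
    """Sample-level adjustment: mean-centering or minimum-adjustment."""
    if spec.kind is CovariateKind.CONTINUOUS_MEAN_CENTERED:
        return pair_values - pair_values.mean()
    return pair_values - pair_values.min()


def _posteriors_for_batch(
    marker: MarkerModel,
    father: np.ndarray,
    mother: np.ndarray,
    sib1: np.ndarray,
    sib2: np.ndarray,
    ibd: np.ndarray,
) -> np.ndarray:
    if marker.kind is MarkerKind.FULLY_INFORMATIVE:
        return np.eye(3)[ibd]
    if marker.parents_typed:
        return posterior_batch_typed(father, mother, sib1, sib2)
    return posterior_batch_untyped(sib1, sib2, marker.frequencies())


def run_null_replicates(study: ReplicateStudy) -> EmpiricalNull:
    """Run the replicate study; a pure function of the master seed.

    Each replicate simulates ``n_families`` families from its own counter-
    derived random substream, computes exact IBD posteriors, applies the
    sample-level covariate adjustment, and maximizes the LOD under the
    study's analysis model.  Fully informative no-covariate replicates are
    collapsed to IBD counts and fitted results are cached per count triple.
    """
    model = study.model
    marker = study.marker
    n = study.n_families
    lods = np.empty(study.n_replicates)
    converged = np.ones(study.n_replicates, dtype=bool)
    fast = (
        marker.kind is MarkerKind.FULLY_INFORMATIVE
        and study.covariate.kind is CovariateKind.NONE
    )
    cache: dict[tuple[int, int, int], FitResult] = {}
    eye = np.eye(3)
    F1 = _PRIOR[None, :]

    for r in range(study.n_replicates):
        rng = _replicate_rng(study.seed, r)
        father, mother, sib1, sib2, ibd = _simulate_marker_batch(marker, n, rng)
        if fast:
            counts = np.bincount(ibd, minlength=3)
            key = tuple(int(x) for x in counts)
            fit = cache.get(key)
            if fit is None:
                fit = maximize_lod_arrays(
                    eye, np.repeat(F1, 3, axis=0), np.empty((3, 0)), model,
                    weights=counts.astype(float),
                )
                cache[key] = fit
        else:
            G = _posteriors_for_batch(marker, father, mother, sib1, sib2, ibd)
            F = np.repeat(F1, n, axis=0)
            if study.covariate.kind is not CovariateKind.NONE:
                pair = _simulate_covariates_batch(study.covariate, n, rng).sum(axis=1)
                X = _adjust_pair_covariates(study.covariate, pair)[:, None]
            else:
                X = np.empty((n, 0))
            fit = maximize_lod_arrays(G, F, X, model)
        lods[r] = fit.lod
        converged[r] = fit.converged

    return EmpiricalNull(
        lods=lods, empirical_pvalues=empirical_pvalues(lods), converged=converged
    )


def empirical_pvalues(lods: Sequence[float]) -> np.ndarray:
    """Rank-based p-values: p = (r + 1) / (N + 1), r = 0 at the largest LOD.

    Ties are broken by input order (stable sort), so the maximum LOD always
    receives 1/(N+1) and N equal values receive the full ladder.
    """
    lods = np.asarray(lods, dtype=float)
    if lods.size == 0:
        raise ValueError("empty LOD list")
    order = np.argsort(-lods, kind="stable")
    p = np.empty(lods.size)
    p[order] = np.arange(1, lods.size + 1) / (lods.size + 1.0)
    return p


def qq_table(empirical: EmpiricalNull, mix: ChiSquareMixture) -> pd.DataFrame:
    """Per-replicate (lod, -log10 empirical p, -log10 asymptotic p), by LOD.

    Rows are sorted by decreasing LOD, matching the ranking that defines
    the empirical p-values.
    """
    order = np.argsort(-empirical.lods, kind="stable")
    lods = empirical.lods[order]
    p_emp = empirical.empirical_pvalues[order]
    p_asym = np.array([asymptotic_pvalue(l, mix) for l in lods])
    return pd.DataFrame(
        {
            "lod": lods,
            "neglog10_empirical_p": -np.log10(p_emp),
            "neglog10_asymptotic_p": -np.log10(p_asym),
        }
    )


def empirical_critical_lods(empirical: EmpiricalNull, alphas: Sequence[float]) -> list[float]:
    """Empirical critical LODs: largest empirical p-value not exceeding alpha.

    With p = k/(N+1) this is the floor(alpha (N+1))-th largest LOD.
    """
    N = empirical.n_replicates
    out = []
    lods_desc = np.sort(empirical.lods)[::-1]
    for alpha in alphas:
        k = int(np.floor(alpha * (N + 1) + 1e-12))
        if k < 1:
            raise ValueError(
                f"alpha={alpha} below the empirical resolution; the smallest "
                f"attainable level is {1.0 / (N + 1):g}"
            )
        out.append(float(lods_desc[k - 1]))
    return out
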