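"""Shared fixtures and oracles for the test suite."""
from __future__ import annotations

from itertools import product

import numpy as np
import pytest

from clasp.ibd import IBDPosterior, prior_ibd_asp
from clasp.likelihood import PairData

FULL_SIB_PRIOR = np.array([0.25, 0.5, 0.25])


def pairs_from_counts(n0: int, n1: int, n2: int) -> list[PairData]:
    """Fully informative sample as indicator-posterior pairs."""
    out = []
    for count, g in zip((n0, n1, n2), np.eye(3)):
        out.extend(PairData(IBDPosterior(*g)) for _ in range(count))
    return out


def multinomial_lod(n0: int, n1: int, n2: int) -> float:
    """Closed-form unconstrained maximum LOD for IBD counts.

    The unconstrained two-parameter model is a reparameterized multinomial,
    so the maximized LOD is sum_i n_i log10(z_i / f_i) at z = n / n.
    """
    counts = np.array([n0, n1, n2], dtype=float)
    z = counts / counts.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(counts > 0, counts * np.log10(z / FULL_SIB_PRIOR), 0.0)
    return float(terms.sum())


def brute_force_untyped_posterior(sib1, sib2, freqs) -> np.ndarray:
    """Independent enumeration oracle for untyped-parent sib-pair posteriors.

    Sums over all ordered parental genotype pairs (HWE weights) and the 16
    transmission patterns, written without reuse of the library internals.
    """
    p = np.asarray(freqs, dtype=float)
    k = len(p)
    tally = np.zeros(3)
    s1, s2 = tuple(sorted(sib1)), tuple(sorted(sib2))
    for f1, f2, m1, m2 in product(range(k), repeat=4):
        w = p[f1] * p[f2] * p[m1] * p[m2]
        for a, b, c, d in product((0, 1), repeat=4):
            g1 = tuple(sorted(((f1, f2)[a], (m1, m2)[b])))
            g2 = tuple(sorted(((f1, f2)[c], (m1, m2)[d])))
            if g1 == s1 and g2 == s2:
                tally[(a == c) + (b == d)] += w / 16.0
    return tally / tally.sum()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
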