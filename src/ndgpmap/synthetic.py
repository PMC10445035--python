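"""Synthetic ND GP maps: a fixed toy fixture and a seeded random generator.

These make every quantity, oracle and estimator testable without a folding
engine.  The random generator emulates the two gross features real GP maps
show: *bias* (phenotype frequencies spanning orders of magnitude, via
power-law phenotype weights) and tunable *determinism* (how peaked each
genotype's distribution is).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core import GenotypeSpace, NDGPMap, PhenotypeDistribution
from .errors import StateSpaceError

__all__ = ["toy_map_T1", "SyntheticMapSpec", "random_nd_map"]

#: Guard on K**L for the random generator.
MAX_GENERATED_GENOTYPES = 1_000_000


def toy_map_T1() -> NDGPMap:
    """The canonical 4-genotype toy ND map (K=2, L=2, two phenotypes).

    00 -> {A: 0.8, B: 0.2}, 01 -> {A: 0.6, B: 0.4}, 10 -> {A: 1.0},
    11 -> {B: 1.0}.  Every expected value used in the tests is derived from
    this map by the exact joint-realization oracle.
    """
    space = GenotypeSpace(("0", "1"), 2)
    table = {
        "00": PhenotypeDistribution({"A": 0.8, "B": 0.2}),
        "01": PhenotypeDistribution({"A": 0.6, "B": 0.4}),
        "10": PhenotypeDistribution({"A": 1.0}),
        "11": PhenotypeDistribution({"B": 1.0}),
    }
    return NDGPMap(space, table, complete=True)


@dataclass(frozen=True)
class SyntheticMapSpec:
    """Parameters of the random ND-map generator.

    Parameters
    ----------
    K, L
        Alphabet size and genotype length (alphabet is 0..K-1 as characters
        for K <= 10).
    n_phenotypes
        Size of the phenotype pool ("P00", "P01", ...).
    determinism
        Peakedness of per-genotype distributions.  Probabilities are a
        flat-Dirichlet draw raised to this power and renormalized: 0 gives
        uniform distributions, 1 a flat simplex draw, ``math.inf`` exact
        point masses.
    bias
        Power-law exponent of the phenotype weights (weight of the i-th
        phenotype ~ (i+1)**-bias).  Larger values skew the frequency
        distribution over orders of magnitude; 0 is unbiased.
    max_support
        Largest per-genotype support size (drawn uniformly in 1..max_support).
    seed
        Master seed; each genotype uses an independent substream keyed by
        its rank, so generation is order-independent.
    """

    K: int = 2
    L: int = 3
    n_phenotypes: int = 4
    determinism: float = 1.0
    bias: float = 1.0
    max_support: int = 3
    seed: int = 0


def _digits_alphabet(K: int) -> tuple[str, ...]:
    if K > 10:
        raise ValueError("synthetic generator supports K <= 10")
    return tuple(str(i) for i in range(K))


def random_nd_map(spec: SyntheticMapSpec) -> NDGPMap:
    """Seeded, reproducible random ND GP map over the full genotype space."""
    space = GenotypeSpace(_digits_alphabet(spec.K), spec.L)
    if space.size > MAX_GENERATED_GENOTYPES:
        raise StateSpaceError(
            f"K**L = {space.size} exceeds the generator guard {MAX_GENERATED_GENOTYPES}"
        )
    if spec.determinism < 0:
        raise ValueError("determinism must be >= 0")
    width = len(str(spec.n_phenotypes - 1))
    labels = [f"P{i:0{width}d}" for i in range(spec.n_phenotypes)]
    weights = np.array([(i + 1.0) ** -spec.bias for i in range(spec.n_phenotypes)])
    weights /= weights.sum()
    max_support = min(spec.max_support, spec.n_phenotypes)

    table = {}
    for rank in range(space.size):
        rng = np.random.default_rng(np.random.SeedSequence(spec.seed, spawn_key=(rank,)))
        m = int(rng.integers(1, max_support + 1))
        support = rng.choice(spec.n_phenotypes, size=m, replace=False, p=weights)
        if m == 1 or math.isinf(spec.determinism):
            # point mass on the most heavily weighted drawn phenotype
            chosen = min(support, key=lambda i: (-weights[i], i))
            probs = {labels[chosen]: 1.0}
        else:
            x = rng.dirichlet(np.ones(m))
            logits = spec.determinism * np.log(x)
            logits -= logits.max()
            w = np.exp(logits)
            w /= w.sum()
            # drop entries that underflow to numerical zero
            probs = {labels[i]: float(v) for i, v in zip(support, w) if v > 0.0}
            total = math.fsum(probs.values())
            probs = {p: v / total for p, v in probs.items()}
        table[space.unrank(rank)] = PhenotypeDistribution(probs, renormalize=True)
    return NDGPMap(space, table, complete=True)
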