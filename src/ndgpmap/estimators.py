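"""Sample-based estimation of ND quantities for large genotype spaces.

When the genotype space is too large to enumerate (e.g. 4**30 sequences),
quantities are estimated from a uniform i.i.d. sample of genotypes:

* frequencies:   f^_p = (1/n) sum_{g in sample} P(p|g)
* phenotypic robustness: the exact formula with both genotype sums taken
  over the sample and the neutral-set size K**L * f~_p replaced by n * f^_p
* genotypic quantities: evaluated exactly per sampled sequence (they only
  depend on the sequence's own neighbourhood, so no bias correction is
  needed)

Phenotypes absent from the sample cannot be estimated and are simply absent
from the output.  Phenotypic evolvability cannot be inferred reliably from
samples at all and is refused.

The ``fold`` argument is any callable mapping a genotype string to its
:class:`~ndgpmap.core.PhenotypeDistribution`; use :func:`fold_from_map` to
adapt a complete in-memory map, or an RNA backend ensemble function.
Neighbour lookups are routed through a per-run cache because sampled
sequences share neighbours.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd

from .core import GenotypeSpace, NDGPMap, PhenotypeDistribution
from .errors import SampledMapEstimationError

__all__ = [
    "SequenceSample",
    "draw_sequence_sample",
    "fold_from_map",
    "CachedFold",
    "estimate_nd_frequency",
    "estimate_nd_phenotype_robustness",
    "genotype_quantities_on_sample",
    "half_sample_diagnostic",
]

FoldFunction = Callable[[str], PhenotypeDistribution]


@dataclass(frozen=True)
class SequenceSample:
    """Genotypes drawn i.i.d. uniformly from a space (duplicates retained)."""

    space: GenotypeSpace
    sequences: tuple[str, ...]
    seed: int | None = None

    @property
    def n(self) -> int:
        return len(self.sequences)


def draw_sequence_sample(space: GenotypeSpace, n: int, seed: int) -> SequenceSample:
    """Uniform i.i.d. sample of ``n`` genotypes (with replacement)."""
    if n < 1:
        raise ValueError("sample size must be >= 1")
    rng = np.random.default_rng(seed)
    codes = rng.integers(0, space.K, size=(n, space.length))
    alphabet = np.array(space.alphabet)
    seqs = tuple("".join(row) for row in alphabet[codes])
    return SequenceSample(space, seqs, seed)


def exhaustive_sample(space: GenotypeSpace) -> SequenceSample:
    """The whole space as a sample (estimators then reduce to exact values)."""
    return SequenceSample(space, tuple(space.genotypes()), None)


def fold_from_map(nd: NDGPMap) -> FoldFunction:
    """Adapt a complete in-memory ND map as a fold function."""
    return nd.distribution


class CachedFold:
    """Memoizing wrapper around a fold function (results are identical with
    the cache on or off; it only avoids refolding shared neighbours)."""

    def __init__(self, fold: FoldFunction, enabled: bool = True):
        self._fold = fold
        self._enabled = enabled
        self._cache: dict[str, PhenotypeDistribution] = {}
        self.calls = 0
        self.misses = 0

    def __call__(self, genotype: str) -> PhenotypeDistribution:
        self.calls += 1
        if not self._enabled:
            self.misses += 1
            return self._fold(genotype)
        hit = self._cache.get(genotype)
        if hit is None:
            self.misses += 1
            hit = self._cache[genotype] = self._fold(genotype)
        return hit


def estimate_nd_frequency(sample: SequenceSample, fold: FoldFunction) -> pd.Series:
    """Sample estimate of the ND phenotypic frequencies.

    The estimates sum to 1 over the phenotypes present in the sample;
    phenotypes never seen are absent from the output.
    """
    totals: dict[str, float] = {}
    for g in sample.sequences:
        for p, w in fold(g).items():
            totals[p] = totals.get(p, 0.0) + w
    out = pd.Series(totals, name="f_p_hat").sort_index() / sample.n
    out.index.name = "phenotype"
    return out


def estimate_nd_phenotype_robustness(
    sample: SequenceSample,
    fold: FoldFunction,
    *,
    frequencies: pd.Series | None = None,
    use_cache: bool = True,
) -> pd.Series:
    """Sample estimate of the ND phenotypic robustness per phenotype.

    Both genotype sums run over the sample; the ND neutral-set size is
    ``n * f^_p`` with ``f^_p`` estimated from the same sample unless
    ``frequencies`` supplies external estimates (e.g. from a larger
    frequency-only sample).
    """
    fold = CachedFold(fold, use_cache)
    num: dict[str, float] = {}
    mass: dict[str, float] = {}
    nbrs = sample.space.neighbors_per_genotype
    for g in sample.sequences:
        dist = fold(g)
        nb_dists = [fold(nb) for nb in sample.space.neighbors(g)]
        for p, w in dist.items():
            s = math.fsum(nb[p] for nb in nb_dists)
            num[p] = num.get(p, 0.0) + w * s
            mass[p] = mass.get(p, 0.0) + w
    if frequencies is not None:
        denom = {p: sample.n * float(frequencies[p]) * nbrs for p in num if p in frequencies}
    else:
        denom = {p: mass[p] * nbrs for p in num}
    out = pd.Series(
        {p: num[p] / denom[p] for p in num if p in denom and denom[p] > 0},
        name="rho_p_nd_hat",
    ).sort_index()
    out.index.name = "phenotype"
    return out


def genotype_quantities_on_sample(
    sample: SequenceSample,
    fold: FoldFunction,
    *,
    include_deterministic: bool = True,
    use_cache: bool = True,
) -> pd.DataFrame:
    """Per-sequence genotypic quantities (one row per sampled sequence).

    Columns ``rho_g_nd`` and ``e_g_nd`` always; ``rho_g`` and ``e_g`` on the
    most-probable-phenotype projection when ``include_deterministic``.
    Duplicate sequences yield duplicate identical rows.
    """
    fold = CachedFold(fold, use_cache)
    nbrs = sample.space.neighbors_per_genotype
    rows = []
    for g in sample.sequences:
        dist = fold(g)
        nb_dists = [fold(nb) for nb in sample.space.neighbors(g)]
        # rho~_g
        rho_nd = (
            math.fsum(w * math.fsum(nb[p] for nb in nb_dists) for p, w in dist.items()) / nbrs
        )
        # e~_g via log-space products over the neighbourhood
        log_absent: dict[str, float] = {}
        for nb in nb_dists:
            for p2, w2 in nb.items():
                log_absent[p2] = log_absent.get(p2, 0.0) + (
                    -math.inf if w2 >= 1.0 else math.log1p(-w2)
                )
        reach = {p2: 1.0 - math.exp(s) for p2, s in log_absent.items()}
        total_reach = math.fsum(reach.values())
        e_nd = math.fsum(w * (total_reach - reach.get(p, 0.0)) for p, w in dist.items())
        row = {"genotype": g, "rho_g_nd": rho_nd, "e_g_nd": e_nd}
        if include_deterministic:
            p0 = dist.argmax()
            nb_phen = [nb.argmax() for nb in nb_dists]
            row["rho_g"] = sum(1 for p2 in nb_phen if p2 == p0) / nbrs
            row["e_g"] = len(set(nb_phen) - {p0})
        rows.append(row)
    return pd.DataFrame(rows)


def estimate_phenotype_evolvability(*args, **kwargs):
    """Refused: phenotypic evolvability cannot be estimated from samples."""
    raise SampledMapEstimationError(
        "phenotypic evolvability depends on the whole neutral set and cannot "
        "be inferred reliably from a random sequence sample"
    )


def half_sample_diagnostic(
    sample: SequenceSample, fold: FoldFunction, *, quantity: str = "frequency"
) -> pd.DataFrame:
    """Convergence diagnostic: first-half vs full-sample estimates.

    Reports, per phenotype, the full-sample estimate, the half-sample
    estimate and their relative difference.  Large relative differences flag
    phenotypes whose estimates have not converged at this sample size.
    """
    half = SequenceSample(sample.space, sample.sequences[: sample.n // 2], sample.seed)
    if quantity == "frequency":
        full_est = estimate_nd_frequency(sample, fold)
        half_est = estimate_nd_frequency(half, fold)
    elif quantity == "robustness":
        fold = CachedFold(fold, True)
        full_est = estimate_nd_phenotype_robustness(sample, fold)
        half_est = estimate_nd_phenotype_robustness(half, fold)
    else:
        raise ValueError(f"unknown quantity {quantity!r}")
    df = pd.DataFrame({"full": full_est, "half": half_est})
    df["rel_diff"] = (df["half"] - df["full"]).abs() / df["full"]
    return df
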