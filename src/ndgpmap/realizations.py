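"""Deterministic realizations of an ND GP map.

A *realization* draws one phenotype per genotype, independently, with
probability P(p|g), producing an ordinary deterministic map.  The ND
quantities are constructed to match averages of the deterministic
quantities over many realizations; this module provides

* :func:`sample_realization` -- one seeded realization,
* :func:`average_deterministic_quantities` -- streamed Monte-Carlo means
  and standard errors over ``n_samples`` realizations (the validation
  protocol, default 500 samples),
* :func:`exact_expectation_oracle` -- brute-force enumeration of *all*
  joint realizations for small maps, giving exact expectations.

Sampling uses one RNG substream per genotype, keyed by the genotype's rank
in the space, so results do not depend on iteration order.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import DGPMap, NDGPMap
from .errors import StateSpaceError

__all__ = [
    "sample_realization",
    "sample_realizations",
    "average_deterministic_quantities",
    "exact_expectation_oracle",
    "RealizationAverages",
    "ExactExpectations",
]

#: Enumeration guard for the exact oracle: product of support sizes.
ORACLE_STATE_GUARD = 1_000_000


def _support_arrays(nd: NDGPMap):
    """Sorted genotypes with sorted supports and probability vectors."""
    genotypes = sorted(nd.table, key=nd.space.rank)
    supports, probs = [], []
    for g in genotypes:
        dist = nd.table[g]
        sup = sorted(dist.support)
        supports.append(sup)
        probs.append(np.array([dist[p] for p in sup]))
    return genotypes, supports, probs


def _draw_choice_matrix(nd: NDGPMap, n_samples: int, seed: int):
    """(genotypes, supports, choices) with choices[i] an (n_samples,) index array."""
    genotypes, supports, probs = _support_arrays(nd)
    choices = []
    for g, sup, pr in zip(genotypes, supports, probs):
        rng = np.random.default_rng(
            np.random.SeedSequence(seed, spawn_key=(nd.space.rank(g),))
        )
        if len(sup) == 1:
            choices.append(np.zeros(n_samples, dtype=np.int64))
        else:
            choices.append(rng.choice(len(sup), size=n_samples, p=pr / pr.sum()))
    return genotypes, supports, choices


def sample_realization(nd: NDGPMap, seed: int) -> DGPMap:
    """Draw one deterministic realization of ``nd`` (reproducible per seed)."""
    genotypes, supports, choices = _draw_choice_matrix(nd, 1, seed)
    table = {g: sup[c[0]] for g, sup, c in zip(genotypes, supports, choices)}
    return DGPMap(nd.space, table, complete=nd.complete, validate=False)


def sample_realizations(nd: NDGPMap, n_samples: int, seed: int):
    """Yield ``n_samples`` seeded realizations (realization 0 equals
    ``sample_realization(nd, seed)``)."""
    genotypes, supports, choices = _draw_choice_matrix(nd, n_samples, seed)
    for r in range(n_samples):
        table = {g: sup[c[r]] for g, sup, c in zip(genotypes, supports, choices)}
        yield DGPMap(nd.space, table, complete=nd.complete, validate=False)


# ---------------------------------------------------------------------------
# per-realization deterministic quantities (single O(G * (K-1)L) pass)


def _realization_quantities(table: dict, space, complete: bool):
    """rho_g, e_g per genotype and f_p, rho_p, e_p per phenotype of one realization.

    Returns (rho, evo, f, rho_p, e_p, present) with per-phenotype entries as
    dicts keyed by phenotype (absent phenotypes omitted); e_p is None for
    incomplete maps.
    """
    nbrs = space.neighbors_per_genotype
    rho: dict[str, float] = {}
    evo: dict[str, int] = {}
    counts: dict[str, int] = {}
    rho_sum: dict[str, float] = {}
    reach: dict[str, set] = {}
    for g, p in table.items():
        same = 0
        others = set()
        for nb in space.neighbors(g):
            p2 = table[nb]
            if p2 == p:
                same += 1
            else:
                others.add(p2)
        rho[g] = same / nbrs
        evo[g] = len(others)
        counts[p] = counts.get(p, 0) + 1
        rho_sum[p] = rho_sum.get(p, 0.0) + rho[g]
        if complete:
            reach.setdefault(p, set()).update(others)
    denom = space.size if complete else len(table)
    f = {p: counts[p] / denom for p in counts}
    rho_p = {p: rho_sum[p] / counts[p] for p in counts}
    e_p = {p: len(reach.get(p, set())) for p in counts} if complete else None
    return rho, evo, f, rho_p, e_p


class _Welford:
    """Streaming mean/variance accumulator over named entities."""

    def __init__(self):
        self.n: dict = {}
        self.mean: dict = {}
        self.m2: dict = {}

    def add(self, key, value):
        n = self.n.get(key, 0) + 1
        mean = self.mean.get(key, 0.0)
        delta = value - mean
        mean += delta / n
        self.n[key] = n
        self.mean[key] = mean
        self.m2[key] = self.m2.get(key, 0.0) + delta * (value - mean)

    def stderr(self, key):
        n = self.n.get(key, 0)
        if n < 2:
            return np.nan
        return math.sqrt(self.m2[key] / (n - 1) / n)


@dataclass
class RealizationAverages:
    """Monte-Carlo means and standard errors of deterministic quantities.

    ``genotypes``: per-genotype mean/stderr of rho_g and e_g next to the ND
    values.  ``phenotypes``: per-phenotype mean/stderr of f_p (unconditional,
    0 when absent), and rho_p / e_p conditional on the phenotype appearing
    in a realization (``n_present`` reports how often it did).
    """

    genotypes: pd.DataFrame
    phenotypes: pd.DataFrame
    n_samples: int
    seed: int


def average_deterministic_quantities(
    nd: NDGPMap,
    n_samples: int = 500,
    seed: int = 0,
    *,
    conditional: bool = True,
    nd_reference: bool = True,
) -> RealizationAverages:
    """Average deterministic quantities over seeded realizations of ``nd``.

    Per-phenotype robustness/evolvability averages skip realizations where
    the phenotype is absent when ``conditional`` (the default); with
    ``conditional=False`` absent realizations contribute 0.
    """
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    if not nd.complete:
        raise StateSpaceError(
            "realization averaging requires a complete map; use the estimators "
            "module for sampled maps"
        )
    include_ep = nd.complete
    g_acc = {q: _Welford() for q in ("rho_g", "e_g")}
    p_acc = {q: _Welford() for q in ("f_p", "rho_p", "e_p")}
    universe = list(nd.phenotype_universe)
    for real in sample_realizations(nd, n_samples, seed):
        rho, evo, f, rho_p, e_p = _realization_quantities(real.table, nd.space, nd.complete)
        for g in real.table:
            g_acc["rho_g"].add(g, rho[g])
            g_acc["e_g"].add(g, evo[g])
        for p in universe:
            p_acc["f_p"].add(p, f.get(p, 0.0))
            if p in f:
                p_acc["rho_p"].add(p, rho_p[p])
                if include_ep:
                    p_acc["e_p"].add(p, e_p[p])
            elif not conditional:
                p_acc["rho_p"].add(p, 0.0)
                if include_ep:
                    p_acc["e_p"].add(p, 0.0)

    genotypes = sorted(nd.table, key=nd.space.rank)
    gdf = pd.DataFrame(
        {
            "rho_g_mean": [g_acc["rho_g"].mean[g] for g in genotypes],
            "rho_g_stderr": [g_acc["rho_g"].stderr(g) for g in genotypes],
            "e_g_mean": [g_acc["e_g"].mean[g] for g in genotypes],
            "e_g_stderr": [g_acc["e_g"].stderr(g) for g in genotypes],
        },
        index=pd.Index(genotypes, name="genotype"),
    )
    pdf = pd.DataFrame(
        {
            "f_p_mean": [p_acc["f_p"].mean[p] for p in universe],
            "f_p_stderr": [p_acc["f_p"].stderr(p) for p in universe],
            "rho_p_mean": [p_acc["rho_p"].mean.get(p, np.nan) for p in universe],
            "rho_p_stderr": [p_acc["rho_p"].stderr(p) for p in universe],
            "e_p_mean": [p_acc["e_p"].mean.get(p, np.nan) for p in universe],
            "e_p_stderr": [p_acc["e_p"].stderr(p) for p in universe],
            "n_present": [p_acc["rho_p"].n.get(p, 0) for p in universe],
        },
        index=pd.Index(universe, name="phenotype"),
    )
    if nd_reference:
        from .quantities import (
            nd_genotype_evolvability,
            nd_genotype_robustness,
            nd_phenotype_evolvability,
            nd_phenotype_frequency,
            nd_phenotype_robustness,
        )

        gdf["rho_g_nd"] = [nd_genotype_robustness(nd, g) for g in genotypes]
        gdf["e_g_nd"] = [nd_genotype_evolvability(nd, g) for g in genotypes]
        pdf["f_p_nd"] = [nd_phenotype_frequency(nd, p) for p in universe]
        pdf["rho_p_nd"] = [nd_phenotype_robustness(nd, p) for p in universe]
        pdf["e_p_nd"] = [
            nd_phenotype_evolvability(nd, p) if include_ep else np.nan for p in universe
        ]
    return RealizationAverages(gdf, pdf, n_samples, seed)


# ---------------------------------------------------------------------------
# exact oracle


@dataclass
class ExactExpectations:
    """Exact expectations of deterministic quantities over all joint realizations.

    ``genotypes``: E[rho_g], E[e_g].
    ``phenotypes``: E[f_p] (absent realizations count 0), presence
    probability, conditional E[rho_p | present] and E[e_p | present], plus
    the numerator/denominator decomposition whose ratio reproduces the ND
    phenotypic robustness: ``E_num`` = E[sum_{g in G_p} #neutral
    neighbours], ``E_den`` = E[|G_p|] * (K-1)L.
    """

    genotypes: pd.DataFrame
    phenotypes: pd.DataFrame
    n_states: int


def exact_expectation_oracle(nd: NDGPMap, *, guard: int = ORACLE_STATE_GUARD) -> ExactExpectations:
    """Enumerate every joint realization of ``nd`` with its probability.

    The state space is the product of per-genotype supports; maps beyond
    ``guard`` joint states are refused with a size estimate.
    """
    if not nd.complete:
        raise StateSpaceError("the exact oracle requires a complete map")
    genotypes, supports, probs = _support_arrays(nd)
    n_states = 1
    for sup in supports:
        n_states *= len(sup)
        if n_states > guard:
            raise StateSpaceError(
                f"joint realization space has at least {n_states} states "
                f"(> guard {guard})"
            )
    universe = list(nd.phenotype_universe)
    space = nd.space
    nbrs = space.neighbors_per_genotype
    idx = {g: i for i, g in enumerate(genotypes)}
    neighbor_idx = [[idx[nb] for nb in space.neighbors(g) if nb in idx] for g in genotypes]
    complete = nd.complete

    e_rho = np.zeros(len(genotypes))
    e_evo = np.zeros(len(genotypes))
    e_f = {p: 0.0 for p in universe}
    pres = {p: 0.0 for p in universe}
    e_rho_p = {p: 0.0 for p in universe}
    e_e_p = {p: 0.0 for p in universe}
    e_num = {p: 0.0 for p in universe}
    denom = space.size if complete else len(genotypes)

    for assignment in itertools.product(*(range(len(s)) for s in supports)):
        weight = 1.0
        phen = []
        for i, c in enumerate(assignment):
            weight *= probs[i][c]
            phen.append(supports[i][c])
        counts: dict[str, int] = {}
        rho_sum: dict[str, float] = {}
        neutral_pairs: dict[str, int] = {}
        reach: dict[str, set] = {}
        for i, p in enumerate(phen):
            same = 0
            others = set()
            for j in neighbor_idx[i]:
                if phen[j] == p:
                    same += 1
                else:
                    others.add(phen[j])
            rho = same / nbrs
            e_rho[i] += weight * rho
            e_evo[i] += weight * len(others)
            counts[p] = counts.get(p, 0) + 1
            rho_sum[p] = rho_sum.get(p, 0.0) + rho
            neutral_pairs[p] = neutral_pairs.get(p, 0) + same
            reach.setdefault(p, set()).update(others)
        for p, c in counts.items():
            e_f[p] += weight * c / denom
            pres[p] += weight
            e_rho_p[p] += weight * rho_sum[p] / c
            e_e_p[p] += weight * len(reach[p])
            e_num[p] += weight * neutral_pairs[p]

    gdf = pd.DataFrame(
        {"E_rho_g": e_rho, "E_e_g": e_evo},
        index=pd.Index(genotypes, name="genotype"),
    )
    e_den = {p: denom * e_f[p] * nbrs for p in universe}
    pdf = pd.DataFrame(
        {
            "E_f_p": [e_f[p] for p in universe],
            "presence_probability": [pres[p] for p in universe],
            "E_rho_p_given_present": [
                e_rho_p[p] / pres[p] if pres[p] > 0 else np.nan for p in universe
            ],
            "E_e_p_given_present": [
                e_e_p[p] / pres[p] if pres[p] > 0 else np.nan for p in universe
            ],
            "E_num": [e_num[p] for p in universe],
            "E_den": [e_den[p] for p in universe],
            "num_over_den": [
                e_num[p] / e_den[p] if e_den[p] > 0 else np.nan for p in universe
            ],
        },
        index=pd.Index(universe, name="phenotype"),
    )
    return ExactExpectations(gdf, pdf, n_states)
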