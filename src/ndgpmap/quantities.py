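"""Robustness, evolvability and frequency statistics for GP maps.

Deterministic quantities (on a many-to-one map, phenotype set of size N):

* ``f_p``   -- phenotypic frequency, |G_p| / K**L
* ``rho_g`` -- genotypic robustness, fraction of the (K-1)L point-mutation
  neighbours with the same phenotype
* ``rho_p`` -- phenotypic robustness, mean of rho_g over the neutral set G_p
* ``e_g``   -- genotypic evolvability, number of distinct other phenotypes in
  the neighbourhood of g
* ``e_p``   -- phenotypic evolvability, number of distinct other phenotypes in
  the neighbourhood of the whole neutral set

Non-deterministic counterparts (on a many-to-many map with per-genotype
distributions P(p|g), phenotype universe of size N-tilde) replace the 0/1
indicators with probabilities and are constructed so that they match
averages of the deterministic quantities over independent realizations of
the map:

* ``f~_p    = (1/K**L) * sum_g P(p|g)``                       (exactly E[f_p])
* ``rho~_g  = (1/(K-1)L) * sum_p P(p|g) * sum_{g' in N_g} P(p|g')``
  (exactly E[rho_g])
* ``rho~_p  = [sum_g P(p|g) sum_{g'} P(p|g')] / [K**L f~_p (K-1)L]``
  (a ratio of exact expectations, E[numerator]/E[neutral-set size x (K-1)L];
  close to, but not identical to, the mean of per-realization rho_p)
* ``e~_g    = sum_p P(p|g) sum_{p' != p} (1 - prod_{g'} (1 - P(p'|g')))``
  (exactly E[e_g])
* ``e~_p    = sum_{p' != p} (1 - prod_{g in G~_p} prod_{g'} (1 - P(p'|g') P(p|g)))``
  (approximates E[e_p]; the per-pair events are treated as independent)

The sums over p' run over the observed phenotype universe of the map at
hand; unobserved phenotypes would contribute 0.  Long products of (1 - x)
are accumulated in log space via log1p and short-circuit at exactly 0.

Phenotypic evolvability (both variants) requires a complete map: it cannot
be estimated from a genotype sample.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import DGPMap, NDGPMap, project_deterministic
from .errors import (
    InvalidGenotypeError,
    SampledMapEstimationError,
    UndefinedQuantityError,
)

__all__ = [
    "nd_phenotype_frequency",
    "det_phenotype_frequency",
    "det_genotype_robustness",
    "nd_genotype_robustness",
    "det_phenotype_robustness",
    "nd_phenotype_robustness",
    "det_genotype_evolvability",
    "nd_genotype_evolvability",
    "det_phenotype_evolvability",
    "nd_phenotype_evolvability",
    "null_model_robustness",
    "QuantityTable",
    "compute_quantity_table",
]


def _one_minus_product(log_terms_done: float) -> float:
    # log_terms_done = sum of log1p(-x); -inf short-circuits to probability 1
    return 1.0 - math.exp(log_terms_done)


def _log1m(x: float) -> float:
    """log(1 - x) for x in [0, 1], -inf at x = 1."""
    if x >= 1.0:
        return -math.inf
    return math.log1p(-x)


# ---------------------------------------------------------------------------
# frequencies


def nd_phenotype_frequency(nd: NDGPMap, phenotype: str, *, strict: bool = False) -> float:
    """ND phenotypic frequency f~_p = (1/K**L) sum_g P(p|g).

    For a complete map the denominator is K**L; for a declared sample it is
    the sample size (the estimator convention).
    """
    total = math.fsum(dist[phenotype] for dist in nd.table.values())
    if total == 0.0 and strict:
        raise UndefinedQuantityError(f"phenotype {phenotype!r} not present in map")
    denom = nd.space.size if nd.complete else len(nd.table)
    return total / denom


def det_phenotype_frequency(d: DGPMap, phenotype: str) -> float:
    """Deterministic phenotypic frequency f_p = |G_p| / K**L."""
    count = sum(1 for p in d.table.values() if p == phenotype)
    denom = d.space.size if d.complete else len(d.table)
    return count / denom


# ---------------------------------------------------------------------------
# genotypic robustness


def _neighbor_entries(map_table, space, genotype, allow_partial: bool):
    """Yield mapped neighbours; raise on unmapped ones unless allowed."""
    entries = []
    for nb in space.neighbors(genotype):
        if nb in map_table:
            entries.append(nb)
        elif not allow_partial:
            raise InvalidGenotypeError(
                f"neighbour {nb!r} of {genotype!r} is not mapped; pass "
                "allow_partial_neighborhood=True to average over mapped neighbours only"
            )
    return entries


def det_genotype_robustness(
    d: DGPMap, genotype: str, *, allow_partial_neighborhood: bool = False
) -> float:
    """rho_g: fraction of point-mutation neighbours with the same phenotype."""
    p = d.phenotype(genotype)
    nbs = _neighbor_entries(d.table, d.space, genotype, allow_partial_neighborhood)
    denom = len(nbs) if allow_partial_neighborhood else d.space.neighbors_per_genotype
    if denom == 0:
        raise UndefinedQuantityError(f"genotype {genotype!r} has no mapped neighbours")
    return sum(1 for nb in nbs if d.table[nb] == p) / denom


def nd_genotype_robustness(
    nd: NDGPMap, genotype: str, *, allow_partial_neighborhood: bool = False
) -> float:
    """rho~_g = (1/(K-1)L) sum_p P(p|g) sum_{g' in N_g} P(p|g')."""
    dist = nd.distribution(genotype)
    nbs = _neighbor_entries(nd.table, nd.space, genotype, allow_partial_neighborhood)
    denom = len(nbs) if allow_partial_neighborhood else nd.space.neighbors_per_genotype
    if denom == 0:
        raise UndefinedQuantityError(f"genotype {genotype!r} has no mapped neighbours")
    total = 0.0
    for p, w in dist.items():
        total += w * math.fsum(nd.table[nb][p] for nb in nbs)
    return total / denom


# ---------------------------------------------------------------------------
# phenotypic robustness


def det_phenotype_robustness(
    d: DGPMap, phenotype: str, *, allow_partial_neighborhood: bool = False
) -> float:
    """rho_p: mean genotypic robustness over the neutral set G_p."""
    neutral = d.neutral_set(phenotype)
    if not neutral:
        raise UndefinedQuantityError(f"phenotype {phenotype!r} has an empty neutral set")
    return math.fsum(
        det_genotype_robustness(d, g, allow_partial_neighborhood=allow_partial_neighborhood)
        for g in neutral
    ) / len(neutral)


def nd_phenotype_robustness(
    nd: NDGPMap, phenotype: str, *, allow_partial_neighborhood: bool = False
) -> float:
    """rho~_p: ND robustness summed over G~_p, normalized by the ND neutral-set size.

    Numerator and denominator are each exact expectations over realizations:
    E[sum_{g in G_p} #neutral neighbours] / E[|G_p| * (K-1)L].
    """
    mass = math.fsum(dist[phenotype] for dist in nd.table.values())
    if mass == 0.0:
        raise UndefinedQuantityError(f"phenotype {phenotype!r} has zero ND frequency")
    terms = []
    weights = []
    for g, dist in nd.table.items():
        w = dist[phenotype]
        if w == 0.0:
            continue
        nbs = _neighbor_entries(nd.table, nd.space, g, allow_partial_neighborhood)
        denom_g = len(nbs) if allow_partial_neighborhood else nd.space.neighbors_per_genotype
        if denom_g == 0:
            raise UndefinedQuantityError(f"genotype {g!r} has no mapped neighbours")
        terms.append(w * math.fsum(nd.table[nb][phenotype] for nb in nbs) / denom_g)
        weights.append(w)
    # the terms carry the per-genotype 1/(K-1)L; divide by the ND neutral-set
    # size (exactly-rounded sums so the point-mass case reduces bit-exactly)
    return math.fsum(terms) / math.fsum(weights)


# ---------------------------------------------------------------------------
# genotypic evolvability


def det_genotype_evolvability(
    d: DGPMap, genotype: str, *, allow_partial_neighborhood: bool = False
) -> int:
    """e_g: number of distinct phenotypes other than p(g) among the neighbours."""
    p = d.phenotype(genotype)
    nbs = _neighbor_entries(d.table, d.space, genotype, allow_partial_neighborhood)
    return len({d.table[nb] for nb in nbs} - {p})


def nd_genotype_evolvability(
    nd: NDGPMap, genotype: str, *, allow_partial_neighborhood: bool = False
) -> float:
    """e~_g: expected number of distinct other phenotypes in the neighbourhood,
    averaged over the phenotype g itself realizes."""
    dist = nd.distribution(genotype)
    nbs = _neighbor_entries(nd.table, nd.space, genotype, allow_partial_neighborhood)
    # log prod_{g'} (1 - P(p'|g')) for every phenotype seen in the neighbourhood
    log_absent: dict[str, float] = {}
    for nb in nbs:
        for p2, w2 in nd.table[nb].items():
            log_absent[p2] = log_absent.get(p2, 0.0) + _log1m(w2)
    total_reach = math.fsum(_one_minus_product(s) for s in log_absent.values())
    out = 0.0
    for p, w in dist.items():
        own = _one_minus_product(log_absent[p]) if p in log_absent else 0.0
        out += w * (total_reach - own)
    return out


# ---------------------------------------------------------------------------
# phenotypic evolvability (complete maps only)


def _require_complete(gpmap, what: str):
    if not gpmap.complete:
        raise SampledMapEstimationError(
            f"{what} requires a complete map over the genotype space; "
            "it cannot be inferred reliably from a genotype sample"
        )


def det_phenotype_evolvability(d: DGPMap, phenotype: str) -> int:
    """e_p: distinct phenotypes != p adjacent to any genotype of the neutral set."""
    _require_complete(d, "deterministic phenotypic evolvability")
    neutral = d.neutral_set(phenotype)
    if not neutral:
        raise UndefinedQuantityError(f"phenotype {phenotype!r} has an empty neutral set")
    seen: set[str] = set()
    for g in neutral:
        for nb in d.space.neighbors(g):
            seen.add(d.table[nb])
    seen.discard(phenotype)
    return len(seen)


def nd_phenotype_evolvability(nd: NDGPMap, phenotype: str) -> float:
    """e~_p: expected number of other phenotypes accessible from the ND neutral set.

    Per alternative phenotype p', accumulates
    sum_{g in G~_p} sum_{g' in N_g} log(1 - P(p'|g') P(p|g)) in log space.
    """
    _require_complete(nd, "ND phenotypic evolvability")
    log_terms: dict[str, float] = {}
    any_member = False
    for g, dist in nd.table.items():
        w = dist[phenotype]
        if w == 0.0:
            continue
        any_member = True
        for nb in nd.space.neighbors(g):
            for p2, w2 in nd.table[nb].items():
                log_terms[p2] = log_terms.get(p2, 0.0) + _log1m(w * w2)
    if not any_member:
        raise UndefinedQuantityError(f"phenotype {phenotype!r} has an empty ND neutral set")
    return math.fsum(
        _one_minus_product(s) for p2, s in log_terms.items() if p2 != phenotype
    )


# ---------------------------------------------------------------------------
# null model


def null_model_robustness(nd_frequency: float) -> float:
    """Null-model ND phenotypic robustness for a random phenotype placement.

    With phenotypes assigned at random, the chance a neighbour carries p is
    just the frequency, so the null expectation is rho~_p = f~_p.
    """
    if not 0.0 < nd_frequency <= 1.0:
        raise UndefinedQuantityError(f"frequency {nd_frequency!r} outside (0, 1]")
    return nd_frequency


# ---------------------------------------------------------------------------
# tables

GENOTYPE_COLUMNS = ["rho_g", "rho_g_nd", "e_g", "e_g_nd"]
PHENOTYPE_COLUMNS = [
    "f_p",
    "f_p_nd",
    "rho_p",
    "rho_p_nd",
    "e_p",
    "e_p_nd",
    "e_p_norm",
    "e_p_nd_norm",
]


@dataclass
class QuantityTable:
    """Per-genotype and per-phenotype quantities of a (paired ND/D) GP map.

    ``genotypes``:  index genotype; columns rho_g, rho_g_nd, e_g, e_g_nd.
    ``phenotypes``: index phenotype; columns f_p, f_p_nd, rho_p, rho_p_nd,
    e_p, e_p_nd, e_p_norm, e_p_nd_norm.  Deterministic columns are NaN for
    phenotypes absent from the deterministic projection (they are missing,
    not zero); evolvability columns are NaN for maps where phenotypic
    evolvability is unavailable (sampled maps).
    """

    genotypes: pd.DataFrame
    phenotypes: pd.DataFrame
    n_deterministic: int
    n_nd: int

    def to_tsv(self, genotype_path=None, phenotype_path=None) -> None:
        if genotype_path is not None:
            self.genotypes.to_csv(genotype_path, sep="\t", index_label="genotype")
        if phenotype_path is not None:
            self.phenotypes.to_csv(phenotype_path, sep="\t", index_label="phenotype")


def compute_quantity_table(
    nd: NDGPMap,
    d: DGPMap | None = None,
    *,
    method: str = "auto",
    include_phenotype_evolvability: bool | None = None,
) -> QuantityTable:
    """All quantities for an ND map and its deterministic companion.

    Parameters
    ----------
    nd
        The ND map (must be complete for phenotypic evolvability).
    d
        Deterministic companion; the most-probable projection by default.
    method
        ``"reference"`` uses the per-entity pure-Python formulas;
        ``"fast"`` the vectorized full-map engine; ``"auto"`` picks the fast
        engine for complete maps beyond ~2000 genotypes.
    """
    if d is None:
        d = project_deterministic(nd)
    if include_phenotype_evolvability is None:
        include_phenotype_evolvability = nd.complete
    if method == "auto":
        method = "fast" if (nd.complete and len(nd) > 2000) else "reference"
    if method == "fast":
        from .fast import fast_quantity_table

        return fast_quantity_table(
            nd, d, include_phenotype_evolvability=include_phenotype_evolvability
        )
    if method != "reference":
        raise ValueError(f"unknown method {method!r}")

    genotypes = sorted(nd.table)
    grows = {
        "rho_g": [det_genotype_robustness(d, g) for g in genotypes],
        "rho_g_nd": [nd_genotype_robustness(nd, g) for g in genotypes],
        "e_g": [det_genotype_evolvability(d, g) for g in genotypes],
        "e_g_nd": [nd_genotype_evolvability(nd, g) for g in genotypes],
    }
    gdf = pd.DataFrame(grows, index=pd.Index(genotypes, name="genotype"))

    universe = list(nd.phenotype_universe)
    det_set = set(d.phenotypes)
    n_det, n_nd = len(det_set), len(universe)
    prows = []
    for p in universe:
        in_det = p in det_set
        row = {
            "f_p": det_phenotype_frequency(d, p) if in_det else np.nan,
            "f_p_nd": nd_phenotype_frequency(nd, p),
            "rho_p": det_phenotype_robustness(d, p) if in_det else np.nan,
            "rho_p_nd": nd_phenotype_robustness(nd, p),
        }
        if include_phenotype_evolvability:
            row["e_p"] = det_phenotype_evolvability(d, p) if in_det else np.nan
            row["e_p_nd"] = nd_phenotype_evolvability(nd, p)
        else:
            row["e_p"] = np.nan
            row["e_p_nd"] = np.nan
        prows.append(row)
    pdf = pd.DataFrame(prows, index=pd.Index(universe, name="phenotype"))
    # normalized evolvabilities use each map's own phenotype count (e_p/N, e~_p/N~)
    pdf["e_p_norm"] = pdf["e_p"] / n_det
    pdf["e_p_nd_norm"] = pdf["e_p_nd"] / n_nd
    return QuantityTable(gdf, pdf[PHENOTYPE_COLUMNS], n_det, n_nd)
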