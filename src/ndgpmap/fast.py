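"""Array engine for complete GP maps (compiled inner loops).

Complete maps over a full genotype space admit a compact representation:
genotypes are integer ranks, per-genotype distributions live in one
CSR-like triple ``(indptr, phenotype_idx, prob)`` and point-mutation
neighbours are computed arithmetically from the rank.  A single compiled
pass then accumulates every genotypic and phenotypic quantity, including
the pairwise log-product matrix behind the ND phenotypic evolvability.

Deterministic quantities are obtained by running the same kernel on the
point-mass representation of the projected map: on point masses every ND
quantity reduces exactly to its deterministic counterpart (products of 0/1
stay exact in floating point), so no second code path is needed.  The
dict-based reference implementations in :mod:`ndgpmap.quantities` remain
the independent formulation; the test suite pins this engine against them.
"""

from __future__ import annotations

import math

import numba
import numpy as np
import pandas as pd

from .core import DGPMap, NDGPMap, project_deterministic
from .errors import StateSpaceError

__all__ = ["fast_quantity_table", "nd_to_csr"]


def nd_to_csr(nd: NDGPMap):
    """(phenotypes, indptr, idx, prob) in genotype-rank order; complete maps only."""
    if not nd.complete:
        raise StateSpaceError("the array engine requires a complete map")
    space = nd.space
    phenotypes = list(nd.phenotype_universe)
    pindex = {p: i for i, p in enumerate(phenotypes)}
    nnz = sum(len(dist) for dist in nd.table.values())
    indptr = np.zeros(space.size + 1, dtype=np.int64)
    idx = np.empty(nnz, dtype=np.int64)
    prob = np.empty(nnz, dtype=np.float64)
    k = 0
    for rank in range(space.size):
        dist = nd.table[space.unrank(rank)]
        for p, w in sorted(dist.items()):
            idx[k] = pindex[p]
            prob[k] = w
            k += 1
        indptr[rank + 1] = k
    return phenotypes, indptr, idx, prob


def d_to_csr(d: DGPMap):
    """Point-mass CSR of a deterministic map, over its own phenotype list."""
    space = d.space
    phenotypes = list(d.phenotypes)
    pindex = {p: i for i, p in enumerate(phenotypes)}
    indptr = np.arange(space.size + 1, dtype=np.int64)
    idx = np.empty(space.size, dtype=np.int64)
    for rank in range(space.size):
        idx[rank] = pindex[d.table[space.unrank(rank)]]
    prob = np.ones(space.size, dtype=np.float64)
    return phenotypes, indptr, idx, prob


@numba.njit(cache=True)
def _full_map_kernel(K, L, indptr, idx, prob, n_phen, compute_pair):  # pragma: no cover
    size = indptr.shape[0] - 1
    nbrs = (K - 1) * L
    powK = np.empty(L, dtype=np.int64)
    acc = 1
    for pos in range(L):
        powK[pos] = acc
        acc *= K
    nbr_ranks = np.empty(nbrs, dtype=np.int64)

    freq_mass = np.zeros(n_phen)
    num_p = np.zeros(n_phen)
    rho_g = np.zeros(size)
    evo_g = np.zeros(size)
    if compute_pair:
        logC = np.zeros((n_phen, n_phen))
    else:
        logC = np.zeros((1, 1))

    S = np.zeros(n_phen)  # sum of neighbour probabilities per phenotype
    lq = np.zeros(n_phen)  # sum of log(1 - neighbour probability) per phenotype
    seen = np.zeros(n_phen, dtype=np.uint8)
    touched = np.empty(n_phen, dtype=np.int64)

    for g in range(size):
        t = 0
        for pos in range(L):
            digit = (g // powK[pos]) % K
            for b in range(K):
                if b != digit:
                    nbr_ranks[t] = g + (b - digit) * powK[pos]
                    t += 1
        ntouch = 0
        for j in range(nbrs):
            gp = nbr_ranks[j]
            for k in range(indptr[gp], indptr[gp + 1]):
                p2 = idx[k]
                w2 = prob[k]
                if seen[p2] == 0:
                    seen[p2] = 1
                    touched[ntouch] = p2
                    ntouch += 1
                S[p2] += w2
                if w2 >= 1.0:
                    lq[p2] = -np.inf
                else:
                    lq[p2] += math.log1p(-w2)
        total_reach = 0.0
        for m in range(ntouch):
            total_reach += 1.0 - math.exp(lq[touched[m]])
        rho = 0.0
        evo = 0.0
        for k in range(indptr[g], indptr[g + 1]):
            p = idx[k]
            w = prob[k]
            rho += w * S[p]
            own = 1.0 - math.exp(lq[p])  # untouched phenotypes have lq 0 -> own 0
            evo += w * (total_reach - own)
            num_p[p] += w * S[p]
            freq_mass[p] += w
        rho_g[g] = rho / nbrs
        evo_g[g] = evo
        if compute_pair:
            for j in range(nbrs):
                gp = nbr_ranks[j]
                for k in range(indptr[g], indptr[g + 1]):
                    p = idx[k]
                    w = prob[k]
                    for k2 in range(indptr[gp], indptr[gp + 1]):
                        x = w * prob[k2]
                        if x >= 1.0:
                            logC[p, idx[k2]] = -np.inf
                        else:
                            logC[p, idx[k2]] += math.log1p(-x)
        for m in range(ntouch):
            p2 = touched[m]
            S[p2] = 0.0
            lq[p2] = 0.0
            seen[p2] = 0
    return freq_mass, rho_g, evo_g, num_p, logC


def _run(space, phenotypes, indptr, idx, prob, compute_pair):
    freq_mass, rho_g, evo_g, num_p, logC = _full_map_kernel(
        space.K, space.length, indptr, idx, prob, len(phenotypes), compute_pair
    )
    f = freq_mass / space.size
    nbrs = space.neighbors_per_genotype
    with np.errstate(invalid="ignore", divide="ignore"):
        rho_p = np.where(freq_mass > 0, num_p / (freq_mass * nbrs), np.nan)
    e_p = None
    if compute_pair:
        reach = 1.0 - np.exp(logC)
        np.fill_diagonal(reach, 0.0)
        e_p = reach.sum(axis=1)
    return f, rho_g, evo_g, rho_p, e_p


def fast_quantity_table(
    nd: NDGPMap,
    d: DGPMap | None = None,
    *,
    include_phenotype_evolvability: bool = True,
):
    """Full :class:`~ndgpmap.quantities.QuantityTable` via the array engine."""
    from .quantities import PHENOTYPE_COLUMNS, QuantityTable

    if d is None:
        d = project_deterministic(nd)
    space = nd.space
    nd_phen, indptr, idx, prob = nd_to_csr(nd)
    f_nd, rho_g_nd, e_g_nd, rho_p_nd, e_p_nd = _run(
        space, nd_phen, indptr, idx, prob, include_phenotype_evolvability
    )
    d_phen, dindptr, didx, dprob = d_to_csr(d)
    f_d, rho_g_d, e_g_d, rho_p_d, e_p_d = _run(
        space, d_phen, dindptr, didx, dprob, include_phenotype_evolvability
    )

    genotypes = [space.unrank(r) for r in range(space.size)]
    gdf = pd.DataFrame(
        {
            "rho_g": rho_g_d,
            "rho_g_nd": rho_g_nd,
            "e_g": np.rint(e_g_d).astype(np.int64),
            "e_g_nd": e_g_nd,
        },
        index=pd.Index(genotypes, name="genotype"),
    )
    det_pos = {p: i for i, p in enumerate(d_phen)}
    n_det, n_nd = len(d_phen), len(nd_phen)

    def det_col(values, as_int=False):
        out = np.full(n_nd, np.nan)
        for i, p in enumerate(nd_phen):
            j = det_pos.get(p)
            if j is not None and values is not None:
                out[i] = values[j]
        if as_int:
            out = np.where(np.isnan(out), np.nan, np.rint(out))
        return out

    pdf = pd.DataFrame(
        {
            "f_p": det_col(f_d),
            "f_p_nd": f_nd,
            "rho_p": det_col(rho_p_d),
            "rho_p_nd": rho_p_nd,
            "e_p": det_col(e_p_d, as_int=True),
            "e_p_nd": e_p_nd if e_p_nd is not None else np.nan,
        },
        index=pd.Index(nd_phen, name="phenotype"),
    )
    pdf["e_p_norm"] = pdf["e_p"] / n_det
    pdf["e_p_nd_norm"] = pdf["e_p_nd"] / n_nd
    return QuantityTable(gdf, pdf[PHENOTYPE_COLUMNS], n_det, n_nd)
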