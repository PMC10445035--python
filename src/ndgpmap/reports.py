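"""End-to-end analyses: ND-vs-deterministic comparison, correlation and
neutral-correlation (biphasic-scaling) reports.

These operate on :class:`~ndgpmap.quantities.QuantityTable` frames and
return plain dataclasses / DataFrames suitable for TSV export; no plotting
is done here (figure data, not figures).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import DGPMap, NDGPMap, project_deterministic
from .errors import UndefinedQuantityError
from .quantities import QuantityTable, compute_quantity_table, null_model_robustness

__all__ = [
    "ComparisonReport",
    "compare_nd_vs_deterministic",
    "CorrelationReport",
    "correlation_report",
    "NeutralCorrelationReport",
    "neutral_correlation_report",
]


@dataclass
class ComparisonReport:
    """Paired ND / deterministic quantities for one map.

    ``genotypes`` pairs (rho_g, rho~_g) and (e_g, e~_g) per genotype;
    ``phenotypes`` carries all phenotypes of the ND universe with
    deterministic columns NaN where the phenotype is absent from the
    deterministic map; ``shared_phenotypes`` restricts to the phenotypes
    present in both maps (the only ones whose quantities are directly
    comparable).  Normalized evolvabilities use each map's own phenotype
    count.
    """

    table: QuantityTable
    shared_phenotypes: pd.DataFrame
    n_deterministic: int
    n_nd: int

    @property
    def genotypes(self) -> pd.DataFrame:
        return self.table.genotypes

    @property
    def phenotypes(self) -> pd.DataFrame:
        return self.table.phenotypes

    @property
    def n_shared(self) -> int:
        return len(self.shared_phenotypes)


def compare_nd_vs_deterministic(
    nd: NDGPMap, d: DGPMap | None = None, *, method: str = "auto"
) -> ComparisonReport:
    """Pair every quantity of the ND map with its deterministic counterpart.

    ``d`` defaults to the most-probable projection of ``nd``.
    """
    if d is None:
        d = project_deterministic(nd)
    qt = compute_quantity_table(nd, d, method=method)
    shared = qt.phenotypes.dropna(subset=["f_p"])
    if shared.empty:
        warnings.warn(
            "deterministic and ND phenotype sets are disjoint; "
            "no shared-phenotype comparison possible",
            stacklevel=2,
        )
    return ComparisonReport(qt, shared, qt.n_deterministic, qt.n_nd)


@dataclass
class CorrelationReport:
    x: str
    y: str
    pearson_r: float
    p_value: float
    n: int
    n_dropped: int


def correlation_report(table: pd.DataFrame, x: str, y: str) -> CorrelationReport:
    """Pearson correlation between two columns, dropping missing pairs.

    Requires at least 3 finite pairs and non-degenerate variance in both
    columns.
    """
    sub = table[[x, y]].replace([np.inf, -np.inf], np.nan).dropna()
    n_dropped = len(table) - len(sub)
    if len(sub) < 3:
        raise UndefinedQuantityError(
            f"correlation of {x!r} vs {y!r} needs >= 3 finite pairs, have {len(sub)}"
        )
    if sub[x].nunique() < 2 or sub[y].nunique() < 2:
        raise UndefinedQuantityError(
            f"correlation of {x!r} vs {y!r} is undefined: a column is constant"
        )
    r, p = stats.pearsonr(sub[x].to_numpy(), sub[y].to_numpy())
    return CorrelationReport(x, y, float(r), float(p), len(sub), n_dropped)


@dataclass
class NeutralCorrelationReport:
    """Per-phenotype robustness vs frequency with biphasic-regime labels.

    ``phenotypes`` has columns ``f_p_nd``, ``rho_p_nd``, ``rho_null``
    (= f~_p), the relative distance to the null model, the distance to the
    log-linear fit, and a descriptive ``regime`` label ('null' or
    'correlated': whichever of the two residuals is smaller).  ``slope`` /
    ``intercept`` describe the fit rho~_p = intercept + slope * log10 f~_p
    (NaN when too few phenotypes for a regression).
    """

    phenotypes: pd.DataFrame
    slope: float
    intercept: float
    fit_r: float
    n: int


def neutral_correlation_report(
    phenotype_table: pd.DataFrame,
    *,
    frequency_col: str = "f_p_nd",
    robustness_col: str = "rho_p_nd",
) -> NeutralCorrelationReport:
    """Classify phenotypes into the null regime (rho~_p ~ f~_p) and the
    neutral-correlation regime (rho~_p ~ log f~_p).

    The classification is descriptive: each phenotype is labelled by
    whichever relationship it sits closer to (relative distance to the null
    line vs absolute distance to the global log-linear fit).
    """
    sub = phenotype_table[[frequency_col, robustness_col]].dropna()
    f = sub[frequency_col].to_numpy(dtype=float)
    rho = sub[robustness_col].to_numpy(dtype=float)
    if np.any(f <= 0):
        raise UndefinedQuantityError("frequencies must be positive")
    slope = intercept = fit_r = np.nan
    if len(sub) >= 3 and np.unique(f).size >= 2:
        res = stats.linregress(np.log10(f), rho)
        slope, intercept, fit_r = res.slope, res.intercept, res.rvalue
    null = np.array([null_model_robustness(v) for v in f])
    resid_null = np.abs(rho - null)
    resid_null_rel = resid_null / null
    if np.isfinite(slope):
        fit = intercept + slope * np.log10(f)
        resid_fit = np.abs(rho - fit)
        regime = np.where(resid_null <= resid_fit, "null", "correlated")
    else:
        resid_fit = np.full_like(rho, np.nan)
        regime = np.where(resid_null_rel <= 0.5, "null", "correlated")
    out = pd.DataFrame(
        {
            frequency_col: f,
            robustness_col: rho,
            "rho_null": null,
            "resid_null": resid_null,
            "resid_null_rel": resid_null_rel,
            "resid_fit": resid_fit,
            "regime": regime,
        },
        index=sub.index,
    )
    return NeutralCorrelationReport(out, float(slope), float(intercept), float(fit_r), len(sub))
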