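"""Decision layer: LRTs, divergence filter, CV statistic and the
SRV+/SRV− and PS+/PS− family calls.

A family is called SRV+ when the M3-vs-DUAL likelihood ratio test is
significant and the fitted synonymous rate distribution has a strictly
positive coefficient of variation (the CV > 0 condition excludes ML
artifacts where the LRT prefers the richer model while estimating a
degenerate dS distribution).

A family is called PS+ when (1) both the M0-vs-M3 and M7-vs-M8 LRTs
are significant with an M8 positive-selection class omega_s > 1,
(2) the estimated proportion of positively selected sites covers at
least one site of the alignment, and (3) the SRV-aware DUAL fit also
supports positive selection — operationalized here as at least one
(dN, dS) grid cell with dN/dS > 1 whose prior weight covers at least
one site.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .codon_engine import DiscreteRateDistribution, ModelFit
from .seqio import PhyloTree

__all__ = [
    "LRTResult",
    "DivergenceStat",
    "ClassificationRecord",
    "lrt",
    "divergence_filter",
    "cv_of_rate_distribution",
    "classify_srv",
    "classify_ps",
    "classify_family",
]

#: numeric tolerance for the "CV strictly positive" condition
CV_POSITIVE_TOL = 1e-6

#: tolerance before a decrease in the alternative's lnL triggers a warning
LNL_DECREASE_TOL = 1e-6

#: degrees of freedom of the three LRTs (M3 with k=3 omega classes;
#: DUAL adds 2 free dS rates after the mean-one constraint plus 2 weights)
DF_M0_VS_M3 = 4
DF_M7_VS_M8 = 2
DF_M3_VS_DUAL = 4


class IncompleteRecordError(ValueError):
    """A required model fit is missing from a classification record."""


@dataclass(frozen=True)
class LRTResult:
    """A likelihood ratio test between nested codon models."""

    statistic: float
    df: int
    p_value: float
    boundary: bool = False


@dataclass(frozen=True)
class DivergenceStat:
    """Average per-branch divergence of a family tree.

    ``per_branch = tree_length / (2T - 3)`` with T leaves; families
    whose average divergence strictly exceeds the threshold (default
    two expected substitutions per amino-acid site per branch) are
    flagged for removal as saturated.
    """

    tree_length: float
    n_taxa: int
    per_branch_divergence: float
    removed: bool


def lrt(lnl_null: float, lnl_alt: float, df: int) -> LRTResult:
    """Chi-square LRT of nested models; statistic clamped at zero.

    A decrease of the alternative's log-likelihood beyond tolerance is
    an optimizer-failure signal: it is warned about and clamped, never
    silently accepted.
    """
    if df < 1:
        raise ValueError("df must be >= 1")
    raw = 2.0 * (lnl_alt - lnl_null)
    if raw < -LNL_DECREASE_TOL:
        warnings.warn(
            f"alternative lnL {lnl_alt:.6f} is below null lnL {lnl_null:.6f}; "
            "LRT statistic clamped to 0 (check optimizer convergence)",
            RuntimeWarning,
            stacklevel=2,
        )
    statistic = max(0.0, raw)
    p = float(stats.chi2.sf(statistic, df))
    return LRTResult(statistic=statistic, df=df, p_value=p)


def divergence_filter(tree: PhyloTree, threshold: float = 2.0) -> DivergenceStat:
    """Flag saturated families by average per-branch divergence.

    ``tree`` must carry branch lengths in expected substitutions per
    amino-acid site.  The removal test is a strict inequality: exactly
    ``threshold`` is kept.  With two taxa the denominator 2T-3 is 1.
    """
    t = tree.n_leaves
    if t < 2:
        raise ValueError("tree must have at least 2 leaves")
    length = tree.total_length
    per_branch = length / (2 * t - 3)
    return DivergenceStat(
        tree_length=length,
        n_taxa=t,
        per_branch_divergence=per_branch,
        removed=per_branch > threshold,
    )


def cv_of_rate_distribution(dist: DiscreteRateDistribution) -> float:
    """Coefficient of variation sqrt(sum p_i (r_i - mu)^2) / mu."""
    return dist.cv


@dataclass(frozen=True)
class ClassificationRecord:
    """Per-family fits, test p-values and the SRV/PS calls."""

    family_id: str
    fits: dict = field(default_factory=dict)  # model name -> ModelFit
    p_m0_vs_m3: float = np.nan
    p_m7_vs_m8: float = np.nan
    p_m3_vs_dual: float = np.nan
    cv_ds: float = np.nan
    omega_m0: float = np.nan
    srv_call: str = "SRV-"
    ps_call: str = "PS-"
    extreme_cv_08: bool = False
    extreme_cv_10: bool = False


def classify_srv(
    fit_m3: ModelFit, fit_dual: ModelFit, alpha: float = 0.05
) -> tuple[str, float, LRTResult]:
    """SRV call from the M3-vs-DUAL LRT and the dS distribution CV.

    Returns ``(call, cv, lrt_result)`` with call in {"SRV+", "SRV-"}.
    """
    if fit_m3 is None or fit_dual is None:
        raise IncompleteRecordError("classify_srv requires both M3 and DUAL fits")
    test = lrt(fit_m3.lnL, fit_dual.lnL, DF_M3_VS_DUAL)
    cv = fit_dual.syn_dist.cv
    call = "SRV+" if (test.p_value < alpha and cv > CV_POSITIVE_TOL) else "SRV-"
    return call, cv, test


def _dual_supports_ps(fit_dual: ModelFit, n_sites: int) -> bool:
    """At least one DUAL grid cell with dN/dS > 1 covering >= 1 site."""
    syn = fit_dual.syn_dist
    nonsyn = fit_dual.nonsyn_dist
    for s, ws in zip(syn.rates, syn.weights):
        if s <= 0:
            continue
        for n, wn in zip(nonsyn.rates, nonsyn.weights):
            if n / s > 1.0 and ws * wn * n_sites >= 1.0:
                return True
    return False


def classify_ps(
    fit_m0: ModelFit,
    fit_m3: ModelFit,
    fit_m7: ModelFit,
    fit_m8: ModelFit,
    fit_dual: ModelFit,
    n_sites: int,
    alpha: float = 0.05,
) -> tuple[str, LRTResult, LRTResult]:
    """PS call from the M0-vs-M3 and M7-vs-M8 LRTs plus DUAL confirmation.

    Returns ``(call, lrt_m0_vs_m3, lrt_m7_vs_m8)``.
    """
    for name, fit in (
        ("M0", fit_m0),
        ("M3", fit_m3),
        ("M7", fit_m7),
        ("M8", fit_m8),
        ("DUAL", fit_dual),
    ):
        if fit is None:
            raise IncompleteRecordError(f"classify_ps requires the {name} fit")
    test1 = lrt(fit_m0.lnL, fit_m3.lnL, DF_M0_VS_M3)
    test2 = lrt(fit_m7.lnL, fit_m8.lnL, DF_M7_VS_M8)
    omega_s = fit_m8.extras.get("omega_s", np.nan)
    p1 = fit_m8.extras.get("p1", 0.0)

    cond1 = test1.p_value < alpha and test2.p_value < alpha and omega_s > 1.0
    cond2 = p1 * n_sites >= 1.0
    cond3 = _dual_supports_ps(fit_dual, n_sites)
    call = "PS+" if (cond1 and cond2 and cond3) else "PS-"
    return call, test1, test2


def classify_family(
    family_id: str,
    fits: dict,
    n_sites: int,
    alpha: float = 0.05,
    cv_extreme: float = 0.8,
    cv_extreme_strict: float = 1.0,
) -> ClassificationRecord:
    """Assemble the full classification record from the five fits."""
    needed = {"M0", "M3", "M7", "M8", "DUAL"}
    missing = needed - set(fits)
    if missing:
        raise IncompleteRecordError(f"missing fits: {sorted(missing)}")
    srv_call, cv, srv_test = classify_srv(fits["M3"], fits["DUAL"], alpha=alpha)
    ps_call, test1, test2 = classify_ps(
        fits["M0"], fits["M3"], fits["M7"], fits["M8"], fits["DUAL"],
        n_sites=n_sites, alpha=alpha,
    )
    return ClassificationRecord(
        family_id=family_id,
        fits=dict(fits),
        p_m0_vs_m3=test1.p_value,
        p_m7_vs_m8=test2.p_value,
        p_m3_vs_dual=srv_test.p_value,
        cv_ds=cv,
        omega_m0=fits["M0"].omega,
        srv_call=srv_call,
        ps_call=ps_call,
        extreme_cv_08=cv >= cv_extreme,
        extreme_cv_10=cv >= cv_extreme_strict,
    )
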