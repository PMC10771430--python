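"""Two-step network MR with Sobel inference, and multivariable MR.

Two-step mediation decomposes a protein's total effect on an outcome into
an indirect path through a mediator (e.g. BMI) — the product a*b of the
protein->mediator and mediator->outcome MR estimates — and a direct
remainder. The Sobel test provides normal-theory inference on the product.
Multivariable MR (MVMR) regresses SNP-outcome effects jointly on several
exposures' SNP effects to estimate each exposure's direct effect.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .mr import MRResult

logger = logging.getLogger(__name__)


@dataclass
class MediationResult:
    """Direct/indirect/total decomposition with Sobel inference.

    ``indirect = a * b`` (years); ``proportion_mediated = indirect/total``
    is reported unclamped, with a warning outside [0, 1].
    """

    a: float
    se_a: float
    b: float
    se_b: float
    indirect: float
    se_indirect: float
    pval: float
    total: float
    proportion_mediated: float


@dataclass
class MVMRResult:
    """Per-exposure direct effects from multivariable MR."""

    exposures: list[str]
    direct_effects: np.ndarray
    se: np.ndarray
    pval: np.ndarray
    n_snp: int


def two_step_mediation(
    step1: MRResult,
    step2: MRResult,
    total: MRResult,
    second_order: bool = False,
) -> MediationResult:
    """Sobel decomposition of a mediated effect.

    ``step1`` is the protein->mediator MR (a), ``step2`` the
    mediator->outcome MR (b), ``total`` the univariable protein->outcome MR.
    The first-order Sobel standard error sqrt(a^2 se_b^2 + b^2 se_a^2) is
    the classical test; ``second_order=True`` adds the se_a^2 se_b^2 term.
    """
    a, se_a = step1.beta, step1.se
    b, se_b = step2.beta, step2.se
    indirect = a * b
    var = a**2 * se_b**2 + b**2 * se_a**2
    if second_order:
        var += se_a**2 * se_b**2
    se_ind = float(np.sqrt(var))
    pval = 1.0 if indirect == 0 else float(2.0 * stats.norm.sf(abs(indirect) / se_ind))
    if total.beta == 0:
        warnings.warn("total effect is zero; proportion mediated undefined", RuntimeWarning)
        proportion = float("nan")
    else:
        proportion = indirect / total.beta
        if not 0.0 <= proportion <= 1.0:
            warnings.warn(
                f"proportion mediated {proportion:.3f} outside [0, 1] (reported unclamped)",
                RuntimeWarning,
            )
    return MediationResult(
        a=a, se_a=se_a, b=b, se_b=se_b,
        indirect=indirect, se_indirect=se_ind, pval=pval,
        total=total.beta, proportion_mediated=proportion,
    )


def mvmr_ivw(
    bx: np.ndarray,
    by: np.ndarray,
    se_y: np.ndarray,
    exposures: list[str] | None = None,
) -> MVMRResult:
    """Multivariable IVW: 1/se_y^2-weighted regression of SNP-outcome
    effects on the SNP-exposure effect matrix, no intercept.

    ``bx`` is (m SNPs, k exposures). Needs m >= k + 1. Exposure columns
    that are exactly zero are dropped (their direct effect is undefined and
    reported as NaN), so a one-exposure problem reduces to univariable IVW.
    Residual sd is floored at 1, matching the univariable IVW's
    multiplicative random-effects convention. Rank deficiency raises an
    error naming the collinear exposures.
    """
    bx = np.atleast_2d(np.asarray(bx, dtype=float))
    by = np.asarray(by, dtype=float)
    se_y = np.asarray(se_y, dtype=float)
    m, k = bx.shape
    if exposures is None:
        exposures = [f"exposure{i + 1}" for i in range(k)]
    if len(exposures) != k:
        raise ValueError("one name per exposure column required")
    if m < k + 1:
        raise ValueError(f"need >= {k + 1} SNPs for {k} exposures, got {m}")

    nonzero = [j for j in range(k) if np.any(bx[:, j] != 0)]
    dropped = [exposures[j] for j in range(k) if j not in nonzero]
    if dropped:
        logger.warning("dropping all-zero exposure column(s): %s", dropped)
    X = bx[:, nonzero]
    w = 1.0 / se_y**2
    WX = X * w[:, None]
    xtx = X.T @ WX
    if np.linalg.matrix_rank(xtx) < len(nonzero):
        raise ValueError(
            f"instrument matrix is rank-deficient; collinear exposures among "
            f"{[exposures[j] for j in nonzero]}"
        )
    coef = np.linalg.solve(xtx, WX.T @ by)
    resid = by - X @ coef
    dof = m - len(nonzero)
    sigma2 = max(1.0, float(np.sum(w * resid**2) / dof))
    cov = sigma2 * np.linalg.inv(xtx)
    se_sub = np.sqrt(np.diag(cov))

    beta = np.full(k, np.nan)
    se = np.full(k, np.nan)
    pval = np.full(k, np.nan)
    for pos, j in enumerate(nonzero):
        beta[j] = coef[pos]
        se[j] = se_sub[pos]
        pval[j] = 2.0 * stats.norm.sf(abs(coef[pos] / se_sub[pos]))
    return MVMRResult(exposures=list(exposures), direct_effects=beta, se=se, pval=pval, n_snp=m)


def mediation_table(
    rows: list[tuple[str, str, str, MediationResult]],
) -> pd.DataFrame:
    """TSV-ready frame: exposure, mediator, outcome, a, se_a, b, se_b,
    indirect, se_indirect, p_sobel, total, proportion."""
    return pd.DataFrame(
        [
            {
                "exposure": e, "mediator": med, "outcome": o,
                "a": r.a, "se_a": r.se_a, "b": r.b, "se_b": r.se_b,
                "indirect": r.indirect, "se_indirect": r.se_indirect,
                "p_sobel": r.pval, "total": r.total, "proportion": r.proportion_mediated,
            }
            for e, med, o, r in rows
        ]
    )


def mvmr_table(result: MVMRResult) -> pd.DataFrame:
    """TSV-ready frame: exposure, direct_beta, se, p, n_snp."""
    return pd.DataFrame(
        {
            "exposure": result.exposures,
            "direct_beta": result.direct_effects,
            "se": result.se,
            "p": result.pval,
            "n_snp": result.n_snp,
        }
    )
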