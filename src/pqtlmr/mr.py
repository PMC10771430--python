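"""Two-sample Mendelian randomization estimators, directionality, and power.

Implements the single-instrument Wald ratio and the multi-instrument
inverse-variance-weighted (IVW), MR-Egger, weighted-median, and
weighted-mode estimators on harmonized SNP-exposure / SNP-outcome effects;
the Steiger directionality test; Bonferroni thresholds; and the analytic
power of a two-sample MR with a continuous outcome.

Conventions follow the field's standard MR tooling: first-order delta-method
Wald standard errors, 1/se_y^2 regression weights, multiplicative
random-effects inflation of the IVW/Egger standard error when Cochran's Q
exceeds its degrees of freedom, two-sided normal tests throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .instruments import variance_explained
from .sumstats import SummaryStatsTable, align_alleles

logger = logging.getLogger(__name__)


@dataclass
class HarmonizedSet:
    """Allele-aligned per-SNP exposure and outcome effects.

    ``df`` columns: snp, bx, se_x, by, se_y, eaf, n_x, n_y.
    """

    exposure_trait: str
    outcome_trait: str
    df: pd.DataFrame

    def __post_init__(self) -> None:
        if len(self.df) < 1:
            raise ValueError("harmonized set needs at least one row")


@dataclass
class MRResult:
    method: str
    beta: float
    se: float
    pval: float
    n_snp: int
    intercept: float = float("nan")
    intercept_se: float = float("nan")
    intercept_pval: float = float("nan")


@dataclass
class SteigerResult:
    r2_exposure: float
    r2_outcome: float
    direction_true: bool
    pval: float


def harmonize(
    exposure: SummaryStatsTable,
    outcome: SummaryStatsTable,
    drop_ambiguous: bool = True,
) -> HarmonizedSet:
    """Join two tables on shared SNPs with outcome effects re-expressed on
    the exposure's effect allele; ambiguous palindromic variants are dropped
    (logged) by default."""
    odf = outcome.df.set_index("snp")
    rows = []
    n_ambiguous = 0
    for rec in exposure.records():
        if rec.snp not in odf.index:
            continue
        out_rec = outcome.record(rec.snp)
        aligned = align_alleles(rec, out_rec)
        if aligned.ambiguous and drop_ambiguous:
            n_ambiguous += 1
            continue
        rows.append(
            {
                "snp": rec.snp,
                "bx": rec.beta,
                "se_x": rec.se,
                "by": aligned.beta,
                "se_y": aligned.se,
                "eaf": rec.eaf,
                "n_x": rec.n,
                "n_y": aligned.n,
            }
        )
    if n_ambiguous:
        logger.warning(
            "%s~%s: dropped %d ambiguous palindromic SNP(s)",
            exposure.trait, outcome.trait, n_ambiguous,
        )
    return HarmonizedSet(exposure.trait, outcome.trait, pd.DataFrame(rows))


def _p_from_z(z: np.ndarray | float) -> np.ndarray | float:
    return 2.0 * stats.norm.sf(np.abs(z))


def wald_ratio(row: pd.Series | dict, second_order: bool = False) -> MRResult:
    """Single-instrument Wald ratio by/bx.

    The default standard error is the first-order delta method |se_y/bx|;
    ``second_order=True`` adds the exposure-uncertainty term
    by^2 se_x^2 / bx^4.
    """
    bx, by, se_y = float(row["bx"]), float(row["by"]), float(row["se_y"])
    if bx == 0:
        raise ZeroDivisionError("Wald ratio undefined for bx = 0")
    beta = by / bx
    var = se_y**2 / bx**2
    if second_order:
        var += by**2 * float(row["se_x"]) ** 2 / bx**4
    se = float(np.sqrt(var))
    return MRResult("wald", beta, se, float(_p_from_z(beta / se)), 1)


def _qstat(ratios: np.ndarray, w: np.ndarray, beta: float) -> float:
    return float(np.sum(w * (ratios - beta) ** 2))


def ivw(h: HarmonizedSet) -> MRResult:
    """Inverse-variance-weighted estimate: the 1/se_y^2-weighted zero-
    intercept regression of by on bx, with multiplicative random-effects
    standard-error inflation when Q/(n-1) > 1."""
    df = h.df
    if len(df) < 2:
        raise ValueError("ivw needs >= 2 instruments; use wald_ratio for one")
    bx, by, se_y = (df[c].to_numpy(dtype=float) for c in ("bx", "by", "se_y"))
    w = (bx / se_y) ** 2
    ratios = by / bx
    beta = float(np.sum(w * ratios) / np.sum(w))
    se = float(1.0 / np.sqrt(np.sum(w)))
    q = _qstat(ratios, w, beta)
    phi = max(1.0, q / (len(df) - 1))
    se *= np.sqrt(phi)
    return MRResult("ivw", beta, se, float(_p_from_z(beta / se)), len(df))


def mr_egger(h: HarmonizedSet) -> MRResult:
    """Weighted regression of by on bx with intercept (weights 1/se_y^2);
    the slope is the pleiotropy-adjusted effect and the intercept tests for
    directional pleiotropy. Residual sd is floored at 1 (the convention of
    the standard MR tooling)."""
    df = h.df
    if len(df) < 3:
        raise ValueError("mr_egger needs >= 3 instruments")
    bx, by, se_y = (df[c].to_numpy(dtype=float) for c in ("bx", "by", "se_y"))
    # orient so all exposure effects are positive (InSIDE convention)
    sign = np.sign(bx)
    sign[sign == 0] = 1.0
    bx, by = bx * sign, by * sign
    w = 1.0 / se_y**2
    X = np.column_stack([np.ones_like(bx), bx])
    WX = X * w[:, None]
    xtx = X.T @ WX
    coef = np.linalg.solve(xtx, WX.T @ by)
    resid = by - X @ coef
    dof = len(df) - 2
    sigma2 = float(np.sum(w * resid**2) / dof)
    sigma2 = max(1.0, sigma2)
    cov = sigma2 * np.linalg.inv(xtx)
    se = np.sqrt(np.diag(cov))
    return MRResult(
        "egger",
        beta=float(coef[1]),
        se=float(se[1]),
        pval=float(_p_from_z(coef[1] / se[1])),
        n_snp=len(df),
        intercept=float(coef[0]),
        intercept_se=float(se[0]),
        intercept_pval=float(_p_from_z(coef[0] / se[0])),
    )


def _weighted_median_point(ratios: np.ndarray, w: np.ndarray) -> float:
    order = np.argsort(ratios)
    r, ww = ratios[order], w[order]
    cum = (np.cumsum(ww) - 0.5 * ww) / np.sum(ww)
    return float(np.interp(0.5, cum, r))


def _bootstrap_se(
    h: HarmonizedSet,
    point_fn,
    n_boot: int,
    seed: int,
) -> float:
    df = h.df
    bx, se_x = df["bx"].to_numpy(float), df["se_x"].to_numpy(float)
    by, se_y = df["by"].to_numpy(float), df["se_y"].to_numpy(float)
    rng = np.random.default_rng(seed)
    est = np.empty(n_boot)
    for i in range(n_boot):
        bxb = bx + se_x * rng.standard_normal(len(bx))
        byb = by + se_y * rng.standard_normal(len(by))
        bxb[bxb == 0] = 1e-300
        est[i] = point_fn(byb / bxb, (bxb / se_y) ** 2)
    return float(np.std(est, ddof=1))


def weighted_median(h: HarmonizedSet, n_boot: int = 5000, seed: int = 20240106) -> MRResult:
    """Weighted median of per-SNP ratio estimates (weights (bx/se_y)^2);
    consistent when instruments carrying >= 50% of the weight are valid.
    Standard error by parametric bootstrap."""
    df = h.df
    if len(df) < 3:
        raise ValueError("weighted_median needs >= 3 instruments")
    bx, by, se_y = (df[c].to_numpy(dtype=float) for c in ("bx", "by", "se_y"))
    ratios, w = by / bx, (bx / se_y) ** 2
    beta = _weighted_median_point(ratios, w)
    se = _bootstrap_se(h, _weighted_median_point, n_boot, seed)
    return MRResult("weighted_median", beta, se, float(_p_from_z(beta / se)), len(df))


def _weighted_mode_point(ratios: np.ndarray, w: np.ndarray, bandwidth_factor: float = 1.5) -> float:
    sd = np.std(ratios, ddof=1) if len(ratios) > 1 else 1.0
    iqr = np.subtract(*np.percentile(ratios, [75, 25]))
    spread = min(sd, iqr / 1.349) if iqr > 0 else sd
    h_bw = bandwidth_factor * 0.9 * max(spread, 1e-12) * len(ratios) ** (-0.2)
    grid = np.linspace(ratios.min() - 3 * h_bw, ratios.max() + 3 * h_bw, 512)
    dens = np.sum(
        w[:, None] * np.exp(-0.5 * ((grid[None, :] - ratios[:, None]) / h_bw) ** 2), axis=0
    )
    return float(grid[np.argmax(dens)])


def weighted_mode(h: HarmonizedSet, n_boot: int = 5000, seed: int = 20240106) -> MRResult:
    """Mode of a kernel-smoothed inverse-variance-weighted ratio density
    (Silverman-style bandwidth x 1.5); consistent when the largest group of
    instruments sharing a ratio is valid. Standard error by bootstrap."""
    df = h.df
    if len(df) < 3:
        raise ValueError("weighted_mode needs >= 3 instruments")
    bx, by, se_y = (df[c].to_numpy(dtype=float) for c in ("bx", "by", "se_y"))
    ratios, w = by / bx, (bx / se_y) ** 2
    beta = _weighted_mode_point(ratios, w)
    se = _bootstrap_se(h, _weighted_mode_point, n_boot, seed)
    return MRResult("weighted_mode", beta, se, float(_p_from_z(beta / se)), len(df))


def steiger(row: pd.Series | dict, n_x: int | None = None, n_y: int | None = None) -> SteigerResult:
    """Steiger directionality test for one instrument.

    Compares the variance the instrument explains in the exposure vs the
    outcome (both via 2 b^2 f (1-f) on standardized scales); TRUE means the
    instrument explains more of the exposure, supporting the assumed
    exposure -> outcome direction. The p-value is a two-sample z-test on the
    Fisher-transformed instrument-trait correlations.
    """
    eaf = float(row["eaf"])
    if np.isnan(eaf):
        raise ValueError("steiger requires eaf")
    n_x = int(row["n_x"]) if n_x is None else n_x
    n_y = int(row["n_y"]) if n_y is None else n_y
    r2x = variance_explained(float(row["bx"]), eaf)
    r2y = variance_explained(float(row["by"]), eaf)
    rx, ry = np.sqrt(min(r2x, 1 - 1e-12)), np.sqrt(min(r2y, 1 - 1e-12))
    z = (np.arctanh(rx) - np.arctanh(ry)) / np.sqrt(1.0 / (n_x - 3) + 1.0 / (n_y - 3))
    return SteigerResult(
        r2_exposure=r2x,
        r2_outcome=r2y,
        direction_true=bool(r2x > r2y),
        pval=float(_p_from_z(z)),
    )


def bonferroni_threshold(m: int, alpha: float = 0.05) -> float:
    """Per-test significance threshold alpha/m for m tested proteins."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return alpha / m


def mr_power(
    n_outcome: int,
    r2_instrument: float,
    effect_years: float,
    outcome_sd_years: float = 1.0,
    alpha: float = 0.05,
) -> float:
    """Analytic power of a two-sample MR with a continuous outcome.

    The Wald z-statistic has non-centrality |b| sqrt(n R^2) where
    b = effect_years / outcome_sd_years is the standardized causal effect,
    n the outcome sample size, and R^2 the instrument's variance explained
    in the exposure; power is the two-sided normal rejection probability.
    """
    if min(n_outcome, r2_instrument, outcome_sd_years) <= 0 or not 0 < alpha < 1:
        raise ValueError("n_outcome, r2_instrument, outcome_sd_years must be > 0; alpha in (0,1)")
    b = effect_years / outcome_sd_years
    ncp = abs(b) * np.sqrt(n_outcome * r2_instrument)
    zcrit = stats.norm.isf(alpha / 2)
    return float(stats.norm.cdf(-zcrit + ncp) + stats.norm.cdf(-zcrit - ncp))


def results_table(
    results: list[tuple[str, str, MRResult]],
    bonferroni_alpha: float | None = None,
) -> pd.DataFrame:
    """Forest-plot-ready frame: exposure, outcome, method, n_snp, beta, se,
    ci_low, ci_high, pval, passes_bonferroni."""
    z = stats.norm.isf(0.025)
    rows = []
    for exposure, outcome, res in results:
        rows.append(
            {
                "exposure": exposure,
                "outcome": outcome,
                "method": res.method,
                "n_snp": res.n_snp,
                "beta": res.beta,
                "se": res.se,
                "ci_low": res.beta - z * res.se,
                "ci_high": res.beta + z * res.se,
                "pval": res.pval,
                "passes_bonferroni": (
                    res.pval <= bonferroni_alpha if bonferroni_alpha is not None else pd.NA
                ),
            }
        )
    return pd.DataFrame(rows)
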