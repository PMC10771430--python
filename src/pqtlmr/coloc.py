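"""Bayesian colocalization and sum-of-single-effects fine-mapping.

Colocalization asks whether two traits' association signals in a cis region
are driven by one shared causal variant. Under the single-causal-variant
assumption the enumeration over per-SNP Wakefield approximate Bayes factors
yields posterior probabilities for five hypotheses:

    H0  no association with either trait
    H1  association with trait 1 only
    H2  association with trait 2 only
    H3  both traits, two distinct causal variants (possibly in LD)
    H4  both traits, one shared causal variant

To relax the single-variant assumption, :func:`susie_rss` fits a
sum-of-single-effects model to z-scores and an LD matrix, and
:func:`coloc_susie` runs the H0-H4 enumeration on every pair of fine-mapped
signals, one per trait. :func:`multi_trait_coloc` is a simplified
simultaneous-colocalization test across three or more traits.

All hypothesis accumulations are carried out in log space.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp, softmax

from .sumstats import LDMatrix, SummaryStatsTable

logger = logging.getLogger(__name__)

DEFAULT_PRIORS = (1e-4, 1e-4, 1e-5)  # p1, p2, p12
#: Effect-scale prior sd for a standardized quantitative trait.
DEFAULT_PRIOR_SD = 0.15

HYPOTHESES = ("h0", "h1", "h2", "h3", "h4")


@dataclass
class ColocResult:
    """Posterior probabilities over H0..H4 for one region/trait pair."""

    pp: np.ndarray  # length 5, sums to 1
    priors: tuple[float, float, float]
    n_snps: int
    best_snp_h4: str | None
    components: tuple[int, int] | None = None  # set by coloc_susie

    def __post_init__(self) -> None:
        self.pp = np.asarray(self.pp, dtype=float)
        if self.pp.shape != (5,) or np.any(self.pp < -1e-12):
            raise ValueError("pp must be 5 non-negative probabilities")
        if abs(self.pp.sum() - 1.0) > 1e-9:
            raise ValueError(f"pp must sum to 1, got {self.pp.sum()}")

    def __getitem__(self, hyp: str) -> float:
        return float(self.pp[HYPOTHESES.index(hyp)])

    @property
    def argmax(self) -> str:
        return HYPOTHESES[int(np.argmax(self.pp))]


def log_abf(beta: np.ndarray, se: np.ndarray, prior_sd: float = DEFAULT_PRIOR_SD) -> np.ndarray:
    """Wakefield log approximate Bayes factor for association at one SNP.

    With V = se^2, z = beta/se, and shrinkage r = w/(w+V) for prior effect
    variance w = prior_sd^2: log ABF = 0.5 log(1-r) + 0.5 z^2 r.
    """
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0):
        raise ValueError("se must be > 0")
    v = se**2
    r = prior_sd**2 / (prior_sd**2 + v)
    z = beta / se
    return 0.5 * np.log1p(-r) + 0.5 * z**2 * r


def _enumerate(
    l1: np.ndarray,
    l2: np.ndarray,
    priors: tuple[float, float, float],
    snps: list[str] | None,
) -> ColocResult:
    """H0-H4 enumeration from two vectors of per-SNP log Bayes factors."""
    p1, p2, p12 = priors
    log_s1 = logsumexp(l1)
    log_s2 = logsumexp(l2)
    log_s12 = logsumexp(l1 + l2)
    log_h = np.empty(5)
    log_h[0] = 0.0
    log_h[1] = np.log(p1) + log_s1
    log_h[2] = np.log(p2) + log_s2
    # H3: sum over ordered distinct pairs = S1*S2 - S12
    a, b = log_s1 + log_s2, log_s12
    if b >= a:
        # single-SNP regions (or numerically degenerate ones) can leave no
        # mass for distinct-variant configurations
        warnings.warn("H3 accumulator non-positive; clamped to zero", RuntimeWarning)
        log_h[3] = -np.inf
    else:
        log_h[3] = np.log(p1) + np.log(p2) + a + np.log1p(-np.exp(b - a))
    log_h[4] = np.log(p12) + log_s12
    pp = softmax(log_h)
    best = snps[int(np.argmax(l1 + l2))] if snps else None
    return ColocResult(pp=pp, priors=priors, n_snps=len(l1), best_snp_h4=best)


def coloc_abf(
    t1: SummaryStatsTable,
    t2: SummaryStatsTable,
    priors: tuple[float, float, float] = DEFAULT_PRIORS,
    maf_min: float = 0.01,
    window: float = 1_000_000,
    center_pos: int | None = None,
    prior_sd: float = DEFAULT_PRIOR_SD,
) -> ColocResult:
    """Single-causal-variant colocalization of two traits.

    Analyzes the SNPs shared by both tables with minor allele frequency
    above ``maf_min`` and, when ``center_pos`` is given, within ``window``
    bp of it (the study's convention: MAF > 0.01 within 1 Mb of the
    cis-pQTL). Only z-score magnitudes enter the Bayes factors, so allele
    orientation does not need to be harmonized first.
    """
    d1 = t1.df.set_index("snp")
    d2 = t2.df.set_index("snp")
    shared = [s for s in t1.snps if s in d2.index]

    def keep(snp: str) -> bool:
        for d in (d1, d2):
            eaf = d.loc[snp, "eaf"]
            if np.isnan(eaf) or min(eaf, 1 - eaf) <= maf_min:
                return False
            if center_pos is not None and abs(int(d.loc[snp, "pos"]) - center_pos) > window:
                return False
        return True

    shared = [s for s in shared if keep(s)]
    if not shared:
        raise ValueError(
            f"no shared SNPs between {t1.trait!r} and {t2.trait!r} after MAF/window filters"
        )
    l1 = log_abf(d1.loc[shared, "beta"].to_numpy(), d1.loc[shared, "se"].to_numpy(), prior_sd)
    l2 = log_abf(d2.loc[shared, "beta"].to_numpy(), d2.loc[shared, "se"].to_numpy(), prior_sd)
    return _enumerate(l1, l2, priors, shared)


@dataclass
class CredibleSet:
    """Smallest SNP set reaching the coverage target for one signal."""

    snps: list[str]
    indices: list[int]
    coverage: float
    purity: float  # minimum absolute pairwise LD within the set


@dataclass
class SusieFit:
    """Sum-of-single-effects fit on summary statistics."""

    alpha: np.ndarray  # (L, p) per-component posterior inclusion probabilities
    lbf_variable: np.ndarray  # (L, p) per-component per-SNP log Bayes factors
    lbf_component: np.ndarray  # (L,) log marginal BF of each component
    credible_sets: list[CredibleSet] = field(default_factory=list)
    cs_components: list[int] = field(default_factory=list)  # component index per CS
    snps: list[str] = field(default_factory=list)
    converged: bool = True


def _single_effect(
    zr: np.ndarray,
    prior_grid: np.ndarray,
    log_pi: np.ndarray,
) -> tuple[np.ndarray, float, float]:
    """Fit one single-effect component to residual z-scores.

    Observation model zr_j ~ N(lambda_j, 1) with prior lambda_j ~ N(0, s0);
    s0 is chosen from ``prior_grid`` by maximizing the component's log
    marginal Bayes factor. Returns (per-SNP lbf at the chosen s0, s0,
    component log marginal BF).
    """
    z2 = zr**2
    best_lbf = None
    best = (np.zeros_like(zr), 0.0, -np.inf)
    for s0 in prior_grid:
        shrink = s0 / (1.0 + s0)
        lbf = -0.5 * np.log1p(s0) + 0.5 * z2 * shrink
        total = float(logsumexp(lbf + log_pi))
        if best_lbf is None or total > best_lbf:
            best_lbf = total
            best = (lbf, float(s0), total)
    return best


def susie_rss(
    z: np.ndarray,
    ld: LDMatrix,
    n: int,
    L: int = 10,
    coverage: float = 0.95,
    purity_min: float = 0.5,
    max_iter: int = 100,
    tol: float = 1e-3,
    ridge: float = 1e-4,
) -> SusieFit:
    """Sum-of-single-effects fine-mapping from z-scores and LD.

    Iterative Bayesian stepwise selection: each of ``L`` components models
    one causal effect; per iteration a component computes per-SNP Bayes
    factors on the z-scores residualized for all other components, updates
    its inclusion probabilities, and the loop repeats until posterior-mean
    changes fall below ``tol``. Each component's prior effect variance is
    optimized over a grid; components whose best log marginal Bayes factor
    is <= 0.01 are deactivated, so a null region yields no credible sets.
    Credible sets are the smallest SNP sets reaching ``coverage`` posterior
    mass, kept only when their purity (minimum absolute pairwise LD) is
    >= ``purity_min``. The LD matrix is ridge-regularized (``ridge`` added
    to the diagonal) for numerical stability.
    """
    z = np.asarray(z, dtype=float)
    p = len(z)
    if z.shape != (p,) or p != len(ld.snps):
        raise ValueError("z must align with the LD matrix")
    R = ld.r + ridge * np.eye(p)
    log_pi = np.full(p, -np.log(p))
    zmax2 = max(float(np.max(z**2)), 1.0)
    prior_grid = np.concatenate([[0.0], np.geomspace(0.1, 2.0 * zmax2, 24)])

    alpha = np.full((L, p), 1.0 / p)
    lbf_var = np.zeros((L, p))
    lbf_comp = np.full(L, -np.inf)
    b = np.zeros((L, p))  # per-component posterior mean effects (z units)
    s0s = np.zeros(L)
    fitted = np.zeros(p)
    converged = False
    for _ in range(max_iter):
        b_old = b.copy()
        for l in range(L):
            fitted -= R @ b[l]
            zr = z - fitted
            lbf, s0, total = _single_effect(zr, prior_grid, log_pi)
            if total <= 0.01 or s0 == 0.0:
                # component carries no signal
                alpha[l] = 1.0 / p
                lbf_var[l] = 0.0
                lbf_comp[l] = total
                b[l] = 0.0
                s0s[l] = 0.0
            else:
                alpha[l] = softmax(lbf + log_pi)
                lbf_var[l] = lbf
                lbf_comp[l] = total
                b[l] = alpha[l] * zr * (s0 / (1.0 + s0))
                s0s[l] = s0
            fitted += R @ b[l]
        if float(np.max(np.abs(b - b_old))) < tol:
            converged = True
            break
    if not converged:
        warnings.warn("susie_rss did not converge within max_iter", RuntimeWarning)

    fit = SusieFit(
        alpha=alpha,
        lbf_variable=lbf_var,
        lbf_component=lbf_comp,
        snps=list(ld.snps),
        converged=converged,
    )
    for l in range(L):
        if s0s[l] == 0.0:
            continue
        order = np.argsort(alpha[l])[::-1]
        cum = np.cumsum(alpha[l][order])
        k = int(np.searchsorted(cum, coverage) + 1)
        idx = sorted(order[:k].tolist())
        sub = np.abs(ld.r[np.ix_(idx, idx)])
        purity = float(sub.min())
        if purity < purity_min:
            continue
        fit.credible_sets.append(
            CredibleSet(
                snps=[ld.snps[i] for i in idx],
                indices=idx,
                coverage=float(cum[k - 1]),
                purity=purity,
            )
        )
        fit.cs_components.append(l)
    return fit


def coloc_susie(
    f1: SusieFit,
    f2: SusieFit,
    priors: tuple[float, float, float] = DEFAULT_PRIORS,
) -> list[ColocResult]:
    """Pairwise colocalization of fine-mapped signals.

    For every pair of credible-set-bearing components (one from each fit),
    the H0-H4 enumeration is run on the pair's per-SNP component log Bayes
    factors, relaxing the single-causal-variant assumption to one variant
    per signal. Empty list when either fit has no credible sets.
    """
    if f1.snps != f2.snps:
        raise ValueError("fits must share a SNP list")
    out: list[ColocResult] = []
    for i in f1.cs_components:
        for j in f2.cs_components:
            res = _enumerate(f1.lbf_variable[i], f2.lbf_variable[j], priors, f1.snps)
            res.components = (i, j)
            out.append(res)
    return out


@dataclass
class MultiColocResult:
    """Simplified simultaneous colocalization across >= 3 traits."""

    traits: list[str]
    pp_all_shared: float
    candidate_snp: str | None
    method: str = "simplified-joint-abf"  # not the full regional-selection algorithm


def multi_trait_coloc(
    tables: list[SummaryStatsTable],
    prior_all: float = 1e-5,
    report_threshold: float = 0.25,
    prior_sd: float = DEFAULT_PRIOR_SD,
) -> MultiColocResult:
    """Posterior that a single SNP is causal for all traits jointly.

    Simplified implementation (flagged in the result's ``method``): per-SNP
    log Bayes factors are summed across traits and the all-shared
    configuration is weighed against the null and every all-but-one-trait
    partition, each alternative carrying prior weight ``prior_all``. Below
    ``report_threshold`` the candidate SNP is reported as None — the
    convention for "no simultaneous colocalization detected".
    """
    if len(tables) < 3:
        raise ValueError("multi_trait_coloc needs >= 3 traits; use coloc_abf for two")
    shared = set(tables[0].snps)
    for t in tables[1:]:
        shared &= set(t.snps)
    snps = [s for s in tables[0].snps if s in shared]
    if not snps:
        raise ValueError("no SNPs shared by all traits")
    lbfs = []
    for t in tables:
        d = t.df.set_index("snp").loc[snps]
        lbfs.append(log_abf(d["beta"].to_numpy(), d["se"].to_numpy(), prior_sd))
    lbfs = np.array(lbfs)  # (T, p)
    joint = lbfs.sum(axis=0)
    log_h = [0.0, np.log(prior_all) + logsumexp(joint)]
    for i in range(len(tables)):
        loo = joint - lbfs[i]
        log_h.append(np.log(prior_all) + logsumexp(loo))
    pp = softmax(np.array(log_h))
    pp_all = float(pp[1])
    candidate = snps[int(np.argmax(joint))] if pp_all >= report_threshold else None
    return MultiColocResult(
        traits=[t.trait for t in tables], pp_all_shared=pp_all, candidate_snp=candidate
    )
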