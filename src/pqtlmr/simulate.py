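"""Synthetic GWAS summary statistics over a simulated cis region.

Emulates the statistical structure of the study's inputs — a cis-pQTL
region within 1 Mb of a gene's transcription start site, with 1-2 causal
variants under block or autoregressive LD, per-trait sample sizes from a
few thousand (proteomic GWAS) to hundreds of thousands (reproductive-timing
GWAS), a protein -> outcome causal effect in years per SD, optional BMI
mediation, and optional reverse causation — so every downstream stage has
a no-download test surface with known ground truth.

Marginal association z-scores for a region are drawn jointly from

    z ~ N(R @ lam, R)

where R is the LD correlation matrix and lam carries non-centrality values
sqrt(n * r2 / (1 - r2)) at the causal variants. z is converted to per-allele
beta/se on a standardized phenotype scale via se = 1 / sqrt(2 f (1-f) n),
the scale on which R^2 ~= 2 b^2 f (1-f). Exposure, outcome, and mediator
draws are independent given the truth (two-sample design, no overlap).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .sumstats import GeneAnnotation, LDMatrix, SummaryStatsTable, SumstatsError

CAUSAL_MODELS = (
    "null",
    "shared_causal",
    "two_causal_in_ld",
    "mediated",
    "reverse",
    "pleiotropic",
)

#: Non-palindromic allele pairs assigned to simulated variants.
_ALLELE_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C")]


@dataclass
class SimConfig:
    """Configuration for one simulated cis region.

    Defaults mirror the study conditions: an exposure GWAS of 3,301
    (SomaLogic-scale proteomics), an outcome GWAS of 370,000 (menarche
    timing), a mediator GWAS of 40,000 (childhood adiposity), a cis-pQTL
    explaining 10% of protein variance, and a protein effect of 0.2 years
    per SD on the outcome — inside the printed range of significant effects.

    ``theta`` and ``b`` are in years per SD and are divided by
    ``outcome_sd`` (years) to put the outcome on a standardized scale;
    ``a`` is SD of mediator per SD of protein.
    """

    n_snps: int = 200
    ld_decay: float = 0.9
    ld_blocks: Sequence[tuple[int, float]] | None = None
    n_exposure: int = 3301
    n_outcome: int = 370_000
    n_mediator: int = 40_000
    causal_model: str = "shared_causal"
    theta: float = 0.2
    a: float = 0.2
    b: float = 0.5
    r2_instrument: float = 0.1
    r2_outcome: float | None = None
    pleiotropy: float = 0.05
    outcome_sd: float = 1.0
    maf_range: tuple[float, float] = (0.05, 0.5)
    seed: int = 0

    def validate(self) -> None:
        if self.n_snps < 1:
            raise ValueError("n_snps must be >= 1")
        if not 0.0 <= self.ld_decay < 1.0:
            raise ValueError("ld_decay must be in [0, 1)")
        for name in ("n_exposure", "n_outcome", "n_mediator"):
            if getattr(self, name) < 2:
                raise ValueError(f"{name} must be >= 2")
        if self.causal_model not in CAUSAL_MODELS:
            raise ValueError(f"causal_model must be one of {CAUSAL_MODELS}")
        if not 0.0 < self.r2_instrument < 1.0:
            raise ValueError("r2_instrument must be in (0, 1)")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range bounds must satisfy 0 < lo <= hi <= 0.5")
        if self.ld_blocks is not None:
            if sum(size for size, _ in self.ld_blocks) != self.n_snps:
                raise SumstatsError(
                    f"ld_blocks sizes must sum to n_snps={self.n_snps}: {self.ld_blocks}"
                )
            for size, rho in self.ld_blocks:
                if not 0.0 <= rho < 1.0:
                    raise SumstatsError(
                        f"block correlation {rho} outside [0, 1); "
                        "compound-symmetric blocks are only PSD there"
                    )


@dataclass
class SimRegion:
    """A simulated cis region: variants, LD, per-trait tables, and truth."""

    variants: pd.DataFrame  # columns snp, chr, pos, maf, ea, nea
    ld: LDMatrix
    gene: GeneAnnotation
    truth: dict
    tables: dict[str, SummaryStatsTable]

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, table in self.tables.items():
            table.write(outdir / f"{name}.tsv")
        self.ld.write(outdir / "ld.txt", outdir / "ld.snps")
        (outdir / "truth.json").write_text(json.dumps(self.truth, indent=2) + "\n")


def _ncp(n: int, r2: float) -> float:
    """Marginal z-score non-centrality for a variant explaining r2 at size n."""
    r2 = min(r2, 0.99)
    return float(np.sqrt(n * r2 / (1.0 - r2)))


def ld_matrix(config: SimConfig, snps: Sequence[str]) -> LDMatrix:
    """AR(1) LD with coefficient ``ld_decay``, or compound-symmetric blocks."""
    p = config.n_snps
    if config.ld_blocks is None:
        idx = np.arange(p)
        r = config.ld_decay ** np.abs(idx[:, None] - idx[None, :])
    else:
        r = np.zeros((p, p))
        start = 0
        for size, rho in config.ld_blocks:
            block = np.full((size, size), rho)
            np.fill_diagonal(block, 1.0)
            r[start : start + size, start : start + size] = block
            start += size
    return LDMatrix(list(snps), r)


def _draw_z(rng: np.random.Generator, ld: LDMatrix, lam: np.ndarray) -> np.ndarray:
    # small jitter keeps Cholesky stable for near-singular AR(1) at high decay
    chol = np.linalg.cholesky(ld.r + 1e-10 * np.eye(len(lam)))
    return ld.r @ lam + chol @ rng.standard_normal(len(lam))


def _z_to_table(
    trait: str,
    z: np.ndarray,
    variants: pd.DataFrame,
    n: int,
) -> SummaryStatsTable:
    f = variants["maf"].to_numpy()
    se = 1.0 / np.sqrt(2.0 * f * (1.0 - f) * n)
    beta = z * se
    pval = np.clip(2.0 * stats.norm.sf(np.abs(z)), 1e-300, 1.0)
    df = pd.DataFrame(
        {
            "snp": variants["snp"],
            "chr": variants["chr"],
            "pos": variants["pos"],
            "ea": variants["ea"],
            "nea": variants["nea"],
            "eaf": f,
            "beta": beta,
            "se": se,
            "pval": pval,
            "n": n,
        }
    )
    return SummaryStatsTable(trait, df)


def simulate_region(config: SimConfig) -> SimRegion:
    """Simulate summary statistics for exposure/outcome(/mediator) traits.

    The causal variant sits at the region's center (the two-causal scenario
    adds a second one immediately adjacent, so their LD equals ``ld_decay``
    under AR(1)). Ground truth (causal indices and standardized effects per
    trait) is recorded in :attr:`SimRegion.truth`.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    p = config.n_snps

    snps = [f"rs{i + 1}" for i in range(p)]
    # spread across a 1 Mb window centered on the gene's TSS
    tss = 1_000_000
    pos = np.linspace(tss - 500_000, tss + 500_000, p).astype(int) if p > 1 else np.array([tss])
    mafs = rng.uniform(*config.maf_range, size=p)
    pairs = [_ALLELE_PAIRS[i] for i in rng.integers(0, len(_ALLELE_PAIRS), size=p)]
    variants = pd.DataFrame(
        {
            "snp": snps,
            "chr": "1",
            "pos": pos,
            "maf": mafs,
            "ea": [ea for ea, _ in pairs],
            "nea": [nea for _, nea in pairs],
        }
    )
    ld = ld_matrix(config, snps)
    gene = GeneAnnotation("GENE1", "1", tss)

    c1 = p // 2
    c2 = min(c1 + 1, p - 1)
    r2 = config.r2_instrument
    theta_std = config.theta / config.outcome_sd
    b_std = config.b / config.outcome_sd

    lam_x = np.zeros(p)
    lam_y = np.zeros(p)
    lam_m = np.zeros(p)
    truth_effects: dict[str, dict] = {"exposure": {}, "outcome": {}, "mediator": {}}

    model = config.causal_model
    if model == "null":
        pass
    elif model in ("shared_causal", "pleiotropic"):
        lam_x[c1] = _ncp(config.n_exposure, r2)
        beta_y = theta_std * np.sqrt(r2)
        if model == "pleiotropic":
            beta_y += config.pleiotropy
        lam_y[c1] = np.sign(beta_y) * _ncp(config.n_outcome, beta_y**2)
        truth_effects["exposure"] = {"index": c1, "r2": r2}
        truth_effects["outcome"] = {"index": c1, "beta_std": beta_y}
    elif model == "two_causal_in_ld":
        lam_x[c1] = _ncp(config.n_exposure, r2)
        if config.r2_outcome is not None:
            q = config.r2_outcome
            lam_y[c2] = _ncp(config.n_outcome, q)
        else:
            # default: match the exposure's non-centrality so neither
            # trait's signal dominates the H3-vs-H4 contrast
            lam_y[c2] = lam_x[c1]
            q = lam_y[c2] ** 2 / (config.n_outcome + lam_y[c2] ** 2)
        truth_effects["exposure"] = {"index": c1, "r2": r2}
        truth_effects["outcome"] = {"index": c2, "r2": q}
    elif model == "mediated":
        lam_x[c1] = _ncp(config.n_exposure, r2)
        r2_m = config.a**2 * r2
        lam_m[c1] = np.sign(config.a) * _ncp(config.n_mediator, r2_m)
        total_std = theta_std + config.a * b_std
        beta_y = total_std * np.sqrt(r2)
        lam_y[c1] = np.sign(beta_y) * _ncp(config.n_outcome, beta_y**2)
        truth_effects["exposure"] = {"index": c1, "r2": r2}
        truth_effects["mediator"] = {"index": c1, "r2": r2_m}
        truth_effects["outcome"] = {"index": c1, "beta_std": beta_y, "total_std": total_std}
    elif model == "reverse":
        # outcome owns the causal variant; the protein inherits an
        # attenuated downstream signal, so Steiger should flag FALSE
        lam_y[c1] = _ncp(config.n_outcome, r2)
        r2_x = config.theta**2 * r2
        lam_x[c1] = np.sign(config.theta) * _ncp(config.n_exposure, r2_x)
        truth_effects["outcome"] = {"index": c1, "r2": r2}
        truth_effects["exposure"] = {"index": c1, "r2": r2_x}

    tables = {
        "exposure": _z_to_table("exposure", _draw_z(rng, ld, lam_x), variants, config.n_exposure),
        "outcome": _z_to_table("outcome", _draw_z(rng, ld, lam_y), variants, config.n_outcome),
    }
    if model in ("mediated",):
        tables["mediator"] = _z_to_table(
            "mediator", _draw_z(rng, ld, lam_m), variants, config.n_mediator
        )

    truth = {
        "model": model,
        "theta": config.theta,
        "a": config.a,
        "b": config.b,
        "effects": truth_effects,
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in asdict(config).items()
        },
    }
    return SimRegion(variants=variants, ld=ld, gene=gene, truth=truth, tables=tables)


def simulate_tables(
    effects: Mapping[str, np.ndarray],
    ns: Mapping[str, int],
    ld: LDMatrix,
    mafs: np.ndarray,
    seed: int,
    chrom: str = "1",
    pos: np.ndarray | None = None,
) -> dict[str, SummaryStatsTable]:
    """Low-level generator for custom multi-causal scenarios.

    ``effects[trait]`` is a vector of per-SNP standardized effects beta;
    marginal z means are sqrt(n) * R @ beta (no residual-variance shrink —
    adequate for the small effects simulated here). Used for scenarios the
    scenario enum does not cover, e.g. one trait with two signals of which
    the second is shared.
    """
    p = len(ld.snps)
    if pos is None:
        pos = np.arange(1, p + 1) * 1000
    rng = np.random.default_rng(seed)
    pair_idx = rng.integers(0, len(_ALLELE_PAIRS), size=p)
    variants = pd.DataFrame(
        {
            "snp": ld.snps,
            "chr": chrom,
            "pos": pos,
            "maf": np.asarray(mafs, dtype=float),
            "ea": [_ALLELE_PAIRS[i][0] for i in pair_idx],
            "nea": [_ALLELE_PAIRS[i][1] for i in pair_idx],
        }
    )
    out: dict[str, SummaryStatsTable] = {}
    for trait, beta in effects.items():
        beta = np.asarray(beta, dtype=float)
        if beta.shape != (p,):
            raise ValueError(f"effects[{trait!r}] must have length {p}")
        lam = np.sqrt(ns[trait]) * beta
        z = ld.r @ lam + np.linalg.cholesky(ld.r + 1e-10 * np.eye(p)) @ rng.standard_normal(p)
        out[trait] = _z_to_table(trait, z, variants, ns[trait])
    return out


def simulate_instrument_panel(
    n_snps: int = 10,
    n_exposure: int = 35_000,
    n_outcome: int = 50_000,
    theta: float = 0.2,
    r2_per_snp: float | tuple[float, float] = 0.02,
    prop_pleiotropic: float = 0.0,
    pleiotropy: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Independent (post-clumping) instruments on a standardized scale.

    Returns a frame with columns ``bx, se_x, by, se_y, eaf, n_x, n_y`` plus
    the ground truth in ``attrs``. Instrument effects are sqrt(r2) per SNP,
    with ``r2_per_snp`` either a common value or a (lo, hi) range drawn
    uniformly — real panels have variable instrument strength, and the
    Egger intercept is only identified when they do. The first
    ``round(prop_pleiotropic * n_snps)`` instruments add a direct
    (directional) effect ``pleiotropy`` on the standardized outcome. This
    is the multi-instrument surface for IVW / Egger / weighted-median /
    weighted-mode and reverse-MR testing. Effects are oriented to the
    exposure-increasing allele (all bx_true positive), the convention under
    which directional pleiotropy is also directional in ratio space.
    """
    rng = np.random.default_rng(seed)
    if isinstance(r2_per_snp, tuple):
        r2 = rng.uniform(r2_per_snp[0], r2_per_snp[1], size=n_snps)
    else:
        r2 = np.full(n_snps, float(r2_per_snp))
    bx_true = np.sqrt(r2)
    alpha = np.zeros(n_snps)
    n_pleio = int(round(prop_pleiotropic * n_snps))
    alpha[:n_pleio] = pleiotropy
    by_true = theta * bx_true + alpha
    se_x = np.full(n_snps, 1.0 / np.sqrt(n_exposure))
    se_y = np.full(n_snps, 1.0 / np.sqrt(n_outcome))
    df = pd.DataFrame(
        {
            "snp": [f"iv{i + 1}" for i in range(n_snps)],
            "bx": bx_true + se_x * rng.standard_normal(n_snps),
            "se_x": se_x,
            "by": by_true + se_y * rng.standard_normal(n_snps),
            "se_y": se_y,
            "eaf": rng.uniform(0.05, 0.95, size=n_snps),
            "n_x": n_exposure,
            "n_y": n_outcome,
        }
    )
    df.attrs["truth"] = {"theta": theta, "bx_true": bx_true, "alpha": alpha}
    return df


@dataclass
class MediationPanel:
    """Simulated per-SNP effects for a protein + mediator instrument set."""

    protein_on_protein: pd.DataFrame  # 1 row: the cis-pQTL
    protein_on_mediator: pd.DataFrame
    protein_on_outcome: pd.DataFrame
    mediator_set: pd.DataFrame  # mediator instruments: bx (on mediator), by (on outcome)
    mvmr_bx: np.ndarray  # (m, 2): columns protein, mediator
    mvmr_by: np.ndarray
    mvmr_se_y: np.ndarray
    truth: dict


def simulate_mediation_panel(
    a: float = 0.2,
    b: float = 0.5,
    theta_direct: float = 0.05,
    r2_protein: float = 0.1,
    n_mediator_snps: int = 17,
    r2_mediator_per_snp: float = 0.005,
    n_exposure: int = 35_559,
    n_mediator: int = 40_000,
    n_outcome: int = 370_000,
    seed: int = 0,
) -> MediationPanel:
    """Two-step mediation design: protein -> mediator (a) -> outcome (b),
    plus a direct protein -> outcome path ``theta_direct`` (years per SD,
    outcome standardized). One cis-pQTL instruments the protein;
    ``n_mediator_snps`` independent SNPs (17 by default, a childhood-BMI
    instrument count) instrument the mediator. The protein GWAS defaults to
    the deCODE-scale n of 35,559, the largest of the proteomic sources;
    note that with a much smaller protein GWAS the noise in the mediator
    instruments' protein effects attenuates the MVMR protein coefficient
    (an errors-in-variables effect of order k * se_x^2 / R^2). Total
    protein effect is ``theta_direct + a * b``.
    """
    rng = np.random.default_rng(seed)
    g_p = np.sqrt(r2_protein)  # cis-pQTL standardized effect on protein
    total = theta_direct + a * b

    se_p_x = 1.0 / np.sqrt(n_exposure)
    se_p_m = 1.0 / np.sqrt(n_mediator)
    se_p_y = 1.0 / np.sqrt(n_outcome)

    # observed cis-pQTL effects on each trait
    bx_p = g_p + se_p_x * rng.standard_normal()
    bm_p = a * g_p + se_p_m * rng.standard_normal()
    by_p = total * g_p + se_p_y * rng.standard_normal()
    protein_on_protein = pd.DataFrame(
        {"snp": ["cispqtl"], "beta": [bx_p], "se": [se_p_x], "n": [n_exposure]}
    )
    protein_on_mediator = pd.DataFrame(
        {"snp": ["cispqtl"], "beta": [bm_p], "se": [se_p_m], "n": [n_mediator]}
    )
    protein_on_outcome = pd.DataFrame(
        {"snp": ["cispqtl"], "beta": [by_p], "se": [se_p_y], "n": [n_outcome]}
    )

    signs = rng.choice([-1.0, 1.0], size=n_mediator_snps)
    gm_true = signs * np.sqrt(r2_mediator_per_snp)  # effects on mediator
    gm = gm_true + se_p_m * rng.standard_normal(n_mediator_snps)
    gy = b * gm_true + se_p_y * rng.standard_normal(n_mediator_snps)
    mediator_set = pd.DataFrame(
        {
            "snp": [f"bmi{i + 1}" for i in range(n_mediator_snps)],
            "bx": gm,
            "se_x": se_p_m,
            "by": gy,
            "se_y": se_p_y,
            "n_x": n_mediator,
            "n_y": n_outcome,
        }
    )

    # MVMR instrument set: the cis-pQTL plus the mediator instruments, with
    # observed effects on both exposures and on the outcome
    m = n_mediator_snps + 1
    bx_mat = np.zeros((m, 2))
    bx_mat[0, 0] = bx_p
    bx_mat[0, 1] = bm_p
    bx_mat[1:, 0] = se_p_x * rng.standard_normal(n_mediator_snps)  # true 0 on protein
    bx_mat[1:, 1] = gm
    by_vec = np.concatenate([[by_p], gy])
    se_y_vec = np.full(m, se_p_y)

    return MediationPanel(
        protein_on_protein=protein_on_protein,
        protein_on_mediator=protein_on_mediator,
        protein_on_outcome=protein_on_outcome,
        mediator_set=mediator_set,
        mvmr_bx=bx_mat,
        mvmr_by=by_vec,
        mvmr_se_y=se_y_vec,
        truth={
            "a": a,
            "b": b,
            "theta_direct": theta_direct,
            "total": total,
            "indirect": a * b,
            "proportion_mediated": a * b / total if total else np.nan,
        },
    )
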