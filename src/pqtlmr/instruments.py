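"""cis-pQTL instrument selection, LD proxies, clumping, and strength metrics.

A cis-pQTL is a variant within 1 Mb of the encoding gene's transcription
start site, associated with the protein below a significance threshold
(5e-8 by default). Instrument strength is summarized by the variance
explained R^2 ~= 2 b^2 f (1-f) (b on a standardized phenotype, f the
effect-allele frequency) and the one-instrument F-statistic
F = (R^2/k) / ((1 - R^2) / (n - k - 1)); F > 10 is the conventional
adequacy bound.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .sumstats import GeneAnnotation, LDMatrix, SummaryStatsTable, VariantRecord

logger = logging.getLogger(__name__)

CIS_WINDOW_BP = 1_000_000


@dataclass
class Instrument:
    """A selected cis-pQTL with strength metrics."""

    snp: str
    gene: str
    distance_to_tss: int
    exposure: VariantRecord
    r2: float
    f_stat: float
    is_proxy: bool = False
    proxy_r2: float = float("nan")


def variance_explained(beta: float, eaf: float) -> float:
    """R^2 ~= 2 b^2 f (1-f) for a standardized phenotype."""
    if not 0.0 < eaf < 1.0:
        raise ValueError(f"eaf must be in (0, 1), got {eaf}")
    return 2.0 * beta**2 * eaf * (1.0 - eaf)


def f_statistic(r2: float, n: int, k: int = 1) -> float:
    """F = (R^2/k) / ((1 - R^2) / (n - k - 1))."""
    if not 0.0 <= r2 < 1.0:
        raise ValueError(f"r2 must be in [0, 1), got {r2}")
    if n <= k + 1:
        raise ValueError(f"need n > k + 1, got n={n}, k={k}")
    return (r2 / k) / ((1.0 - r2) / (n - k - 1))


def select_cis_pqtl(
    sumstats: SummaryStatsTable,
    gene: GeneAnnotation,
    window: int = CIS_WINDOW_BP,
    p_threshold: float = 5e-8,
) -> list[Instrument]:
    """Variants within ``window`` of the TSS passing ``p_threshold``, ranked
    by p-value (position breaks ties, making the output invariant to input
    row order). Records without eaf are ineligible for R^2/F and are skipped
    with a logged count. A gene on another chromosome yields an empty list.
    """
    if len(sumstats) == 0:
        raise ValueError("sumstats is empty")
    df = sumstats.df
    hits = df[
        (df["chr"] == gene.chr)
        & ((df["pos"] - gene.tss).abs() <= window)
        & (df["pval"] <= p_threshold)
    ]
    no_eaf = int(hits["eaf"].isna().sum())
    if no_eaf:
        logger.warning(
            "%s: %d candidate cis-pQTL(s) lack eaf and are ineligible", gene.gene, no_eaf
        )
        hits = hits[hits["eaf"].notna()]
    hits = hits.sort_values(["pval", "pos"], kind="mergesort")
    out = []
    for _, row in hits.iterrows():
        r2 = variance_explained(float(row["beta"]), float(row["eaf"]))
        out.append(
            Instrument(
                snp=str(row["snp"]),
                gene=gene.gene,
                distance_to_tss=int(row["pos"]) - gene.tss,
                exposure=sumstats.record(str(row["snp"])),
                r2=r2,
                f_stat=f_statistic(r2, int(row["n"])),
            )
        )
    return out


def find_proxy(
    snp: str,
    ld: LDMatrix,
    candidates: SummaryStatsTable,
    r2_threshold: float = 0.8,
) -> str | None:
    """Best LD proxy for ``snp`` among ``candidates``: highest squared
    correlation strictly above ``r2_threshold``; ties broken by smaller
    candidate p-value, then by position. None when no candidate qualifies.
    """
    i = ld.index(snp)  # raises KeyError when snp absent
    rows = []
    cdf = candidates.df.set_index("snp")
    for cand in candidates.snps:
        if cand == snp or cand not in ld:
            continue
        r2 = float(ld.r[i, ld.index(cand)] ** 2)
        if r2 > r2_threshold:
            rows.append((cand, r2, float(cdf.loc[cand, "pval"]), int(cdf.loc[cand, "pos"])))
    if not rows:
        return None
    rows.sort(key=lambda t: (-t[1], t[2], t[3]))
    return rows[0][0]


def clump(
    sumstats: SummaryStatsTable,
    ld: LDMatrix,
    p_threshold: float = 5e-8,
    r2_threshold: float = 0.001,
) -> list[str]:
    """Greedy LD clumping: repeatedly keep the smallest-p remaining
    significant SNP and discard every remaining SNP with squared correlation
    >= ``r2_threshold`` to it. The retained set is mutually quasi-independent
    by construction.
    """
    df = sumstats.df
    sig = df[df["pval"] <= p_threshold].sort_values(["pval", "pos"], kind="mergesort")
    remaining = [s for s in sig["snp"] if s in ld]
    kept: list[str] = []
    while remaining:
        lead = remaining.pop(0)
        kept.append(lead)
        i = ld.index(lead)
        remaining = [s for s in remaining if ld.r[i, ld.index(s)] ** 2 < r2_threshold]
    return kept


def write_instruments(instruments: list[Instrument], path: str | Path) -> None:
    """Export as TSV: gene, snp, pos, distance_to_tss, beta, se, pval, eaf,
    r2, f_stat, is_proxy."""
    rows = [
        {
            "gene": iv.gene,
            "snp": iv.snp,
            "pos": iv.exposure.pos,
            "distance_to_tss": iv.distance_to_tss,
            "beta": iv.exposure.beta,
            "se": iv.exposure.se,
            "pval": iv.exposure.pval,
            "eaf": iv.exposure.eaf,
            "r2": iv.r2,
            "f_stat": iv.f_stat,
            "is_proxy": iv.is_proxy,
        }
        for iv in instruments
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.8g")
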