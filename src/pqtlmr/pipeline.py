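"""Study-design orchestration over many protein-outcome pairs.

Runs the forward screen (per protein: cis-pQTL selection with proxy
fallback, Wald MR against the outcome, Bonferroni control at alpha / number
of proteins tested, Steiger directionality, then colocalization for
MR-significant proteins) and the reverse MR (outcome as exposure: clump the
outcome GWAS, then IVW / Egger / weighted-median / weighted-mode against
each protein). All outputs are TSV/JSON under a run directory with a
manifest; reruns with the same config and seed are byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import coloc as coloc_mod
from . import instruments as iv_mod
from . import mr as mr_mod
from .simulate import SimConfig, simulate_instrument_panel, simulate_region

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Thresholds, priors, synthetic-panel settings, and output location."""

    outdir: str = "pqtlmr_run"
    seed: int = 0
    # synthetic panel
    n_proteins: int = 20
    n_causal: int = 4
    sim: SimConfig = field(default_factory=SimConfig)
    # thresholds
    p_instrument: float = 5e-8
    proxy_r2: float = 0.8
    clump_r2: float = 0.001
    maf_min: float = 0.01
    window_bp: int = 1_000_000
    alpha: float = 0.05
    coloc_priors: tuple[float, float, float] = coloc_mod.DEFAULT_PRIORS
    coloc_h4_threshold: float = 0.8
    run_susie: bool = True
    # reverse MR: 172 genome-wide significant, LD-independent outcome
    # instruments (the menarche-timing GWAS count)
    reverse_n_instruments: int = 172
    reverse_theta: float = 0.4

    def validate(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        for name in ("p_instrument", "maf_min"):
            if not 0 < getattr(self, name) < 1:
                raise ValueError(f"{name} must be in (0, 1)")
        if not 0 < self.proxy_r2 <= 1 or not 0 <= self.clump_r2 <= 1:
            raise ValueError("proxy_r2 in (0, 1], clump_r2 in [0, 1] required")
        if self.n_proteins < 1 or self.n_causal < 0 or self.n_causal > self.n_proteins:
            raise ValueError("need 0 <= n_causal <= n_proteins, n_proteins >= 1")
        self.sim.validate()

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        sim = d.pop("sim", {})
        if "maf_range" in sim:
            sim["maf_range"] = tuple(sim["maf_range"])
        if sim.get("ld_blocks") is not None:
            sim["ld_blocks"] = [tuple(b) for b in sim["ld_blocks"]]
        d["sim"] = SimConfig(**sim)
        if "coloc_priors" in d:
            d["coloc_priors"] = tuple(d["coloc_priors"])
        return cls(**d)


def _protein_configs(config: RunConfig) -> list[SimConfig]:
    """One SimConfig per protein; the first ``n_causal`` are truly causal,
    the rest carry a cis-pQTL but no outcome effect (theta = 0 is encoded
    as a shared_causal with zero effect via the null outcome path)."""
    rng = np.random.default_rng(config.seed)
    out = []
    for i in range(config.n_proteins):
        causal = i < config.n_causal
        sim = dataclasses.replace(
            config.sim,
            causal_model="shared_causal",
            theta=config.sim.theta if causal else 0.0,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        out.append(sim)
    return out


def run_forward_screen(config: RunConfig) -> dict:
    """Forward proteome-wide screen on a synthetic protein panel.

    Returns the summary dict and writes ``screen_results.tsv``,
    ``screen_summary.json``, ``config.yaml``, and ``manifest.json`` under
    ``config.outdir``. Per-protein failures are logged and skipped.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    m = config.n_proteins
    threshold = mr_mod.bonferroni_threshold(m, config.alpha)

    rows = []
    n_instrumented = 0
    for i, sim in enumerate(_protein_configs(config)):
        protein = f"P{i + 1:03d}"
        try:
            region = simulate_region(sim)
            ivs = iv_mod.select_cis_pqtl(
                region.tables["exposure"], region.gene,
                window=config.window_bp, p_threshold=config.p_instrument,
            )
            if not ivs:
                rows.append({"protein": protein, "stage": "no_instrument"})
                continue
            best = ivs[0]
            n_instrumented += 1
            outcome_tab = region.tables["outcome"]
            snp = best.snp
            is_proxy = False
            if snp not in outcome_tab.snps:
                proxy = iv_mod.find_proxy(
                    snp, region.ld, outcome_tab, r2_threshold=config.proxy_r2
                )
                if proxy is None:
                    rows.append({"protein": protein, "stage": "no_outcome_match"})
                    continue
                snp, is_proxy = proxy, True
            h = mr_mod.harmonize(
                region.tables["exposure"].subset([snp]), outcome_tab.subset([snp])
            )
            row = h.df.iloc[0]
            res = mr_mod.wald_ratio(row)
            st = mr_mod.steiger(row)
            significant = res.pval <= threshold
            rec = {
                "protein": protein,
                "stage": "tested",
                "snp": snp,
                "is_proxy": is_proxy,
                "f_stat": best.f_stat,
                "r2": best.r2,
                "beta": res.beta,
                "se": res.se,
                "pval": res.pval,
                "passes_bonferroni": significant,
                "steiger_true": st.direction_true,
                "truly_causal": bool(region.truth["theta"] != 0),
            }
            if significant:
                cres = coloc_mod.coloc_abf(
                    region.tables["exposure"], outcome_tab,
                    priors=config.coloc_priors, maf_min=config.maf_min,
                    window=config.window_bp, center_pos=best.exposure.pos,
                )
                rec["pp_h4"] = cres["h4"]
                rec["coloc_argmax"] = cres.argmax
                if config.run_susie:
                    z_exp = (
                        region.tables["exposure"].df["beta"]
                        / region.tables["exposure"].df["se"]
                    ).to_numpy()
                    z_out = (outcome_tab.df["beta"] / outcome_tab.df["se"]).to_numpy()
                    f_exp = coloc_mod.susie_rss(z_exp, region.ld, sim.n_exposure, L=5)
                    f_out = coloc_mod.susie_rss(z_out, region.ld, sim.n_outcome, L=5)
                    pairs = coloc_mod.coloc_susie(f_exp, f_out, priors=config.coloc_priors)
                    rec["susie_max_h4"] = max((p["h4"] for p in pairs), default=float("nan"))
            rows.append(rec)
        except Exception as exc:  # failure isolation: never fatal to the screen
            logger.exception("protein %s failed: %s", protein, exc)
            rows.append({"protein": protein, "stage": "error", "error": str(exc)})

    results = pd.DataFrame(rows)
    n_tested = int((results.get("stage") == "tested").sum())
    n_sig = int(results.get("passes_bonferroni", pd.Series(dtype=bool)).fillna(False).sum())
    coloc_col = results.get("pp_h4", pd.Series(dtype=float))
    n_coloc_tested = int(coloc_col.notna().sum()) if len(coloc_col) else 0
    n_coloc = (
        int((coloc_col >= config.coloc_h4_threshold).sum()) if len(coloc_col) else 0
    )
    summary = {
        "n_proteins": m,
        "bonferroni_threshold": threshold,
        "n_instrumented": n_instrumented,
        "n_tested": n_tested,
        "n_significant": n_sig,
        "n_coloc_tested": n_coloc_tested,
        "n_colocalizing": n_coloc,
    }
    results.to_csv(outdir / "screen_results.tsv", sep="\t", index=False, float_format="%.6g")
    (outdir / "screen_summary.json").write_text(json.dumps(summary, indent=2) + "\n")
    config.to_yaml(outdir / "config.yaml")
    manifest = {
        "outputs": ["screen_results.tsv", "screen_summary.json", "config.yaml"],
        "seed": config.seed,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return summary


def run_reverse_mr(config: RunConfig) -> pd.DataFrame:
    """Reverse MR: outcome (AAM/ANM) as exposure, protein level as outcome.

    Simulates a genome-wide set of independent outcome instruments whose
    protein effects follow a reverse-causal model with effect
    ``reverse_theta``, then runs IVW, MR-Egger, weighted median and
    weighted mode, tabulating which methods reach nominal significance.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    panel = simulate_instrument_panel(
        n_snps=config.reverse_n_instruments,
        n_exposure=config.sim.n_outcome,  # outcome GWAS instruments the exposure here
        n_outcome=config.sim.n_exposure,
        theta=config.reverse_theta,
        r2_per_snp=(0.0002, 0.001),  # ~10% total variance across 172 SNPs
        seed=config.seed,
    )
    h = mr_mod.HarmonizedSet("outcome", "protein", panel)
    methods = {
        "ivw": mr_mod.ivw(h),
        "egger": mr_mod.mr_egger(h),
        "weighted_median": mr_mod.weighted_median(h),
        "weighted_mode": mr_mod.weighted_mode(h),
    }
    rows = [
        {
            "method": name,
            "beta": res.beta,
            "se": res.se,
            "pval": res.pval,
            "nominally_significant": res.pval < 0.05,
        }
        for name, res in methods.items()
    ]
    df = pd.DataFrame(rows)
    df.to_csv(outdir / "reverse_mr.tsv", sep="\t", index=False, float_format="%.6g")
    return df
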