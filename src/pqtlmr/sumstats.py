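"""GWAS summary-statistic containers, IO, and allele harmonization.

Core record types shared by every stage: per-variant association records
(:class:`VariantRecord`), per-trait tables (:class:`SummaryStatsTable`), a
signed LD correlation matrix (:class:`LDMatrix`), and gene annotations with
transcription start sites (:class:`GeneAnnotation`).

Tables are plain tab-delimited text with a fixed header; the LD matrix is a
plain-text square matrix plus a one-column SNP-list sidecar.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SUMSTATS_COLUMNS = ["snp", "chr", "pos", "ea", "nea", "eaf", "beta", "se", "pval", "n"]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: Effect-allele-frequency band in which a palindromic (A/T or C/G) variant
#: cannot be strand-resolved from frequency alone.
PALINDROMIC_AMBIGUITY_BAND = (0.42, 0.58)


class SumstatsError(ValueError):
    """Malformed or inconsistent summary-statistics input."""


class AlleleMismatchError(SumstatsError):
    """Two records for the same SNP carry incompatible allele pairs."""


@dataclass
class VariantRecord:
    """One variant's association record for a single trait.

    ``beta`` is the per-allele effect of ``ea`` in trait units; ``eaf`` is
    the effect-allele frequency. ``eaf`` may be NaN on input, in which case
    the record is ineligible for R², Steiger, and colocalization.
    """

    snp: str
    chr: str
    pos: int
    ea: str
    nea: str
    eaf: float
    beta: float
    se: float
    pval: float
    n: int
    ambiguous: bool = field(default=False, compare=False)

    def is_valid(self) -> bool:
        eaf_ok = np.isnan(self.eaf) or 0.0 < self.eaf < 1.0
        return (
            self.se > 0
            and eaf_ok
            and self.ea != self.nea
            and 0.0 < self.pval <= 1.0
            and self.pos >= 1
            and self.n > 0
        )


@dataclass
class SummaryStatsTable:
    """Ordered variant-level records for one trait, backed by a DataFrame."""

    trait: str
    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in SUMSTATS_COLUMNS if c not in self.df.columns]
        if missing:
            raise SumstatsError(f"summary-stats table missing columns: {missing}")
        dup = self.df["snp"][self.df["snp"].duplicated()].tolist()
        if dup:
            raise SumstatsError(f"duplicated snp identifiers: {sorted(set(dup))}")
        self.df = self.df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def snps(self) -> list[str]:
        return self.df["snp"].tolist()

    def record(self, snp: str) -> VariantRecord:
        rows = self.df[self.df["snp"] == snp]
        if rows.empty:
            raise KeyError(snp)
        return _row_to_record(rows.iloc[0])

    def records(self) -> Iterator[VariantRecord]:
        for _, row in self.df.iterrows():
            yield _row_to_record(row)

    def subset(self, snps: Sequence[str]) -> "SummaryStatsTable":
        """Rows for ``snps``, in the order given (missing ids are skipped)."""
        idx = self.df.set_index("snp")
        keep = [s for s in snps if s in idx.index]
        return SummaryStatsTable(self.trait, idx.loc[keep].reset_index())

    def write(self, path: str | Path) -> None:
        out = self.df.copy()
        out["trait"] = self.trait
        out.to_csv(path, sep="\t", index=False, float_format="%.8g")


def _row_to_record(row: pd.Series) -> VariantRecord:
    return VariantRecord(
        snp=str(row["snp"]),
        chr=str(row["chr"]),
        pos=int(row["pos"]),
        ea=str(row["ea"]),
        nea=str(row["nea"]),
        eaf=float(row["eaf"]),
        beta=float(row["beta"]),
        se=float(row["se"]),
        pval=float(row["pval"]),
        n=int(row["n"]),
    )


def read_sumstats(
    path: str | Path,
    trait: str | None = None,
    column_map: Mapping[str, str] | None = None,
) -> SummaryStatsTable:
    """Read a tab-delimited summary-stats file, dropping invalid rows.

    Parameters
    ----------
    path
        Tab-delimited file with a header row.
    trait
        Trait label; defaults to a ``trait`` column if present, else the
        file stem.
    column_map
        Optional mapping from the canonical column names (``snp``, ``chr``,
        ``pos``, ``ea``, ``nea``, ``eaf``, ``beta``, ``se``, ``pval``, ``n``)
        to the names used in the file.

    Rows violating the record invariants (se <= 0, eaf outside (0,1),
    p outside (0,1], identical alleles) are dropped with a logged count.
    Missing eaf is kept as NaN. Raises :class:`SumstatsError` on missing
    mandatory columns, duplicated SNP ids, or an empty table after filtering.
    """
    path = Path(path)
    raw = pd.read_csv(path, sep="\t", dtype={"chr": str})
    if column_map:
        raw = raw.rename(columns={v: k for k, v in column_map.items()})
    missing = [c for c in SUMSTATS_COLUMNS if c not in raw.columns]
    if missing:
        raise SumstatsError(f"{path}: missing mandatory column(s) {missing}")
    if trait is None:
        trait = str(raw["trait"].iloc[0]) if "trait" in raw.columns and len(raw) else path.stem

    df = raw[SUMSTATS_COLUMNS].copy()
    df["chr"] = df["chr"].astype(str)
    for col in ("pos", "n"):
        df[col] = df[col].astype(int)
    for col in ("eaf", "beta", "se", "pval"):
        df[col] = df[col].astype(float)

    eaf_ok = df["eaf"].isna() | ((df["eaf"] > 0) & (df["eaf"] < 1))
    ok = (
        (df["se"] > 0)
        & eaf_ok
        & (df["ea"] != df["nea"])
        & (df["pval"] > 0)
        & (df["pval"] <= 1)
        & (df["pos"] >= 1)
        & (df["n"] > 0)
    )
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.warning("%s: dropped %d row(s) violating record invariants", path, n_dropped)
    df = df[ok]
    if df.empty:
        raise SumstatsError(f"{path}: no valid rows after filtering")
    return SummaryStatsTable(trait, df.reset_index(drop=True))


@dataclass
class LDMatrix:
    """Signed LD correlation matrix aligned to an ordered SNP list."""

    snps: list[str]
    r: np.ndarray

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        p = len(self.snps)
        if self.r.shape != (p, p):
            raise SumstatsError(f"LD matrix shape {self.r.shape} != ({p}, {p})")
        if not np.allclose(self.r, self.r.T, atol=1e-8):
            raise SumstatsError("LD matrix is not symmetric")
        if not np.allclose(np.diag(self.r), 1.0, atol=1e-8):
            raise SumstatsError("LD matrix diagonal is not 1")
        if np.any(np.abs(self.r) > 1 + 1e-8):
            raise SumstatsError("LD entries outside [-1, 1]")
        if p and np.linalg.eigvalsh(self.r)[0] < -1e-8:
            raise SumstatsError("LD matrix is not positive semi-definite")
        self._index = {s: i for i, s in enumerate(self.snps)}

    def index(self, snp: str) -> int:
        try:
            return self._index[snp]
        except KeyError:
            raise KeyError(f"snp {snp!r} not in LD matrix") from None

    def __contains__(self, snp: str) -> bool:
        return snp in self._index

    def subset(self, snps: Sequence[str]) -> "LDMatrix":
        idx = [self.index(s) for s in snps]
        return LDMatrix(list(snps), self.r[np.ix_(idx, idx)])

    def write(self, matrix_path: str | Path, snplist_path: str | Path) -> None:
        np.savetxt(matrix_path, self.r, fmt="%.8g")
        Path(snplist_path).write_text("\n".join(self.snps) + "\n")

    @classmethod
    def read(cls, matrix_path: str | Path, snplist_path: str | Path) -> "LDMatrix":
        snps = Path(snplist_path).read_text().split()
        r = np.loadtxt(matrix_path, ndmin=2)
        return cls(snps, r)


@dataclass(frozen=True)
class GeneAnnotation:
    """Gene identifier with chromosome and transcription start site (1-based)."""

    gene: str
    chr: str
    tss: int

    def __post_init__(self) -> None:
        if self.tss < 1:
            raise SumstatsError(f"{self.gene}: tss must be >= 1")


def read_gene_annotations(path: str | Path) -> list[GeneAnnotation]:
    """Read a 3-column TSV (gene, chr, tss)."""
    df = pd.read_csv(path, sep="\t", dtype={"chr": str})
    return [GeneAnnotation(str(r["gene"]), str(r["chr"]), int(r["tss"])) for _, r in df.iterrows()]


def is_palindromic(ea: str, nea: str) -> bool:
    """True for A/T and C/G variants, whose strand cannot be told from alleles."""
    return _COMPLEMENT.get(ea.upper()) == nea.upper()


def align_alleles(
    a: VariantRecord,
    b: VariantRecord,
    ambiguity_band: tuple[float, float] = PALINDROMIC_AMBIGUITY_BAND,
) -> VariantRecord:
    """Re-express ``b`` on ``a``'s effect allele.

    Handles swapped alleles (flip beta sign, eaf -> 1 - eaf), strand flips
    (complement alleles, then compare), and palindromic variants, which are
    resolved by allele frequency: if either trait's eaf falls inside
    ``ambiguity_band`` the returned record carries ``ambiguous=True``;
    otherwise eaf sides of 0.5 decide the orientation. Idempotent on an
    already-aligned record. Raises :class:`AlleleMismatchError` for
    incompatible allele pairs.
    """
    if a.snp != b.snp:
        raise SumstatsError(f"cannot align different snps {a.snp!r} vs {b.snp!r}")
    ea_a, nea_a = a.ea.upper(), a.nea.upper()
    ea_b, nea_b = b.ea.upper(), b.nea.upper()

    if is_palindromic(ea_a, nea_a):
        if {ea_b, nea_b} != {ea_a, nea_a}:
            raise AlleleMismatchError(
                f"{a.snp}: alleles {ea_b}/{nea_b} incompatible with {ea_a}/{nea_a}"
            )
        lo, hi = ambiguity_band
        in_band = lambda f: np.isnan(f) or lo <= f <= hi  # noqa: E731
        if in_band(a.eaf) or in_band(b.eaf):
            return replace(b, ambiguous=True)
        # Same allele label: frequencies on the same side of 0.5 mean same
        # strand; opposite sides mean the labels refer to opposite strands.
        same_side = (a.eaf > 0.5) == (b.eaf > 0.5)
        if ea_b == ea_a:
            return replace(b) if same_side else _flip(b, ea_a, nea_a)
        # b's effect allele is labelled as a's other allele: a matching
        # frequency side implies the labels sit on opposite strands (same
        # physical allele, no flip); a mismatching side implies a true swap.
        return replace(b, ea=ea_a, nea=nea_a) if same_side else _flip(b, ea_a, nea_a)

    comp = {allele: _COMPLEMENT.get(allele, allele) for allele in (ea_b, nea_b)}
    if (ea_b, nea_b) == (ea_a, nea_a):
        return replace(b)
    if (ea_b, nea_b) == (nea_a, ea_a):
        return _flip(b, ea_a, nea_a)
    if (comp[ea_b], comp[nea_b]) == (ea_a, nea_a):
        return replace(b, ea=ea_a, nea=nea_a)
    if (comp[ea_b], comp[nea_b]) == (nea_a, ea_a):
        return _flip(b, ea_a, nea_a)
    raise AlleleMismatchError(
        f"{a.snp}: alleles {ea_b}/{nea_b} incompatible with {ea_a}/{nea_a}"
    )


def _flip(b: VariantRecord, ea: str, nea: str) -> VariantRecord:
    eaf = 1.0 - b.eaf if not np.isnan(b.eaf) else b.eaf
    return replace(b, ea=ea, nea=nea, beta=-b.beta, eaf=eaf)
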