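"""Reading, validation, harmonization, and QC of cis-region GWAS summary statistics.

Two datasets are compared per protein, so everything downstream assumes a
single aligned variant universe: same variants, same effect alleles, same
orientation of betas and allele frequencies. This module owns that contract.

Conventions: coordinates are 1-based inclusive; a variant is identified by
(chrom, pos, unordered allele pair); the effect allele is ``a1`` and betas
are per copy of ``a1``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats as sps

log = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGT")
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: default column names of the on-disk tab-delimited dialect
DEFAULT_COLUMNS = {
    "chrom": "CHR",
    "pos": "POS",
    "a1": "A1",
    "a2": "A2",
    "eaf": "EAF",
    "beta": "BETA",
    "se": "SE",
    "p": "P",
    "n": "N",
}

REQUIRED_FIELDS = ("chrom", "pos", "a1", "a2", "eaf", "beta", "se", "p", "n")


class AssocError(ValueError):
    """Malformed or internally inconsistent summary statistics."""


class VariantKey(NamedTuple):
    """Variant identity: chromosome, 1-based position, effect/other allele."""

    chrom: str
    pos: int
    a1: str
    a2: str

    def unordered(self) -> tuple[str, int, str, str]:
        """Order-free identity used for cross-dataset matching."""
        lo, hi = sorted((self.a1, self.a2))
        return (self.chrom, int(self.pos), lo, hi)

    def is_palindromic(self) -> bool:
        return _COMPLEMENT[self.a1] == self.a2

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.chrom}:{self.pos}:{self.a1}:{self.a2}"


@dataclass
class LocusSumStats:
    """Per-protein cis-region association table for one trait.

    ``df`` columns: chrom, pos, a1, a2, eaf, beta, se, p, n — one row per
    variant, sorted by position. Gene-body coordinates anchor the cis window.
    """

    protein_id: str
    chrom: str
    gene_start: int
    gene_end: int
    df: pd.DataFrame = field(repr=False)

    def __len__(self) -> int:
        return len(self.df)

    def keys(self) -> list[VariantKey]:
        return [
            VariantKey(c, int(p), a1, a2)
            for c, p, a1, a2 in zip(
                self.df["chrom"], self.df["pos"], self.df["a1"], self.df["a2"]
            )
        ]

    def min_p(self) -> float:
        return float(self.df["p"].min()) if len(self.df) else math.inf

    def with_df(self, df: pd.DataFrame) -> "LocusSumStats":
        return replace(self, df=df.reset_index(drop=True))


def _validate_records(df: pd.DataFrame, origin: str) -> pd.DataFrame:
    """Normalize and validate a raw record table; drop bad rows with logging."""
    n0 = len(df)
    df = df.dropna(subset=["beta", "se", "eaf"])
    if len(df) < n0:
        log.warning("%s: dropped %d rows with missing beta/se/eaf", origin, n0 - len(df))

    df = df.copy()
    df["a1"] = df["a1"].astype(str).str.upper()
    df["a2"] = df["a2"].astype(str).str.upper()

    ok_alleles = (
        df["a1"].isin(VALID_BASES) & df["a2"].isin(VALID_BASES) & (df["a1"] != df["a2"])
    )
    if (~ok_alleles).any():
        log.warning("%s: dropped %d rows with invalid alleles", origin, int((~ok_alleles).sum()))
        df = df[ok_alleles]

    bad = (df["se"] <= 0) | (df["eaf"] <= 0) | (df["eaf"] >= 1) | (df["p"] <= 0) | (df["p"] > 1)
    if bad.any():
        log.warning("%s: dropped %d rows violating se>0 / eaf in (0,1) / p in (0,1]", origin, int(bad.sum()))
        df = df[~bad]

    df = df.astype({"pos": int, "eaf": float, "beta": float, "se": float, "p": float})
    df["chrom"] = df["chrom"].astype(str)

    keys = list(zip(df["chrom"], df["pos"], np.minimum(df["a1"], df["a2"]), np.maximum(df["a1"], df["a2"])))
    if len(set(keys)) != len(keys):
        raise AssocError(f"{origin}: duplicate variant keys present")

    # consistency warning only: |z| implied by p under the two-sided normal
    with np.errstate(divide="ignore"):
        z_obs = np.abs(df["beta"] / df["se"])
        z_p = np.abs(sps.norm.isf(np.clip(df["p"], 1e-300, 1.0) / 2))
    # skip rows where p underflows double precision — z cannot be recovered
    off = (np.abs(z_obs - z_p) > np.maximum(0.5, 0.1 * z_p)) & (df["p"] > 1e-290)
    if off.any():
        log.warning("%s: %d rows with beta/se inconsistent with p (kept)", origin, int(off.sum()))

    return df.sort_values("pos", kind="mergesort").reset_index(drop=True)


def read_sumstats(
    path,
    column_map: dict[str, str] | None = None,
    *,
    protein_id: str = "",
    gene_start: int = 0,
    gene_end: int = 0,
) -> LocusSumStats:
    """Read a tab-delimited summary-statistics file into a validated locus table.

    ``column_map`` maps internal field names (chrom, pos, a1, ...) to the
    file's header names; unmapped fields use :data:`DEFAULT_COLUMNS`.
    Duplicate variant keys raise :class:`AssocError` rather than being
    silently deduplicated.
    """
    cmap = dict(DEFAULT_COLUMNS)
    if column_map:
        cmap.update(column_map)
    raw = pd.read_csv(path, sep="\t")
    missing = [cmap[f] for f in REQUIRED_FIELDS if cmap[f] not in raw.columns]
    if missing:
        raise AssocError(f"{path}: missing required columns {missing}")
    df = raw.rename(columns={v: k for k, v in cmap.items()})[list(REQUIRED_FIELDS)]
    df = _validate_records(df, str(path))
    chroms = df["chrom"].unique()
    if len(chroms) > 1:
        raise AssocError(f"{path}: records span multiple chromosomes: {list(chroms)}")
    chrom = chroms[0] if len(chroms) else ""
    return LocusSumStats(protein_id, chrom, int(gene_start), int(gene_end), df)


def write_sumstats(stats: LocusSumStats, path, column_map: dict[str, str] | None = None) -> None:
    """Write a locus table back to the tab-delimited dialect (17 sig. digits)."""
    cmap = dict(DEFAULT_COLUMNS)
    if column_map:
        cmap.update(column_map)
    out = stats.df[list(REQUIRED_FIELDS)].rename(columns=cmap)
    out.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_gene_bed(path) -> dict[str, tuple[str, int, int]]:
    """Read a 4-column BED (chrom, start, end, gene_id).

    BED is half-open zero-based on disk; returned coordinates are 1-based
    inclusive gene-body bounds.
    """
    genes: dict[str, tuple[str, int, int]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end, gene_id = line.split("\t")[:4]
            genes[gene_id] = (chrom, int(start) + 1, int(end))
    return genes


def filter_cis(stats: LocusSumStats, window: int = 500_000) -> LocusSumStats:
    """Keep variants within ``window`` bp of the gene body, boundaries inclusive."""
    lo = stats.gene_start - window
    hi = stats.gene_end + window
    keep = (stats.df["pos"] >= lo) & (stats.df["pos"] <= hi)
    return stats.with_df(stats.df[keep])


def apply_qc(stats: LocusSumStats, maf_min: float = 0.05) -> LocusSumStats:
    """Keep variants with minor allele frequency strictly above ``maf_min``."""
    maf = np.minimum(stats.df["eaf"], 1.0 - stats.df["eaf"])
    return stats.with_df(stats.df[maf > maf_min])


def locus_eligible(a: LocusSumStats, b: LocusSumStats, p_thresh: float = 5e-8) -> bool:
    """True iff both traits reach genome-wide significance at the locus (strict)."""
    return a.min_p() < p_thresh and b.min_p() < p_thresh


def _flip_row(row: pd.Series) -> pd.Series:
    row = row.copy()
    row["a1"], row["a2"] = row["a2"], row["a1"]
    row["beta"] = -row["beta"]
    row["eaf"] = 1.0 - row["eaf"]
    return row


def harmonize_pair(
    a: LocusSumStats,
    b: LocusSumStats,
    *,
    palindrome_eaf_band: tuple[float, float] = (0.40, 0.60),
) -> tuple[LocusSumStats, LocusSumStats]:
    """Intersect two loci on variant identity and orient ``b`` to ``a``'s alleles.

    Where ``b``'s alleles are swapped relative to ``a``, ``b``'s beta is
    negated and its eaf replaced by 1 − eaf. Palindromic (A/T, C/G) variants
    are oriented by allele frequency when informative — the minor-allele
    frequency is at most ``palindrome_eaf_band[0]`` in both datasets — and
    dropped otherwise. Outputs are index-aligned.
    """
    if a.chrom != b.chrom:
        raise AssocError(f"chromosome mismatch: {a.chrom} vs {b.chrom}")
    lo_band, hi_band = palindrome_eaf_band

    b_index: dict[tuple, int] = {}
    for i, k in enumerate(b.keys()):
        b_index[k.unordered()] = i

    rows_a, rows_b = [], []
    n_pal_dropped = 0
    for i, ka in enumerate(a.keys()):
        j = b_index.get(ka.unordered())
        if j is None:
            continue
        ra = a.df.iloc[i]
        rb = b.df.iloc[j]
        if ka.is_palindromic():
            ea, eb = float(ra["eaf"]), float(rb["eaf"])
            if lo_band < ea < hi_band or lo_band < eb < hi_band:
                n_pal_dropped += 1
                continue
            # orient by frequency: minor sides must agree
            same_orientation = (ea < 0.5) == (eb < 0.5)
            rb = rb.copy() if same_orientation else _flip_row(rb)
            # strandless identity: relabel to a's allele order either way
            rb["a1"], rb["a2"] = ka.a1, ka.a2
        else:
            if (rb["a1"], rb["a2"]) == (ka.a1, ka.a2):
                pass
            elif (rb["a2"], rb["a1"]) == (ka.a1, ka.a2):
                rb = _flip_row(rb)
            else:  # pragma: no cover - unordered key match precludes this
                continue
        rows_a.append(ra)
        rows_b.append(rb)

    if n_pal_dropped:
        log.info("harmonize_pair: dropped %d unresolvable palindromic variants", n_pal_dropped)

    cols = list(REQUIRED_FIELDS)
    df_a = pd.DataFrame(rows_a, columns=cols).reset_index(drop=True) if rows_a else a.df.iloc[0:0]
    df_b = pd.DataFrame(rows_b, columns=cols).reset_index(drop=True) if rows_b else b.df.iloc[0:0]
    return a.with_df(df_a), b.with_df(df_b)
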