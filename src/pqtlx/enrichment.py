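"""Tissue-specific expression enrichment from a gene×sample read-count matrix.

Counts are filtered for detection, normalized between samples by the trimmed
mean of M-values (TMM), summarized as per-tissue medians, and converted to
enrichment z-scores by two rounds of robust standardization: first across
genes within each tissue, then across tissues within each gene (median /
1.4826·MAD both times). A gene is "elevated" in a tissue when z > 2
(strict). Chi-squared contrasts then ask, per tissue, whether elevated
expression is more or less common among genes whose pQTLs colocalized.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

log = logging.getLogger(__name__)

MAD_SCALE = 1.4826  # normal-consistency constant


@dataclass
class CountMatrix:
    """Gene×sample non-negative integer read counts with tissue labels."""

    genes: list[str]
    samples: list[str]
    tissue_of: dict[str, str]
    counts: np.ndarray = field(repr=False)

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.genes), len(self.samples)):
            raise ValueError("count matrix shape does not match genes×samples")
        if self.counts.size and self.counts.min() < 0:
            raise ValueError("counts must be non-negative")
        missing = [s for s in self.samples if s not in self.tissue_of]
        if missing:
            raise ValueError(f"samples without tissue label: {missing[:5]}")

    @property
    def tissues(self) -> list[str]:
        seen = []
        for s in self.samples:
            t = self.tissue_of[s]
            if t not in seen:
                seen.append(t)
        return seen

    @classmethod
    def from_tsv(cls, counts_path, tissues_path) -> "CountMatrix":
        df = pd.read_csv(counts_path, sep="\t", index_col=0)
        tmap = pd.read_csv(tissues_path, sep="\t", index_col=0).iloc[:, 0].to_dict()
        return cls(
            [str(g) for g in df.index],
            [str(s) for s in df.columns],
            {str(k): str(v) for k, v in tmap.items()},
            df.to_numpy(),
        )


def filter_genes(m: CountMatrix, min_count: int = 5, min_frac: float = 0.20) -> CountMatrix:
    """Keep genes with >= min_count reads in >= min_frac of all samples (inclusive)."""
    frac = (m.counts >= min_count).mean(axis=1)
    keep = frac >= min_frac
    return CountMatrix(
        [g for g, k in zip(m.genes, keep) if k], m.samples, m.tissue_of, m.counts[keep]
    )


def _quantile_ratio(counts: np.ndarray, p: float = 0.75) -> np.ndarray:
    lib = counts.sum(axis=0).astype(float)
    return np.quantile(counts, p, axis=0) / lib


def tmm_factors(
    m: CountMatrix,
    *,
    log_ratio_trim: float = 0.30,
    abs_expr_trim: float = 0.05,
    weighted: bool = True,
) -> np.ndarray:
    """Trimmed-mean-of-M-values scaling factors, geometric mean 1.

    The reference sample is the one whose 75th-percentile count over library
    size is closest to the mean of that quantity. For each sample vs the
    reference, over genes positive in both, M = log2 ratio of library-scaled
    counts and A = average log2 abundance; 30% of each M tail and 5% of each
    A tail are trimmed, and the factor is 2 to the (inverse-variance weighted)
    trimmed mean of M. Normalized expression downstream is
    counts / (library size × factor) × 1e6.
    """
    counts = m.counts.astype(float)
    lib = counts.sum(axis=0)
    if np.any(lib <= 0):
        raise ValueError("sample with zero library size")
    q = _quantile_ratio(counts)
    ref = int(np.argmin(np.abs(q - q.mean())))
    yr = counts[:, ref]
    Nr = lib[ref]

    factors = np.empty(counts.shape[1])
    for s in range(counts.shape[1]):
        ys, Ns = counts[:, s], lib[s]
        ok = (ys > 0) & (yr > 0)
        if not ok.any():
            factors[s] = 1.0
            continue
        ysn, yrn = ys[ok] / Ns, yr[ok] / Nr
        M = np.log2(ysn / yrn)
        A = 0.5 * (np.log2(ysn) + np.log2(yrn))
        if np.max(np.abs(M)) < 1e-6:
            factors[s] = 1.0
            continue
        n = M.size
        loM = np.floor(n * log_ratio_trim) + 1
        hiM = n + 1 - loM
        loA = np.floor(n * abs_expr_trim) + 1
        hiA = n + 1 - loA
        rM = sps.rankdata(M)
        rA = sps.rankdata(A)
        keep = (rM >= loM) & (rM <= hiM) & (rA >= loA) & (rA <= hiA)
        if not keep.any():
            factors[s] = 1.0
            continue
        if weighted:
            w = 1.0 / ((Ns - ys[ok]) / (Ns * ys[ok]) + (Nr - yr[ok]) / (Nr * yr[ok]))
            factors[s] = 2 ** (np.sum(w[keep] * M[keep]) / np.sum(w[keep]))
        else:
            factors[s] = 2 ** np.mean(M[keep])
    factors = factors / np.exp(np.mean(np.log(factors)))
    return factors


def cpm(m: CountMatrix, factors: np.ndarray) -> np.ndarray:
    """TMM-normalized counts-per-million: counts / (library size × factor) × 1e6."""
    lib = m.counts.sum(axis=0).astype(float)
    return m.counts / (lib * factors) * 1e6


def tissue_medians(m: CountMatrix, factors: np.ndarray) -> pd.DataFrame:
    """Per-gene, per-tissue median of TMM-normalized expression (genes×tissues)."""
    expr = cpm(m, factors)
    tissues = m.tissues
    labels = np.array([m.tissue_of[s] for s in m.samples])
    out = np.empty((len(m.genes), len(tissues)))
    for j, t in enumerate(tissues):
        sel = labels == t
        if not sel.any():
            raise ValueError(f"tissue {t!r} has no samples")
        out[:, j] = np.median(expr[:, sel], axis=1)
    return pd.DataFrame(out, index=m.genes, columns=tissues)


def _mad(x: np.ndarray, axis: int):
    med = np.median(x, axis=axis, keepdims=True)
    return np.median(np.abs(x - med), axis=axis), np.squeeze(med, axis=axis)


@dataclass
class EnrichmentMatrix:
    """Gene×tissue enrichment scores with elevated flags and exclusions."""

    genes: list[str]
    tissues: list[str]
    median_expr: pd.DataFrame = field(repr=False)
    stage1: pd.DataFrame = field(repr=False)
    z: pd.DataFrame = field(repr=False)
    elevated: pd.DataFrame = field(repr=False)
    excluded_genes: dict[str, str] = field(default_factory=dict)
    excluded_tissues: list[str] = field(default_factory=list)


def enrichment_z(med: pd.DataFrame, z_threshold: float = 2.0) -> EnrichmentMatrix:
    """Two-stage robust enrichment z-scores from gene×tissue medians.

    Stage 1 standardizes each tissue's column across genes by its median and
    scaled MAD; a tissue whose MAD is zero carries no ranking information and
    is excluded (error-level log). Stage 2 standardizes each gene's row of
    stage-1 scores across tissues the same way; genes with zero stage-2 MAD
    are excluded with a recorded reason. Elevated means z strictly above
    ``z_threshold``.
    """
    if med.shape[0] < 2 or med.shape[1] < 2:
        raise ValueError("need at least 2 genes and 2 tissues")
    x = med.to_numpy(dtype=float)

    mad1, med1 = _mad(x, axis=0)
    keep_t = mad1 > 0
    excluded_tissues = [t for t, k in zip(med.columns, keep_t) if not k]
    for t in excluded_tissues:
        log.error("enrichment_z: tissue %r has zero MAD across genes; excluded", t)
    x = x[:, keep_t]
    tissues = [t for t, k in zip(med.columns, keep_t) if k]
    if len(tissues) < 2:
        raise ValueError("fewer than 2 tissues remain after stage-1 MAD screen")
    s1 = (x - med1[keep_t]) / (MAD_SCALE * mad1[keep_t])

    mad2, med2 = _mad(s1, axis=1)
    keep_g = mad2 > 0
    excluded = {g: "stage-2 MAD = 0" for g, k in zip(med.index, keep_g) if not k}
    z = np.full_like(s1, np.nan)
    z[keep_g] = (s1[keep_g] - med2[keep_g, None]) / (MAD_SCALE * mad2[keep_g, None])

    genes = list(med.index)
    zdf = pd.DataFrame(z, index=genes, columns=tissues)
    s1df = pd.DataFrame(s1, index=genes, columns=tissues)
    elevated = (zdf > z_threshold).fillna(False)
    return EnrichmentMatrix(
        genes, tissues, med.loc[:, tissues], s1df, zdf, elevated, excluded, excluded_tissues
    )


@dataclass
class TissueContrast:
    tissue: str
    n_elevated_coloc: int
    n_total_coloc: int
    n_elevated_noncoloc: int
    n_total_noncoloc: int
    chi2: float | None
    p: float | None
    direction: str  # which group has the larger elevated proportion


def pearson_chi2_2x2(table: np.ndarray) -> tuple[float, float]:
    """Pearson chi-squared (df=1, no continuity correction) and two-sided p."""
    table = np.asarray(table, dtype=float)
    chi2, p, _, _ = sps.chi2_contingency(table, correction=False)
    return float(chi2), float(p)


def contrast_by_group(
    e: EnrichmentMatrix, group_of: dict[str, str], yates: bool = False
) -> list[TissueContrast]:
    """Per-tissue 2×2 chi-squared tests of elevated expression by coloc group.

    ``group_of`` maps gene -> 'coloc' or 'noncoloc'; unlabeled or excluded
    genes are ignored. Tissues with a zero marginal get chi2/p recorded as
    absent (None).
    """
    genes = [g for g in e.genes if g in group_of and g not in e.excluded_genes]
    if not genes:
        raise ValueError("no labeled, non-excluded genes")
    is_coloc = np.array([group_of[g] == "coloc" for g in genes])
    if is_coloc.all() or not is_coloc.any():
        raise ValueError("both groups must be nonempty")
    elev = e.elevated.loc[genes].to_numpy()

    out = []
    for j, t in enumerate(e.tissues):
        a = int(elev[is_coloc, j].sum())
        b = int(is_coloc.sum()) - a
        c = int(elev[~is_coloc, j].sum())
        d = int((~is_coloc).sum()) - c
        table = np.array([[a, b], [c, d]], dtype=float)
        chi2 = p = None
        if not (np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0)):
            res = sps.chi2_contingency(table, correction=yates)
            chi2, p = float(res[0]), float(res[1])
        pc = a / (a + b)
        pn = c / (c + d)
        direction = "coloc" if pc > pn else ("noncoloc" if pn > pc else "tie")
        out.append(TissueContrast(t, a, a + b, c, c + d, chi2, p, direction))
    return out
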