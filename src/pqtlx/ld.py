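"""Reference-panel genotypes and variant-variant LD matrices.

The colocalization stage conditions on selected variants using a Pearson
correlation matrix of allele dosages from a reference panel (the study design
mirrors an n = 5,000 external panel). Missing genotypes are mean-imputed per
variant rather than dropped pairwise, so the correlation matrix stays
consistent with a single completed data matrix (pairwise-complete estimates
need not be positive semidefinite).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from pqtlx.sumstats import VariantKey

log = logging.getLogger(__name__)


@dataclass
class GenotypePanel:
    """n×m ALT-allele dosage matrix with variant identities.

    ``keys[j].a1`` is the counted (ALT) allele of column j. ``missing_rate``
    records the per-variant fraction of genotypes that were mean-imputed.
    """

    samples: list[str]
    keys: list[VariantKey]
    dosages: np.ndarray = field(repr=False)
    missing_rate: np.ndarray = field(default=None, repr=False)

    def __post_init__(self):
        if self.missing_rate is None:
            self.missing_rate = np.zeros(len(self.keys))
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.samples), len(self.keys)):
            raise ValueError("dosage matrix shape does not match samples×variants")
        if self.dosages.size and (self.dosages.min() < 0 or self.dosages.max() > 2):
            raise ValueError("dosages must lie in [0, 2]")

    def index_of(self) -> dict[tuple, int]:
        return {k.unordered(): j for j, k in enumerate(self.keys)}


@dataclass
class LDMatrix:
    """Ordered variant keys and their Pearson dosage-correlation matrix."""

    keys: list[VariantKey]
    r: np.ndarray = field(repr=False)

    def __post_init__(self):
        self.r = np.asarray(self.r, dtype=float)

    def to_tsv(self, path) -> None:
        header = "\t".join(str(k) for k in self.keys)
        np.savetxt(path, self.r, delimiter="\t", header=header, comments="#", fmt="%.17g")

    @classmethod
    def from_tsv(cls, path) -> "LDMatrix":
        with open(path) as fh:
            header = fh.readline().lstrip("#").strip().split("\t")
        keys = []
        for tok in header:
            chrom, pos, a1, a2 = tok.split(":")
            keys.append(VariantKey(chrom, int(pos), a1, a2))
        r = np.loadtxt(path, delimiter="\t", skiprows=1, ndmin=2)
        return cls(keys, r)


def _parse_region(region: str) -> tuple[str, int, int]:
    chrom, span = region.split(":")
    start, end = span.split("-")
    return chrom, int(start), int(end)


def load_panel(path, region: str | None = None) -> GenotypePanel:
    """Load GT genotypes from a VCF into an ALT-dosage panel.

    ``region`` is ``chrom:start-end`` (1-based inclusive); filtering is done
    while streaming, so an uncompressed, unindexed VCF works. Multi-allelic
    records are skipped with a warning; missing genotypes are mean-imputed.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    want = _parse_region(region) if region else None

    keys: list[VariantKey] = []
    cols: list[np.ndarray] = []
    miss: list[float] = []
    n_multi = 0
    for v in vcf:
        if want is not None:
            chrom, start, end = want
            if v.CHROM != chrom or not (start <= v.POS <= end):
                continue
        if len(v.ALT) != 1:
            n_multi += 1
            continue
        gt = v.genotype.array()  # (n, ploidy+1); allele codes, -1 = missing
        alleles = gt[:, :2].astype(float)
        missing = alleles < 0
        dos = np.where(missing, np.nan, alleles).sum(axis=1)
        m_rate = float(np.isnan(dos).mean())
        if m_rate == 1.0:
            log.warning("load_panel: %s:%d fully missing, skipped", v.CHROM, v.POS)
            continue
        if m_rate > 0:
            dos = np.where(np.isnan(dos), np.nanmean(dos), dos)
        keys.append(VariantKey(str(v.CHROM), int(v.POS), str(v.ALT[0]).upper(), str(v.REF).upper()))
        cols.append(dos)
        miss.append(m_rate)
    if n_multi:
        log.warning("load_panel: skipped %d multi-allelic records", n_multi)
    if not keys:
        raise ValueError(f"{path}: no usable variants in region {region!r}")
    dosages = np.column_stack(cols)
    return GenotypePanel(samples, keys, dosages, np.array(miss))


def load_dosage_tsv(path) -> GenotypePanel:
    """Load a plain dosage table: header of ``chrom:pos:a1:a2`` keys, one row per sample.

    First column is the sample id.
    """
    import pandas as pd

    df = pd.read_csv(path, sep="\t", index_col=0)
    keys = []
    for tok in df.columns:
        chrom, pos, a1, a2 = tok.split(":")
        keys.append(VariantKey(chrom, int(pos), a1, a2))
    return GenotypePanel([str(s) for s in df.index], keys, df.to_numpy(dtype=float))


def compute_ld(panel: GenotypePanel, keys: list[VariantKey] | None = None) -> LDMatrix:
    """Pearson dosage correlations, oriented to the requested effect alleles.

    ``keys`` selects and orders variants by order-free identity; where the
    requested effect allele is the panel's other (REF) allele, the variant's
    row and column of r are sign-flipped so downstream conditioning never
    re-orients. Monomorphic variants are excluded with a warning.
    """
    if keys is None:
        keys = list(panel.keys)
    index = panel.index_of()
    cols, out_keys, signs = [], [], []
    for k in keys:
        j = index.get(k.unordered())
        if j is None:
            raise KeyError(f"variant {k} absent from panel")
        pk = panel.keys[j]
        sign = 1.0 if k.a1 == pk.a1 else -1.0
        col = panel.dosages[:, j]
        if np.std(col) == 0:
            log.warning("compute_ld: monomorphic variant %s excluded", k)
            continue
        cols.append(col)
        out_keys.append(k)
        signs.append(sign)
    if not cols:
        raise ValueError("no polymorphic variants among requested keys")
    x = np.column_stack(cols)
    r = np.corrcoef(x, rowvar=False)
    r = np.atleast_2d(r)
    s = np.array(signs)
    r = r * np.outer(s, s)
    r = (r + r.T) / 2.0
    np.fill_diagonal(r, 1.0)
    return LDMatrix(out_keys, r)
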