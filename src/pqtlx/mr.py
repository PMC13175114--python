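"""Two-sample Mendelian randomization with colocalized lead variants as instruments.

Instruments are the shared lead variants (highest posterior inclusion
probability) of colocalized credible sets; proteins without a colocalized
locus are excluded, since for those a discrepant estimate could reflect
power rather than biology. One instrument gives a Wald ratio, two or more a
fixed-effect inverse-variance-weighted average of the per-instrument Wald
ratios. Instrument independence (pairwise r² < 0.01 against the LD panel)
is a hard contract: a violation raises rather than silently pruning.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from pqtlx.coloc import LocusColocResult
from pqtlx.ld import LDMatrix
from pqtlx.sumstats import LocusSumStats, VariantKey

log = logging.getLogger(__name__)

Z975 = 1.959964
ALPHA_DEFAULT = 1e-5
R2_INDEPENDENT = 0.01


class InstrumentDependenceError(RuntimeError):
    """Two instruments of one protein violate the pairwise r² < 0.01 contract."""


@dataclass
class Instrument:
    key: VariantKey
    beta_x: float
    se_x: float
    beta_y: float
    se_y: float
    source_pair: object | None = None


@dataclass
class MRResult:
    protein_id: str
    tissue_source: str
    n_instruments: int
    method: str  # "wald" | "ivw"
    estimate: float
    se: float
    ci95: tuple[float, float]
    p: float
    significant: bool
    instruments: list[Instrument] = field(default_factory=list)


def _finalize(protein_id, source, method, est, se, instruments, alpha) -> MRResult:
    z = est / se if se > 0 else math.inf * np.sign(est)
    p = 1.0 if est == 0 else float(2 * sps.norm.sf(abs(z)))
    return MRResult(
        protein_id,
        source,
        len(instruments),
        method,
        float(est),
        float(se),
        (float(est - Z975 * se), float(est + Z975 * se)),
        p,
        p < alpha,
        instruments,
    )


def wald_ratio(i: Instrument, *, protein_id: str = "", source: str = "", alpha: float = ALPHA_DEFAULT) -> MRResult:
    """Single-instrument Wald ratio: beta_y/beta_x, first-order delta SE se_y/|beta_x|."""
    if i.beta_x == 0:
        raise ValueError("Wald ratio undefined for beta_x = 0")
    est = i.beta_y / i.beta_x
    se = i.se_y / abs(i.beta_x)
    return _finalize(protein_id, source, "wald", est, se, [i], alpha)


def ivw(results: list[MRResult], *, protein_id: str = "", source: str = "", alpha: float = ALPHA_DEFAULT) -> MRResult:
    """Fixed-effect inverse-variance-weighted average of Wald ratios."""
    if len(results) < 2:
        raise ValueError("IVW requires at least 2 instruments")
    theta = np.array([r.estimate for r in results])
    w = np.array([r.se for r in results]) ** -2.0
    est = float(np.sum(w * theta) / np.sum(w))
    se = float(np.sum(w) ** -0.5)
    instruments = [inst for r in results for inst in r.instruments]
    return _finalize(protein_id, source, "ivw", est, se, instruments, alpha)


def _lookup(stats: LocusSumStats, key: VariantKey):
    """Effect aligned to key.a1 from a harmonized table; None when absent."""
    df = stats.df
    hit = df[(df["pos"] == key.pos) & (df["chrom"] == key.chrom)]
    for _, row in hit.iterrows():
        if (row["a1"], row["a2"]) == (key.a1, key.a2):
            return float(row["beta"]), float(row["se"])
        if (row["a2"], row["a1"]) == (key.a1, key.a2):
            return -float(row["beta"]), float(row["se"])
    return None


def select_instruments(
    results: list[LocusColocResult],
    exposure_stats: dict[str, LocusSumStats],
    outcome_stats: dict[str, LocusSumStats],
    ld: dict[str, LDMatrix] | None = None,
    *,
    r2_max: float = R2_INDEPENDENT,
) -> dict[str, list[Instrument]]:
    """One instrument per colocalized matched signal pair, per protein.

    ``exposure_stats``/``outcome_stats`` map protein id to that protein's
    harmonized cis table (for the outcome, its slice of the outcome GWAS).
    Instruments absent from the outcome GWAS are dropped with a logged
    reason; proteins with no colocalized locus are excluded entirely.
    When ``ld`` is given, pairwise instrument independence is asserted
    against the panel LD and a violation raises
    :class:`InstrumentDependenceError`.
    """
    out: dict[str, list[Instrument]] = {}
    for res in results:
        if not res.colocalized:
            continue
        pid = res.protein_id
        exp = exposure_stats[pid]
        outc = outcome_stats.get(pid)
        instruments: list[Instrument] = []
        for pair in res.matched_pairs:
            if pair.pp[4] <= 0.8:
                continue
            key = pair.lead
            hit_x = _lookup(exp, key)
            hit_y = _lookup(outc, key) if outc is not None else None
            if hit_y is None:
                log.warning("protein %s: lead %s absent from outcome GWAS; dropped", pid, key)
                continue
            bx, sx = hit_x
            by, sy = hit_y
            instruments.append(Instrument(key, bx, sx, by, sy, pair))
        if not instruments:
            log.warning("protein %s: no usable instruments; skipped", pid)
            continue
        if ld is not None and len(instruments) > 1:
            mat = ld[pid]
            idx = {k.unordered(): i for i, k in enumerate(mat.keys)}
            for i in range(len(instruments)):
                for j in range(i + 1, len(instruments)):
                    r = mat.r[idx[instruments[i].key.unordered()], idx[instruments[j].key.unordered()]]
                    if r**2 >= r2_max:
                        raise InstrumentDependenceError(
                            f"protein {pid}: instruments {instruments[i].key} and "
                            f"{instruments[j].key} have r²={r**2:.3f} >= {r2_max}"
                        )
        out[pid] = instruments
    return out


def run_mr(
    instrument_map: dict[str, dict[str, list[Instrument]]],
    alpha: float = ALPHA_DEFAULT,
) -> list[MRResult]:
    """Dispatch Wald ratio (1 instrument) or IVW (>= 2) per protein and tissue source.

    ``instrument_map`` maps protein -> tissue source -> instruments; results
    for the sources are emitted side by side so cross-tissue effect-direction
    consistency can be read off per protein.
    """
    out: list[MRResult] = []
    for pid, by_source in instrument_map.items():
        for source, instruments in by_source.items():
            if not instruments:
                continue
            walds = [
                wald_ratio(i, protein_id=pid, source=source, alpha=alpha) for i in instruments
            ]
            if len(walds) == 1:
                out.append(walds[0])
            else:
                out.append(ivw(walds, protein_id=pid, source=source, alpha=alpha))
    return out


def cross_tissue_direction(results: list[MRResult]) -> dict[str, str]:
    """Per-protein flag: 'concordant' | 'discordant' | 'single-source'."""
    by_pid: dict[str, dict[str, MRResult]] = {}
    for r in results:
        by_pid.setdefault(r.protein_id, {})[r.tissue_source] = r
    flags = {}
    for pid, d in by_pid.items():
        if len(d) < 2:
            flags[pid] = "single-source"
        else:
            signs = {np.sign(r.estimate) for r in d.values()}
            flags[pid] = "concordant" if len(signs) == 1 else "discordant"
    return flags
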