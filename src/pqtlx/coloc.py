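"""Multi-signal colocalization of two traits' cis association signals.

Pipeline per locus, given harmonized summary statistics and a reference LD
matrix:

1. Detect up to K independent signals per trait by stepwise approximate
   conditional analysis on the standardized scale (b = z/sqrt(n)), using only
   marginal statistics and the LD matrix R: the conditional effect of variant
   j given a selected set S is ``b_j - R_jS (R_SS + eps I)^-1 b_S`` with
   conditional SE ``sqrt((1 - q_j)/n_j)``, ``q_j = R_jS (R_SS+eps I)^-1 R_Sj``.
2. For every cross-trait signal pair, compute per-variant Wakefield
   approximate Bayes factors from each signal's leave-one-out conditional
   statistics and enumerate the classical five colocalization hypotheses
   (H0 no association ... H4 shared causal variant) in log space.
3. Greedily match signal pairs one-to-one by descending PP4; the locus-level
   colocalization probability is the maximum PP4 and is called colocalized
   when it exceeds 0.8 (strict). Effect-direction concordance compares the
   sign of the two traits' marginal betas at the shared lead variant (the
   highest posterior-inclusion-probability variant of the best pair).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from scipy.special import logsumexp

from pqtlx.ld import LDMatrix
from pqtlx.sumstats import LocusSumStats, VariantKey

log = logging.getLogger(__name__)

#: |z| for two-sided p = 5e-8
Z_GW = 5.4513
#: prior effect-size SD 0.15 on the standardized scale -> variance 0.0225
W_DEFAULT = 0.0225
#: per-hypothesis priors (p1, p2, p12)
PRIORS_DEFAULT = (1e-4, 1e-4, 1e-5)
RIDGE = 1e-6
COLLINEARITY_MAX = 0.95
CS_MASS = 0.95


class SingularLDError(RuntimeError):
    """Selected-variant LD block is singular despite the ridge adjustment."""


@dataclass
class Signal:
    """One conditionally independent association signal for one trait.

    Conditional arrays span the whole harmonized locus and are conditioned on
    the other selected leads (leave-one-out), so the signal's own association
    is preserved while the others are regressed out.
    """

    trait: str
    lead: VariantKey
    lead_idx: int
    step: int
    cond_beta: np.ndarray = field(repr=False)
    cond_se: np.ndarray = field(repr=False)

    @property
    def cond_z(self) -> np.ndarray:
        return self.cond_beta / self.cond_se


@dataclass
class ColocPair:
    """Colocalization evidence for one cross-trait signal pair."""

    signal_a: Signal
    signal_b: Signal
    pp: np.ndarray  # PP0..PP4
    pip: np.ndarray = field(repr=False)
    credible_set: list[int] = field(default_factory=list)
    lead_idx: int = -1
    lead: VariantKey | None = None
    concordant: bool | None = None


@dataclass
class LocusColocResult:
    protein_id: str
    n_signals_a: int
    n_signals_b: int
    coloc_prob: float
    colocalized: bool
    best_pair: ColocPair | None = None
    matched_pairs: list[ColocPair] = field(default_factory=list)
    discordant: bool | None = None  # defined only when colocalized


def wakefield_log_abf(beta, se, W: float = W_DEFAULT):
    """Log approximate Bayes factor for association under a N(0, W) effect prior.

    With V = se² and z = beta/se:
    ``log ABF = 0.5 log(V/(V+W)) + (z²/2) · W/(V+W)``.
    Vectorized over ``beta``/``se``.
    """
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(~np.isfinite(beta)) or np.any(~np.isfinite(se)) or np.any(se <= 0) or W < 0:
        raise ValueError("wakefield_log_abf requires finite inputs, se > 0, W >= 0")
    V = se**2
    z2 = (beta / se) ** 2
    return 0.5 * np.log(V / (V + W)) + 0.5 * z2 * (W / (V + W))


def _conditional(b, n, R, sel, ridge=RIDGE):
    """Conditional standardized effects and SEs of all variants given set `sel`."""
    m = len(b)
    if not sel:
        return b.copy(), np.sqrt(1.0 / n), np.zeros(m)
    S = np.asarray(sel, dtype=int)
    Rss = R[np.ix_(S, S)] + ridge * np.eye(len(S))
    try:
        inv = np.linalg.inv(Rss)
    except np.linalg.LinAlgError as e:  # pragma: no cover - ridge makes this rare
        raise SingularLDError("selected-variant LD block singular despite ridge") from e
    Rjs = R[:, S]
    proj = Rjs @ inv
    q = np.einsum("ij,ij->i", proj, Rjs)
    q = np.clip(q, 0.0, 0.9999)
    cond_b = b - proj @ b[S]
    cond_se = np.sqrt((1.0 - q) / n)
    return cond_b, cond_se, q


def detect_signals(
    stats: LocusSumStats,
    ld: LDMatrix,
    z_thresh: float = Z_GW,
    K: int = 10,
    *,
    trait: str = "",
) -> list[Signal]:
    """Stepwise forward selection of up to K conditionally independent signals.

    Works on the standardized scale ``b_j = z_j / sqrt(n_j)`` so that traits
    measured in arbitrary units are comparable. At each step the variant with
    the largest conditional |z| among those passing the collinearity guard
    (q_j <= 0.95 against the selected set) is added; selection stops below
    ``z_thresh``. Each returned signal carries conditional statistics
    conditioned on the other selected leads only.

    Ties in |cond_z| break toward the smaller genomic position.
    """
    df = stats.df
    m = len(df)
    if m == 0:
        return []
    if m != len(ld.keys):
        raise ValueError("summary statistics and LD matrix are not index-aligned")
    n = df["n"].to_numpy(dtype=float)
    if np.any(~np.isfinite(n)) or np.any(n <= 0):
        med = float(np.nanmedian(np.where(n > 0, n, np.nan)))
        log.warning("detect_signals: missing/invalid n, falling back to locus median %g", med)
        n = np.where(np.isfinite(n) & (n > 0), n, med)
    z = df["beta"].to_numpy(dtype=float) / df["se"].to_numpy(dtype=float)
    b = z / np.sqrt(n)
    pos = df["pos"].to_numpy()
    R = ld.r

    selected: list[int] = []
    while len(selected) < K:
        cond_b, cond_se, q = _conditional(b, n, R, selected)
        cz = np.abs(cond_b / cond_se)
        cz[selected] = -np.inf
        cz[q > COLLINEARITY_MAX] = -np.inf
        if not np.any(np.isfinite(cz)) or np.nanmax(cz) < z_thresh:
            break
        best = np.max(cz)
        cand = np.flatnonzero(cz == best)
        j = int(cand[np.argmin(pos[cand])])  # deterministic tie-break
        selected.append(j)

    keys = stats.keys()
    signals = []
    for step, j in enumerate(selected, start=1):
        others = [s for s in selected if s != j]
        cond_b, cond_se, _ = _conditional(b, n, R, others)
        signals.append(Signal(trait, keys[j], j, step, cond_b, cond_se))
    return signals


def coloc_pair(
    sig_a: Signal,
    sig_b: Signal,
    priors: tuple[float, float, float] = PRIORS_DEFAULT,
    W: float = W_DEFAULT,
    *,
    marginal_beta_a: np.ndarray | None = None,
    marginal_beta_b: np.ndarray | None = None,
    keys: list[VariantKey] | None = None,
    cs_mass: float = CS_MASS,
) -> ColocPair:
    """Five-hypothesis colocalization of one signal pair via Wakefield ABFs.

    Per-variant log-ABFs A_k, B_k come from each signal's leave-one-out
    conditional statistics. On the natural scale L1 = ΣA, L2 = ΣB,
    L12 = ΣA·B and Lcross = L1·L2 − L12 = Σ_{j≠k} A_j·B_k; hypothesis weights
    {1, p1·L1, p2·L2, p1·p2·Lcross, p12·L12} are normalized into PP0..PP4.
    All sums run in log space. Lcross is accumulated directly over the j≠k
    pairs, which keeps it exact (and zero) for a single-variant locus, forcing
    PP3 = 0 there.
    """
    p1, p2, p12 = priors
    A = wakefield_log_abf(sig_a.cond_beta, sig_a.cond_se, W)
    B = wakefield_log_abf(sig_b.cond_beta, sig_b.cond_se, W)
    if A.shape != B.shape:
        raise ValueError("signal pair not index-aligned")
    m = A.size

    logL1 = logsumexp(A)
    logL2 = logsumexp(B)
    logL12 = logsumexp(A + B)
    if m > 1:
        cross = A[:, None] + B[None, :]
        np.fill_diagonal(cross, -np.inf)
        logLcross = logsumexp(cross)
    else:
        logLcross = -np.inf

    logw = np.array(
        [
            0.0,
            np.log(p1) + logL1,
            np.log(p2) + logL2,
            np.log(p1) + np.log(p2) + logLcross,
            np.log(p12) + logL12,
        ]
    )
    pp = np.exp(logw - logsumexp(logw))

    log_pip = (A + B) - logL12
    pip = np.exp(log_pip)

    order = np.argsort(-pip, kind="mergesort")
    cum = np.cumsum(pip[order])
    ncs = int(np.searchsorted(cum, cs_mass) + 1)
    ncs = min(ncs, m)
    credible = [int(i) for i in order[:ncs]]
    lead_idx = int(order[0])

    pair = ColocPair(sig_a, sig_b, pp, pip, credible, lead_idx)
    if keys is not None:
        pair.lead = keys[lead_idx]
    if marginal_beta_a is not None and marginal_beta_b is not None:
        pair.concordant = bool(
            np.sign(marginal_beta_a[lead_idx]) == np.sign(marginal_beta_b[lead_idx])
        )
    return pair


def colocalize_locus(
    a: LocusSumStats,
    b: LocusSumStats,
    ld: LDMatrix,
    K: int = 10,
    *,
    z_thresh: float = Z_GW,
    priors: tuple[float, float, float] = PRIORS_DEFAULT,
    W: float = W_DEFAULT,
    coloc_threshold: float = 0.8,
) -> LocusColocResult:
    """Detect signals in both traits, colocalize all pairs, report the locus call.

    Signal pairs are matched one-to-one greedily by descending PP4 (a signal
    feeds at most one matched pair); the locus colocalization probability is
    the maximum PP4 over matched pairs, called colocalized when strictly
    above ``coloc_threshold``. Discordance is defined only for colocalized
    loci, from the best pair's lead-variant marginal beta signs.
    """
    sig_a = detect_signals(a, ld, z_thresh, K, trait="a")
    sig_b = detect_signals(b, ld, z_thresh, K, trait="b")
    res = LocusColocResult(a.protein_id, len(sig_a), len(sig_b), 0.0, False)
    if not sig_a or not sig_b:
        return res

    beta_a = a.df["beta"].to_numpy(dtype=float)
    beta_b = b.df["beta"].to_numpy(dtype=float)
    keys = a.keys()
    pairs = [
        coloc_pair(
            sa, sb, priors, W, marginal_beta_a=beta_a, marginal_beta_b=beta_b, keys=keys
        )
        for sa in sig_a
        for sb in sig_b
    ]
    pairs.sort(key=lambda p: (-p.pp[4], p.signal_a.step, p.signal_b.step))
    used_a: set[int] = set()
    used_b: set[int] = set()
    matched: list[ColocPair] = []
    for p in pairs:
        if p.signal_a.step in used_a or p.signal_b.step in used_b:
            continue
        used_a.add(p.signal_a.step)
        used_b.add(p.signal_b.step)
        matched.append(p)

    res.matched_pairs = matched
    best = max(matched, key=lambda p: p.pp[4])
    res.best_pair = best
    res.coloc_prob = float(best.pp[4])
    res.colocalized = res.coloc_prob > coloc_threshold
    if res.colocalized:
        res.discordant = not best.concordant
    return res


def summarize_concordance(
    results: list[LocusColocResult],
    a_stats: dict[str, LocusSumStats],
    b_stats: dict[str, LocusSumStats],
) -> dict:
    """Cohort-level concordance summary across colocalized loci.

    Reports counts and proportions of colocalized and discordant loci and the
    Spearman rank correlation of the two traits' marginal betas at each best
    pair's lead variant (absent with fewer than two colocalized loci).
    """
    n_tested = len(results)
    coloc = [r for r in results if r.colocalized]
    n_coloc = len(coloc)
    n_disc = sum(1 for r in coloc if r.discordant)
    lead_a, lead_b = [], []
    for r in coloc:
        i = r.best_pair.lead_idx
        lead_a.append(float(a_stats[r.protein_id].df["beta"].iloc[i]))
        lead_b.append(float(b_stats[r.protein_id].df["beta"].iloc[i]))
    rho = None
    if n_coloc >= 2:
        rho = float(sps.spearmanr(lead_a, lead_b).statistic)
    return {
        "n_tested": n_tested,
        "n_colocalized": n_coloc,
        "prop_colocalized": n_coloc / n_tested if n_tested else float("nan"),
        "n_discordant": n_disc,
        "prop_discordant_among_colocalized": (n_disc / n_coloc) if n_coloc else float("nan"),
        "spearman_rho": rho,
        "lead_beta_a": lead_a,
        "lead_beta_b": lead_b,
    }
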