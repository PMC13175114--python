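"""Reusable simulation studies: calibration, recovery, and type-I-error runs.

Each function generates loci (or expression matrices) under a named
scenario, pushes them through the analysis path a real dataset would take
(QC → harmonization → eligibility → LD → colocalization → MR), and compares
the calls against the generator's recorded truth. The analysis drivers, the
test suite, and the acceptance script all call these, so the measured
operating characteristics always come from the same code path.
"""

from __future__ import annotations

import dataclasses
from dataclasses import replace

import numpy as np

from pqtlx import mr as _mr
from pqtlx.coloc import colocalize_locus
from pqtlx.enrichment import enrichment_z, filter_genes, tissue_medians, tmm_factors
from pqtlx.ld import compute_ld
from pqtlx.simulate import LocusScenario, simulate_expression, simulate_locus, simulate_outcome
from pqtlx.sumstats import apply_qc, filter_cis, harmonize_pair, locus_eligible


def _locus_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.SeedSequence(seed).generate_state(n) % (2**31 - 1)


def run_one_locus(scenario: LocusScenario, *, maf_min=0.05, cis_window=500_000,
                  gwas_p=5e-8, K=10, coloc_threshold=0.8):
    """Simulate one locus and run the full per-locus colocalization path.

    Returns ``(result, a, b, panel, truth)`` where ``result`` is the locus
    colocalization call (never-eligible loci yield a not-colocalized result
    with zero signals).
    """
    from pqtlx.coloc import LocusColocResult

    stats_a, stats_b, panel, truth = simulate_locus(scenario)
    a = apply_qc(filter_cis(stats_a, cis_window), maf_min)
    b = apply_qc(filter_cis(stats_b, cis_window), maf_min)
    a, b = harmonize_pair(a, b)
    if len(a) == 0 or not locus_eligible(a, b, gwas_p):
        return LocusColocResult(a.protein_id, 0, 0, 0.0, False), a, b, panel, truth
    ld = compute_ld(panel, a.keys())
    res = colocalize_locus(a, b, ld, K, coloc_threshold=coloc_threshold)
    return res, a, b, panel, truth


def coloc_calibration(label: str, n_loci: int, seed: int, K: int = 10, **scenario_kw) -> dict:
    """Fraction of loci called colocalized (and discordant) under one scenario."""
    seeds = _locus_seeds(seed, n_loci)
    n_coloc = n_disc = n_eligible = 0
    for s in seeds:
        sc = LocusScenario(label=label, seed=int(s), **scenario_kw)
        res, *_ = run_one_locus(sc, K=K)
        if res.n_signals_a or res.n_signals_b:
            n_eligible += 1
        if res.colocalized:
            n_coloc += 1
            if res.discordant:
                n_disc += 1
    return {
        "n_loci": n_loci,
        "n_eligible": n_eligible,
        "n_colocalized": n_coloc,
        "coloc_rate": n_coloc / n_loci,
        "n_discordant": n_disc,
        "discordant_rate_among_coloc": (n_disc / n_coloc) if n_coloc else float("nan"),
    }


def multisignal_recovery(n_reps: int, seed: int, *, n=10_000, h2=0.01,
                         r2_max=0.01, tag_r2=0.8, m=100, n_blocks=5) -> dict:
    """Two independent causal variants: rate of detecting exactly 2 tagging signals.

    Per-signal variance is set so the true marginal |z| is ~sqrt(n·h2) = 10;
    success requires exactly two detected signals whose leads are the causal
    variants or tags with panel r² > ``tag_r2`` (one causal per signal).
    """
    from pqtlx.coloc import detect_signals

    seeds = _locus_seeds(seed, n_reps)
    ok = 0
    for s in seeds:
        sc = LocusScenario(
            label="SHARED_CONCORDANT", n_shared=2, distinct_r2_max=r2_max,
            m_variants=m, n_blocks=n_blocks, h2_signal=h2,
            n_a=n, n_b=200, n_panel=2_000, seed=int(s),
        )
        stats_a, _, panel, truth = simulate_locus(sc)
        a = apply_qc(stats_a)
        ld = compute_ld(panel, a.keys())
        pos_to_idx = {k.pos: i for i, k in enumerate(ld.keys)}
        causal_idx = [pos_to_idx[truth["layout"].positions[c]] for c in truth["causal_a"]]
        sigs = detect_signals(a, ld)
        if len(sigs) != 2:
            continue
        tagged = set()
        for sig in sigs:
            for ci in causal_idx:
                if ci in tagged:
                    continue
                if ld.r[sig.lead_idx, ci] ** 2 > tag_r2:
                    tagged.add(ci)
                    break
        if len(tagged) == 2:
            ok += 1
    return {"n_reps": n_reps, "n_recovered": ok, "recovery_rate": ok / n_reps}


def _single_instrument_scenario(seed, theta, h2, n_x, n_outcome):
    return LocusScenario(
        label="SHARED_CONCORDANT", m_variants=1, n_blocks=1, h2_signal=h2,
        n_a=n_x, n_b=100, n_panel=100, theta=theta, n_outcome=n_outcome, seed=int(seed),
    )


def mr_recovery(n_reps: int, seed: int, *, theta=0.3, h2=0.05,
                n_x=35_000, n_outcome=100_000) -> dict:
    """Wald-ratio recovery of a true protein→outcome effect.

    One causal variant explaining ``h2`` of protein variance instruments the
    protein; reports the mean estimate and the fraction of replicates whose
    estimate lies within ±3 SE of the truth.
    """
    seeds = _locus_seeds(seed, n_reps)
    within = 0
    ests = []
    for s in seeds:
        sc = _single_instrument_scenario(s, theta, h2, n_x, n_outcome)
        stats_a, _, panel, truth = simulate_locus(sc)
        outcome = simulate_outcome(panel, truth, sc)
        i = truth["causal_a"][0]
        inst = _mr.Instrument(
            stats_a.keys()[i],
            float(stats_a.df["beta"].iloc[i]), float(stats_a.df["se"].iloc[i]),
            float(outcome.df["beta"].iloc[i]), float(outcome.df["se"].iloc[i]),
        )
        res = _mr.wald_ratio(inst)
        ests.append(res.estimate)
        if abs(res.estimate - theta) <= 3 * res.se:
            within += 1
    return {
        "n_reps": n_reps,
        "mean_estimate": float(np.mean(ests)),
        "within_3se_rate": within / n_reps,
    }


def mr_type1(n_reps: int, seed: int, *, alpha=1e-5, h2=0.05,
             n_x=35_000, n_outcome=100_000) -> dict:
    """Type-I error of the Wald test under a null protein→outcome effect."""
    seeds = _locus_seeds(seed, n_reps)
    n_sig = 0
    for s in seeds:
        sc = _single_instrument_scenario(s, 0.0, h2, n_x, n_outcome)
        stats_a, _, panel, truth = simulate_locus(sc)
        outcome = simulate_outcome(panel, truth, sc)
        i = truth["causal_a"][0]
        inst = _mr.Instrument(
            stats_a.keys()[i],
            float(stats_a.df["beta"].iloc[i]), float(stats_a.df["se"].iloc[i]),
            float(outcome.df["beta"].iloc[i]), float(outcome.df["se"].iloc[i]),
        )
        if _mr.wald_ratio(inst, alpha=alpha).significant:
            n_sig += 1
    return {"n_reps": n_reps, "n_significant": n_sig, "significant_rate": n_sig / n_reps}


def mr_cross_tissue_discordance(n_loci: int, seed: int, *, theta=0.3, alpha=1e-5,
                                **scenario_kw) -> dict:
    """Opposite-signed plasma vs brain MR estimates at shared-discordant loci.

    For each colocalized SHARED_DISCORDANT locus, the shared lead instruments
    the protein once with plasma (tissue A) and once with brain (tissue B)
    effects against the same outcome; among loci where both estimates are
    significant, reports how often the signs disagree.
    """
    seeds = _locus_seeds(seed, n_loci)
    n_coloc = n_signif = n_opposite = 0
    for s in seeds:
        sc = LocusScenario(label="SHARED_DISCORDANT", theta=theta, seed=int(s), **scenario_kw)
        res, a, b, panel, truth = run_one_locus(sc)
        if not res.colocalized:
            continue
        n_coloc += 1
        outcome = simulate_outcome(panel, truth, sc)
        key = res.best_pair.lead
        hit_y = _mr._lookup(outcome, key)
        hit_xa = _mr._lookup(a, key)
        hit_xb = _mr._lookup(b, key)
        if hit_y is None or hit_xa is None or hit_xb is None:
            continue
        ra = _mr.wald_ratio(_mr.Instrument(key, *hit_xa, *hit_y), alpha=alpha)
        rb = _mr.wald_ratio(_mr.Instrument(key, *hit_xb, *hit_y), alpha=alpha)
        if ra.significant and rb.significant:
            n_signif += 1
            if np.sign(ra.estimate) != np.sign(rb.estimate):
                n_opposite += 1
    return {
        "n_loci": n_loci,
        "n_colocalized": n_coloc,
        "n_both_significant": n_signif,
        "opposite_sign_rate": (n_opposite / n_signif) if n_signif else float("nan"),
    }


def enrichment_recovery(seed: int, *, g_genes=2000, n_tissues=50, n_per_tissue=20,
                        planted_frac=0.05, fold=8.0, z_threshold=2.0) -> dict:
    """Sensitivity/specificity of elevated flags against planted enrichment."""
    cm, truth = simulate_expression(
        g_genes=g_genes, n_tissues=n_tissues, n_per_tissue=n_per_tissue,
        planted_frac=planted_frac, fold=fold, seed=seed,
    )
    cm = filter_genes(cm)
    enr = enrichment_z(tissue_medians(cm, tmm_factors(cm)), z_threshold)
    planted = truth["enriched"]
    kept = [g for g in enr.genes if g not in enr.excluded_genes]
    tp = fn = fp = tn = 0
    elev = enr.elevated
    for g in kept:
        for t in enr.tissues:
            is_planted = planted.get(g) == t
            flagged = bool(elev.loc[g, t])
            if is_planted and flagged:
                tp += 1
            elif is_planted:
                fn += 1
            elif flagged:
                fp += 1
            else:
                tn += 1
    return {
        "n_gene_tissue": tp + fn + fp + tn,
        "sensitivity": tp / (tp + fn) if tp + fn else float("nan"),
        "specificity": tn / (tn + fp) if tn + fp else float("nan"),
        "false_elevated_rate": fp / (fp + tn) if fp + tn else float("nan"),
    }
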