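"""End-to-end orchestration: simulate → colocalize → enrich → MR → summarize.

Every analysis stage is deterministic given its inputs; all randomness lives
in the synthetic-data generator and is forked from one root seed with a
counter-based scheme (numpy ``SeedSequence`` spawning), so re-running with
the same configuration reproduces every artifact byte for byte. Each stage
writes its table under the run directory and the run report records every
threshold consumed.
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

from pqtlx import coloc as _coloc
from pqtlx import mr as _mr
from pqtlx.enrichment import contrast_by_group, enrichment_z, filter_genes, tissue_medians, tmm_factors
from pqtlx.ld import compute_ld
from pqtlx.simulate import LocusScenario, StudyConfig, simulate_study
from pqtlx.sumstats import apply_qc, filter_cis, harmonize_pair, locus_eligible, read_sumstats

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All thresholds and study conditions for one pipeline run.

    Threshold defaults are the analysis constants used throughout: 500 kb cis
    window, MAF > 0.05, genome-wide significance p < 5e-8, up to K = 10
    signals, colocalization probability > 0.8, enrichment z > 2, MR
    significance p < 1e-5.
    """

    out_dir: str = "run"
    seed: int = 0
    cis_window: int = 500_000
    maf_min: float = 0.05
    gwas_p: float = 5e-8
    K: int = 10
    coloc_threshold: float = 0.8
    z_enrich: float = 2.0
    mr_alpha: float = 1e-5
    run_enrichment: bool = True
    run_mr: bool = True
    study: StudyConfig = field(default_factory=StudyConfig)

    def thresholds(self) -> dict:
        return {
            "cis_window": self.cis_window,
            "maf_min": self.maf_min,
            "gwas_p": self.gwas_p,
            "K": self.K,
            "coloc_threshold": self.coloc_threshold,
            "z_enrich": self.z_enrich,
            "mr_alpha": self.mr_alpha,
        }

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        study_raw = raw.pop("study", {})
        scenario_raw = study_raw.pop("scenario", {})
        study = StudyConfig(scenario=LocusScenario(**scenario_raw), **study_raw)
        return cls(study=study, **raw)


@dataclass
class CohortSummary:
    n_proteins_tested: int
    n_colocalized: int
    prop_colocalized: float
    n_discordant: int
    prop_discordant_among_colocalized: float
    spearman_rho: float | None
    confusion: dict
    contrasts: list[dict] = field(default_factory=list)
    mr_hits: list[dict] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True)


def prepare_locus(stats_a, stats_b, cfg: RunConfig):
    """QC + cis filter + harmonization for one protein's pair of tables."""
    a = apply_qc(filter_cis(stats_a, cfg.cis_window), cfg.maf_min)
    b = apply_qc(filter_cis(stats_b, cfg.cis_window), cfg.maf_min)
    return harmonize_pair(a, b)


def stage_coloc(bundle: dict, cfg: RunConfig):
    """Harmonize, test eligibility, and colocalize every protein locus."""
    results, harm_a, harm_b, ld_map = [], {}, {}, {}
    for lo in bundle["loci"]:
        pid = lo["protein_id"]
        a, b = prepare_locus(lo["stats_a"], lo["stats_b"], cfg)
        harm_a[pid], harm_b[pid] = a, b
        if len(a) == 0 or not locus_eligible(a, b, cfg.gwas_p):
            results.append(_coloc.LocusColocResult(pid, 0, 0, 0.0, False))
            continue
        ld = compute_ld(lo["panel"], a.keys())
        ld_map[pid] = ld
        results.append(
            _coloc.colocalize_locus(
                a, b, ld, cfg.K, coloc_threshold=cfg.coloc_threshold
            )
        )
    return results, harm_a, harm_b, ld_map


def coloc_table(results, harm_a, harm_b) -> pd.DataFrame:
    rows = []
    for r in results:
        row = {
            "protein_id": r.protein_id,
            "n_signals_a": r.n_signals_a,
            "n_signals_b": r.n_signals_b,
            "coloc_prob": r.coloc_prob,
            "colocalized": r.colocalized,
            "lead": "",
            "lead_pip": np.nan,
            "beta_a": np.nan,
            "beta_b": np.nan,
            "concordant": "",
        }
        if r.best_pair is not None:
            bp = r.best_pair
            i = bp.lead_idx
            row.update(
                lead=str(bp.lead),
                lead_pip=float(bp.pip[i]),
                beta_a=float(harm_a[r.protein_id].df["beta"].iloc[i]),
                beta_b=float(harm_b[r.protein_id].df["beta"].iloc[i]),
                concordant=bool(bp.concordant),
            )
        rows.append(row)
    return pd.DataFrame(rows)


def stage_enrichment(bundle: dict, results, cfg: RunConfig):
    """TMM-normalize counts, score enrichment, and contrast by coloc status."""
    cm = filter_genes(bundle["counts"])
    factors = tmm_factors(cm)
    med = tissue_medians(cm, factors)
    enr = enrichment_z(med, cfg.z_enrich)
    status = {r.protein_id: ("coloc" if r.colocalized else "noncoloc") for r in results}
    group_of = {g: status[g] for g in enr.genes if g in status}
    contrasts = contrast_by_group(enr, group_of) if len(set(group_of.values())) == 2 else []
    return enr, contrasts


def stage_mr(bundle: dict, results, harm_a, harm_b, ld_map, cfg: RunConfig):
    """Two-sample MR per tissue source with colocalized leads as instruments."""
    outcome = {}
    for lo in bundle["loci"]:
        pid = lo["protein_id"]
        if pid in harm_a and len(harm_a[pid]):
            # align outcome slice to the harmonized exposure universe
            _, out_h = harmonize_pair(harm_a[pid], lo["outcome"])
            outcome[pid] = out_h
    inst_a = _mr.select_instruments(results, harm_a, outcome, ld_map)
    inst_b = _mr.select_instruments(results, harm_b, outcome, ld_map)
    inst_map = {
        pid: {"plasma": inst_a.get(pid, []), "brain": inst_b.get(pid, [])}
        for pid in set(inst_a) | set(inst_b)
    }
    mr_results = _mr.run_mr(inst_map, cfg.mr_alpha)
    flags = _mr.cross_tissue_direction(mr_results)
    return mr_results, flags


def mr_table(mr_results, flags) -> pd.DataFrame:
    rows = []
    for r in sorted(mr_results, key=lambda r: (r.protein_id, r.tissue_source)):
        rows.append(
            {
                "protein_id": r.protein_id,
                "tissue_source": r.tissue_source,
                "n_instruments": r.n_instruments,
                "method": r.method,
                "estimate": r.estimate,
                "se": r.se,
                "ci95_lo": r.ci95[0],
                "ci95_hi": r.ci95[1],
                "p": r.p,
                "significant": r.significant,
                "cross_tissue": flags.get(r.protein_id, ""),
            }
        )
    return pd.DataFrame(rows)


def confusion_vs_truth(bundle: dict, results) -> dict:
    """Locus-level confusion matrix of colocalization calls against truth."""
    truth_shared = {
        lo["protein_id"]: lo["scenario"].label.startswith("SHARED")
        for lo in bundle["loci"]
    }
    calls = {r.protein_id: r.colocalized for r in results}
    tp = sum(1 for p, t in truth_shared.items() if t and calls[p])
    fn = sum(1 for p, t in truth_shared.items() if t and not calls[p])
    fp = sum(1 for p, t in truth_shared.items() if not t and calls[p])
    tn = sum(1 for p, t in truth_shared.items() if not t and not calls[p])
    return {
        "tp": tp,
        "fn": fn,
        "fp": fp,
        "tn": tn,
        "sensitivity": tp / (tp + fn) if tp + fn else float("nan"),
        "fpr": fp / (fp + tn) if fp + tn else float("nan"),
    }


def run_all(cfg: RunConfig) -> CohortSummary:
    """Run every enabled stage, writing artifacts under ``cfg.out_dir``."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    study = dataclasses.replace(cfg.study, seed=cfg.seed)
    bundle = simulate_study(study, out / "inputs")
    log.info("simulated %d protein loci", len(bundle["loci"]))

    results, harm_a, harm_b, ld_map = stage_coloc(bundle, cfg)
    ctab = coloc_table(results, harm_a, harm_b)
    ctab.to_csv(out / "coloc_loci.tsv", sep="\t", index=False, float_format="%.10g")

    contrasts_rows: list[dict] = []
    if cfg.run_enrichment:
        enr, contrasts = stage_enrichment(bundle, results, cfg)
        enr.z.to_csv(out / "enrichment_z.tsv", sep="\t", float_format="%.10g")
        contrasts_rows = [dataclasses.asdict(c) for c in contrasts]
        pd.DataFrame(contrasts_rows).to_csv(
            out / "tissue_contrasts.tsv", sep="\t", index=False, float_format="%.10g"
        )

    mr_rows: list[dict] = []
    if cfg.run_mr:
        mr_results, flags = stage_mr(bundle, results, harm_a, harm_b, ld_map, cfg)
        mtab = mr_table(mr_results, flags)
        mtab.to_csv(out / "mr_results.tsv", sep="\t", index=False, float_format="%.10g")
        mr_rows = mtab[mtab["significant"]].to_dict(orient="records")

    eligible = [r for r in results if r.n_signals_a > 0 or r.n_signals_b > 0]
    conc = _coloc.summarize_concordance(results, harm_a, harm_b)
    summary = CohortSummary(
        n_proteins_tested=len(results),
        n_colocalized=conc["n_colocalized"],
        prop_colocalized=conc["prop_colocalized"],
        n_discordant=conc["n_discordant"],
        prop_discordant_among_colocalized=conc["prop_discordant_among_colocalized"],
        spearman_rho=conc["spearman_rho"],
        confusion=confusion_vs_truth(bundle, results),
        contrasts=contrasts_rows,
        mr_hits=mr_rows,
    )
    (out / "summary.json").write_text(summary.to_json())
    report = {
        "seed": cfg.seed,
        "thresholds": cfg.thresholds(),
        "n_eligible": len(eligible),
        "stages": {
            "simulate": True,
            "coloc": True,
            "enrichment": cfg.run_enrichment,
            "mr": cfg.run_mr,
        },
    }
    (out / "run_report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    return summary
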