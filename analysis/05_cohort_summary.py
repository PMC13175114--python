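#!/usr/bin/env python
"""Assemble the cohort-level summary and compare every call against truth.

Collects the per-locus colocalization calls, the tissue contrasts, and the
MR hits produced by the earlier steps, recomputes the headline proportions,
and scores the colocalization calls against the generator's truth (shared
scenarios = positive class).

Writes results/summary.json.
"""

import json
from pathlib import Path

import pandas as pd

RESULTS = Path("results")


def main() -> None:
    coloc = pd.read_csv(RESULTS / "coloc_loci.tsv", sep="\t")
    # keep_default_na: the scenario label "NULL" is data, not a missing value
    truth = pd.read_csv(RESULTS / "study_truth.tsv", sep="\t",
                        keep_default_na=False, na_values=[""])
    conc = json.loads((RESULTS / "concordance_summary.json").read_text())
    mr = pd.read_csv(RESULTS / "mr_results.tsv", sep="\t")

    merged = coloc.merge(truth, on="protein_id")
    shared = merged["scenario"].str.startswith("SHARED")
    called = merged["colocalized"]
    tp = int((shared & called).sum())
    fn = int((shared & ~called).sum())
    fp = int((~shared & called).sum())
    tn = int((~shared & ~called).sum())

    sig = mr[mr["significant"]]
    summary = {
        "n_proteins_tested": int(len(coloc)),
        "n_colocalized": conc["n_colocalized"],
        "prop_colocalized": conc["prop_colocalized"],
        "n_discordant": conc["n_discordant"],
        "prop_discordant_among_colocalized": conc["prop_discordant_among_colocalized"],
        "spearman_rho": conc["spearman_rho"],
        "confusion": {
            "tp": tp, "fn": fn, "fp": fp, "tn": tn,
            "sensitivity": tp / (tp + fn) if tp + fn else None,
            "fpr": fp / (fp + tn) if fp + tn else None,
        },
        "n_mr_significant_proteins": int(sig["protein_id"].nunique()),
        "n_mr_discordant_direction": int(
            sig.loc[sig["cross_tissue"] == "discordant", "protein_id"].nunique()
        ),
    }
    (RESULTS / "summary.json").write_text(json.dumps(summary, indent=1))

    c = summary["confusion"]
    print(f"{summary['n_colocalized']}/{summary['n_proteins_tested']} loci colocalized "
          f"({100 * summary['prop_colocalized']:.1f}%); "
          f"{summary['n_discordant']} discordant among colocalized "
          f"({100 * summary['prop_discordant_among_colocalized']:.1f}%)")
    print(f"calls vs truth: sensitivity {c['sensitivity']:.2f}, FPR {c['fpr']:.2f} "
          f"(tp={tp} fn={fn} fp={fp} tn={tn})")
    print(f"Spearman rho of lead betas: {summary['spearman_rho']:.3f}")
    print(f"MR: {summary['n_mr_significant_proteins']} significant proteins, "
          f"{summary['n_mr_discordant_direction']} with discordant cross-tissue direction")
    print(f"summary -> {RESULTS / 'summary.json'}")


if __name__ == "__main__":
    main()
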