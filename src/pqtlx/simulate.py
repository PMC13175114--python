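"""Synthetic study generator with recorded ground truth.

Generates every input the pipeline consumes, emulating the statistical
structure of a two-tissue cis-pQTL comparison at desk scale:

* **Genotypes** — dichotomized-Gaussian haplotypes with AR(1) block LD:
  a latent Gaussian with within-block correlation ``rho`` is thresholded at
  the MAF quantile, twice per individual, and dosage is the sum. This gives
  exact control of block structure and allele frequency; dosage correlation
  is attenuated relative to ``rho`` by the dichotomization.
* **Two-tissue cis-pQTL summary statistics** — per-tissue protein phenotypes
  are linear in standardized causal dosages with each signal explaining
  ``h2_signal`` of variance; marginal per-variant OLS in independent cohorts
  (defaults mirror a 35,000-sample plasma study vs a 1,000-sample brain
  study) yields beta/SE/p on the standardized scale.
* **Outcome GWAS** — the outcome is ``theta`` times the mediating tissue's
  protein value plus noise in an independent cohort.
* **Expression counts** — negative-binomial counts with log-normal library
  sizes and planted tissue-enriched genes at a configurable fold change.

Scenario labels: SHARED_CONCORDANT (one causal variant shared with equal
signs), SHARED_DISCORDANT (shared, tissue B's sign flipped), DISTINCT (one
causal variant per tissue in different LD blocks, r² < 0.1), A_ONLY (causal
in tissue A only), NULL (no causal variant).

All generators are pure functions of (configuration, seed).
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from pqtlx.enrichment import CountMatrix
from pqtlx.ld import GenotypePanel
from pqtlx.sumstats import LocusSumStats, VariantKey

log = logging.getLogger(__name__)

SCENARIOS = ("SHARED_CONCORDANT", "SHARED_DISCORDANT", "DISTINCT", "A_ONLY", "NULL")

# non-palindromic SNV allele pairs (ref, alt); palindromic pairs would be
# dropped at harmonization when common, so the generator avoids them
_ALLELE_PAIRS = [
    ("A", "G"), ("A", "C"), ("G", "A"), ("C", "A"),
    ("T", "G"), ("T", "C"), ("G", "T"), ("C", "T"),
]


@dataclass
class LocusScenario:
    """Study conditions for one simulated cis locus."""

    label: str = "SHARED_CONCORDANT"
    m_variants: int = 100
    n_blocks: int = 5
    rho: float = 0.9
    maf_range: tuple[float, float] = (0.05, 0.5)
    h2_signal: float = 0.05
    n_a: int = 35_000
    n_b: int = 1_000
    n_panel: int = 5_000
    theta: float = 0.3
    n_outcome: int = 100_000
    n_shared: int = 1  # number of shared causal signals for SHARED_* labels
    effect_sign: float = 1.0  # sign of the protein-increasing allele's effect
    distinct_r2_max: float = 0.1
    mediating_tissue: str = "a"
    chrom: str = "1"
    seed: int = 0

    def __post_init__(self):
        if self.label not in SCENARIOS:
            raise ValueError(f"unknown scenario label {self.label!r}")
        if not (0 < self.h2_signal < 0.5):
            raise ValueError("h2_signal must lie in (0, 0.5)")
        if not (0 <= self.rho <= 0.99):
            raise ValueError("rho must lie in [0, 0.99]")


def _block_sizes(m: int, n_blocks: int) -> list[int]:
    base, extra = divmod(m, n_blocks)
    return [base + (i < extra) for i in range(n_blocks)]


@dataclass
class LocusLayout:
    """Variant identities shared by every cohort drawn for one locus."""

    chrom: str
    positions: np.ndarray
    ref: list[str]
    alt: list[str]
    mafs: np.ndarray
    block_sizes: list[int]
    gene_start: int
    gene_end: int

    def keys(self) -> list[VariantKey]:
        return [
            VariantKey(self.chrom, int(p), a, r)
            for p, r, a in zip(self.positions, self.ref, self.alt)
        ]

    def block_of(self) -> np.ndarray:
        return np.repeat(np.arange(len(self.block_sizes)), self.block_sizes)


def _layout(scenario: LocusScenario, rng: np.random.Generator) -> LocusLayout:
    m = scenario.m_variants
    gene_start, gene_end = 1_000_000, 1_020_000
    lo, hi = gene_start - 400_000, gene_end + 400_000
    positions = np.sort(rng.choice(np.arange(lo, hi), size=m, replace=False))
    pair_idx = rng.integers(0, len(_ALLELE_PAIRS), size=m)
    ref = [_ALLELE_PAIRS[i][0] for i in pair_idx]
    alt = [_ALLELE_PAIRS[i][1] for i in pair_idx]
    mafs = rng.uniform(*scenario.maf_range, size=m)
    return LocusLayout(
        scenario.chrom, positions, ref, alt, mafs,
        _block_sizes(m, scenario.n_blocks), gene_start, gene_end,
    )


def _haplotypes(rng: np.random.Generator, n: int, layout: LocusLayout, rho: float) -> np.ndarray:
    """One haplotype draw: latent AR(1) Gaussian per block, thresholded at MAF."""
    from scipy.signal import lfilter

    m = len(layout.mafs)
    out = np.empty((n, m), dtype=np.int8)
    thresh = sps.norm.ppf(layout.mafs)
    c = np.sqrt(1.0 - rho**2)
    j0 = 0
    for L in layout.block_sizes:
        eps = rng.standard_normal((n, L))
        eps[:, 1:] *= c  # innovation scale; first column keeps unit variance
        x = lfilter([1.0], [1.0, -rho], eps, axis=1)
        out[:, j0 : j0 + L] = x < thresh[j0 : j0 + L]
        j0 += L
    return out


def _dosages(rng: np.random.Generator, n: int, layout: LocusLayout, rho: float) -> np.ndarray:
    return (_haplotypes(rng, n, layout, rho) + _haplotypes(rng, n, layout, rho)).astype(np.int8)


def simulate_genotypes(n: int, scenario: LocusScenario, layout: LocusLayout | None = None,
                       rng: np.random.Generator | None = None) -> GenotypePanel:
    """Draw an n-sample genotype panel for the scenario's locus layout.

    Variant identities (positions, alleles, MAFs, blocks) are a deterministic
    function of the scenario seed, so repeated cohorts share the same locus.
    """
    ss = np.random.SeedSequence(scenario.seed)
    layout_rng, geno_rng = (np.random.default_rng(s) for s in ss.spawn(2))
    if layout is None:
        layout = _layout(scenario, layout_rng)
    if rng is None:
        rng = geno_rng
    dos = _dosages(rng, n, layout, scenario.rho)
    samples = [f"S{i:06d}" for i in range(n)]
    return GenotypePanel(samples, layout.keys(), dos.astype(float))


def _standardize(dos: np.ndarray) -> np.ndarray:
    x = dos.astype(float)
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    return (x - mu) / sd


def _marginal_ols(x_std: np.ndarray, y: np.ndarray) -> pd.DataFrame:
    """Per-variant marginal OLS of y on each standardized dosage column."""
    n = x_std.shape[0]
    xty = x_std.T @ y
    beta = xty / n
    yty = float(y @ y)
    rss = np.maximum(yty - n * beta**2, 1e-12)
    se = np.sqrt(rss / ((n - 2) * n))
    z = beta / se
    p = np.clip(2 * sps.norm.sf(np.abs(z)), 1e-300, 1.0)
    return beta, se, p


def _sumstats_df(layout: LocusLayout, dos: np.ndarray, beta, se, p, n: int) -> pd.DataFrame:
    eaf = dos.mean(axis=0) / 2.0
    return pd.DataFrame(
        {
            "chrom": layout.chrom,
            "pos": layout.positions.astype(int),
            "a1": layout.alt,
            "a2": layout.ref,
            "eaf": eaf,
            "beta": beta,
            "se": se,
            "p": p,
            "n": n,
        }
    )


def _pick_causals(scenario: LocusScenario, layout: LocusLayout, panel_dos: np.ndarray,
                  rng: np.random.Generator) -> dict:
    """Choose causal variant indices and signed standardized effects per tissue."""
    blocks = layout.block_of()
    b = scenario.effect_sign * np.sqrt(scenario.h2_signal)
    lab = scenario.label

    def pick_in_distinct_blocks(k: int, r2_max: float) -> list[int]:
        x = _standardize(panel_dos)
        for _ in range(100):
            chosen_blocks = rng.choice(len(layout.block_sizes), size=k, replace=False)
            idx = [int(rng.choice(np.flatnonzero(blocks == blk))) for blk in chosen_blocks]
            ok = True
            for i in range(k):
                for j in range(i + 1, k):
                    r = float(np.mean(x[:, idx[i]] * x[:, idx[j]]))
                    if r**2 >= r2_max:
                        ok = False
            if ok:
                return sorted(idx)
        raise RuntimeError(f"could not place {k} causal variants at r² < {r2_max} in 100 redraws")

    if lab == "NULL":
        return {"causal_a": [], "effects_a": [], "causal_b": [], "effects_b": []}
    if lab == "A_ONLY":
        idx = pick_in_distinct_blocks(1, 1.0)
        return {"causal_a": idx, "effects_a": [b], "causal_b": [], "effects_b": []}
    if lab == "DISTINCT":
        idx = pick_in_distinct_blocks(2, scenario.distinct_r2_max)
        return {"causal_a": [idx[0]], "effects_a": [b], "causal_b": [idx[1]], "effects_b": [b]}
    # SHARED_* : n_shared causal variants in distinct blocks, shared identically
    k = scenario.n_shared
    idx = pick_in_distinct_blocks(k, scenario.distinct_r2_max) if k > 1 else \
        [int(rng.integers(0, scenario.m_variants))]
    eff_a = [b] * k
    sign_b = -1.0 if lab == "SHARED_DISCORDANT" else 1.0
    eff_b = [sign_b * b] * k
    return {"causal_a": idx, "effects_a": eff_a, "causal_b": idx, "effects_b": eff_b}


def _phenotype(x_std: np.ndarray, causal: list[int], effects: list[float],
               rng: np.random.Generator) -> np.ndarray:
    n = x_std.shape[0]
    h2 = float(np.sum(np.square(effects)))
    g = x_std[:, causal] @ np.asarray(effects) if causal else np.zeros(n)
    return g + rng.standard_normal(n) * np.sqrt(max(1.0 - h2, 1e-9))


def simulate_locus(scenario: LocusScenario):
    """Simulate one locus: tissue A and B summary statistics, LD panel, truth.

    Returns ``(stats_a, stats_b, panel, truth)`` where ``truth`` records the
    causal variant indices/keys, signed effects, scenario label, and the
    locus layout needed to draw further cohorts (outcome GWAS).
    """
    ss = np.random.SeedSequence(scenario.seed)
    streams = [np.random.default_rng(s) for s in ss.spawn(6)]
    rng_layout, rng_panel, rng_causal, rng_a, rng_b, _rng_outcome = streams

    layout = _layout(scenario, rng_layout)
    panel_dos = _dosages(rng_panel, scenario.n_panel, layout, scenario.rho)
    panel = GenotypePanel(
        [f"P{i:05d}" for i in range(scenario.n_panel)], layout.keys(), panel_dos.astype(float)
    )
    causals = _pick_causals(scenario, layout, panel_dos, rng_causal)

    def one_tissue(rng, n, causal, effects, tissue):
        dos = _dosages(rng, n, layout, scenario.rho)
        x = _standardize(dos)
        y = _phenotype(x, causal, effects, rng)
        beta, se, p = _marginal_ols(x, y)
        df = _sumstats_df(layout, dos, beta, se, p, n)
        pid = f"protein_{scenario.seed}"
        return LocusSumStats(pid, layout.chrom, layout.gene_start, layout.gene_end, df)

    stats_a = one_tissue(rng_a, scenario.n_a, causals["causal_a"], causals["effects_a"], "a")
    stats_b = one_tissue(rng_b, scenario.n_b, causals["causal_b"], causals["effects_b"], "b")

    keys = layout.keys()
    truth = {
        "label": scenario.label,
        "causal_a": causals["causal_a"],
        "effects_a": causals["effects_a"],
        "causal_b": causals["causal_b"],
        "effects_b": causals["effects_b"],
        "causal_keys_a": [str(keys[i]) for i in causals["causal_a"]],
        "causal_keys_b": [str(keys[i]) for i in causals["causal_b"]],
        "theta": scenario.theta,
        "mediating_tissue": scenario.mediating_tissue,
        "layout": layout,
    }
    return stats_a, stats_b, panel, truth


def simulate_outcome(panel: GenotypePanel, truth: dict, scenario: LocusScenario) -> LocusSumStats:
    """Outcome GWAS for the locus: outcome = theta · protein + noise, fresh cohort.

    The protein value is rebuilt from the mediating tissue's causal model in
    an independent cohort of size ``n_outcome``; marginal OLS summary
    statistics are emitted for every locus variant.
    """
    layout: LocusLayout = truth["layout"]
    ss = np.random.SeedSequence(scenario.seed)
    rng = np.random.default_rng(ss.spawn(6)[5])
    n = scenario.n_outcome
    dos = _dosages(rng, n, layout, scenario.rho)
    x = _standardize(dos)
    side = truth["mediating_tissue"]
    causal = truth[f"causal_{side}"]
    effects = truth[f"effects_{side}"]
    protein = _phenotype(x, causal, effects, rng)
    theta = truth["theta"]
    noise_var = max(1.0 - theta**2 * float(np.var(protein)), 1e-9)
    y = theta * protein + rng.standard_normal(n) * np.sqrt(noise_var)
    beta, se, p = _marginal_ols(x, y)
    df = _sumstats_df(layout, dos, beta, se, p, n)
    pid = f"protein_{scenario.seed}"
    return LocusSumStats(pid, layout.chrom, layout.gene_start, layout.gene_end, df)


def simulate_expression(
    g_genes: int = 2000,
    n_tissues: int = 50,
    n_per_tissue: int = 20,
    planted_frac: float = 0.05,
    fold: float = 8.0,
    dispersion: float = 0.1,
    seed: int = 0,
    gene_ids: list[str] | None = None,
    tissue_ids: list[str] | None = None,
    planted_assign: dict[str, str] | None = None,
):
    """Negative-binomial count matrix with planted tissue-enriched genes.

    Per-gene baseline log2-expression is Normal(5, 2); planted genes (a
    ``planted_frac`` fraction, or an explicit gene→tissue assignment) gain
    log2(fold) in their enriched tissue. Library sizes are log-normal around
    5×10⁵. Returns ``(CountMatrix, truth)`` with ``truth['enriched']``
    mapping planted gene → tissue.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    genes = gene_ids or [f"G{i:05d}" for i in range(g_genes)]
    tissues = tissue_ids or [f"tissue_{t:02d}" for t in range(n_tissues)]
    g_genes, n_tissues = len(genes), len(tissues)
    samples = [f"{t}_s{i:02d}" for t in tissues for i in range(n_per_tissue)]
    tissue_of = {s: s.rsplit("_s", 1)[0] for s in samples}

    base_log2 = rng.normal(5.0, 2.0, size=g_genes)
    shift = np.zeros((g_genes, n_tissues))
    if planted_assign is None:
        n_plant = int(round(planted_frac * g_genes))
        planted_genes = rng.choice(g_genes, size=n_plant, replace=False)
        planted_assign = {
            genes[int(g)]: tissues[int(rng.integers(0, n_tissues))] for g in planted_genes
        }
    t_index = {t: j for j, t in enumerate(tissues)}
    g_index = {g: i for i, g in enumerate(genes)}
    for g, t in planted_assign.items():
        shift[g_index[g], t_index[t]] = np.log2(fold)

    rel = 2.0 ** (base_log2[:, None] + shift)  # genes × tissues relative expression
    lib = rng.lognormal(mean=np.log(5e5), sigma=0.3, size=len(samples))
    counts = np.empty((g_genes, len(samples)), dtype=np.int64)
    size = 1.0 / dispersion
    for si, s in enumerate(samples):
        tj = t_index[tissue_of[s]]
        frac = rel[:, tj] / rel[:, tj].sum()
        mu = frac * lib[si]
        counts[:, si] = rng.negative_binomial(size, size / (size + mu))
    cm = CountMatrix(genes, samples, tissue_of, counts)
    truth = {"enriched": dict(planted_assign), "fold": fold, "base_log2": base_log2}
    return cm, truth


def write_panel_vcf(panel: GenotypePanel, path) -> None:
    """Write hard-call dosages as an uncompressed VCF 4.2 with GT fields."""
    gt_map = np.array(["0/0", "0/1", "1/1"])
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        chroms = sorted({k.chrom for k in panel.keys}, key=str)
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(panel.samples) + "\n")
        dos = np.rint(panel.dosages).astype(int).T  # variants × samples
        for j, k in enumerate(panel.keys):
            row = gt_map[dos[j]]
            fh.write(f"{k.chrom}\t{k.pos}\t.\t{k.a2}\t{k.a1}\t.\tPASS\t.\tGT\t")
            fh.write("\t".join(row) + "\n")


DEFAULT_MIX = {
    "SHARED_CONCORDANT": 0.40,
    "SHARED_DISCORDANT": 0.10,
    "DISTINCT": 0.25,
    "A_ONLY": 0.15,
    "NULL": 0.10,
}


@dataclass
class StudyConfig:
    """Default study conditions for the end-to-end simulated cohort."""

    n_proteins: int = 40
    mix: dict = field(default_factory=lambda: dict(DEFAULT_MIX))
    scenario: LocusScenario = field(default_factory=LocusScenario)
    # per-protein effect heterogeneity: explained variance drawn uniformly and
    # the protein-increasing allele's sign randomized, as in real pQTL panels
    h2_range: tuple[float, float] | None = (0.04, 0.12)
    vary_effect_sign: bool = True
    # expression stage
    g_genes: int = 2000
    n_tissues: int = 50
    n_per_tissue: int = 20
    planted_frac: float = 0.05
    fold: float = 8.0
    dispersion: float = 0.1
    link_expression_to_scenario: bool = True
    seed: int = 0


def _scenario_labels(cfg: StudyConfig) -> list[str]:
    """Deterministic scenario assignment matching the mix exactly."""
    counts = {lab: int(round(frac * cfg.n_proteins)) for lab, frac in cfg.mix.items()}
    drift = cfg.n_proteins - sum(counts.values())
    counts[max(counts, key=counts.get)] += drift
    labels = [lab for lab in SCENARIOS if lab in counts for _ in range(counts[lab])]
    return labels[: cfg.n_proteins]


def simulate_study(cfg: StudyConfig, out_dir: str | Path | None = None) -> dict:
    """Generate the full input bundle: per-protein loci, outcome GWAS, expression.

    Returns an in-memory bundle and, when ``out_dir`` is given, writes the
    on-disk form: per-protein summary-statistics TSVs (tissues A/B and the
    outcome), one LD-panel VCF, the gene-coordinates BED, the count matrix and
    tissue map, and the ground-truth JSON.
    """
    from pqtlx.sumstats import write_sumstats

    labels = _scenario_labels(cfg)
    root_ss = np.random.SeedSequence(cfg.seed)
    locus_seeds = root_ss.generate_state(cfg.n_proteins) % (2**31 - 1)

    het_rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 911)))
    loci = []
    for i, lab in enumerate(labels):
        h2 = (
            float(het_rng.uniform(*cfg.h2_range))
            if cfg.h2_range is not None
            else cfg.scenario.h2_signal
        )
        sign = float(het_rng.choice([-1.0, 1.0])) if cfg.vary_effect_sign else 1.0
        sc = replace(
            cfg.scenario, label=lab, chrom=str(i + 1), seed=int(locus_seeds[i]),
            h2_signal=h2, effect_sign=sign,
        )
        stats_a, stats_b, panel, truth = simulate_locus(sc)
        outcome = simulate_outcome(panel, truth, sc)
        pid = f"P{i:03d}"
        for s in (stats_a, stats_b, outcome):
            s.protein_id = pid
        loci.append(
            {
                "protein_id": pid,
                "scenario": sc,
                "stats_a": stats_a,
                "stats_b": stats_b,
                "outcome": outcome,
                "panel": panel,
                "truth": truth,
            }
        )

    # expression: protein genes carry scenario-linked planted enrichment so the
    # coloc-vs-expression contrast has signal to find
    gene_ids = [f"P{i:03d}" for i in range(cfg.n_proteins)] + [
        f"G{i:05d}" for i in range(cfg.g_genes - cfg.n_proteins)
    ]
    tissue_ids = ["brain_cortex", "whole_blood"] + [
        f"tissue_{t:02d}" for t in range(cfg.n_tissues - 2)
    ]
    expr_rng = np.random.default_rng(root_ss.spawn(1)[0])
    planted: dict[str, str] = {}
    if cfg.link_expression_to_scenario:
        for lo in loci:
            lab = lo["scenario"].label
            if lab in ("A_ONLY", "DISTINCT", "NULL") and expr_rng.random() < 0.5:
                planted[lo["protein_id"]] = "brain_cortex"
            elif lab.startswith("SHARED") and expr_rng.random() < 0.5:
                planted[lo["protein_id"]] = "whole_blood"
    n_bg = int(round(cfg.planted_frac * cfg.g_genes))
    bg_genes = expr_rng.choice(gene_ids[cfg.n_proteins :], size=n_bg, replace=False)
    for g in bg_genes:
        planted[str(g)] = tissue_ids[int(expr_rng.integers(0, len(tissue_ids)))]
    counts, expr_truth = simulate_expression(
        g_genes=cfg.g_genes,
        n_tissues=cfg.n_tissues,
        n_per_tissue=cfg.n_per_tissue,
        fold=cfg.fold,
        dispersion=cfg.dispersion,
        seed=int(root_ss.generate_state(cfg.n_proteins + 1)[-1] % (2**31 - 1)),
        gene_ids=gene_ids,
        tissue_ids=tissue_ids,
        planted_assign=planted,
    )

    bundle = {"config": cfg, "loci": loci, "counts": counts, "expr_truth": expr_truth}

    if out_dir is not None:
        out = Path(out_dir)
        (out / "sumstats_a").mkdir(parents=True, exist_ok=True)
        (out / "sumstats_b").mkdir(exist_ok=True)
        (out / "outcome").mkdir(exist_ok=True)
        bed_lines = []
        vcf_keys: list[VariantKey] = []
        vcf_cols = []
        for lo in loci:
            pid = lo["protein_id"]
            write_sumstats(lo["stats_a"], out / "sumstats_a" / f"{pid}.tsv")
            write_sumstats(lo["stats_b"], out / "sumstats_b" / f"{pid}.tsv")
            write_sumstats(lo["outcome"], out / "outcome" / f"{pid}.tsv")
            st = lo["stats_a"]
            bed_lines.append(f"{st.chrom}\t{st.gene_start - 1}\t{st.gene_end}\t{pid}")
            vcf_keys.extend(lo["panel"].keys)
            vcf_cols.append(lo["panel"].dosages)
        (out / "genes.bed").write_text("\n".join(bed_lines) + "\n")
        merged = GenotypePanel(
            loci[0]["panel"].samples, vcf_keys, np.concatenate(vcf_cols, axis=1)
        )
        write_panel_vcf(merged, out / "panel.vcf")
        counts_df = pd.DataFrame(counts.counts, index=counts.genes, columns=counts.samples)
        counts_df.to_csv(out / "counts.tsv", sep="\t")
        pd.Series(counts.tissue_of, name="tissue").rename_axis("sample").to_csv(
            out / "tissues.tsv", sep="\t"
        )
        truth_json = {
            "labels": {lo["protein_id"]: lo["scenario"].label for lo in loci},
            "theta": {lo["protein_id"]: lo["truth"]["theta"] for lo in loci},
            "causal_keys_a": {lo["protein_id"]: lo["truth"]["causal_keys_a"] for lo in loci},
            "causal_keys_b": {lo["protein_id"]: lo["truth"]["causal_keys_b"] for lo in loci},
            "enriched": expr_truth["enriched"],
        }
        (out / "truth.json").write_text(json.dumps(truth_json, indent=1))
    return bundle


def load_study(in_dir: str | Path) -> dict:
    """Reload a study bundle from its on-disk form (inverse of :func:`simulate_study`).

    The returned bundle has the same shape the pipeline stages consume;
    scenario ground truth is restricted to what the truth file records
    (labels, causal variant keys, theta).
    """
    from types import SimpleNamespace

    from pqtlx.enrichment import CountMatrix
    from pqtlx.ld import load_panel
    from pqtlx.sumstats import read_gene_bed, read_sumstats

    root = Path(in_dir)
    genes = read_gene_bed(root / "genes.bed")
    truth_json = json.loads((root / "truth.json").read_text())
    panel_all = load_panel(root / "panel.vcf")
    by_chrom: dict[str, list[int]] = {}
    for j, k in enumerate(panel_all.keys):
        by_chrom.setdefault(k.chrom, []).append(j)

    loci = []
    for pid in sorted(genes):
        chrom, gstart, gend = genes[pid]
        kw = dict(protein_id=pid, gene_start=gstart, gene_end=gend)
        stats_a = read_sumstats(root / "sumstats_a" / f"{pid}.tsv", **kw)
        stats_b = read_sumstats(root / "sumstats_b" / f"{pid}.tsv", **kw)
        outcome = read_sumstats(root / "outcome" / f"{pid}.tsv", **kw)
        cols = by_chrom[chrom]
        panel = GenotypePanel(
            panel_all.samples,
            [panel_all.keys[j] for j in cols],
            panel_all.dosages[:, cols],
            panel_all.missing_rate[cols],
        )
        loci.append(
            {
                "protein_id": pid,
                "scenario": SimpleNamespace(label=truth_json["labels"][pid]),
                "stats_a": stats_a,
                "stats_b": stats_b,
                "outcome": outcome,
                "panel": panel,
                "truth": {
                    "label": truth_json["labels"][pid],
                    "theta": truth_json["theta"][pid],
                    "causal_keys_a": truth_json["causal_keys_a"][pid],
                    "causal_keys_b": truth_json["causal_keys_b"][pid],
                },
            }
        )
    counts = CountMatrix.from_tsv(root / "counts.tsv", root / "tissues.tsv")
    return {"config": None, "loci": loci, "counts": counts,
            "expr_truth": {"enriched": truth_json["enriched"]}}
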