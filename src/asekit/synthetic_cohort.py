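"""Synthetic cohorts with the data structure the ASE analysis assumes.

The generator draws phased subject genotypes from an explicit haplotype
pool (LD arises only from that pool — no recombination model), plants a
cis-regulatory allele that multiplies the expression of any haplotype
carrying it, and emits noisy allelic peak-area measurements with the
assay's replicate design: per heterozygous 3'-UTR marker SNP, a gDNA
pair per replicate slot and n_preps x n_duplicates cDNA pairs, each peak
area perturbed by multiplicative lognormal noise.

Defaults emulate a 118-subject colorectal-cancer cohort genotyped at 23
SNPs (19 locus SNPs, four of which are the 3'-UTR assay markers, plus 4
filler SNPs), a causal allele at frequency 0.10 halving one haplotype's
expression, and clinical covariates drawn independently of ASE status.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .ase_calling import DEFAULT_MARKERS, classify

__all__ = [
    "PanelBlock",
    "HaplotypePanel",
    "SimulationConfig",
    "PhasedGenotypes",
    "ConfigError",
    "default_blocks",
    "build_panel",
    "draw_subjects",
    "simulate_expression",
    "simulate_peaks",
    "simulate_covariates",
    "simulate_cohort",
    "genotype_matrix",
    "expected_prevalence",
    "write_cohort",
]


class ConfigError(ValueError):
    """Invalid simulation configuration; the message names the field."""


@dataclass(frozen=True)
class PanelBlock:
    """An LD block: haplotypes over a few SNPs with their frequencies.

    Blocks are statistically independent of each other; the full panel is
    their cross product.
    """

    snp_ids: tuple[str, ...]
    haplotypes: tuple[tuple[int, ...], ...]
    frequencies: tuple[float, ...]


@dataclass
class HaplotypePanel:
    """Explicit haplotype pool: allele vectors over {0,1}^M with frequencies."""

    snp_ids: tuple[str, ...]
    haplotypes: np.ndarray  # (H, M) int
    frequencies: np.ndarray  # (H,)

    def __post_init__(self) -> None:
        self.haplotypes = np.asarray(self.haplotypes, dtype=int)
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        if self.haplotypes.ndim != 2 or self.haplotypes.shape[0] < 2:
            raise ConfigError("haplotypes: need >= 2 haplotype vectors")
        if self.haplotypes.shape[1] != len(self.snp_ids):
            raise ConfigError("haplotypes: vector length must equal len(snp_ids)")
        if not np.isin(self.haplotypes, [0, 1]).all():
            raise ConfigError("haplotypes: alleles must be 0/1")
        if (self.frequencies < 0).any():
            raise ConfigError("frequencies: must be non-negative")
        if abs(self.frequencies.sum() - 1.0) > 1e-9:
            raise ConfigError(f"frequencies: sum {self.frequencies.sum()} != 1 within 1e-9")

    def allele_freq(self, snp_id: str) -> float:
        j = self.snp_ids.index(snp_id)
        return float(self.frequencies @ self.haplotypes[:, j])


@dataclass(frozen=True)
class PhasedGenotypes:
    subject_id: str
    haplotype_a: np.ndarray
    haplotype_b: np.ndarray
    phase_known: bool
    snp_ids: tuple[str, ...]

    def genotype(self, snp_id: str) -> int:
        j = self.snp_ids.index(snp_id)
        return int(self.haplotype_a[j] + self.haplotype_b[j])

    def heterozygous(self, snp_id: str) -> bool:
        return self.genotype(snp_id) == 1


def default_blocks() -> tuple[PanelBlock, ...]:
    """Default LD blocks for the 23-SNP synthetic locus.

    The causal block couples the causal coding SNP (9A/6A, allele frequency
    0.10) to a perfect proxy (rs11568785, r2 = 1) and a partial proxy
    (rs7034462, r2 ~ 0.63).  The four assay markers form two internally
    perfect blocks with MAF 0.28 and 0.12, giving ~53% of subjects at least
    one heterozygous marker and an expected noise-free ASE prevalence of
    ~9.5% at the default effect fold.
    """
    return (
        PanelBlock(("rs7034462", "9A/6A", "rs11568785"),
                   ((1, 1, 1), (1, 0, 0), (0, 0, 0)), (0.10, 0.05, 0.85)),
        PanelBlock(("rs334348", "rs334349"), ((1, 1), (0, 0)), (0.28, 0.72)),
        PanelBlock(("rs1590", "rs7871490"), ((1, 1), (0, 0)), (0.12, 0.88)),
        PanelBlock(("rs4742761", "rs2416666", "rs7874183"),
                   ((1, 1, 1), (1, 0, 0), (0, 0, 0)), (0.20, 0.05, 0.75)),
        PanelBlock(("rs10819634", "rs1888223", "rs10988705"),
                   ((0, 0, 0), (1, 1, 0), (0, 1, 1)), (0.55, 0.25, 0.20)),
        PanelBlock(("rs6478974", "rs10739778", "rs2026811"),
                   ((0, 0, 0), (1, 1, 1), (1, 0, 0)), (0.45, 0.40, 0.15)),
        PanelBlock(("rs10512263", "rs7850895", "rs1626340"),
                   ((0, 0, 0), (1, 0, 1), (0, 1, 0)), (0.80, 0.10, 0.10)),
        PanelBlock(("rs990001", "rs990002", "rs990003", "rs990004"),
                   ((0, 0, 0, 0), (1, 1, 1, 1), (1, 1, 0, 0)), (0.50, 0.30, 0.20)),
    )


_DEFAULT_COVARIATES: dict[str, dict[str, float]] = {
    "sex": {"female": 0.466, "male": 0.534},
    "tumor_location": {"colon": 0.653, "rectum": 0.339, "both": 0.008},
    "ethnicity": {"caucasian": 0.831, "african_american": 0.119,
                  "asian": 0.025, "hispanic": 0.025},
    "stage": {"1": 0.093, "2": 0.254, "3": 0.373, "4": 0.280},
    "family_history": {"no": 0.644, "yes": 0.288, "unknown": 0.068},
}


@dataclass
class SimulationConfig:
    """Study-design parameters of the synthetic cohort.

    ``effect_fold`` multiplies the expression of every haplotype carrying
    allele 1 at ``causal_snp_id`` (0.5 = the carried allele is transcribed
    at half the level of the other).  ``sigma_gdna``/``sigma_cdna`` are the
    standard deviations of the lognormal multiplicative noise on each peak
    area; ``baseline_area`` is the noise-free fluorescence peak area.
    """

    n_subjects: int = 118
    seed: int = 0
    marker_snp_ids: tuple[str, ...] = DEFAULT_MARKERS
    causal_snp_id: str = "9A/6A"
    effect_fold: float = 0.5
    sigma_gdna: float = 0.05
    sigma_cdna: float = 0.10
    n_preps: int = 2
    n_duplicates: int = 2
    baseline_area: float = 10_000.0
    shared_gdna: bool = False
    covariate_distributions: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in _DEFAULT_COVARIATES.items()})
    age_mean: float = 60.0
    age_sd: float = 11.0
    age_range: tuple[int, int] = (35, 84)
    panel_blocks: tuple[PanelBlock, ...] | None = None

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ConfigError("n_subjects: must be >= 1")
        if not self.effect_fold > 0:
            raise ConfigError("effect_fold: must be > 0")
        if self.sigma_gdna < 0 or self.sigma_cdna < 0:
            raise ConfigError("sigma_gdna/sigma_cdna: must be >= 0")
        if self.n_preps * self.n_duplicates < 1:
            raise ConfigError("n_preps x n_duplicates: must be >= 1")
        if not self.baseline_area > 0:
            raise ConfigError("baseline_area: must be > 0")
        for col, dist in self.covariate_distributions.items():
            if abs(sum(dist.values()) - 1.0) > 1e-9:
                raise ConfigError(
                    f"covariate_distributions[{col!r}]: probabilities sum to "
                    f"{sum(dist.values())}, not 1 within 1e-9")

    def blocks(self) -> tuple[PanelBlock, ...]:
        return self.panel_blocks if self.panel_blocks is not None else default_blocks()


def build_panel(config: SimulationConfig) -> HaplotypePanel:
    """Expand the config's LD blocks into the full haplotype cross product."""
    blocks = config.blocks()
    for b in blocks:
        if abs(sum(b.frequencies) - 1.0) > 1e-9:
            raise ConfigError(f"panel_blocks[{b.snp_ids}]: frequencies must sum to 1")
        if any(len(h) != len(b.snp_ids) for h in b.haplotypes):
            raise ConfigError(f"panel_blocks[{b.snp_ids}]: haplotype length mismatch")
    snp_ids = tuple(s for b in blocks for s in b.snp_ids)
    if len(set(snp_ids)) != len(snp_ids):
        raise ConfigError("panel_blocks: duplicate snp_ids across blocks")
    haps = np.array([[1]])  # seed for the cross product
    haps = np.zeros((1, 0), dtype=int)
    freqs = np.array([1.0])
    for b in blocks:
        bh = np.asarray(b.haplotypes, dtype=int)
        bf = np.asarray(b.frequencies, dtype=float)
        haps = np.concatenate(
            [np.repeat(haps, len(bh), axis=0),
             np.tile(bh, (len(haps), 1))], axis=1)
        freqs = np.kron(freqs, bf)
    panel = HaplotypePanel(snp_ids, haps, freqs)
    for m in config.marker_snp_ids:
        if m not in snp_ids:
            raise ConfigError(f"marker_snp_ids: {m!r} not in panel SNPs")
    if config.causal_snp_id not in snp_ids:
        raise ConfigError(f"causal_snp_id: {config.causal_snp_id!r} not in panel SNPs")
    return panel


def draw_subjects(panel: HaplotypePanel, n: int, seed) -> list[PhasedGenotypes]:
    """Draw n subjects as independent haplotype pairs (Hardy-Weinberg)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(panel.frequencies), size=(n, 2), p=panel.frequencies)
    width = max(3, len(str(n)))
    return [
        PhasedGenotypes(f"S{i + 1:0{width}d}",
                        panel.haplotypes[a].copy(), panel.haplotypes[b].copy(),
                        True, panel.snp_ids)
        for i, (a, b) in enumerate(idx)
    ]


def simulate_expression(subject: PhasedGenotypes, causal_snp_id: str,
                        effect_fold: float) -> tuple[float, float]:
    """Per-haplotype expression: 1.0, times effect_fold on causal carriers."""
    j = subject.snp_ids.index(causal_snp_id)
    e_a = effect_fold if subject.haplotype_a[j] == 1 else 1.0
    e_b = effect_fold if subject.haplotype_b[j] == 1 else 1.0
    return (e_a, e_b)


def simulate_peaks(
    subject: PhasedGenotypes,
    expression_levels: tuple[float, float],
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> list[dict]:
    """Noisy allelic peak areas for every heterozygous marker SNP.

    Emits long-format rows (subject_id, snp_id, template, prep, duplicate,
    area_allele0, area_allele1).  The expected cDNA area of an allele is
    proportional to the expression of the haplotype carrying it; gDNA areas
    are balanced at ``baseline_area``.  Each area is multiplied by
    lognormal(0, sigma) noise, sigma per template.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    e_a, e_b = expression_levels
    rows: list[dict] = []
    slots = [(p, d) for p in range(1, config.n_preps + 1)
             for d in range(1, config.n_duplicates + 1)]
    gdna_slots = [(1, 1)] if config.shared_gdna else slots

    def noisy(expected: float, sigma: float) -> float:
        return expected * float(np.exp(rng.normal(0.0, sigma))) if sigma > 0 else expected

    for j, snp in enumerate(subject.snp_ids):
        if snp not in config.marker_snp_ids:
            continue
        a_allele, b_allele = int(subject.haplotype_a[j]), int(subject.haplotype_b[j])
        if a_allele + b_allele != 1:
            continue  # measurements only exist for heterozygous markers
        # expression of the haplotype carrying allele 0 / allele 1
        e0, e1 = (e_a, e_b) if a_allele == 0 else (e_b, e_a)
        for prep, dup in gdna_slots:
            rows.append({
                "subject_id": subject.subject_id, "snp_id": snp,
                "template": "gDNA", "prep": prep, "duplicate": dup,
                "area_allele0": noisy(config.baseline_area, config.sigma_gdna),
                "area_allele1": noisy(config.baseline_area, config.sigma_gdna),
            })
        for prep, dup in slots:
            rows.append({
                "subject_id": subject.subject_id, "snp_id": snp,
                "template": "cDNA", "prep": prep, "duplicate": dup,
                "area_allele0": noisy(config.baseline_area * e0, config.sigma_cdna),
                "area_allele1": noisy(config.baseline_area * e1, config.sigma_cdna),
            })
    return rows


def simulate_covariates(config: SimulationConfig, subject_ids: list[str],
                        rng: np.random.Generator) -> pd.DataFrame:
    """Clinical covariates drawn independently of ASE status (null design)."""
    n = len(subject_ids)
    lo, hi = config.age_range
    age = np.clip(np.round(rng.normal(config.age_mean, config.age_sd, size=n)),
                  lo, hi).astype(int)
    data: dict = {"age": age}
    for col, dist in config.covariate_distributions.items():
        levels = list(dist)
        probs = np.array([dist[l] for l in levels], dtype=float)
        probs = probs / probs.sum()
        data[col] = rng.choice(levels, size=n, p=probs)
    return pd.DataFrame(data, index=pd.Index(subject_ids, name="subject_id"))


def genotype_matrix(subjects: list[PhasedGenotypes]) -> pd.DataFrame:
    """Subjects x SNPs 0/1/2 matrix counting allele 1."""
    snp_ids = subjects[0].snp_ids
    rows = [s.haplotype_a + s.haplotype_b for s in subjects]
    return pd.DataFrame(np.array(rows), columns=list(snp_ids),
                        index=pd.Index([s.subject_id for s in subjects],
                                       name="subject_id"))


def simulate_cohort(config: SimulationConfig) -> dict:
    """End-to-end simulation: panel, subjects, peaks, covariates, truth.

    One master seed; derived child streams (subjects, peak noise,
    covariates) are spawned deterministically so stages can be rerun in
    isolation.
    """
    panel = build_panel(config)
    ss = np.random.SeedSequence(config.seed)
    seed_subjects, seed_noise, seed_cov = ss.spawn(3)
    subjects = draw_subjects(panel, config.n_subjects, seed_subjects)
    noise_rng = np.random.default_rng(seed_noise)
    cov_rng = np.random.default_rng(seed_cov)

    peaks_rows: list[dict] = []
    truth_subjects: dict[str, dict] = {}
    for s in subjects:
        expr = simulate_expression(s, config.causal_snp_id, config.effect_fold)
        peaks_rows.extend(simulate_peaks(s, expr, config, rng=noise_rng))
        het_causal = s.heterozygous(config.causal_snp_id)
        het_markers = [m for m in config.marker_snp_ids if s.heterozygous(m)]
        fold = expr[0] / expr[1] if expr[1] else float("inf")
        expected_call = "uninformative"
        if het_markers:
            expected_call = classify(max(fold, 1.0 / fold)) if fold != 1.0 else "negative"
        truth_subjects[s.subject_id] = {
            "het_causal": het_causal,
            "informative": bool(het_markers),
            "het_markers": het_markers,
            "expression": list(expr),
            "true_fold": fold,
            "expected_call": expected_call,
        }
    peaks = pd.DataFrame(
        peaks_rows, columns=["subject_id", "snp_id", "template", "prep",
                             "duplicate", "area_allele0", "area_allele1"])
    covariates = simulate_covariates(config, [s.subject_id for s in subjects], cov_rng)
    truth = {
        "causal_snp_id": config.causal_snp_id,
        "effect_fold": config.effect_fold,
        "subjects": truth_subjects,
    }
    return {"panel": panel, "subjects": subjects, "peaks": peaks,
            "covariates": covariates, "truth": truth,
            "genotypes": genotype_matrix(subjects)}


def expected_prevalence(panel: HaplotypePanel, config: SimulationConfig) -> float:
    """Exact noise-free ASE-positive probability under the panel and config.

    Enumerates ordered haplotype pairs: a subject is expected positive iff
    heterozygous at the causal SNP (so the allelic fold is effect_fold or
    its inverse), heterozygous at >= 1 marker (assayable), and the fold
    falls outside the diagnostic band.
    """
    f = panel.frequencies
    jc = panel.snp_ids.index(config.causal_snp_id)
    hc = panel.haplotypes[:, jc]
    het_causal = hc[:, None] != hc[None, :]
    informative = np.zeros_like(het_causal)
    for m in config.marker_snp_ids:
        hm = panel.haplotypes[:, panel.snp_ids.index(m)]
        informative |= hm[:, None] != hm[None, :]
    fold = config.effect_fold
    passes = (classify(fold) == "positive") or (classify(1.0 / fold) == "positive") \
        if fold != 1.0 else False
    if not passes:
        return 0.0
    w = np.outer(f, f)
    return float(w[het_causal & informative].sum())


def write_cohort(cohort: dict, out_dir: str | Path) -> dict[str, Path]:
    """Write genotypes (VCF + TSV), peaks CSV, covariates CSV and truth JSON."""
    from . import io as _io

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": out / "genotypes.vcf",
        "tsv": out / "genotypes.tsv",
        "peaks": out / "peaks.csv",
        "covariates": out / "covariates.csv",
        "truth": out / "truth.json",
    }
    _io.write_vcf(cohort["subjects"], paths["vcf"])
    _io.write_genotype_tsv(cohort["genotypes"], paths["tsv"])
    _io.write_peaks(cohort["peaks"], paths["peaks"])
    _io.write_covariates(cohort["covariates"], paths["covariates"])
    _io.write_truth(cohort["truth"], paths["truth"])
    return paths
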