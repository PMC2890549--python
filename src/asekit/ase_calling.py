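"""Allele-specific expression (ASE) calling from allelic peak areas.

The assay quantifies both alleles of a transcribed marker SNP in a
heterozygous subject as two fluorescence peak areas, once from genomic DNA
(gDNA, expected balanced) and repeatedly from cDNA.  The ASE statistic per
replicate is

    R = [cDNA area(common allele) / cDNA area(rare allele)]
        / [gDNA area(common allele) / gDNA area(rare allele)]

i.e. the cDNA allelic ratio normalised by the gDNA ratio to cancel
allele-specific amplification bias.  Replicates (two independent cDNA
preparations, each in duplicate — four ratios) are averaged arithmetically,
and the subject is called ASE-positive when the mean ratio falls outside the
band (0.67, 1.5): mean >= 1.5 or <= 0.67, boundaries inclusive.

Subjects with no heterozygous marker SNP cannot be assayed and are
"uninformative"; they are excluded from the phenotype denominator used in
association testing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import association

__all__ = [
    "PeakMeasurement",
    "SnpASE",
    "ASECall",
    "CohortSummary",
    "MeasurementError",
    "PairingError",
    "normalized_ratio",
    "replicate_mean",
    "classify",
    "informative_subject",
    "common_alleles",
    "call_cohort",
    "summarize_cohort",
]

GDNA = "gDNA"
CDNA = "cDNA"

#: Default diagnostic band: positive iff mean ratio >= upper or <= lower.
ASE_UPPER = 1.5
ASE_LOWER = 0.67

#: The four 3'-UTR marker SNPs assayed by default.
DEFAULT_MARKERS = ("rs334348", "rs334349", "rs1590", "rs7871490")


class MeasurementError(ValueError):
    """Non-positive peak area or otherwise unusable measurement."""


class PairingError(ValueError):
    """cDNA/gDNA measurements that do not belong together."""


@dataclass(frozen=True)
class PeakMeasurement:
    """One allelic peak-area pair, oriented common/rare.

    ``prep`` and ``duplicate`` are 1-based replicate coordinates; gDNA and
    cDNA measurements share the same coordinate system so they can be paired
    slot by slot.
    """

    subject_id: str
    snp_id: str
    template: str
    prep: int
    duplicate: int
    area_common: float
    area_rare: float

    def __post_init__(self) -> None:
        if self.template not in (GDNA, CDNA):
            raise ValueError(f"template must be {GDNA!r} or {CDNA!r}, got {self.template!r}")
        if not (self.area_common > 0 and self.area_rare > 0):
            raise MeasurementError(
                f"peak areas must be > 0 "
                f"({self.subject_id}/{self.snp_id}: {self.area_common}, {self.area_rare})"
            )
        if self.prep < 1 or self.duplicate < 1:
            raise ValueError("prep and duplicate are 1-based")

    @property
    def ratio(self) -> float:
        return self.area_common / self.area_rare


@dataclass
class SnpASE:
    """Per-SNP replicate ratios for one subject."""

    replicate_ratios: list[float]
    mean_ratio: float
    n_ratios: int


@dataclass
class ASECall:
    subject_id: str
    per_snp: dict[str, SnpASE]
    call: str  # positive | negative | uninformative
    concordant: bool
    informative_snps: list[str]
    warnings: list[str] = field(default_factory=list)


@dataclass
class CohortSummary:
    """Stratified demographics by ASE status plus clinical Fisher contrasts."""

    n_total: int
    n_positive: int
    n_negative: int
    n_uninformative: int
    strata: pd.DataFrame  # covariate, level, n_all, n_pos, n_neg + percentages
    fisher_contrasts: dict[str, float]

    @property
    def prevalence(self) -> float:
        return self.n_positive / self.n_total if self.n_total else 0.0


def normalized_ratio(gdna: PeakMeasurement, cdna: PeakMeasurement) -> float:
    """cDNA common/rare ratio divided by the matching gDNA common/rare ratio."""
    if gdna.template != GDNA or cdna.template != CDNA:
        raise PairingError("arguments must be (gDNA, cDNA) in that order")
    if (gdna.subject_id, gdna.snp_id) != (cdna.subject_id, cdna.snp_id):
        raise PairingError(
            f"mismatched keys: {(gdna.subject_id, gdna.snp_id)} vs "
            f"{(cdna.subject_id, cdna.snp_id)}"
        )
    return cdna.ratio / gdna.ratio


def replicate_mean(ratios: list[float], *, expected_n: int = 4) -> SnpASE:
    """Arithmetic mean of replicate ratios; warns when replicates are short."""
    if len(ratios) == 0:
        raise ValueError("no replicate ratios to average")
    if any(r <= 0 for r in ratios):
        raise MeasurementError("ratios must be positive")
    if len(ratios) < expected_n:
        warnings.warn(
            f"only {len(ratios)} of {expected_n} expected replicate ratios",
            stacklevel=2,
        )
    return SnpASE(list(ratios), float(np.mean(ratios)), len(ratios))


def classify(mean_ratio: float, *, upper: float = ASE_UPPER, lower: float = ASE_LOWER,
             strict: bool = False) -> str:
    """Call one mean ratio: positive outside the (lower, upper) band.

    Boundaries are inclusive by default (>= upper or <= lower); ``strict``
    switches to strict inequalities.  Note the band is not reciprocal:
    1/1.5 = 0.667 <= 0.67 is positive.
    """
    if not mean_ratio > 0:
        raise ValueError(f"mean ratio must be > 0, got {mean_ratio}")
    if strict:
        return "positive" if (mean_ratio > upper or mean_ratio < lower) else "negative"
    return "positive" if (mean_ratio >= upper or mean_ratio <= lower) else "negative"


def informative_subject(
    genotypes_at_markers: pd.Series | dict,
) -> tuple[bool, list[str]]:
    """A subject is informative iff heterozygous at >= 1 marker SNP.

    Missing genotypes are treated as non-informative at that marker.
    Returns the flag and the list of heterozygous (usable) markers.
    """
    geno = pd.Series(genotypes_at_markers, dtype="float64")
    hets = [str(s) for s, g in geno.items() if g == 1]
    return bool(hets), hets


def common_alleles(genotypes: pd.DataFrame) -> dict[str, int]:
    """Designate the cohort-common allele (0 or 1) per SNP.

    ``genotypes`` codes count allele "1"; the common allele is the one with
    the higher cohort allele frequency, ties broken toward allele "0"
    (lexicographically smaller symbol).
    """
    out: dict[str, int] = {}
    for snp in genotypes.columns:
        g = pd.to_numeric(genotypes[snp], errors="coerce").dropna()
        n1 = g.sum()
        n0 = 2 * len(g) - n1
        out[str(snp)] = 1 if n1 > n0 else 0
    return out


def _orient(row: pd.Series, common: int) -> tuple[float, float]:
    a0, a1 = float(row["area_allele0"]), float(row["area_allele1"])
    return (a1, a0) if common == 1 else (a0, a1)


def call_cohort(
    peaks: pd.DataFrame,
    genotypes: pd.DataFrame,
    *,
    marker_snp_ids: tuple[str, ...] = DEFAULT_MARKERS,
    upper: float = ASE_UPPER,
    lower: float = ASE_LOWER,
    strict: bool = False,
    expected_replicates: int = 4,
) -> list[ASECall]:
    """Call the ASE phenotype for every subject in the genotype matrix.

    ``peaks`` is the long measurement table with columns
    subject_id, snp_id, template, prep, duplicate, area_allele0, area_allele1;
    ``genotypes`` is subjects x SNPs coded 0/1/2/NaN counting allele 1.

    Per subject and heterozygous marker SNP, each cDNA replicate slot is
    normalised by the gDNA measurement in the same (prep, duplicate) slot
    when one exists, otherwise all cDNA slots share the mean gDNA ratio; the
    replicate ratios are averaged and classified.  The subject is positive
    if any informative SNP's mean ratio is classified positive; discordance
    (one SNP >= upper while another <= lower) clears the ``concordant`` flag.

    Raises
    ------
    ValueError
        If peaks reference a marker at which the subject is not heterozygous
        (QC failure listing the offending rows).
    """
    required = {"subject_id", "snp_id", "template", "prep", "duplicate",
                "area_allele0", "area_allele1"}
    missing = required - set(peaks.columns)
    if missing:
        raise ValueError(f"peaks table missing columns: {sorted(missing)}")
    markers = [m for m in marker_snp_ids if m in genotypes.columns]
    if len(markers) < len(marker_snp_ids):
        absent = set(marker_snp_ids) - set(markers)
        raise ValueError(f"marker SNPs absent from genotype matrix: {sorted(absent)}")
    common = common_alleles(genotypes)

    geno_long = genotypes.stack(future_stack=True)
    keys = pd.MultiIndex.from_arrays([peaks["subject_id"], peaks["snp_id"]])
    gvals = geno_long.reindex(keys).to_numpy()
    bad_mask = ~(pd.notna(gvals) & (gvals == 1))
    bad = list(map(tuple, keys[bad_mask]))
    if bad:
        raise ValueError(
            f"peak rows for non-heterozygous subject/SNP pairs: {sorted(set(bad))[:10]}"
        )

    grouped = peaks.groupby(["subject_id", "snp_id"], sort=False)
    per_subject: dict[str, dict[str, SnpASE]] = {}
    warn_map: dict[str, list[str]] = {}
    for (subj, snp), grp in grouped:
        gd = grp[grp["template"] == GDNA]
        cd = grp[grp["template"] == CDNA]
        if len(cd) == 0:
            warn_map.setdefault(subj, []).append(f"{snp}: no cDNA measurements")
            continue
        if len(gd) == 0:
            warn_map.setdefault(subj, []).append(f"{snp}: no gDNA measurements, skipped")
            continue
        gd_slots = {(int(r["prep"]), int(r["duplicate"])): _orient(r, common[snp])
                    for _, r in gd.iterrows()}
        gd_mean_ratio = float(np.mean([c / r for c, r in gd_slots.values()]))
        ratios = []
        for _, r in cd.iterrows():
            c_common, c_rare = _orient(r, common[snp])
            if c_common <= 0 or c_rare <= 0:
                raise MeasurementError(f"non-positive cDNA area for {subj}/{snp}")
            slot = (int(r["prep"]), int(r["duplicate"]))
            if slot in gd_slots:
                g_common, g_rare = gd_slots[slot]
                ratios.append((c_common / c_rare) / (g_common / g_rare))
            else:
                ratios.append((c_common / c_rare) / gd_mean_ratio)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ase = replicate_mean(ratios, expected_n=expected_replicates)
        if ase.n_ratios < expected_replicates:
            warn_map.setdefault(subj, []).append(
                f"{snp}: {ase.n_ratios}/{expected_replicates} replicates"
            )
        per_subject.setdefault(subj, {})[snp] = ase

    calls = []
    for subj in genotypes.index:
        subj = str(subj)
        flag, het_markers = informative_subject(
            {m: genotypes.at[subj, m] for m in markers}
        )
        snp_map = per_subject.get(subj, {})
        usable = {s: a for s, a in snp_map.items() if s in het_markers}
        if not flag or not usable:
            calls.append(ASECall(subj, snp_map, "uninformative", True, [],
                                 warn_map.get(subj, [])))
            continue
        verdicts = {s: classify(a.mean_ratio, upper=upper, lower=lower, strict=strict)
                    for s, a in usable.items()}
        high = any(a.mean_ratio >= upper for a in usable.values())
        low = any(a.mean_ratio <= lower for a in usable.values())
        call = "positive" if "positive" in verdicts.values() else "negative"
        calls.append(ASECall(subj, snp_map, call, not (high and low),
                             sorted(usable), warn_map.get(subj, [])))
    return calls


#: Clinical 2x2 contrasts run by default: (covariate, level-A, level-B).
#: Level-B "*" means "all other known levels pooled".
DEFAULT_CONTRASTS = (
    ("tumor_location", "colon", "rectum"),
    ("stage", "4", "*"),
)


def summarize_cohort(
    calls: list[ASECall],
    covariates: pd.DataFrame,
    *,
    contrasts: tuple[tuple[str, str, str], ...] = DEFAULT_CONTRASTS,
) -> CohortSummary:
    """Stratify ASE status over clinical covariates and test 2x2 contrasts.

    ``covariates`` is indexed by subject_id; categorical columns are
    stratified into counts and percentages of the cohort; configured
    contrasts get a two-sided Fisher exact p.  Unknown/missing levels go to
    an "unknown" stratum with a warning.
    """
    status = pd.Series({c.subject_id: c.call for c in calls})
    cov = covariates.copy()
    cov.index = cov.index.astype(str)
    missing = status.index.difference(cov.index)
    if len(missing):
        raise ValueError(f"covariates missing for subjects: {list(missing)[:5]}")
    cov = cov.loc[status.index]

    n_total = len(status)
    n_pos = int((status == "positive").sum())
    n_neg = int((status == "negative").sum())
    n_uni = int((status == "uninformative").sum())

    rows = []
    cat_cols = [c for c in cov.columns if cov[c].dtype == object or cov[c].dtype.name == "category"]
    for col in cat_cols:
        levels = cov[col].astype(object).where(cov[col].notna(), "unknown").astype(str)
        if (levels == "unknown").any() and not (cov[col].astype(str) == "unknown").any():
            warnings.warn(f"missing values in covariate {col!r} placed in 'unknown' stratum")
        for level in levels.unique():
            in_level = levels == level
            rows.append({
                "covariate": col,
                "level": level,
                "n_all": int(in_level.sum()),
                "n_ase_pos": int((in_level & (status == "positive")).sum()),
                "n_ase_neg": int((in_level & (status != "positive")).sum()),
            })
    strata = pd.DataFrame(rows)
    if len(strata):
        strata["pct_all"] = 100.0 * strata["n_all"] / n_total
        strata["pct_ase_pos"] = 100.0 * strata["n_ase_pos"] / n_total
        strata["pct_ase_neg"] = 100.0 * strata["n_ase_neg"] / n_total
        strata["prevalence_in_level"] = np.where(
            strata["n_all"] > 0, 100.0 * strata["n_ase_pos"] / strata["n_all"].clip(lower=1), 0.0
        )

    fisher: dict[str, float] = {}
    for col, lv_a, lv_b in contrasts:
        if col not in cov.columns:
            continue
        levels = cov[col].astype(str)
        is_pos = status == "positive"
        in_a = levels == lv_a
        if lv_b == "*":
            in_b = (levels != lv_a) & (levels != "unknown") & cov[col].notna()
            name = f"{col}:{lv_a}_vs_other"
        else:
            in_b = levels == lv_b
            name = f"{col}:{lv_a}_vs_{lv_b}"
        try:
            tab = association.ContingencyTable2x2(
                int((is_pos & in_a).sum()), int((is_pos & in_b).sum()),
                int((~is_pos & in_a).sum()), int((~is_pos & in_b).sum()),
            )
            fisher[name] = association.fisher_exact(tab)
        except association.DegenerateTableError:
            fisher[name] = float("nan")
    return CohortSummary(n_total, n_pos, n_neg, n_uni, strata, fisher)


def calls_frame(calls: list[ASECall]) -> pd.DataFrame:
    """Flatten ASE calls to one row per subject for the ase_calls.tsv artifact."""
    rows = []
    for c in calls:
        row: dict = {
            "subject_id": c.subject_id,
            "call": c.call,
            "concordant": c.concordant,
            "informative_snps": ";".join(c.informative_snps),
            "warnings": ";".join(c.warnings),
        }
        for snp, ase in sorted(c.per_snp.items()):
            row[f"mean_ratio_{snp}"] = ase.mean_ratio
        rows.append(row)
    return pd.DataFrame(rows)
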