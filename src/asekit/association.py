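"""Allelic case/control association tests and clinical contingency tests.

Each SNP is tested for an allele-frequency difference between subjects with
the allele-specific-expression (ASE) phenotype and the remainder of the
cohort: two alleles are counted per subject (allelic coding), the resulting
2x2 table is tested with an uncorrected Pearson chi-square (df = 1), and the
effect size is reported as the cross-product odds ratio.  Clinical 2x2
contrasts (e.g. colon vs rectum by ASE status) use a two-sided Fisher exact
test under the probability-mass rule: the p-value sums the hypergeometric
probabilities of every table with the same margins that is no more probable
than the one observed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ContingencyTable2x2",
    "AssociationResult",
    "DegenerateTableError",
    "allele_table",
    "pearson_chi2",
    "odds_ratio_from_table",
    "odds_ratio_from_freqs",
    "fisher_exact",
    "scan",
]

#: Sentinel printed for odds ratios undefined because of a zero cell.
NA = "n/a"


class DegenerateTableError(ValueError):
    """Raised when a contingency table has an empty group or margin."""


@dataclass(frozen=True)
class ContingencyTable2x2:
    """2x2 table of non-negative counts; rows are groups, columns categories."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        cells = (self.a, self.b, self.c, self.d)
        if any(int(x) != x or x < 0 for x in cells):
            raise ValueError(f"cells must be non-negative integers, got {cells}")
        if self.total == 0:
            raise DegenerateTableError("contingency table is empty")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def row_margins(self) -> tuple[int, int]:
        return (self.a + self.b, self.c + self.d)

    @property
    def col_margins(self) -> tuple[int, int]:
        return (self.a + self.c, self.b + self.d)

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)


@dataclass
class AssociationResult:
    """Per-SNP allelic association against the ASE phenotype."""

    snp_id: str
    freq2_ase: float | None
    freq2_rest: float | None
    allele_counts: ContingencyTable2x2 | None
    chi2: float | None
    p: float | None
    odds_ratio: float | str | None
    n_subjects_used: int
    note: str = ""

    def row(self) -> dict:
        return {
            "snp_id": self.snp_id,
            "freq2_ase": self.freq2_ase,
            "freq2_rest": self.freq2_rest,
            "chi2": self.chi2,
            "p": self.p,
            "odds_ratio": self.odds_ratio,
            "n_subjects_used": self.n_subjects_used,
            "note": self.note,
        }


def allele_table(
    genotypes_for_snp: pd.Series,
    phenotype_labels: pd.Series,
    *,
    carrier: bool = False,
) -> ContingencyTable2x2:
    """Count alleles (or carriers) of allele 2 by phenotype group.

    Parameters
    ----------
    genotypes_for_snp
        Per-subject 0/1/2 codes counting copies of allele 2; NaN = missing.
        Missing subjects are dropped for this SNP only.
    phenotype_labels
        Per-subject phenotype, ``"positive"`` or ``"negative"`` (the ASE call);
        the index must align with ``genotypes_for_snp``.
    carrier
        If true, use dominant coding: one count per subject, carrier vs not.

    Returns
    -------
    ContingencyTable2x2 with rows (ASE+, ASE-) and columns
    (allele-2 count, allele-1 count) — or (carriers, non-carriers).
    """
    geno = pd.to_numeric(genotypes_for_snp, errors="coerce")
    labels = phenotype_labels.reindex(geno.index)
    keep = geno.notna() & labels.isin(["positive", "negative"])
    geno, labels = geno[keep], labels[keep]
    if not (geno.isin([0, 1, 2])).all():
        bad = sorted(set(geno[~geno.isin([0, 1, 2])]))
        raise ValueError(f"genotype codes outside {{0,1,2}}: {bad}")
    pos, neg = geno[labels == "positive"], geno[labels == "negative"]
    if len(pos) == 0 or len(neg) == 0:
        raise DegenerateTableError(
            f"no informative subjects in one phenotype group for {genotypes_for_snp.name!r}"
        )
    if carrier:
        a, b = int((pos > 0).sum()), int((pos == 0).sum())
        c, d = int((neg > 0).sum()), int((neg == 0).sum())
    else:
        a, b = int(pos.sum()), int(2 * len(pos) - pos.sum())
        c, d = int(neg.sum()), int(2 * len(neg) - neg.sum())
    return ContingencyTable2x2(a, b, c, d)


def pearson_chi2(table: ContingencyTable2x2) -> tuple[float, float]:
    """Uncorrected Pearson chi-square on a 2x2 table, df = 1.

    Raises
    ------
    DegenerateTableError
        If a row or column margin is zero (expected counts undefined).
    """
    r1, r2 = table.row_margins
    c1, c2 = table.col_margins
    if 0 in (r1, r2, c1, c2):
        raise DegenerateTableError("zero margin: chi-square test undefined")
    n = table.total
    obs = table.as_array()
    expected = np.outer([r1, r2], [c1, c2]) / n
    chi2 = float(((obs - expected) ** 2 / expected).sum())
    p = float(stats.chi2.sf(chi2, df=1))
    return chi2, p


def odds_ratio_from_table(
    table: ContingencyTable2x2, *, haldane: bool = False
) -> float | str:
    """Cross-product odds ratio (a*d)/(b*c).

    Any zero cell makes the plain estimate undefined; by default the literal
    ``"n/a"`` is returned, or the Haldane–Anscombe +0.5 estimate if
    ``haldane`` is set.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    if 0 in (a, b, c, d):
        if not haldane:
            return NA
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return (a * d) / (b * c)


def odds_ratio_from_freqs(f1: float, f2: float) -> float | str:
    """Odds ratio between two allele frequencies: (f1/(1-f1)) / (f2/(1-f2)).

    Reconstructs a published allelic OR from the two groups' reported allele
    frequencies alone.  Boundary frequencies (0 or 1) leave the odds
    undefined and return ``"n/a"``.
    """
    if not (0.0 < f1 < 1.0) or not (0.0 < f2 < 1.0):
        return NA
    return (f1 / (1.0 - f1)) / (f2 / (1.0 - f2))


# Relative tolerance for "no more probable than observed" — guards against
# float noise deciding ties in the enumeration.
_FISHER_RTOL = 1e-9


def fisher_exact(table: ContingencyTable2x2, *, max_total: int = 100_000) -> float:
    """Two-sided Fisher exact p by enumeration over the support.

    Under fixed margins the (1,1) cell k follows a hypergeometric law; the
    two-sided p sums P(k) over every k whose probability does not exceed the
    observed table's (within relative tolerance 1e-9).

    Raises
    ------
    ValueError
        If the table total exceeds ``max_total`` (use chi-square instead).
    """
    n = table.total
    if n > max_total:
        raise ValueError(
            f"table total {n} exceeds enumeration bound {max_total}; use pearson_chi2"
        )
    r1 = table.a + table.b
    c1 = table.a + table.c
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    if lo == hi:  # degenerate support: the observed table is the only one
        return 1.0
    k = np.arange(lo, hi + 1)
    # log P(k) for the hypergeometric with margins (r1, c1, n)
    lg = math.lgamma
    const = lg(r1 + 1) + lg(n - r1 + 1) + lg(c1 + 1) + lg(n - c1 + 1) - lg(n + 1)
    logp = const - (
        _lgamma_arr(k) + _lgamma_arr(r1 - k) + _lgamma_arr(c1 - k) + _lgamma_arr(n - r1 - c1 + k)
    )
    pmf = np.exp(logp)
    pmf /= pmf.sum()  # renormalise away float drift
    p_obs = pmf[table.a - lo]
    p = float(pmf[pmf <= p_obs * (1.0 + _FISHER_RTOL)].sum())
    return min(p, 1.0)


def _lgamma_arr(k: np.ndarray) -> np.ndarray:
    return np.array([math.lgamma(x + 1) for x in k])


def scan(
    genotype_matrix: pd.DataFrame,
    phenotype_labels: pd.Series,
    *,
    carrier: bool = False,
    haldane: bool = False,
) -> list[AssociationResult]:
    """Test every SNP column for association with the ASE phenotype.

    ``genotype_matrix`` is subjects x SNPs with 0/1/2/NaN codes;
    ``phenotype_labels`` maps subject -> "positive"/"negative" (subjects with
    other labels, e.g. "uninformative", are excluded).  Per-SNP failures are
    recorded in the result row and the scan continues.
    """
    labels = phenotype_labels[phenotype_labels.isin(["positive", "negative"])]
    if labels.nunique() < 2:
        raise DegenerateTableError("need at least one subject in each phenotype group")
    results: list[AssociationResult] = []
    for snp in genotype_matrix.columns:
        geno = genotype_matrix[snp]
        try:
            tab = allele_table(geno, labels, carrier=carrier)
        except (DegenerateTableError, ValueError) as exc:
            results.append(
                AssociationResult(snp, None, None, None, None, None, None, 0, note=str(exc))
            )
            continue
        n_used = tab.total // (1 if carrier else 2)
        f_ase = tab.a / (tab.a + tab.b)
        f_rest = tab.c / (tab.c + tab.d)
        orx = odds_ratio_from_table(tab, haldane=haldane)
        try:
            chi2, p = pearson_chi2(tab)
            note = ""
        except DegenerateTableError as exc:
            chi2, p, note = None, None, str(exc)
        results.append(
            AssociationResult(snp, f_ase, f_rest, tab, chi2, p, orx, n_used, note=note)
        )
    return results


def scan_frame(results: list[AssociationResult]) -> pd.DataFrame:
    """Tabulate scan results in association-report layout."""
    return pd.DataFrame([r.row() for r in results])
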