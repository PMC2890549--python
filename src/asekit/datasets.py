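"""Small bundled example data, constructed programmatically.

``demo_cohort()`` rebuilds, from its published stratified counts, the
demographic structure of a 118-patient colorectal-cancer cohort assayed
for constitutive TGFBR1 allele-specific expression: 11 ASE-positive
subjects, 74 informative (heterozygous at >= 1 of the four 3'-UTR marker
SNPs), and clinical covariates whose ASE+/ASE- stratification matches the
published table.  It is a synthetic reconstruction — per-subject rows are
an arbitrary arrangement consistent with the marginal counts, not real
patient data.

``frequency_table()`` carries the locus-wide allele-2 frequencies by ASE
status from the same study, used as example input for odds-ratio
reconstruction.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .ase_calling import ASECall, SnpASE

__all__ = ["demo_cohort", "frequency_table"]

N_SUBJECTS = 118
N_POSITIVE = 11
N_INFORMATIVE = 74

# (level, count among ASE+, count among ASE-) per covariate; ASE- here means
# "not ASE-positive" (informative-negative plus uninformative), as published.
_STRATA = {
    "sex": [("female", 4, 51), ("male", 7, 56)],
    "tumor_location": [("colon", 6, 71), ("rectum", 5, 35), ("both", 0, 1)],
    "ethnicity": [("caucasian", 10, 88), ("african_american", 1, 13),
                  ("asian", 0, 3), ("hispanic", 0, 3)],
    "stage": [("1", 1, 10), ("2", 5, 25), ("3", 1, 43), ("4", 4, 29)],
    "family_history": [("no", 7, 69), ("yes", 3, 31), ("unknown", 1, 7)],
}

_MARKERS = ("rs334348", "rs334349", "rs1590", "rs7871490")

#: Allele-2 frequency in the ASE-positive group and the remainder of the
#: cohort, per locus SNP (two-decimal precision as published).
_FREQS = [
    ("rs4742761", 0.14, 0.25),
    ("rs2416666", 0.19, 0.19),
    ("rs7874183", 0.13, 0.28),
    ("rs7034462", 0.31, 0.05),
    ("rs10819634", 0.06, 0.26),
    ("rs1888223", 0.50, 0.30),
    ("9A/6A", 0.31, 0.04),
    ("rs10988705", 0.00, 0.04),
    ("rs6478974", 0.50, 0.47),
    ("rs10739778", 0.38, 0.36),
    ("rs2026811", 0.25, 0.32),
    ("rs10512263", 0.00, 0.11),
    ("rs11568785", 0.25, 0.02),
    ("rs334348", 0.31, 0.39),
    ("rs7871490", 0.50, 0.46),
    ("rs334349", 0.25, 0.43),
    ("rs7850895", 0.07, 0.06),
    ("rs1590", 0.25, 0.39),
    ("rs1626340", 0.25, 0.32),
]


def frequency_table() -> pd.DataFrame:
    """Per-SNP allele-2 frequencies by ASE phenotype group."""
    return pd.DataFrame(_FREQS, columns=["snp_id", "freq2_ase", "freq2_rest"])


def _column(pos_counts: list[tuple[str, int, int]]) -> list[str]:
    """Expand (level, n_pos, n_rest) counts into 118 per-subject values.

    ASE-positive subjects occupy the first 11 rows; informative-negative
    subjects rows 12-74; uninformative subjects the rest.
    """
    pos = [lvl for lvl, n_pos, _ in pos_counts for _ in range(n_pos)]
    rest = [lvl for lvl, _, n_rest in pos_counts for _ in range(n_rest)]
    assert len(pos) == N_POSITIVE and len(pos) + len(rest) == N_SUBJECTS
    return pos + rest


def demo_cohort() -> dict:
    """Synthetic reconstruction of the example cohort's summary structure.

    Returns a dict with:

    - ``calls``: 118 ASECall objects (11 positive, 63 negative, 44
      uninformative);
    - ``covariates``: per-subject clinical table matching the published
      ASE+/ASE- stratified counts;
    - ``genotypes``: marker-SNP and 9A/6A genotype matrix in which exactly
      74 subjects are heterozygous at >= 1 marker and 6 of the 11
      ASE-positive subjects carry the 9A/6A allele.
    """
    ids = [f"P{i + 1:03d}" for i in range(N_SUBJECTS)]
    covariates = pd.DataFrame(
        {col: _column(counts) for col, counts in _STRATA.items()},
        index=pd.Index(ids, name="subject_id"),
    )

    calls: list[ASECall] = []
    for i, sid in enumerate(ids):
        if i < N_POSITIVE:
            ase = SnpASE([2.0, 2.0, 2.0, 2.0], 2.0, 4)
            calls.append(ASECall(sid, {"rs334348": ase}, "positive", True, ["rs334348"]))
        elif i < N_INFORMATIVE:
            ase = SnpASE([1.0, 1.0, 1.0, 1.0], 1.0, 4)
            calls.append(ASECall(sid, {"rs334348": ase}, "negative", True, ["rs334348"]))
        else:
            calls.append(ASECall(sid, {}, "uninformative", True, []))

    geno = pd.DataFrame(0, index=pd.Index(ids, name="subject_id"),
                        columns=list(_MARKERS) + ["9A/6A"], dtype=float)
    geno.loc[ids[:N_INFORMATIVE], "rs334348"] = 1.0  # 74 informative subjects
    carriers_pos = ids[:6]                      # 6 of the 11 ASE+ carry 9A/6A
    carriers_rest = ids[N_POSITIVE:N_POSITIVE + 9]  # background carriers
    geno.loc[carriers_pos + carriers_rest, "9A/6A"] = 1.0
    return {"calls": calls, "covariates": covariates, "genotypes": geno}
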