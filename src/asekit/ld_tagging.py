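"""Pairwise linkage disequilibrium, EM haplotype frequencies, tag-SNP selection.

Haplotype frequencies for two (or three) biallelic loci are estimated from
unphased 0/1/2 genotype codes by expectation-maximisation under
Hardy-Weinberg: only subjects heterozygous at more than one locus are
phase-ambiguous, and the E-step splits them across compatible haplotype
pairs in proportion to current frequency products.  From the two-locus
frequencies the standard LD measures follow:

    D  = p11 - pA*pB
    r2 = D**2 / (pA*(1-pA)*pB*(1-pB))
    D' = D / Dmax,   Dmax = min(pA*(1-pB), (1-pA)*pB)        for D > 0
                     Dmax = min(pA*pB, (1-pA)*(1-pB))        for D < 0

Tag SNPs are selected greedily so that every common SNP (MAF above a
cutoff) has a proxy with r2 above a threshold; a SNP no single tag covers
may be rescued by a *two-tag haplotype* — the indicator pseudo-marker for
carrying a specific allele pair across two already-selected tags.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PairLD",
    "TagSet",
    "InsufficientDataError",
    "em_haplotype_freqs",
    "ld_stats",
    "pair_ld",
    "r2_between",
    "greedy_tag",
    "two_tag_haplotype_r2",
    "coverage_report",
]

EM_TOL = 1e-10
EM_MAX_ITER = 1000


class InsufficientDataError(ValueError):
    """Fewer than two subjects with complete genotypes at the loci."""


@dataclass
class PairLD:
    """Two-locus haplotype frequencies and derived LD statistics.

    ``hap_freqs`` is (p11, p10, p01, p00) where the first index is the
    allele-1 state at ``snp_a`` and the second at ``snp_b``; ``r2`` is None
    when undefined (monomorphic locus).
    """

    snp_a: str
    snp_b: str
    hap_freqs: tuple[float, float, float, float]
    allele_freqs: tuple[float, float]
    D: float | None = None
    D_prime: float | None = None
    r2: float | None = None
    em_iterations: int = 0
    converged: bool = True
    loglik_trace: list[float] = field(default_factory=list)

    @property
    def loglik(self) -> float | None:
        return self.loglik_trace[-1] if self.loglik_trace else None


@dataclass
class TagSet:
    """Greedy tagging solution over the common SNPs of a panel."""

    tags: list[str]
    #: target snp_id -> {"proxy": snp_id | (tag, tag, (a, b)), "r2": float,
    #:                   "kind": "self" | "single" | "haplotype"}
    proxy_map: dict[str, dict]
    mean_r2: float
    n_common: int
    n_covered_at_threshold: int
    r2_threshold: float
    maf_threshold: float
    warnings: list[str] = field(default_factory=list)


def _complete(columns: list[pd.Series | np.ndarray]) -> np.ndarray:
    arr = np.column_stack([pd.to_numeric(pd.Series(c), errors="coerce").to_numpy(dtype=float)
                           for c in columns])
    arr = arr[~np.isnan(arr).any(axis=1)]
    if not np.isin(arr, [0.0, 1.0, 2.0]).all():
        raise ValueError("genotype codes must be 0/1/2 or missing")
    return arr.astype(int)


def _compatible_pairs(geno: tuple[int, ...]) -> list[tuple[tuple[int, ...], tuple[int, ...]]]:
    """Unordered haplotype pairs consistent with a multilocus genotype."""
    het = [i for i, g in enumerate(geno) if g == 1]
    base = [g // 2 if g != 1 else 0 for g in geno]
    if not het:
        h = tuple(base)
        return [(h, h)]
    pairs = []
    # fix the first het locus's allele on haplotype one to avoid double counting
    for bits in itertools.product((0, 1), repeat=len(het) - 1):
        h1, h2 = list(base), list(base)
        h1[het[0]], h2[het[0]] = 1, 0
        for locus, bit in zip(het[1:], bits):
            h1[locus], h2[locus] = bit, 1 - bit
        pairs.append((tuple(h1), tuple(h2)))
    return pairs


def _em_run(init: np.ndarray, pairs_h1: np.ndarray, pairs_h2: np.ndarray,
            pairs_mult: np.ndarray, pairs_class: np.ndarray, class_cnt: np.ndarray,
            n: int, n_haps: int, tol: float, max_iter: int
            ) -> tuple[np.ndarray, int, bool, list[float]]:
    """One EM run with flattened (haplotype-pair, genotype-class) arrays."""
    freqs = init.copy()
    n_class = len(class_cnt)
    trace: list[float] = []
    converged = False
    it = 0

    def estep(f):
        w = f[pairs_h1] * f[pairs_h2] * pairs_mult
        tot = np.bincount(pairs_class, w, minlength=n_class)
        bad = tot <= 0.0  # unreachable genotype at a degenerate start
        if bad.any():
            w = np.where(bad[pairs_class], 1.0, w)
            tot = np.bincount(pairs_class, w, minlength=n_class)
        ll = float((class_cnt * np.log(tot)).sum())
        return w, tot, ll

    for it in range(1, max_iter + 1):
        w, tot, loglik = estep(freqs)
        trace.append(loglik)
        share = class_cnt[pairs_class] * w / tot[pairs_class]
        new = (np.bincount(pairs_h1, share, minlength=n_haps)
               + np.bincount(pairs_h2, share, minlength=n_haps)) / (2.0 * n)
        delta = float(np.abs(new - freqs).max())
        freqs = new
        if delta < tol:
            converged = True
            break
    trace.append(estep(freqs)[2])
    return freqs, it, converged, trace


def _em_multilocus(geno: np.ndarray, tol: float = EM_TOL, max_iter: int = EM_MAX_ITER
                   ) -> tuple[dict[tuple[int, ...], float], int, bool, list[float]]:
    """EM over the 2**L haplotypes of L biallelic loci (L small).

    Returns (frequencies, iterations, converged, loglik trace of the
    winning start).  The linkage-equilibrium product of observed allele
    frequencies is an EM fixed point (a likelihood saddle) on some datasets,
    so three deterministic starts are run — the equilibrium product and two
    versions tilted toward/away from the observed genotype covariances — and
    the highest final observed-data log-likelihood wins.
    """
    n, L = geno.shape
    if n < 2:
        raise InsufficientDataError(f"need >= 2 complete subjects, got {n}")
    haps = list(itertools.product((0, 1), repeat=L))
    hap_index = {h: i for i, h in enumerate(haps)}
    allele_freq = geno.mean(axis=0) / 2.0
    equil = np.array([np.prod([allele_freq[i] if h[i] else 1 - allele_freq[i]
                               for i in range(L)]) for h in haps])
    counts_by_geno: dict[tuple[int, ...], int] = {}
    for row in geno:
        key = tuple(int(g) for g in row)
        counts_by_geno[key] = counts_by_geno.get(key, 0) + 1
    # flatten (genotype class, compatible haplotype pair) into parallel arrays
    h1_idx, h2_idx, mult, cls = [], [], [], []
    class_cnt = []
    for ci, (g, cnt) in enumerate(counts_by_geno.items()):
        class_cnt.append(cnt)
        for h1, h2 in _compatible_pairs(g):
            h1_idx.append(hap_index[h1])
            h2_idx.append(hap_index[h2])
            mult.append(1.0 if h1 == h2 else 2.0)
            cls.append(ci)
    arrs = (np.array(h1_idx), np.array(h2_idx), np.array(mult), np.array(cls),
            np.array(class_cnt, dtype=float))

    # covariance-directed tilts break the symmetry of the equilibrium saddle
    cov = np.atleast_2d(np.cov(geno.T)) if L > 1 else np.zeros((1, 1))

    def tilted(delta: float) -> np.ndarray:
        out = equil.copy()
        for k, h in enumerate(haps):
            s = [1.0 if a else -1.0 for a in h]
            tilt = sum(s[i] * s[j] * (np.sign(cov[i, j]) or 1.0)
                       for i in range(L) for j in range(i + 1, L))
            out[k] *= float(np.exp(delta * tilt))
        return out / out.sum()

    starts = [equil] if L == 1 else [equil, tilted(0.2), tilted(-0.2)]
    best = None
    for init in starts:
        result = _em_run(init, *arrs, n, len(haps), tol, max_iter)
        if best is None or result[3][-1] > best[3][-1]:
            best = result
    freqs_arr, it, conv, trace = best
    return {h: float(freqs_arr[hap_index[h]]) for h in haps}, it, conv, trace


def em_haplotype_freqs(
    genotypes_a: pd.Series | np.ndarray,
    genotypes_b: pd.Series | np.ndarray,
    *,
    snp_a: str = "A",
    snp_b: str = "B",
) -> PairLD:
    """Maximum-likelihood two-locus haplotype frequencies from 0/1/2 codes.

    Only double heterozygotes are phase-ambiguous; with none present the EM
    result equals direct gamete counting.  Subjects missing either genotype
    are dropped (pairwise-complete analysis).
    """
    geno = _complete([genotypes_a, genotypes_b])
    freqs, it, conv, trace = _em_multilocus(geno)
    p11, p10 = freqs[(1, 1)], freqs[(1, 0)]
    p01, p00 = freqs[(0, 1)], freqs[(0, 0)]
    pA, pB = p11 + p10, p11 + p01
    return PairLD(snp_a, snp_b, (p11, p10, p01, p00), (pA, pB),
                  em_iterations=it, converged=conv, loglik_trace=trace)


def ld_stats(pair: PairLD) -> PairLD:
    """Populate D, D' and r2 on a PairLD; r2 is None for monomorphic loci."""
    p11, _, _, _ = pair.hap_freqs
    pA, pB = pair.allele_freqs
    D = p11 - pA * pB
    pair.D = D
    denom = pA * (1 - pA) * pB * (1 - pB)
    if denom <= 0.0:
        pair.D_prime = None
        pair.r2 = None
        return pair
    pair.r2 = float(np.clip(D * D / denom, 0.0, 1.0))
    if D > 0:
        dmax = min(pA * (1 - pB), (1 - pA) * pB)
    elif D < 0:
        dmax = min(pA * pB, (1 - pA) * (1 - pB))
    else:
        dmax = None
    pair.D_prime = 0.0 if dmax is None else float(np.clip(D / dmax, -1.0, 1.0))
    return pair


def pair_ld(genotypes_a, genotypes_b, *, snp_a: str = "A", snp_b: str = "B") -> PairLD:
    """EM haplotype frequencies plus LD statistics in one call."""
    return ld_stats(em_haplotype_freqs(genotypes_a, genotypes_b,
                                       snp_a=snp_a, snp_b=snp_b))


def r2_between(genotypes_a, genotypes_b) -> float | None:
    return pair_ld(genotypes_a, genotypes_b).r2


def _maf(col: pd.Series) -> float:
    g = pd.to_numeric(col, errors="coerce").dropna()
    if len(g) == 0:
        return 0.0
    p = float(g.sum() / (2 * len(g)))
    return min(p, 1 - p)


def _r2_matrix(genotypes: pd.DataFrame, snps: list[str]) -> pd.DataFrame:
    k = len(snps)
    mat = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            r2 = r2_between(genotypes[snps[i]], genotypes[snps[j]])
            mat[i, j] = mat[j, i] = np.nan if r2 is None else r2
    return pd.DataFrame(mat, index=snps, columns=snps)


def greedy_tag(
    genotypes: pd.DataFrame,
    *,
    r2_threshold: float = 0.8,
    maf_threshold: float = 0.05,
    exhaustive: bool = False,
    rescue: bool = True,
) -> TagSet:
    """Select tag SNPs so every common SNP has a proxy with r2 > threshold.

    Greedy: repeatedly promote the SNP that covers the most still-uncovered
    common SNPs (ties to higher MAF, then input order); before each
    promotion, uncovered SNPs are first offered rescue by a haplotype of two
    already-selected tags.  With ``exhaustive`` (panels of <= 15 common
    SNPs), the minimum-cardinality pairwise tag set is found by subset
    search instead.
    """
    mafs = {s: _maf(genotypes[s]) for s in genotypes.columns}
    common = [s for s in genotypes.columns if mafs[s] >= maf_threshold]
    warnings_list: list[str] = []
    if not common:
        warnings_list.append(f"no SNP reaches MAF >= {maf_threshold}; empty tag set")
        return TagSet([], {}, float("nan"), 0, 0, r2_threshold, maf_threshold,
                      warnings_list)
    r2m = _r2_matrix(genotypes, common)

    def covers(tag: str, snp: str) -> bool:
        v = r2m.at[tag, snp]
        return bool(v > r2_threshold) if pd.notna(v) else False

    rescue_cache: dict[tuple[str, str, str], dict] = {}

    def rescue_r2(snp: str, t1: str, t2: str) -> dict:
        key = (t1, t2, snp)
        if key not in rescue_cache:
            rescue_cache[key] = two_tag_haplotype_r2(snp, (t1, t2), genotypes)
        return rescue_cache[key]

    if exhaustive:
        if len(common) > 15:
            raise ValueError("exhaustive search limited to <= 15 common SNPs")
        tags = None
        for size in range(1, len(common) + 1):
            for cand in itertools.combinations(common, size):
                if all(any(covers(t, s) or t == s for t in cand) for s in common):
                    tags = list(cand)
                    break
            if tags is not None:
                break
        assert tags is not None
    else:
        tags = []
        uncovered = set(common)
        hap_proxies: dict[str, dict] = {}
        while uncovered:
            if rescue and len(tags) >= 2:
                for snp in sorted(uncovered, key=common.index):
                    best = None
                    for t1, t2 in itertools.combinations(tags, 2):
                        res = rescue_r2(snp, t1, t2)
                        if res["r2"] is not None and (best is None or res["r2"] > best["r2"]):
                            best = {"proxy": (t1, t2, res["haplotype"]),
                                    "r2": res["r2"], "kind": "haplotype"}
                    if best is not None and best["r2"] > r2_threshold:
                        hap_proxies[snp] = best
                uncovered -= set(hap_proxies)
            if not uncovered:
                break
            candidates = [s for s in common if s not in tags]
            gain = {s: sum(1 for u in uncovered if u == s or covers(s, u))
                    for s in candidates}
            best_tag = max(candidates,
                           key=lambda s: (gain[s], mafs[s], -common.index(s)))
            tags.append(best_tag)
            uncovered = {u for u in uncovered
                         if u != best_tag and not covers(best_tag, u)}

    proxy_map: dict[str, dict] = {}
    for snp in common:
        if snp in tags:
            proxy_map[snp] = {"proxy": snp, "r2": 1.0, "kind": "self"}
            continue
        best_tag = max(tags, key=lambda t: (r2m.at[t, snp] if pd.notna(r2m.at[t, snp]) else -1.0))
        best_r2 = r2m.at[best_tag, snp]
        entry = {"proxy": best_tag, "r2": float(best_r2) if pd.notna(best_r2) else None,
                 "kind": "single"}
        if rescue and (entry["r2"] is None or entry["r2"] <= r2_threshold) and len(tags) >= 2:
            best_h = None
            for t1, t2 in itertools.combinations(tags, 2):
                res = rescue_r2(snp, t1, t2)
                if res["r2"] is not None and (best_h is None or res["r2"] > best_h["r2"]):
                    best_h = {"proxy": (t1, t2, res["haplotype"]),
                              "r2": res["r2"], "kind": "haplotype"}
            if best_h is not None and (entry["r2"] is None or best_h["r2"] > entry["r2"]):
                entry = best_h
        proxy_map[snp] = entry

    r2s = [e["r2"] for e in proxy_map.values() if e["r2"] is not None]
    mean_r2 = float(np.mean(r2s)) if r2s else float("nan")
    n_cov = sum(1 for e in proxy_map.values()
                if e["r2"] is not None and (e["kind"] == "self" or e["r2"] > r2_threshold))
    return TagSet(tags, proxy_map, mean_r2, len(common), n_cov,
                  r2_threshold, maf_threshold, warnings_list)


def two_tag_haplotype_r2(
    target_snp: str,
    tag_pair: tuple[str, str],
    genotypes: pd.DataFrame | None = None,
    *,
    haplotypes: pd.DataFrame | None = None,
    hap_weights: np.ndarray | None = None,
) -> dict:
    """Best r2 between a two-tag haplotype pseudo-marker and a target allele.

    Three-locus haplotype frequencies come from direct counting when phased
    ``haplotypes`` (rows = haplotypes, columns = SNPs, optional weights) are
    given, otherwise from an 8-haplotype EM on the unphased genotypes.  Each
    bipartition of the four tag-allele pairs defines a pseudo-marker
    ("carries haplotype (a, b)", or a union such as "carries tag-a allele 1");
    the maximum r2 against the target allele and the achieving haplotype
    (pair, or tuple of pairs for a union) are returned.
    """
    t1, t2 = tag_pair
    converged = True
    if haplotypes is not None:
        h = haplotypes[[t1, t2, target_snp]].to_numpy(dtype=int)
        w = np.ones(len(h)) if hap_weights is None else np.asarray(hap_weights, dtype=float)
        w = w / w.sum()
        freqs = {}
        for combo in itertools.product((0, 1), repeat=3):
            freqs[combo] = float(w[(h == combo).all(axis=1)].sum())
    else:
        if genotypes is None:
            raise ValueError("provide genotypes or phased haplotypes")
        geno = _complete([genotypes[t1], genotypes[t2], genotypes[target_snp]])
        freqs, _, converged, _ = _em_multilocus(geno)

    pT = sum(v for k, v in freqs.items() if k[2] == 1)
    all_haps = list(itertools.product((0, 1), repeat=2))
    # candidate pseudo-markers: each of the four two-tag haplotypes, plus the
    # three two-vs-two groupings (e.g. "carries tag-a allele 1" regardless of
    # tag b), so a target identical to a tag scores r2 = 1
    candidates: list[tuple] = [(h,) for h in all_haps]
    candidates += [tuple(s) for s in itertools.combinations(all_haps, 2)
                   if all_haps[0] in s]  # one representative per bipartition
    best_r2, best_hap = None, None
    for subset in candidates:
        pH = sum(freqs[(a, b, t)] for a, b in subset for t in (0, 1))
        pHT = sum(freqs[(a, b, 1)] for a, b in subset)
        denom = pH * (1 - pH) * pT * (1 - pT)
        if denom <= 0.0:
            continue
        r2 = float(np.clip((pHT - pH * pT) ** 2 / denom, 0.0, 1.0))
        if best_r2 is None or r2 > best_r2:
            best_r2 = r2
            best_hap = subset[0] if len(subset) == 1 else subset
    return {"target": target_snp, "tags": (t1, t2), "haplotype": best_hap,
            "r2": best_r2, "converged": converged}


def coverage_report(tagset: TagSet) -> dict:
    """Coverage summary: mean best-proxy r2 and counts, plus a sorted table."""
    rows = []
    for snp, entry in tagset.proxy_map.items():
        proxy = entry["proxy"]
        rows.append({
            "snp_id": snp,
            "proxy": proxy if isinstance(proxy, str) else
            f"{proxy[0]}+{proxy[1]}:{proxy[2]}",
            "kind": entry["kind"],
            "r2": entry["r2"],
        })
    table = pd.DataFrame(rows).sort_values("r2", ascending=False).reset_index(drop=True) \
        if rows else pd.DataFrame(columns=["snp_id", "proxy", "kind", "r2"])
    return {
        "n_tags": len(tagset.tags),
        "n_common": tagset.n_common,
        "n_covered_at_threshold": tagset.n_covered_at_threshold,
        "mean_r2": tagset.mean_r2,
        "r2_threshold": tagset.r2_threshold,
        "table": table,
    }
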