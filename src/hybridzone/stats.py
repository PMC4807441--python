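"""Within-site disequilibrium statistics.

Exact Hardy-Weinberg tests (Markov-chain Monte Carlo over genotype tables
with fixed allele counts), the inbreeding coefficient F_IS, the
Weir-Cockerham F_ST estimator theta with a permutation test, composite
(phase-free) linkage disequilibrium between pairs of codominant loci,
cytonuclear disequilibrium between a diallelic(-ized) nuclear locus and the
mitochondrial type, and classical one-stage (step-up) FDR adjustment.

All permutation p-values carry the +1 correction, p >= 1/(n_perm + 1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import GenotypeTable, MISSING, _locus_columns


# ---------------------------------------------------------------------------
# genotype counts

def genotype_counts(table: GenotypeTable, site_id: int, locus: str) -> dict:
    """Unordered genotype counts {(a1<=a2): n} at one (site, locus),
    missing calls excluded."""
    sub = table.data[table.data["site_id"] == site_id]
    c1, c2 = _locus_columns(locus)
    out: dict = {}
    for a1, a2 in sub[[c1, c2]].itertuples(index=False):
        if a1 == MISSING or a2 == MISSING:
            continue
        key = (int(min(a1, a2)), int(max(a1, a2)))
        out[key] = out.get(key, 0) + 1
    return out


def _allele_counts(counts: dict) -> dict:
    ac: dict = {}
    for (a, b), n in counts.items():
        ac[a] = ac.get(a, 0) + n
        ac[b] = ac.get(b, 0) + n
    return ac


# ---------------------------------------------------------------------------
# exact HWE test

@dataclass(frozen=True)
class ChainSettings:
    """Markov-chain schedule for the exact HWE test (Genepop defaults)."""

    dememorization: int = 1000
    batches: int = 100
    iterations_per_batch: int = 1000


@dataclass
class HweResult:
    p_global: float
    p_deficit: float
    p_excess: float
    se_global: float
    se_deficit: float
    se_excess: float
    n: int
    chain: ChainSettings
    degenerate: bool = False


def _log_table_prob_terms(counts: dict) -> tuple[float, int]:
    """(-sum log g_ij!, heterozygote count): the table-varying part of the
    conditional (Levene) probability of a genotype table given allele counts."""
    s = 0.0
    het = 0
    for (a, b), n in counts.items():
        s -= math.lgamma(n + 1)
        if a != b:
            het += n
    return s, het


def hwe_exact_test(counts: dict, chain: ChainSettings = ChainSettings(),
                   seed: int | None = 0) -> HweResult:
    """Markov-chain exact test for HWE at one (site, locus).

    The chain operates on pairings of the 2n labelled allele copies: a step
    swaps the contents of two uniformly chosen copy slots, which leaves the
    uniform distribution over pairings -- and hence the Levene conditional
    distribution over genotype tables -- invariant, so every proposal is
    accepted.  ``p_global`` is the probability of tables no more probable
    than the observed one; the one-sided versions order tables by their
    heterozygote count (deficit: as few or fewer heterozygotes; excess: as
    many or more).  Monte-Carlo standard errors are batch-means estimates.
    """
    n = sum(counts.values())
    if n < 1:
        raise ValueError("need at least one typed individual")
    alleles = sorted(_allele_counts(counts))
    if len(alleles) < 2:
        return HweResult(1.0, 1.0, 1.0, 0.0, 0.0, 0.0, n, chain, degenerate=True)

    rng = np.random.default_rng(seed)
    copies: list = []
    for (a, b), m in counts.items():
        copies.extend([a, b] * m)
    copies = list(copies)
    ncopies = len(copies)

    cur: dict = {}
    for i in range(n):
        a, b = copies[2 * i], copies[2 * i + 1]
        key = (min(a, b), max(a, b))
        cur[key] = cur.get(key, 0) + 1
    LOG2 = math.log(2.0)
    logp_obs, het_obs = _log_table_prob_terms(counts)
    score_obs = logp_obs + het_obs * LOG2
    logp_cur, het_cur = _log_table_prob_terms(cur)

    def step(u: int, v: int):
        nonlocal logp_cur, het_cur
        pu, pv = u // 2, v // 2
        if pu == pv:
            return
        au, av = copies[u], copies[v]
        if au == av:
            return
        for p in (pu, pv):
            a, b = copies[2 * p], copies[2 * p + 1]
            key = (min(a, b), max(a, b))
            m = cur[key]
            logp_cur += math.lgamma(m + 1) - math.lgamma(m)
            cur[key] = m - 1
            if a != b:
                het_cur -= 1
        copies[u], copies[v] = av, au
        for p in (pu, pv):
            a, b = copies[2 * p], copies[2 * p + 1]
            key = (min(a, b), max(a, b))
            m = cur.get(key, 0)
            logp_cur += math.lgamma(m + 1) - math.lgamma(m + 2)
            cur[key] = m + 1
            if a != b:
                het_cur += 1

    pairs = rng.integers(0, ncopies, size=(chain.dememorization, 2))
    for u, v in pairs:
        step(int(u), int(v))

    eps = 1e-9
    batch_global, batch_def, batch_exc = [], [], []
    for _ in range(chain.batches):
        hits_g = hits_d = hits_e = 0
        pairs = rng.integers(0, ncopies, size=(chain.iterations_per_batch, 2))
        for u, v in pairs:
            step(int(u), int(v))
            if logp_cur + het_cur * LOG2 <= score_obs + eps:
                hits_g += 1
            if het_cur <= het_obs:
                hits_d += 1
            if het_cur >= het_obs:
                hits_e += 1
        m = chain.iterations_per_batch
        batch_global.append(hits_g / m)
        batch_def.append(hits_d / m)
        batch_exc.append(hits_e / m)

    def mean_se(xs: list) -> tuple[float, float]:
        arr = np.asarray(xs)
        return float(arr.mean()), float(arr.std(ddof=1) / math.sqrt(len(arr)))

    pg, seg = mean_se(batch_global)
    pd_, sed = mean_se(batch_def)
    pe, see = mean_se(batch_exc)
    return HweResult(pg, pd_, pe, seg, sed, see, n, chain)


# ---------------------------------------------------------------------------
# F_IS

@dataclass
class FisResult:
    fis: float | None
    h_obs: float
    h_exp: float
    n: int
    degenerate: bool = False


def inbreeding_coefficient(counts: dict) -> FisResult:
    """F_IS = (H_exp - H_obs) / H_exp with the small-sample-corrected
    (unbiased) expected heterozygosity; positive = heterozygote deficit."""
    n = sum(counts.values())
    if n < 1:
        raise ValueError("need at least one typed individual")
    het = sum(m for (a, b), m in counts.items() if a != b)
    h_obs = het / n
    ac = _allele_counts(counts)
    tot = 2 * n
    h_exp = 1.0 - sum((c / tot) ** 2 for c in ac.values())
    if tot > 1:
        h_exp *= tot / (tot - 1)
    if h_exp == 0.0:
        return FisResult(None, h_obs, 0.0, n, degenerate=True)
    return FisResult(1.0 - h_obs / h_exp, h_obs, h_exp, n)


# ---------------------------------------------------------------------------
# Weir-Cockerham theta with permutation test

@dataclass
class FstResult:
    theta: float
    p_value: float
    n_perm: int
    seed: int | None
    per_locus: dict = field(default_factory=dict)


def _wc_components(calls_by_pop: Sequence[np.ndarray]) -> tuple[float, float]:
    """Summed Weir-Cockerham (1984) variance components (a, a+b+c) over the
    alleles of one locus.  ``calls_by_pop``: per population an (n_i, 2)
    integer call array with missing rows already removed."""
    r = len(calls_by_pop)
    ns = np.array([len(c) for c in calls_by_pop], dtype=float)
    if (ns < 1).any() or r < 2:
        return 0.0, 0.0
    alleles = sorted(set(int(a) for c in calls_by_pop for a in c.ravel()))
    if len(alleles) < 2:
        return 0.0, 0.0
    nbar = ns.mean()
    nc = (r * nbar - (ns ** 2).sum() / (r * nbar)) / (r - 1)
    a_sum = abc_sum = 0.0
    for allele in alleles:
        p = np.array([np.mean(c == allele) for c in calls_by_pop])
        h = np.array([np.mean((c == allele).sum(axis=1) == 1) for c in calls_by_pop])
        pbar = (ns * p).sum() / (r * nbar)
        s2 = (ns * (p - pbar) ** 2).sum() / ((r - 1) * nbar)
        hbar = (ns * h).sum() / (r * nbar)
        if nbar <= 1 or nc <= 0:
            continue
        a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4)
                           / (nbar - 1))
        b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - (r - 1) / r * s2
                                   - (2 * nbar - 1) / (4 * nbar) * hbar)
        c = hbar / 2
        a_sum += a
        abc_sum += a + b + c
    return a_sum, abc_sum


def _theta_from_calls(calls: dict, labels: np.ndarray) -> float:
    """Multilocus theta as a ratio of summed variance components.

    ``calls``: locus -> (n, 2) call array over all individuals (missing = 0);
    ``labels``: 0/1 population assignment per individual."""
    num = den = 0.0
    for arr in calls.values():
        typed = (arr != MISSING).all(axis=1)
        groups = [arr[typed & (labels == g)] for g in (0, 1)]
        if any(len(g) < 1 for g in groups):
            continue
        a, abc = _wc_components(groups)
        num += a
        den += abc
    return num / den if den != 0 else 0.0


def fst_theta(table: GenotypeTable, pool_a: Iterable[int], pool_b: Iterable[int],
              n_perm: int = 999, seed: int | None = 0) -> FstResult:
    """Weir-Cockerham theta between two pools of sites, with a permutation
    p-value (proportion of individual-label shuffles with theta* >= theta,
    +1-corrected)."""
    pool_a, pool_b = set(map(int, pool_a)), set(map(int, pool_b))
    if pool_a & pool_b:
        raise ValueError("pools overlap")
    sub = table.subset(pool_a | pool_b)
    labels = np.where(sub.data["site_id"].isin(pool_a), 0, 1)
    if (labels == 0).sum() < 2 or (labels == 1).sum() < 2:
        raise ValueError("each pool needs at least two individuals")
    calls = {locus: sub.calls(locus) for locus in sub.loci}
    usable = any(((arr != MISSING).all(axis=1) & (labels == g)).sum() > 0
                 for arr in calls.values() for g in (0, 1))
    if not usable:
        raise ValueError("a pool is empty after missing-data filtering at all loci")
    theta = _theta_from_calls(calls, labels)
    per_locus = {}
    for locus, arr in calls.items():
        typed = (arr != MISSING).all(axis=1)
        groups = [arr[typed & (labels == g)] for g in (0, 1)]
        if all(len(g) >= 1 for g in groups):
            a, abc = _wc_components(groups)
            per_locus[locus] = a / abc if abc != 0 else 0.0
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        if _theta_from_calls(calls, perm) >= theta:
            hits += 1
    p = (hits + 1) / (n_perm + 1)
    return FstResult(theta, p, n_perm, seed, per_locus)


# ---------------------------------------------------------------------------
# composite linkage disequilibrium (Black & Krafsur / Weir)

@dataclass
class LdResult:
    statistic: float
    df: int
    p_asymptotic: float
    p_permutation: float
    n: int
    n_perm: int
    seed: int | None
    deltas: pd.DataFrame | None = None
    degenerate: bool = False


def _dose_matrix(calls: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(n, k) matrix of per-individual allele-copy counts and the allele
    labels, for rows typed at the locus (missing rows give all-zero rows)."""
    alleles = np.array(sorted(set(calls.ravel()) - {MISSING}))
    dose = np.zeros((len(calls), len(alleles)))
    for j, a in enumerate(alleles):
        dose[:, j] = (calls == a).sum(axis=1)
    return dose, alleles


def _composite_stat(X: np.ndarray, Y: np.ndarray) -> tuple[float, np.ndarray]:
    """Aggregated composite-disequilibrium chi-square over allele pairs.

    X, Y: (n, k1), (n, k2) allele-dose matrices of individuals typed at both
    loci.  Delta_AB = mean(X_A Y_B)/2 - 2 p_A p_B (Weir's composite
    disequilibrium, no phase assumed); each term is n Delta^2 / (v_A v_B)
    with v = p(1-p) + D_hw the allele's dose variance component.
    """
    n = X.shape[0]
    pA = X.mean(axis=0) / 2
    pB = Y.mean(axis=0) / 2
    delta = (X.T @ Y) / (2 * n) - 2 * np.outer(pA, pB)
    homA = ((X == 2).mean(axis=0))
    homB = ((Y == 2).mean(axis=0))
    vA = pA * (1 - pA) + (homA - pA ** 2)
    vB = pB * (1 - pB) + (homB - pB ** 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = n * delta ** 2 / np.outer(vA, vB)
    terms[~np.isfinite(terms)] = 0.0
    return float(terms.sum()), delta


def composite_ld_test(table: GenotypeTable, site_id: int, locus1: str, locus2: str,
                      n_perm: int = 999, seed: int | None = 0) -> LdResult:
    """Composite genotypic disequilibrium between two loci at one site.

    The permutation p-value (shuffling one locus's genotypes across
    individuals) is the headline p; an asymptotic chi-square p with
    (k1-1)(k2-1) degrees of freedom is also reported.
    """
    sub = table.data[table.data["site_id"] == site_id]
    c1 = sub[list(_locus_columns(locus1))].to_numpy(int)
    c2 = sub[list(_locus_columns(locus2))].to_numpy(int)
    typed = (c1 != MISSING).all(axis=1) & (c2 != MISSING).all(axis=1)
    c1, c2 = c1[typed], c2[typed]
    n = len(c1)
    if n < 5:
        raise ValueError("need at least 5 individuals typed at both loci")
    X, alleles1 = _dose_matrix(c1)
    Y, alleles2 = _dose_matrix(c2)
    k1, k2 = len(alleles1), len(alleles2)
    if k1 < 2 or k2 < 2:
        return LdResult(0.0, 0, 1.0, 1.0, n, n_perm, seed, degenerate=True)
    stat, delta = _composite_stat(X, Y)
    df = (k1 - 1) * (k2 - 1)
    p_asym = float(sps.chi2.sf(stat, df))
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        stat_p, _ = _composite_stat(X, Y[rng.permutation(n)])
        if stat_p >= stat:
            hits += 1
    p_perm = (hits + 1) / (n_perm + 1)
    ddf = pd.DataFrame(delta, index=alleles1, columns=alleles2)
    return LdResult(stat, df, p_asym, p_perm, n, n_perm, seed, deltas=ddf)


# ---------------------------------------------------------------------------
# cytonuclear disequilibrium

@dataclass
class CndResult:
    d_allelic: float
    d1: float
    d2: float
    d3: float
    p_allelic: float
    p_genotypic: tuple
    n: int
    n_perm: int
    seed: int | None
    degenerate: bool = False


def _cnd_stats(dose: np.ndarray, mito01: np.ndarray) -> tuple[float, float, float, float]:
    n = len(dose)
    p_m = mito01.mean()
    p_a = dose.mean() / 2
    d_allelic = (dose * mito01).sum() / (2 * n) - p_a * p_m
    ds = []
    for g in (2, 1, 0):  # homozygote-A, heterozygote, homozygote-B
        pg = (dose == g).mean()
        pgm = ((dose == g) & (mito01 == 1)).mean()
        ds.append(pgm - pg * p_m)
    return d_allelic, ds[0], ds[1], ds[2]


def cytonuclear_disequilibrium(dose: np.ndarray, mito: np.ndarray,
                               n_perm: int = 999, seed: int | None = 0) -> CndResult:
    """Allelic and genotypic cytonuclear disequilibria with permutation p.

    ``dose``: per-individual composite-allele copy count (0/1/2; NaN =
    unusable); ``mito``: "N"/"S" labels ("" = missing).  The allelic D is
    P(nuclear allele ^ northern mito) - p_allele p_mito; D1, D2, D3 are the
    genotype-level analogues for (AA, Aa, aa) and sum to zero.  Significance
    is assessed by shuffling the mito labels.
    """
    dose = np.asarray(dose, dtype=float)
    mito = np.asarray(mito, dtype=object)
    keep = ~np.isnan(dose) & (mito != "")
    dose, mito = dose[keep], mito[keep]
    n = len(dose)
    if n < 5:
        raise ValueError("need at least 5 individuals typed for both markers")
    mito01 = (mito == "N").astype(float)
    if mito01.min() == mito01.max() or dose.min() == dose.max():
        return CndResult(0.0, 0.0, 0.0, 0.0, 1.0, (1.0, 1.0, 1.0), n,
                         n_perm, seed, degenerate=True)
    d_a, d1, d2, d3 = _cnd_stats(dose, mito01)
    rng = np.random.default_rng(seed)
    hits = np.zeros(4, dtype=int)
    obs = np.abs([d_a, d1, d2, d3])
    for _ in range(n_perm):
        perm = _cnd_stats(dose, mito01[rng.permutation(n)])
        hits += np.abs(perm) >= obs - 1e-12
    p = (hits + 1) / (n_perm + 1)
    return CndResult(d_a, d1, d2, d3, float(p[0]),
                     (float(p[1]), float(p[2]), float(p[3])), n, n_perm, seed)


# ---------------------------------------------------------------------------
# FDR

def fdr_adjust(p_values: Sequence[float], q: float = 0.05) -> tuple[np.ndarray, float]:
    """Classical one-stage step-up FDR: sort p ascending, find the largest i
    with p_(i) <= i*q/m and flag the first i.  Returns (flags in input
    order, adjusted threshold p_(i) or 0.0 when nothing is flagged)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool), 0.0
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    ok = ranked <= (np.arange(1, m + 1) * q / m)
    flags = np.zeros(m, dtype=bool)
    if ok.any():
        cut = int(np.max(np.nonzero(ok)[0]))
        flags[order[:cut + 1]] = True
        return flags, float(ranked[cut])
    return flags, 0.0


# ---------------------------------------------------------------------------
# report writers

def write_fis_grid(table: GenotypeTable, path, alpha: float = 0.05) -> pd.DataFrame:
    """Site x locus grid of F_IS values (heterozygote deficit positive),
    written as TSV; returns the grid."""
    rows = {}
    for site in table.site_ids:
        rows[site] = {}
        for locus in table.loci:
            counts = genotype_counts(table, site, locus)
            if not counts:
                rows[site][locus] = np.nan
                continue
            res = inbreeding_coefficient(counts)
            rows[site][locus] = np.nan if res.fis is None else res.fis
    grid = pd.DataFrame(rows).T
    grid.index.name = "site_id"
    grid.to_csv(path, sep="\t", float_format="%.4f")
    return grid


def ld_pair_scan(table: GenotypeTable, n_perm: int = 999, seed: int | None = 0,
                 q: float = 0.05, alpha: float = 0.05) -> pd.DataFrame:
    """All within-site locus-pair composite LD tests, with FDR flags."""
    rows = []
    rng = np.random.default_rng(seed)
    for site in table.site_ids:
        for i, l1 in enumerate(table.loci):
            for l2 in table.loci[i + 1:]:
                try:
                    res = composite_ld_test(table, site, l1, l2, n_perm=n_perm,
                                            seed=int(rng.integers(2 ** 31)))
                except ValueError:
                    continue
                rows.append({"site_id": site, "locus1": l1, "locus2": l2,
                             "statistic": res.statistic, "df": res.df,
                             "p": res.p_permutation})
    df = pd.DataFrame(rows)
    if not df.empty:
        flags, _ = fdr_adjust(df["p"].to_numpy(), q=q)
        df["significant"] = df["p"] < alpha
        df["significant_fdr"] = flags
    return df
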