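"""Independent oracles used by the test suite.

These deliberately avoid the package's own algorithms: the dip oracle
minimizes sup|F_n - G| over unimodal G by direct linear programming per
candidate mode placement; the HWE oracle enumerates every genotype table
with the observed allele counts and sums Levene conditional probabilities;
the theta oracle is a plain scalar transcription of the published
variance-component formulas.
"""

from __future__ import annotations

import math
from itertools import combinations_with_replacement

import numpy as np
from scipy.optimize import linprog


# ---------------------------------------------------------------------------
# dip: LP minimization of sup|F_n - G| over unimodal G

def lp_dip(values) -> float:
    x = np.sort(np.asarray(values, float))
    n = x.size
    t, counts = np.unique(x, return_counts=True)
    k = len(t)
    F_post = np.cumsum(counts) / n
    F_pre = np.concatenate([[0.0], F_post[:-1]])
    if k == 1:
        return 1.0 / (2 * n)

    best = np.inf

    def solve(rows, b, nvar, d_idx):
        c = np.zeros(nvar)
        c[d_idx] = 1.0
        res = linprog(c, A_ub=np.array(rows), b_ub=np.array(b),
                      bounds=[(None, None)] * nvar, method="highs")
        return res.fun if res.status == 0 else np.inf

    def band(rows, b, gi, lo, hi, d_idx, nvar):
        r = np.zeros(nvar); r[gi] = -1; r[d_idx] = -1; rows.append(r); b.append(-lo)
        r = np.zeros(nvar); r[gi] = 1; r[d_idx] = -1; rows.append(r); b.append(hi)

    def mono(rows, b, lo_idx, hi_idx, nvar):
        r = np.zeros(nvar); r[lo_idx] = 1; r[hi_idx] = -1; rows.append(r); b.append(0.0)

    def shape(rows, b, idxs, ts, nvar, concave):
        for a in range(len(idxs) - 2):
            i0, i1, i2 = idxs[a], idxs[a + 1], idxs[a + 2]
            x0, x1, x2 = ts[a], ts[a + 1], ts[a + 2]
            r = np.zeros(nvar)
            r[i0] += -1 / (x1 - x0)
            r[i1] += 1 / (x1 - x0) + 1 / (x2 - x1)
            r[i2] += -1 / (x2 - x1)
            if concave:
                r = -r
            rows.append(r)
            b.append(0.0)

    for p in range(k):  # mode at data point t_p (jump allowed there)
        nvar = k + 2
        vm, d_idx = k, k + 1
        rows, b = [], []
        for i in range(k):
            if i == p:
                band(rows, b, i, F_post[i], F_post[i], d_idx, nvar)
            else:
                band(rows, b, i, F_post[i], F_pre[i], d_idx, nvar)
                r = np.zeros(nvar)
                if i < p:
                    r[i] = -1; rows.append(r); b.append(0.0)   # g >= 0
                else:
                    r[i] = 1; rows.append(r); b.append(1.0)    # g <= 1
        left_idx, left_t = list(range(p)) + [vm], list(t[:p]) + [t[p]]
        for a1, a2 in zip(left_idx, left_idx[1:]):
            mono(rows, b, a1, a2, nvar)
        r = np.zeros(nvar); r[vm] = 1; r[d_idx] = -1; rows.append(r); b.append(F_pre[p])
        r = np.zeros(nvar); r[vm] = -1; rows.append(r); b.append(0.0)
        shape(rows, b, left_idx, left_t, nvar, concave=False)
        mono(rows, b, vm, p, nvar)   # jump at the mode goes up, never down
        right_idx = list(range(p, k))
        for a1, a2 in zip(right_idx, right_idx[1:]):
            mono(rows, b, a1, a2, nvar)
        shape(rows, b, right_idx, list(t[p:]), nvar, concave=True)
        best = min(best, solve(rows, b, nvar, d_idx))

    # modes between data points (jump at either gap edge); these are
    # dominated by point modes in theory, kept so the oracle does not rely
    # on that argument
    for p in range(k - 1):
        for edge in ("left", "right"):
            nvar = k + 2
            w, d_idx = k, k + 1
            rows, b = [], []
            for i in range(k):
                band(rows, b, i, F_post[i], F_pre[i], d_idx, nvar)
                r = np.zeros(nvar)
                if i <= p:
                    r[i] = -1; rows.append(r); b.append(0.0)
                else:
                    r[i] = 1; rows.append(r); b.append(1.0)
            mono(rows, b, p, w, nvar)
            mono(rows, b, w, p + 1, nvar)
            if edge == "left":
                band(rows, b, w, F_post[p], F_post[p], d_idx, nvar)
                left_idx, left_t = list(range(p + 1)), list(t[:p + 1])
                right_idx = [w] + list(range(p + 1, k))
                right_t = [t[p]] + list(t[p + 1:])
            else:
                r = np.zeros(nvar); r[w] = 1; r[d_idx] = -1
                rows.append(r); b.append(F_pre[p + 1])
                left_idx = list(range(p + 1)) + [w]
                left_t = list(t[:p + 1]) + [t[p + 1]]
                right_idx, right_t = list(range(p + 1, k)), list(t[p + 1:])
            for a1, a2 in zip(left_idx, left_idx[1:]):
                mono(rows, b, a1, a2, nvar)
            for a1, a2 in zip(right_idx, right_idx[1:]):
                mono(rows, b, a1, a2, nvar)
            shape(rows, b, left_idx, left_t, nvar, concave=False)
            shape(rows, b, right_idx, right_t, nvar, concave=True)
            best = min(best, solve(rows, b, nvar, d_idx))

    return max(best, 1.0 / (2 * n))


# ---------------------------------------------------------------------------
# HWE: full enumeration of genotype tables with fixed allele counts

def _levene_log_prob(table: dict, allele_counts: dict, n: int) -> float:
    """log P(table | allele counts) = log[ n! prod m_a! 2^H / ((2n)! prod g!) ]."""
    logp = math.lgamma(n + 1) - math.lgamma(2 * n + 1)
    for m in allele_counts.values():
        logp += math.lgamma(m + 1)
    for (a, bb), g in table.items():
        logp -= math.lgamma(g + 1)
        if a != bb:
            logp += g * math.log(2.0)
    return logp


def enumerate_hwe_tables(allele_counts: dict):
    """All genotype tables with the given allele copy counts, with their
    Levene probabilities.  Yields (table, prob, n_het)."""
    alleles = sorted(allele_counts)
    n = sum(allele_counts.values()) // 2
    pairs = list(combinations_with_replacement(alleles, 2))

    def rec(idx, remaining, table):
        if idx == len(pairs):
            if all(v == 0 for v in remaining.values()):
                yield dict(table)
            return
        a, bb = pairs[idx]
        need = 2 if a == bb else 1
        cap = min(remaining[a] // need if a == bb else remaining[a], remaining[bb])
        for g in range(cap + 1):
            remaining[a] -= g * (2 if a == bb else 1)
            if a != bb:
                remaining[bb] -= g
            table[(a, bb)] = g
            yield from rec(idx + 1, remaining, table)
            remaining[a] += g * (2 if a == bb else 1)
            if a != bb:
                remaining[bb] += g
        del table[(a, bb)]

    for table in rec(0, dict(allele_counts), {}):
        table = {k: v for k, v in table.items() if v > 0}
        p = math.exp(_levene_log_prob(table, allele_counts, n))
        het = sum(v for (a, bb), v in table.items() if a != bb)
        yield table, p, het


def hwe_exact_oracle(observed: dict) -> tuple[float, float, float]:
    """(p_global, p_deficit, p_excess) by exhaustive enumeration."""
    ac: dict = {}
    for (a, bb), g in observed.items():
        ac[a] = ac.get(a, 0) + g
        ac[bb] = ac.get(bb, 0) + g
    n = sum(observed.values())
    p_obs = math.exp(_levene_log_prob(
        {k: v for k, v in observed.items() if v > 0}, ac, n))
    het_obs = sum(v for (a, bb), v in observed.items() if a != bb)
    pg = pd = pe = 0.0
    total = 0.0
    for _, p, het in enumerate_hwe_tables(ac):
        total += p
        if p <= p_obs * (1 + 1e-12):
            pg += p
        if het <= het_obs:
            pd += p
        if het >= het_obs:
            pe += p
    assert abs(total - 1.0) < 1e-9, "enumeration probabilities must sum to 1"
    return pg, pd, pe


# ---------------------------------------------------------------------------
# Weir-Cockerham theta: scalar transcription of the 1984 formulas

def theta_oracle(pops: list) -> float:
    """Multilocus theta; ``pops`` is a list over populations of
    {locus: list of (a1, a2) genotypes}."""
    loci = sorted({l for pop in pops for l in pop})
    num = den = 0.0
    for locus in loci:
        genos = [pop.get(locus, []) for pop in pops]
        r = len(genos)
        ns = [len(g) for g in genos]
        if any(n == 0 for n in ns):
            continue
        alleles = sorted({a for g in genos for pair in g for a in pair})
        nbar = sum(ns) / r
        nc = (r * nbar - sum(n * n for n in ns) / (r * nbar)) / (r - 1)
        for allele in alleles:
            p = [sum((pair.count(allele)) for pair in g) / (2 * n)
                 for g, n in zip(genos, ns)]
            h = [sum(1 for pair in g if pair.count(allele) == 1) / n
                 for g, n in zip(genos, ns)]
            pbar = sum(n * pi for n, pi in zip(ns, p)) / (r * nbar)
            s2 = sum(n * (pi - pbar) ** 2 for n, pi in zip(ns, p)) / ((r - 1) * nbar)
            hbar = sum(n * hi for n, hi in zip(ns, h)) / (r * nbar)
            a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2
                                     - hbar / 4) / (nbar - 1))
            b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - (r - 1) / r * s2
                                       - (2 * nbar - 1) / (4 * nbar) * hbar)
            c = hbar / 2
            num += a
            den += a + b + c
    return num / den if den else 0.0
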