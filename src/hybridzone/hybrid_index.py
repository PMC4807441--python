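"""Per-individual maximum-likelihood hybrid index.

The hybrid index h of an individual is the proportion of its ancestry
drawn from the designated "northern" parental gene pool.  Treating the two
allele copies at each codominant locus as independent draws from the
mixture h * p_N + (1 - h) * p_S, the log-likelihood is

    logL(h) = sum over allele copies a of log(h p_N(a) + (1 - h) p_S(a)),

a concave function of h on [0, 1], maximized by a coarse grid followed by
bounded scalar refinement; 2-unit support limits come from the profile
(logL drop of 2, bisected).  Loci whose observed allele is absent from both
parental samples are skipped; an allele absent from exactly one pool gets
the floor frequency 1/(2 n_pool + 1), keeping the likelihood finite without
hiding genuinely private alleles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from .io import (AlleleFrequencyProfile, GenotypeTable, MISSING,
                 allele_frequencies, _locus_columns)


@dataclass
class ParentalFrequencies:
    """Per-locus allele frequency lookups for the two parental pools, with
    the pool sample sizes used for the absent-allele floor."""

    south: dict    # locus -> {allele: freq}
    north: dict
    n_south: dict  # locus -> allele copies sampled
    n_north: dict
    loci: list

    @classmethod
    def from_table(cls, table: GenotypeTable, south_sites, north_sites
                   ) -> "ParentalFrequencies":
        prof = allele_frequencies(table, include_mito=False)
        south = prof.pooled(south_sites)
        north = prof.pooled(north_sites)
        s_map: dict = {}
        n_map: dict = {}
        s_tot: dict = {}
        n_tot: dict = {}
        for df, fmap, tmap in ((south, s_map, s_tot), (north, n_map, n_tot)):
            for locus, g in df.groupby("locus"):
                fmap[locus] = dict(zip(g["allele"], g["freq"]))
                tmap[locus] = int(g["count"].sum())
        return cls(s_map, n_map, s_tot, n_tot, list(table.loci))

    def copy_weights(self, locus: str, allele: int) -> tuple[float, float] | None:
        """(p_S, p_N) for one allele copy, floored when absent from exactly
        one pool; None when the allele was never seen in either pool."""
        ps = self.south.get(locus, {}).get(allele, 0.0)
        pn = self.north.get(locus, {}).get(allele, 0.0)
        if ps == 0.0 and pn == 0.0:
            return None
        if ps == 0.0:
            ps = 1.0 / (self.n_south.get(locus, 0) + 1)
        if pn == 0.0:
            pn = 1.0 / (self.n_north.get(locus, 0) + 1)
        return ps, pn


@dataclass
class HybridIndexResult:
    h: float | None
    support: tuple | None
    log_lik: float | None
    n_loci_used: int
    excluded: bool = False


def _profile_h(ps: np.ndarray, pn: np.ndarray):
    def logl(h: float) -> float:
        return float(np.sum(np.log(h * pn + (1.0 - h) * ps)))
    return logl


def estimate_hybrid_index(ps: np.ndarray, pn: np.ndarray,
                          n_loci: int, grid: int = 1001) -> HybridIndexResult:
    """MLE of h from per-copy parental frequencies (arrays over the usable
    allele copies of one individual)."""
    if len(ps) == 0:
        return HybridIndexResult(None, None, None, 0, excluded=True)
    logl = _profile_h(ps, pn)
    hs = np.linspace(0.0, 1.0, grid)
    vals = np.sum(np.log(np.outer(hs, pn) + np.outer(1 - hs, ps)), axis=1)
    h0 = hs[int(np.argmax(vals))]
    lo, hi = max(0.0, h0 - 2.0 / grid), min(1.0, h0 + 2.0 / grid)
    res = optimize.minimize_scalar(lambda h: -logl(h), bounds=(lo, hi),
                                   method="bounded",
                                   options={"xatol": 1e-8})
    h_hat = float(res.x) if -res.fun >= logl(h0) else float(h0)
    lmax = logl(h_hat)

    target = lmax - 2.0

    def support_edge(lo_h: float, hi_h: float, increasing: bool) -> float:
        # logL is concave: on each side of the MLE it crosses lmax-2 once.
        boundary = lo_h if increasing else hi_h
        if logl(boundary) >= target:
            return boundary  # interval clipped at the parameter bound
        a, b = lo_h, hi_h
        for _ in range(80):
            mid = 0.5 * (a + b)
            if (logl(mid) >= target) == increasing:
                b = mid
            else:
                a = mid
        return 0.5 * (a + b)

    low = support_edge(0.0, h_hat, increasing=True)
    high = support_edge(h_hat, 1.0, increasing=False)
    return HybridIndexResult(h_hat, (low, high), lmax, n_loci)


def hybrid_indices(table: GenotypeTable, parental: ParentalFrequencies
                   ) -> pd.DataFrame:
    """Hybrid index per individual: columns individual_id, site_id, h,
    h_low, h_high, n_loci, excluded."""
    rows = []
    for _, ind in table.data.iterrows():
        ps_list, pn_list = [], []
        used = 0
        for locus in table.loci:
            a1c, a2c = _locus_columns(locus)
            pair = (int(ind[a1c]), int(ind[a2c]))
            if MISSING in pair:
                continue
            weights = [parental.copy_weights(locus, a) for a in pair]
            if any(w is None for w in weights):
                continue  # allele unseen in both pools: locus skipped
            used += 1
            for w in weights:
                ps_list.append(w[0])
                pn_list.append(w[1])
        res = estimate_hybrid_index(np.array(ps_list), np.array(pn_list), used)
        rows.append({"individual_id": ind["individual_id"],
                     "site_id": ind["site_id"],
                     "h": np.nan if res.h is None else res.h,
                     "h_low": np.nan if res.support is None else res.support[0],
                     "h_high": np.nan if res.support is None else res.support[1],
                     "n_loci": res.n_loci_used, "excluded": res.excluded})
    return pd.DataFrame(rows)


def hybrid_index_distribution(values, bin_width: float = 0.10) -> np.ndarray:
    """Histogram counts over [0, 0.1), ..., [0.9, 1.0] (last bin closed)."""
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if v.size == 0:
        return np.zeros(int(round(1 / bin_width)), dtype=int)
    if (v < 0).any() or (v > 1).any():
        raise ValueError("hybrid indices must lie in [0, 1]")
    nbins = int(round(1.0 / bin_width))
    counts, _ = np.histogram(v, bins=np.linspace(0.0, 1.0, nbins + 1))
    return counts
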