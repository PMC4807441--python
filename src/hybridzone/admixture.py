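"""Model-based admixture estimation and the parental-site selection rule.

The model is the standard no-linkage admixture likelihood for codominant
markers: each of an individual's allele copies is drawn from cluster z with
probability q_iz, then the allele itself from that cluster's frequency
vector.  Point estimation is by EM (monotone in the log-likelihood); the
haploid mitochondrial marker is excluded -- admixture proportions describe
the nuclear genome only.  The number of clusters is suggested by the
Evanno second-difference statistic over replicate runs, and the sites
flanking a hybrid zone are picked by the shift from parental q-values
(q < 0.10 or q > 0.90) to predominantly admixed ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import GenotypeTable, MISSING


@dataclass
class AdmixtureResult:
    q: pd.DataFrame                 # individual_id, site_id, q_0..q_{k-1}
    frequencies: dict               # locus -> (k, n_alleles) array
    allele_index: dict              # locus -> allele label list
    log_lik: float
    k: int
    n_iter: int
    converged: bool
    seed: int | None
    log_lik_path: np.ndarray = field(default=None, repr=False)

    def q_matrix(self) -> np.ndarray:
        return self.q[[f"q_{z}" for z in range(self.k)]].to_numpy()


def _dose_arrays(table: GenotypeTable) -> tuple[dict, dict]:
    doses, index = {}, {}
    for locus in table.loci:
        calls = table.calls(locus)
        alleles = sorted(set(calls.ravel()) - {MISSING})
        index[locus] = alleles
        d = np.zeros((len(calls), len(alleles)))
        for j, a in enumerate(alleles):
            d[:, j] = (calls == a).sum(axis=1)
        doses[locus] = d
    return doses, index


def admixture_em(table: GenotypeTable, k: int, seed: int | None = 0,
                 max_iter: int = 2000, tol: float = 1e-6) -> AdmixtureResult:
    """EM point estimate of admixture proportions q and cluster allele
    frequencies for *k* clusters.

    Convergence when the log-likelihood gain drops below *tol*; the
    log-likelihood is asserted non-decreasing along the path.  Cluster
    labels are anchored geographically when a site table with distances is
    attached: cluster 0 is the majority cluster of the southernmost site.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    n = table.n_individuals
    if n < 5 * k:
        raise ValueError("need at least 5*k individuals")
    doses, index = _dose_arrays(table)
    rng = np.random.default_rng(seed)

    # symmetric q start (randomness lives in the frequency perturbation, so
    # permuting individuals permutes the trajectory exactly)
    q = np.full((n, k), 1.0 / k)
    freqs = {}
    for locus, D in doses.items():
        tot = D.sum(axis=0)
        pooled = tot / tot.sum() if tot.sum() else np.full(D.shape[1], 1 / D.shape[1])
        f = pooled[None, :] * np.exp(rng.normal(0, 0.3, size=(k, D.shape[1])))
        freqs[locus] = f / f.sum(axis=1, keepdims=True)

    prev = -np.inf
    path = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        q_num = np.zeros_like(q)
        new_freqs = {}
        logl = 0.0
        for locus, D in doses.items():
            F = freqs[locus]                              # (k, A)
            # mixture density of each allele for each individual: (n, A)
            mix = q @ F
            with np.errstate(divide="ignore", invalid="ignore"):
                logmix = np.where(mix > 0, np.log(mix), 0.0)
            logl += float((D * logmix).sum())
            with np.errstate(divide="ignore", invalid="ignore"):
                W = np.where(mix > 0, D / mix, 0.0)       # (n, A)
            # responsibilities summed over copies:
            q_num += q * (W @ F.T)                        # (n, k)
            Fnew = F * (q.T @ W)                          # (k, A)
            s = Fnew.sum(axis=1, keepdims=True)
            new_freqs[locus] = np.where(s > 0, Fnew / np.where(s == 0, 1, s), F)
        path.append(logl)
        if logl + 1e-8 < prev:
            raise AssertionError("EM log-likelihood decreased")
        if np.isfinite(prev) and logl - prev < tol:
            converged = True
            break
        prev = logl
        copies = sum(D.sum(axis=1) for D in doses.values())  # typed copies per ind
        denom = np.where(copies > 0, copies, 1.0)
        q = q_num / denom[:, None]
        q = np.clip(q, 1e-12, None)
        q = q / q.sum(axis=1, keepdims=True)
        freqs = new_freqs

    # geographic label anchoring: southernmost site's majority cluster first
    order = np.arange(k)
    if k > 1 and table.sites is not None:
        south = min(table.site_ids, key=table.site_distance)
        north = max(table.site_ids, key=table.site_distance)
        mask_s = (table.data["site_id"] == south).to_numpy()
        mask_n = (table.data["site_id"] == north).to_numpy()
        qs = q[mask_s].mean(axis=0) if mask_s.any() else np.zeros(k)
        qn = q[mask_n].mean(axis=0) if mask_n.any() else np.zeros(k)
        first = int(np.argmax(qs))
        last = int(np.argmax(qn - qs))
        rest = [z for z in range(k) if z not in (first, last)]
        order = np.array([first] + rest + [last]) if first != last else order
    q = q[:, order]
    freqs = {locus: f[order] for locus, f in freqs.items()}

    qdf = table.data[["individual_id", "site_id"]].copy()
    for z in range(k):
        qdf[f"q_{z}"] = q[:, z]
    return AdmixtureResult(qdf, freqs, index, float(path[-1]), k, it,
                           converged, seed, np.asarray(path))


def admixture_replicates(table: GenotypeTable, k_values, n_replicates: int = 10,
                         seed: int | None = 0, **kwargs) -> dict:
    """Replicate EM runs per k (different initializations); returns
    k -> list of log-likelihoods, the input to :func:`evanno_delta_k`."""
    rng = np.random.default_rng(seed)
    out: dict = {}
    for k in k_values:
        out[k] = [admixture_em(table, k, seed=int(rng.integers(2 ** 31)),
                               **kwargs).log_lik
                  for _ in range(n_replicates)]
    return out


@dataclass
class EvannoResult:
    table: pd.DataFrame   # k, mean_logl, sd_logl, delta_k
    best_k: int


def evanno_delta_k(logl_by_k: dict) -> EvannoResult:
    """Evanno second-difference statistic:
    delta_k = |mean L(k+1) - 2 mean L(k) + mean L(k-1)| / sd(k),
    defined for interior k with sd > 0; the argmax is the suggested k."""
    ks = sorted(logl_by_k)
    if any(b - a != 1 for a, b in zip(ks, ks[1:])):
        raise ValueError("k values must be consecutive")
    means = {k: float(np.mean(logl_by_k[k])) for k in ks}
    sds = {k: float(np.std(logl_by_k[k], ddof=1)) if len(logl_by_k[k]) > 1 else 0.0
           for k in ks}
    rows = []
    for k in ks:
        dk = np.nan
        if k != ks[0] and k != ks[-1] and sds[k] > 0:
            dk = abs(means[k + 1] - 2 * means[k] + means[k - 1]) / sds[k]
        rows.append({"k": k, "mean_logl": means[k], "sd_logl": sds[k],
                     "delta_k": dk})
    df = pd.DataFrame(rows)
    interior = df.dropna(subset=["delta_k"])
    if interior.empty:
        raise ValueError("delta_k undefined everywhere (need >= 3 consecutive k "
                         "with positive replicate sd)")
    best = int(interior.loc[interior["delta_k"].idxmax(), "k"])
    return EvannoResult(df, best)


def select_parental_sites(q_by_individual: pd.DataFrame, sites: pd.DataFrame,
                          parental_threshold: float = 0.10,
                          majority: float = 0.5) -> tuple[int, int]:
    """Pick the sites flanking the hybrid zone from a k=2 admixture run.

    ``q_by_individual`` needs columns ``site_id`` and ``q_north`` (ancestry
    proportion of the northern cluster); ``sites`` orders the sites by
    ``distance_km``.  A site is *southern-parental* when more than
    ``majority`` of its individuals have q < 0.10, *northern-parental* when
    more than ``majority`` have q > 0.90, and *admixed* when a majority are
    intermediate.  The returned pair is the innermost parental site on each
    flank, i.e. the last parental site before admixed sites take over.
    """
    ordered = sites.sort_values("distance_km")["site_id"].astype(int).tolist()
    kinds = {}
    for site in ordered:
        qs = q_by_individual.loc[q_by_individual["site_id"] == site, "q_north"]
        if qs.empty:
            kinds[site] = "empty"
            continue
        lo = (qs < parental_threshold).mean()
        hi = (qs > 1 - parental_threshold).mean()
        mid = 1.0 - lo - hi
        kinds[site] = ("south" if lo > majority else
                       "north" if hi > majority else
                       "admixed" if mid > majority else "mixed")
    south = None
    for site in ordered:
        if kinds[site] == "south":
            south = site
        elif kinds[site] in ("admixed", "mixed", "north"):
            break
    north = None
    for site in reversed(ordered):
        if kinds[site] == "north":
            north = site
        elif kinds[site] in ("admixed", "mixed", "south"):
            break
    if south is None or north is None:
        raise ValueError("no parental site found on one flank; choose parental "
                         "sites manually")
    return south, north
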