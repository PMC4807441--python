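"""Synthetic hybrid-zone genotype generator with known truth.

The generator emulates the data structure of a two-subspecies coastal
hybrid zone typed at codominant microsatellite-like loci plus one maternal
mitochondrial marker: two parental gene pools with locus-wise allele
frequency differentials, sampling sites at given along-coast distances,
and either

* a **clinal** ancestry regime -- each individual's allele copies are
  independently northern with probability p(x) given by an ancestry cline
  at the site's distance (the unimodal, hybrid-swarm regime), or
* a **class-mixture** regime -- individuals are drawn from the genotype
  classes {P_S, P_N, F1, F2, BC_S, BC_N} with per-site weights (the bimodal
  regime with a deficit of intermediates).

Mitochondria are maternally inherited: fixed per pure class, configurable
per hybrid class, and clinal (northern with probability p(x)) in the clinal
regime.  Every simulation returns the genotype table together with a truth
table (per-individual class or true ancestry, per-site expected allele
frequencies) so downstream estimators can be scored against the generating
parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .cline import ClineModel, cline_eval
from .io import GenotypeTable, _locus_columns

CLASSES = ("P_S", "P_N", "F1", "F2", "BC_S", "BC_N")

#: Expected northern-ancestry proportion of each genotype class.
CLASS_ANCESTRY = {"P_S": 0.0, "P_N": 1.0, "F1": 0.5, "F2": 0.5,
                  "BC_S": 0.25, "BC_N": 0.75}

#: Maternal pool per class: "S", "N", or a probability of a northern mother.
DEFAULT_MITO_RULE = {"P_S": "S", "P_N": "N", "F1": 0.5, "F2": 0.5,
                     "BC_S": "S", "BC_N": "N"}


@dataclass(frozen=True)
class LocusSpec:
    """Parental allele frequency vectors for one codominant locus."""

    name: str
    freqs_south: dict
    freqs_north: dict

    def __post_init__(self):
        for label, freqs in (("south", self.freqs_south), ("north", self.freqs_north)):
            total = sum(freqs.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"{self.name}: {label} frequencies sum to {total}")
            if any(f < 0 for f in freqs.values()):
                raise ValueError(f"{self.name}: negative frequency")

    def differential(self) -> float:
        alleles = set(self.freqs_south) | set(self.freqs_north)
        return 0.5 * sum(abs(self.freqs_north.get(a, 0.0) - self.freqs_south.get(a, 0.0))
                         for a in alleles)


def fixed_difference_loci(n_loci: int, start_allele: int = 101) -> list[LocusSpec]:
    """Diagnostic panel: each locus fixed for a different allele per pool."""
    out = []
    for i in range(n_loci):
        a = start_allele + 10 * i
        out.append(LocusSpec(f"L{i + 1:02d}", {a: 1.0}, {a + 4: 1.0}))
    return out


#: Default nine-locus panel: a mix of strongly and weakly differentiated
#: microsatellite-like loci, loosely shadowing the differential spread of a
#: coastal killifish marker panel (near-diagnostic loci alongside loci
#: separated by only ~0.15 in frequency).
DEFAULT_LOCI: list[LocusSpec] = [
    LocusSpec("MS01", {120: 0.90, 124: 0.10}, {120: 0.02, 124: 0.08, 128: 0.90}),
    LocusSpec("MS02", {143: 0.99, 147: 0.01}, {143: 0.04, 147: 0.96}),
    LocusSpec("MS03", {150: 0.53, 154: 0.47}, {150: 0.39, 154: 0.61}),
    LocusSpec("MS04", {161: 0.997, 165: 0.003}, {161: 0.36, 165: 0.64}),
    LocusSpec("MS05", {170: 0.82, 174: 0.18}, {170: 0.13, 174: 0.87}),
    LocusSpec("MS06", {181: 0.28, 185: 0.72}, {181: 0.04, 185: 0.96}),
    LocusSpec("MS07", {190: 0.84, 194: 0.16}, {190: 0.27, 194: 0.73}),
    LocusSpec("MS08", {203: 1.0}, {207: 1.0}),
    LocusSpec("MS09", {210: 0.58, 214: 0.42}, {210: 0.38, 214: 0.62}),
]

#: Along-coast sampling design of the emulated study region: 13 sites from
#: the southern reference (0 km) to the far north (1631 km), sample sizes
#: 12-50 fish.
DEFAULT_SITES = pd.DataFrame({
    "site_id": range(1, 14),
    "name": ["south_ref", "zone02", "zone03", "zone04", "zone05", "zone06",
             "zone07", "zone08", "zone09", "north10", "north11", "north12",
             "north_ref"],
    "distance_km": [0.0, 1145.77, 1186.03, 1208.94, 1228.41, 1231.88,
                    1242.06, 1257.54, 1285.31, 1357.23, 1363.41, 1393.09,
                    1631.0],
    "n": [19, 50, 50, 49, 13, 50, 49, 50, 39, 22, 12, 48, 20],
})


@dataclass
class SiteSpec:
    site_id: int
    distance_km: float
    n: int
    class_weights: dict | None = None   # class-mixture regime only


@dataclass
class SimulationConfig:
    """Full generative description of a synthetic hybrid zone."""

    loci: Sequence[LocusSpec]
    sites: Sequence[SiteSpec]
    ancestry_cline: ClineModel | None = None    # clinal regime when set
    mito_rule: dict = field(default_factory=lambda: dict(DEFAULT_MITO_RULE))
    seed: int | None = 0

    def __post_init__(self):
        clinal = self.ancestry_cline is not None
        for site in self.sites:
            if clinal:
                continue
            w = site.class_weights
            if w is None:
                raise ValueError(f"site {site.site_id}: class weights required "
                                 "in the class-mixture regime")
            if any(v < 0 for v in w.values()):
                raise ValueError("class weights must be non-negative")
            if abs(sum(w.values()) - 1.0) > 1e-9:
                raise ValueError("class weights must sum to 1")
            unknown = set(w) - set(CLASSES)
            if unknown:
                raise ValueError(f"unknown classes {sorted(unknown)}")


@dataclass
class TruthTable:
    individuals: pd.DataFrame     # individual_id, site_id, class/h_true, mito
    site_freqs: pd.DataFrame      # site_id, locus, allele, expected_freq
    config: SimulationConfig


def _draw_alleles(freqs: dict, size: int, rng: np.random.Generator) -> np.ndarray:
    alleles = np.array(sorted(freqs))
    p = np.array([freqs[a] for a in alleles], dtype=float)
    return rng.choice(alleles, size=size, p=p / p.sum())


def _gamete(locus: LocusSpec, pool: str, rng) -> int:
    freqs = locus.freqs_north if pool == "N" else locus.freqs_south
    return int(_draw_alleles(freqs, 1, rng)[0])


def _class_gametes(locus: LocusSpec, cls: str, rng) -> tuple[int, int]:
    if cls == "P_S":
        return _gamete(locus, "S", rng), _gamete(locus, "S", rng)
    if cls == "P_N":
        return _gamete(locus, "N", rng), _gamete(locus, "N", rng)
    if cls == "F1":
        return _gamete(locus, "S", rng), _gamete(locus, "N", rng)
    if cls == "F2":  # two F1 gametes: pool label Bernoulli(1/2) per copy
        return (_gamete(locus, "NS"[rng.integers(2)], rng),
                _gamete(locus, "NS"[rng.integers(2)], rng))
    if cls == "BC_S":
        return _gamete(locus, "S", rng), _gamete(locus, "NS"[rng.integers(2)], rng)
    if cls == "BC_N":
        return _gamete(locus, "N", rng), _gamete(locus, "NS"[rng.integers(2)], rng)
    raise ValueError(f"unknown class {cls}")


def _mito_for_class(cls: str, rule: dict, rng) -> str:
    r = rule.get(cls, 0.5)
    if r in ("S", "N"):
        return r
    return "N" if rng.random() < float(r) else "S"


def _expected_site_freqs(config: SimulationConfig) -> pd.DataFrame:
    rows = []
    for site in config.sites:
        if config.ancestry_cline is not None:
            hbar = float(cline_eval(config.ancestry_cline, site.distance_km))
        else:
            hbar = sum(site.class_weights.get(c, 0.0) * CLASS_ANCESTRY[c]
                       for c in CLASSES)
        for locus in config.loci:
            alleles = set(locus.freqs_south) | set(locus.freqs_north)
            for a in sorted(alleles):
                f = (hbar * locus.freqs_north.get(a, 0.0)
                     + (1 - hbar) * locus.freqs_south.get(a, 0.0))
                rows.append({"site_id": site.site_id, "locus": locus.name,
                             "allele": a, "expected_freq": f})
    return pd.DataFrame(rows)


def simulate_hybrid_zone(config: SimulationConfig) -> tuple[GenotypeTable, TruthTable]:
    """Draw a genotype table (plus truth) under *config*; deterministic for
    a fixed seed."""
    rng = np.random.default_rng(config.seed)
    rows, truth_rows = [], []
    clinal = config.ancestry_cline is not None
    for site in config.sites:
        if clinal:
            p_north = float(cline_eval(config.ancestry_cline, site.distance_km))
        for i in range(site.n):
            ind = f"s{site.site_id}i{i + 1}"
            row = {"individual_id": ind, "site_id": site.site_id,
                   "sex": "", "year": 0}
            if clinal:
                cls = None
                h_true = p_north
                mito = "N" if rng.random() < p_north else "S"
                for locus in config.loci:
                    a1 = _gamete(locus, "N" if rng.random() < p_north else "S", rng)
                    a2 = _gamete(locus, "N" if rng.random() < p_north else "S", rng)
                    c1, c2 = _locus_columns(locus.name)
                    row[c1], row[c2] = a1, a2
            else:
                names = [c for c in CLASSES if site.class_weights.get(c, 0.0) > 0]
                w = np.array([site.class_weights[c] for c in names])
                cls = names[rng.choice(len(names), p=w / w.sum())]
                h_true = CLASS_ANCESTRY[cls]
                mito = _mito_for_class(cls, config.mito_rule, rng)
                for locus in config.loci:
                    a1, a2 = _class_gametes(locus, cls, rng)
                    c1, c2 = _locus_columns(locus.name)
                    row[c1], row[c2] = a1, a2
            row["mito"] = mito
            rows.append(row)
            truth_rows.append({"individual_id": ind, "site_id": site.site_id,
                               "class": cls, "h_true": h_true, "mito": mito})
    sites_df = pd.DataFrame({
        "site_id": [s.site_id for s in config.sites],
        "name": [f"site{s.site_id}" for s in config.sites],
        "distance_km": [s.distance_km for s in config.sites],
        "lat": np.nan, "lon": np.nan,
    })
    loci_names = [l.name for l in config.loci]
    table = GenotypeTable(pd.DataFrame(rows), loci_names, sites_df)
    truth = TruthTable(pd.DataFrame(truth_rows), _expected_site_freqs(config), config)
    return table, truth


def simulate_parental_pools(loci: Sequence[LocusSpec], n_per_pool: int,
                            seed: int | None = 0,
                            distances: tuple = (0.0, 1631.0)
                            ) -> tuple[GenotypeTable, TruthTable]:
    """Two pure parental samples in Hardy-Weinberg proportions, mito fixed
    per pool (site 1 = southern, site 2 = northern)."""
    sites = [SiteSpec(1, distances[0], n_per_pool, {"P_S": 1.0}),
             SiteSpec(2, distances[1], n_per_pool, {"P_N": 1.0})]
    return simulate_hybrid_zone(SimulationConfig(list(loci), sites, seed=seed))


def simulate_clinal_counts(cline: ClineModel, sites: Sequence[tuple],
                           seed: int | None = 0) -> pd.DataFrame:
    """Binomial allele counts per site under a frequency cline: rows
    (distance_km, successes, total) with successes ~ Bin(total, p(x))."""
    rng = np.random.default_rng(seed)
    rows = []
    for distance, total in sites:
        if total <= 0:
            raise ValueError("total allele count must be positive")
        p = float(cline_eval(cline, distance))
        rows.append({"distance_km": float(distance),
                     "successes": int(rng.binomial(int(total), p)),
                     "total": int(total)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# presets

def metedeconk_bimodal_config(n: int = 89, n_loci: int = 9,
                              seed: int | None = 0) -> SimulationConfig:
    """Single central-marsh sample with a deficit of intermediates: class
    weights {P_S: 0.4, P_N: 0.4, F1: 0.1, BC: 0.1 split} at diagnostic loci
    -- the bimodal regime."""
    weights = {"P_S": 0.4, "P_N": 0.4, "F1": 0.1, "BC_S": 0.05, "BC_N": 0.05}
    sites = [SiteSpec(1, 1208.94, n, weights)]
    return SimulationConfig(fixed_difference_loci(n_loci), sites, seed=seed)


def clinal_zone_config(n_loci: int | None = None, seed: int | None = 0,
                       centre: float = 1217.0, width: float = 58.0,
                       sites: pd.DataFrame | None = None) -> SimulationConfig:
    """Thirteen-site coastal transect with clinal (hybrid-swarm) ancestry."""
    sites = DEFAULT_SITES if sites is None else sites
    loci = DEFAULT_LOCI if n_loci is None else fixed_difference_loci(n_loci)
    site_specs = [SiteSpec(int(r.site_id), float(r.distance_km), int(r.n))
                  for r in sites.itertuples()]
    model = ClineModel(centre=centre, width=width, p_min=0.0, p_max=1.0)
    return SimulationConfig(loci, site_specs, ancestry_cline=model, seed=seed)
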