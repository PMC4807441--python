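"""Genotype table data model and file formats.

The universal input of the package is a table of multilocus codominant
genotypes (microsatellite allele-length pairs per individual per locus),
one optional haploid mitochondrial marker per individual, and a site table
giving the along-coast distance of each sampling location in km.

Two on-disk dialects are supported:

* **Genepop** text format: 3-digit allele codes, ``POP`` separators between
  site blocks, comma-terminated individual identifiers.  The haploid
  mitochondrial marker, when present, is written last as a single 3-digit
  code (``001`` = N, ``002`` = S, ``000`` = missing).  Individual ids are
  written as ``<site_id>_<individual_id>`` so that site membership survives
  the round trip; files without that convention get 1-based block indices
  as site ids.
* **CSV**: columns ``individual_id, site_id, sex, year, mito`` followed by
  two columns per codominant locus named ``LOCUS.a1``/``LOCUS.a2``.

Allele code ``0`` is the single reserved missing-data sentinel (Genepop
convention); missing calls are excluded locus-wise, the individual is kept.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

MISSING = 0
MITO_LABELS = ("N", "S")
_MITO_CODE = {"N": 1, "S": 2}
_MITO_DECODE = {1: "N", 2: "S"}
META_COLUMNS = ["individual_id", "site_id", "sex", "year", "mito"]


class GenotypeFormatError(ValueError):
    """Malformed genotype file; message names the offending line."""


class ValidationError(ValueError):
    """Structurally valid file whose content violates a table invariant."""


@dataclass(frozen=True)
class Locus:
    """A marker: codominant diploid (microsatellite) or haploid mito."""

    name: str
    kind: str = "codominant-diploid"  # or "haploid-mito"
    alleles: tuple = ()

    def __post_init__(self):
        if self.kind not in ("codominant-diploid", "haploid-mito"):
            raise ValidationError(f"unknown locus kind {self.kind!r}")


@dataclass(frozen=True)
class SampleSite:
    """A sampling location with its along-coast distance from the southern
    reference point (km).  Distances are taken verbatim from the site table;
    no geodesic computation is performed."""

    site_id: int
    name: str = ""
    distance_km: float = float("nan")
    latitude: float = float("nan")
    longitude: float = float("nan")

    def __post_init__(self):
        if self.distance_km == self.distance_km and self.distance_km < 0:
            raise ValidationError("distance_km must be non-negative")


def _locus_columns(locus: str) -> tuple[str, str]:
    return f"{locus}.a1", f"{locus}.a2"


class GenotypeTable:
    """Individuals x loci diploid allele calls plus a haploid mito column.

    Parameters
    ----------
    data
        One row per individual with the CSV-dialect columns (see module
        docstring).  Allele columns are integers, 0 = missing; ``mito`` is
        ``"N"``/``"S"`` or ``""`` for missing.
    loci
        Ordered names of the codominant loci.
    sites
        Optional site table (``site_id, name, distance_km, lat, lon``).
    """

    def __init__(self, data: pd.DataFrame, loci: Sequence[str],
                 sites: pd.DataFrame | None = None):
        self.loci = list(loci)
        df = data.copy()
        for col in META_COLUMNS:
            if col not in df.columns:
                df[col] = "" if col in ("sex", "mito") else (0 if col == "year" else None)
        for locus in self.loci:
            for col in _locus_columns(locus):
                if col not in df.columns:
                    raise ValidationError(f"missing allele column {col}")
                df[col] = df[col].fillna(MISSING).astype(int)
        df["site_id"] = df["site_id"].astype(int)
        df["individual_id"] = df["individual_id"].astype(str)
        df["mito"] = df["mito"].fillna("").astype(str)
        order = META_COLUMNS + [c for locus in self.loci for c in _locus_columns(locus)]
        self.data = df[order].reset_index(drop=True)
        self.sites = sites.reset_index(drop=True) if sites is not None else None
        self.validate()

    # -- basic views ------------------------------------------------------

    @property
    def n_individuals(self) -> int:
        return len(self.data)

    @property
    def site_ids(self) -> list[int]:
        return sorted(self.data["site_id"].unique().tolist())

    def calls(self, locus: str) -> np.ndarray:
        """(n, 2) integer array of allele calls at *locus*; 0 = missing."""
        a1, a2 = _locus_columns(locus)
        arr = self.data[[a1, a2]].to_numpy(dtype=int)
        return np.sort(arr, axis=1)  # unordered pair, canonical ascending

    def mito(self) -> np.ndarray:
        return self.data["mito"].to_numpy(dtype=object)

    def subset(self, sites: Iterable[int]) -> "GenotypeTable":
        keep = self.data["site_id"].isin(set(int(s) for s in sites))
        return GenotypeTable(self.data[keep], self.loci, self.sites)

    def site_distance(self, site_id: int) -> float:
        if self.sites is None:
            raise ValidationError("no site table attached")
        row = self.sites[self.sites["site_id"] == site_id]
        if row.empty:
            raise ValidationError(f"site {site_id} not in site table")
        return float(row["distance_km"].iloc[0])

    def validate(self) -> None:
        for locus in self.loci:
            arr = self.calls(locus)
            if (arr < 0).any():
                raise ValidationError(f"negative allele code at locus {locus}")
            part = (arr == MISSING).sum(axis=1)
            if np.any(part == 1):
                bad = self.data["individual_id"].iloc[int(np.argmax(part == 1))]
                raise ValidationError(
                    f"half-missing diploid call at locus {locus}, individual {bad}")
        bad_mito = ~self.data["mito"].isin(list(MITO_LABELS) + [""])
        if bad_mito.any():
            lab = self.data["mito"][bad_mito].iloc[0]
            raise ValidationError(f"unknown mito label {lab!r}")
        if self.sites is not None:
            known = set(self.sites["site_id"].astype(int))
            missing = set(self.site_ids) - known
            if missing:
                raise ValidationError(f"individuals reference unknown sites {sorted(missing)}")
            d = self.sites["distance_km"].to_numpy(float)
            if len(np.unique(d)) != len(d):
                raise ValidationError("duplicate distance_km in site table")

    def __eq__(self, other) -> bool:
        if not isinstance(other, GenotypeTable):
            return NotImplemented
        if self.loci != other.loci or len(self.data) != len(other.data):
            return False
        a = self.data.copy()
        b = other.data.copy()
        for locus in self.loci:  # allele-pair order-insensitive
            c1, c2 = _locus_columns(locus)
            for df in (a, b):
                lo = df[[c1, c2]].min(axis=1)
                hi = df[[c1, c2]].max(axis=1)
                df[c1], df[c2] = lo, hi
        cols = ["individual_id", "site_id", "mito"] + \
            [c for locus in self.loci for c in _locus_columns(locus)]
        key = ["site_id", "individual_id"]
        a = a[cols].sort_values(key).reset_index(drop=True)
        b = b[cols].sort_values(key).reset_index(drop=True)
        return a.equals(b)


# ---------------------------------------------------------------------------
# site table

def read_sites(path) -> pd.DataFrame:
    """Read a site table CSV: site_id, name, distance_km, lat, lon."""
    df = pd.read_csv(path)
    need = {"site_id", "distance_km"}
    if not need.issubset(df.columns):
        raise GenotypeFormatError(f"{path}: site table needs columns {sorted(need)}")
    df["site_id"] = df["site_id"].astype(int)
    df["distance_km"] = df["distance_km"].astype(float)
    if (df["distance_km"] < 0).any():
        raise ValidationError("negative distance_km in site table")
    return df


def write_sites(sites: pd.DataFrame, path) -> Path:
    sites.to_csv(path, index=False)
    return Path(path)


# ---------------------------------------------------------------------------
# CSV dialect

def _read_csv_table(path) -> GenotypeTable:
    df = pd.read_csv(path, dtype={"mito": str}, keep_default_na=False)
    for col in ("individual_id", "site_id"):
        if col not in df.columns:
            raise GenotypeFormatError(f"{path}: missing required column {col!r}")
    allele_cols = [c for c in df.columns if re.fullmatch(r".+\.a[12]", c)]
    loci: list[str] = []
    for c in allele_cols:
        name = c[:-3]
        if name not in loci:
            loci.append(name)
    for locus in loci:
        for col in _locus_columns(locus):
            if col not in df.columns:
                raise GenotypeFormatError(f"{path}: locus {locus} lacks column {col}")
            try:
                df[col] = df[col].replace("", MISSING).astype(int)
            except (TypeError, ValueError) as exc:
                raise GenotypeFormatError(f"{path}: non-integer allele in {col}: {exc}")
    if "year" in df.columns:
        df["year"] = pd.to_numeric(df["year"], errors="coerce")
    return GenotypeTable(df, loci)


def _write_csv_table(table: GenotypeTable, path) -> Path:
    table.data.to_csv(path, index=False)
    return Path(path)


# ---------------------------------------------------------------------------
# Genepop dialect

def _genepop_code(a1: int, a2: int) -> str:
    return f"{a1:03d}{a2:03d}"


def _read_genepop(path) -> GenotypeTable:
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise GenotypeFormatError(f"{path}: empty file")
    loci: list[str] = []
    i = 1  # line 0 is the title
    while i < len(lines) and lines[i].strip().upper() != "POP":
        part = [t.strip() for t in lines[i].split(",") if t.strip()]
        loci.extend(part)
        i += 1
    if i == len(lines):
        raise GenotypeFormatError(f"{path}: no POP separator found")
    has_mito = bool(loci) and loci[-1].lower() in ("mito", "mtdna", "mt")
    mito_name = loci[-1] if has_mito else None
    nuc_loci = loci[:-1] if has_mito else loci

    rows = []
    pop_index = 0
    for lineno in range(i, len(lines)):
        raw = lines[lineno]
        if not raw.strip():
            continue
        if raw.strip().upper() == "POP":
            pop_index += 1
            continue
        if "," not in raw:
            raise GenotypeFormatError(f"{path}:{lineno + 1}: expected 'id , genotypes'")
        ident, geno = raw.split(",", 1)
        ident = ident.strip()
        codes = geno.split()
        expected = len(nuc_loci) + (1 if has_mito else 0)
        if len(codes) != expected:
            raise GenotypeFormatError(
                f"{path}:{lineno + 1}: expected {expected} genotype fields, got {len(codes)}")
        m = re.fullmatch(r"(\d+)_(.+)", ident)
        site_id = int(m.group(1)) if m else pop_index
        ind_id = m.group(2) if m else ident
        row = {"individual_id": ind_id, "site_id": site_id, "sex": "", "year": 0, "mito": ""}
        for locus, code in zip(nuc_loci, codes[:len(nuc_loci)]):
            if not re.fullmatch(r"\d{6}|\d{4}", code):
                raise GenotypeFormatError(
                    f"{path}:{lineno + 1}: bad diploid code {code!r} for locus {locus} "
                    "(need two 2- or 3-digit alleles)")
            half = len(code) // 2
            a1, a2 = _locus_columns(locus)
            row[a1], row[a2] = int(code[:half]), int(code[half:])
        if has_mito:
            code = codes[-1]
            if not re.fullmatch(r"\d{3}", code):
                raise GenotypeFormatError(
                    f"{path}:{lineno + 1}: bad haploid mito code {code!r}")
            v = int(code)
            if v not in (0, 1, 2):
                raise GenotypeFormatError(
                    f"{path}:{lineno + 1}: mito code {code!r} not in 000/001/002")
            row["mito"] = _MITO_DECODE.get(v, "")
        rows.append(row)
    df = pd.DataFrame(rows) if rows else pd.DataFrame(
        columns=META_COLUMNS + [c for l in nuc_loci for c in _locus_columns(l)])
    return GenotypeTable(df, nuc_loci)


def _write_genepop(table: GenotypeTable, path, title="hybridzone export") -> Path:
    has_mito = (table.data["mito"] != "").any()
    out = [title]
    out.extend(table.loci)
    if has_mito:
        out.append("mito")
    for site in table.site_ids:
        out.append("POP")
        block = table.data[table.data["site_id"] == site]
        for _, row in block.iterrows():
            codes = []
            for locus in table.loci:
                a1, a2 = _locus_columns(locus)
                codes.append(_genepop_code(int(row[a1]), int(row[a2])))
            if has_mito:
                codes.append(f"{_MITO_CODE.get(row['mito'], 0):03d}")
            out.append(f"{site}_{row['individual_id']} ,  " + " ".join(codes))
    Path(path).write_text("\n".join(out) + "\n")
    return Path(path)


def read_genotype_table(path, format: str = "csv") -> GenotypeTable:
    """Read a genotype table in the named dialect (``genepop`` or ``csv``)."""
    if not Path(path).exists():
        raise FileNotFoundError(path)
    if format == "csv":
        return _read_csv_table(path)
    if format == "genepop":
        return _read_genepop(path)
    raise ValueError(f"unknown format {format!r}")


def write_genotype_table(table: GenotypeTable, path, format: str = "csv") -> Path:
    """Write *table*; ``read_genotype_table`` of the result reproduces the
    genotype content (allele-pair order-insensitive).  The Genepop dialect
    does not carry sex/year metadata."""
    if format == "csv":
        return _write_csv_table(table, path)
    if format == "genepop":
        return _write_genepop(table, path)
    raise ValueError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# allele frequencies and differentials

MITO_LOCUS = "mito"


class AlleleFrequencyProfile:
    """Per-(site, locus, allele) observed frequencies with allele counts.

    ``freqs`` columns: site_id, locus, allele, count, freq.
    ``totals`` columns: site_id, locus, total (2 x typed individuals for
    diploid loci, 1 x for the mito marker).  Groups with zero typed
    individuals appear in ``totals`` with total 0 and no frequency rows.
    """

    def __init__(self, freqs: pd.DataFrame, totals: pd.DataFrame):
        self.freqs = freqs.reset_index(drop=True)
        self.totals = totals.reset_index(drop=True)
        with_rows = freqs.groupby(["site_id", "locus"])["freq"].sum()
        if len(with_rows) and not np.allclose(with_rows.to_numpy(), 1.0, atol=1e-9):
            raise ValidationError("allele frequencies do not sum to 1 within a (site, locus)")

    def undefined_groups(self) -> pd.DataFrame:
        """(site, locus) groups with zero typed individuals, explicitly flagged."""
        return self.totals[self.totals["total"] == 0].reset_index(drop=True)

    def site_locus(self, site_id: int, locus: str) -> pd.DataFrame:
        f = self.freqs
        return f[(f["site_id"] == site_id) & (f["locus"] == locus)]

    def pooled(self, sites: Iterable[int]) -> pd.DataFrame:
        """Pool allele counts over *sites*; returns locus/allele/count/freq."""
        sites = set(int(s) for s in sites)
        sub = self.freqs[self.freqs["site_id"].isin(sites)]
        g = sub.groupby(["locus", "allele"], as_index=False)["count"].sum()
        tot = g.groupby("locus")["count"].transform("sum")
        g["freq"] = g["count"] / tot
        return g


def allele_frequencies(table: GenotypeTable, include_mito: bool = True
                       ) -> AlleleFrequencyProfile:
    """Observed per-site allele frequencies; missing calls are excluded."""
    freq_rows, total_rows = [], []
    for site in table.site_ids:
        sub = table.data[table.data["site_id"] == site]
        for locus in table.loci:
            a1, a2 = _locus_columns(locus)
            alleles = np.concatenate([sub[a1].to_numpy(int), sub[a2].to_numpy(int)])
            alleles = alleles[alleles != MISSING]
            total_rows.append({"site_id": site, "locus": locus, "total": len(alleles)})
            if len(alleles):
                vals, counts = np.unique(alleles, return_counts=True)
                for v, c in zip(vals, counts):
                    freq_rows.append({"site_id": site, "locus": locus, "allele": int(v),
                                      "count": int(c), "freq": c / len(alleles)})
        if include_mito:
            m = sub["mito"][sub["mito"] != ""].to_numpy(object)
            total_rows.append({"site_id": site, "locus": MITO_LOCUS, "total": len(m)})
            if len(m):
                vals, counts = np.unique(m, return_counts=True)
                for v, c in zip(vals, counts):
                    freq_rows.append({"site_id": site, "locus": MITO_LOCUS, "allele": str(v),
                                      "count": int(c), "freq": c / len(m)})
    freqs = pd.DataFrame(freq_rows, columns=["site_id", "locus", "allele", "count", "freq"])
    totals = pd.DataFrame(total_rows, columns=["site_id", "locus", "total"])
    return AlleleFrequencyProfile(freqs, totals)


@dataclass
class DifferentialTable:
    """Allele frequency differentials between two parental pools.

    ``deltas`` columns: locus, allele, freq_a, freq_b, delta (= pool A minus
    pool B).  ``summary`` maps locus -> half the sum of |delta| over alleles,
    the standard per-locus differential."""

    pool_a: tuple
    pool_b: tuple
    deltas: pd.DataFrame
    summary: dict = field(default_factory=dict)


def frequency_differential(profile: AlleleFrequencyProfile,
                           pool_a: Iterable[int], pool_b: Iterable[int]
                           ) -> DifferentialTable:
    """Per-(locus, allele) differential delta = freq(pool A) - freq(pool B)."""
    pool_a = tuple(sorted(int(s) for s in pool_a))
    pool_b = tuple(sorted(int(s) for s in pool_b))
    overlap = set(pool_a) & set(pool_b)
    if overlap:
        raise ValidationError(f"pools share sites {sorted(overlap)}")
    fa = profile.pooled(pool_a).rename(columns={"freq": "freq_a", "count": "count_a"})
    fb = profile.pooled(pool_b).rename(columns={"freq": "freq_b", "count": "count_b"})
    if fa.empty or fb.empty:
        raise ValidationError("a pool has no typed individuals at any locus")
    merged = fa.merge(fb, on=["locus", "allele"], how="outer")
    merged[["freq_a", "freq_b"]] = merged[["freq_a", "freq_b"]].fillna(0.0)
    merged["delta"] = merged["freq_a"] - merged["freq_b"]
    merged = merged.sort_values(["locus", "allele"]).reset_index(drop=True)
    summary = {locus: float(np.abs(g["delta"]).sum()) / 2.0
               for locus, g in merged.groupby("locus")}
    return DifferentialTable(pool_a, pool_b,
                             merged[["locus", "allele", "freq_a", "freq_b", "delta"]],
                             summary)


def diallelic_reduction(profile: AlleleFrequencyProfile, diff: DifferentialTable
                        ) -> pd.DataFrame:
    """Collapse each multiallelic locus to a diallelic system by delta sign.

    Alleles with delta > 0 (toward pool A) form the composite pool-A allele;
    alleles with delta < 0 the complement.  Ties (delta == 0) belong to
    neither class and their copies are dropped from the counts.  Returns one
    row per (site, locus): ``count_a``, ``total`` (copies in either class)
    and ``freq_a`` = count_a / total; loci where every delta is 0 are flagged
    ``informative = False`` with freq_a = NaN.
    """
    sign = {(r.locus, r.allele): np.sign(r.delta) for r in diff.deltas.itertuples()}
    rows = []
    loci = diff.deltas["locus"].unique()
    for (site, locus), g in profile.freqs.groupby(["site_id", "locus"]):
        if locus not in loci:
            continue
        count_a = count_b = 0
        for r in g.itertuples():
            s = sign.get((locus, r.allele), 0.0)
            if s > 0:
                count_a += r.count
            elif s < 0:
                count_b += r.count
        total = count_a + count_b
        informative = any(sign.get((locus, a)) not in (0.0, None)
                          for a in diff.deltas[diff.deltas["locus"] == locus]["allele"])
        rows.append({"site_id": site, "locus": locus, "count_a": count_a,
                     "total": total, "freq_a": count_a / total if total else np.nan,
                     "informative": bool(informative and total)})
    return pd.DataFrame(rows).sort_values(["locus", "site_id"]).reset_index(drop=True)


def composite_allele_dose(table: GenotypeTable, locus: str,
                          diff: DifferentialTable) -> np.ndarray:
    """Per-individual copies of the composite pool-A allele at *locus*.

    Returns floats in {0, 1, 2} counting allele copies whose differential is
    positive; NaN for individuals missing at the locus or carrying only
    tied (delta == 0) alleles on both copies.
    """
    sign = {r.allele: np.sign(r.delta) for r in
            diff.deltas[diff.deltas["locus"] == locus].itertuples()}
    calls = table.calls(locus)
    dose = np.full(len(calls), np.nan)
    for i, (a1, a2) in enumerate(calls):
        if a1 == MISSING or a2 == MISSING:
            continue
        signs = [sign.get(int(a), 0.0) for a in (a1, a2)]
        if any(s == 0.0 for s in signs):
            continue  # tied allele: diploid class undefined
        dose[i] = sum(1 for s in signs if s > 0)
    return dose
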