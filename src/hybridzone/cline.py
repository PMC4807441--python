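"""Maximum-likelihood geographic cline fitting.

A geographic cline describes how the frequency of a "northern" allele rises
with along-coast distance x (km).  The central shape is the sigmoid

    p(x) = p_min + (p_max - p_min) * (1 + tanh(2 (x - c) / w)) / 2,

with centre c (the inflection point) and width w (the inverse of the
maximal slope, scaled to the p_min..p_max range).  Four model variants are
fitted by bounded multi-start maximum likelihood on binomial site counts:

* ``null`` -- flat frequency, one parameter;
* ``I``    -- c and w free, end frequencies fixed to supplied constants;
* ``II``   -- c, w, p_min, p_max all free, no tails;
* ``III``  -- model II plus exponential introgression tails spliced
  continuously beyond c - delta_L and c + delta_R, each with a slope-ratio
  tau in [0, 1] relative to the sigmoid slope at the splice point.

Model choice is by lowest AIC (ties toward fewer parameters); parameter
uncertainty by 2-unit support limits from the profile likelihood.  The
concordance/coincidence test compares a free model (per-locus centre and
width) against a model constraining all loci to a common centre and width,
using the scaled-logit cline shape, via a likelihood-ratio chi-square with
2(L-1) degrees of freedom.

The neutral-diffusion expectation for a cline of age T generations with
per-generation dispersal sigma is w = sigma * sqrt(2 pi T); clines much
narrower than this are candidates for selection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats as sps

_PCLAMP = 1e-9

VARIANT_PARAMS = {
    "null": ("p",),
    "I": ("centre", "width"),
    "II": ("centre", "width", "p_min", "p_max"),
    "III": ("centre", "width", "p_min", "p_max",
            "delta_l", "tau_l", "delta_r", "tau_r"),
}


@dataclass(frozen=True)
class ClineModel:
    """A sigmoid frequency-vs-distance cline, optionally with tails."""

    centre: float
    width: float
    p_min: float = 0.0
    p_max: float = 1.0
    delta_l: float = 0.0
    tau_l: float = 1.0
    delta_r: float = 0.0
    tau_r: float = 1.0
    variant: str = "II"

    def __post_init__(self):
        if self.width <= 0:
            raise ValueError("cline width must be positive")
        if not (0 <= self.p_min <= self.p_max <= 1):
            raise ValueError("need 0 <= p_min <= p_max <= 1")
        if min(self.delta_l, self.delta_r) < 0:
            raise ValueError("tail distances must be non-negative")
        if not (0 <= self.tau_l <= 1 and 0 <= self.tau_r <= 1):
            raise ValueError("tail slope-ratios must lie in [0, 1]")


def _sigmoid01(x, centre, width):
    return 0.5 * (1.0 + np.tanh(2.0 * (np.asarray(x, float) - centre) / width))


def cline_eval(model: ClineModel, x) -> np.ndarray | float:
    """Expected northern-allele frequency at distance(s) *x* (km).

    Variant III splices exponential tails at c - delta_l and c + delta_r:
    each tail is continuous at the splice and its initial slope is tau times
    the sigmoid slope there, decaying toward p_min (left) or p_max (right).
    """
    x = np.asarray(x, dtype=float)
    c, w = model.centre, model.width
    s = _sigmoid01(x, c, w)
    if model.variant == "III":
        if model.delta_l > 0 or True:  # tails always evaluable; delta=0 splices at centre
            xl = c - model.delta_l
            s0 = float(_sigmoid01(xl, c, w))
            lam = model.tau_l * (4.0 / w) * (1.0 - s0)
            left = s0 * np.exp(np.minimum(lam * (x - xl), 0.0))
            s = np.where(x < xl, left, s)
            xr = c + model.delta_r
            s1 = float(_sigmoid01(xr, c, w))
            lam_r = model.tau_r * (4.0 / w) * s1
            right = 1.0 - (1.0 - s1) * np.exp(np.minimum(-lam_r * (x - xr), 0.0))
            s = np.where(x > xr, right, s)
    p = model.p_min + (model.p_max - model.p_min) * s
    return float(p) if p.ndim == 0 else p


@dataclass
class ClineData:
    """Per-site binomial observations of a northern-allele frequency."""

    distance_km: np.ndarray
    successes: np.ndarray
    totals: np.ndarray

    def __post_init__(self):
        self.distance_km = np.asarray(self.distance_km, dtype=float)
        self.successes = np.asarray(self.successes, dtype=float)
        self.totals = np.asarray(self.totals, dtype=float)
        if not (len(self.distance_km) == len(self.successes) == len(self.totals)):
            raise ValueError("distance/successes/totals length mismatch")
        if (self.totals <= 0).any():
            raise ValueError("totals must be positive")
        if (self.successes < 0).any() or (self.successes > self.totals).any():
            raise ValueError("successes must lie in [0, total]")
        if not np.isfinite(self.distance_km).all():
            raise ValueError("distances must be finite")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ClineData":
        return cls(df["distance_km"].to_numpy(), df["successes"].to_numpy(),
                   df["total"].to_numpy())


def cline_loglik(model: ClineModel, data: ClineData) -> float:
    """Binomial log-likelihood of *data* under *model* (p clamped away from
    0 and 1 by 1e-9)."""
    p = np.clip(cline_eval(model, data.distance_km), _PCLAMP, 1.0 - _PCLAMP)
    return float(np.sum(data.successes * np.log(p)
                        + (data.totals - data.successes) * np.log1p(-p)))


@dataclass
class ClineFitResult:
    model: ClineModel
    log_lik: float
    aic: float
    n_params: int
    variant: str
    support: dict = field(default_factory=dict)
    n_starts: int = 0
    n_converged: int = 0
    seed: int | None = None
    fixed: dict = field(default_factory=dict)
    data: ClineData | None = None


def _model_from_vector(theta: np.ndarray, variant: str, fixed: dict) -> ClineModel:
    names = VARIANT_PARAMS[variant]
    kw = dict(zip(names, theta))
    if variant == "null":
        p = min(max(kw.pop("p"), 0.0), 1.0)
        return ClineModel(centre=0.0, width=1.0, p_min=p, p_max=p, variant="null")
    if variant == "I":
        kw["p_min"] = fixed["p_min"]
        kw["p_max"] = fixed["p_max"]
    if "p_min" in kw and kw["p_min"] > kw["p_max"]:  # orientation-safe swap
        kw["p_min"], kw["p_max"] = kw["p_max"], kw["p_min"]
    kw = {k: float(v) for k, v in kw.items()}
    return ClineModel(variant=variant, **kw)


def _default_bounds(data: ClineData, variant: str) -> list[tuple[float, float]]:
    lo, hi = data.distance_km.min(), data.distance_km.max()
    span = max(hi - lo, 1.0)
    cb = (lo - 200.0, hi + 200.0)
    wb = (1.0, 3000.0)
    if variant == "null":
        return [(0.0, 1.0)]
    if variant == "I":
        return [cb, wb]
    if variant == "II":
        return [cb, wb, (0.0, 1.0), (0.0, 1.0)]
    return [cb, wb, (0.0, 1.0), (0.0, 1.0),
            (0.0, span), (0.0, 1.0), (0.0, span), (0.0, 1.0)]


def _starts(data: ClineData, variant: str, bounds, n_starts: int,
            rng: np.random.Generator) -> list[np.ndarray]:
    freqs = data.successes / data.totals
    x = data.distance_km
    lo, hi = x.min(), x.max()
    # heuristic: centre where the observed frequency crosses its midrange
    mid = (freqs.min() + freqs.max()) / 2.0
    order = np.argsort(x)
    above = freqs[order] >= mid
    idx = int(np.argmax(above)) if above.any() else len(x) // 2
    c0 = x[order][idx]
    w0 = max((hi - lo) / 4.0, 2.0)
    if variant == "null":
        base = [np.array([freqs.mean()])]
    elif variant == "I":
        base = [np.array([c0, w0])]
    elif variant == "II":
        base = [np.array([c0, w0, freqs.min(), freqs.max()])]
    else:
        base = [np.array([c0, w0, freqs.min(), freqs.max(), (hi - lo) / 10, 0.5,
                          (hi - lo) / 10, 0.5])]
    lo_b = np.array([b[0] for b in bounds])
    hi_b = np.array([b[1] for b in bounds])
    while len(base) < n_starts:
        draw = lo_b + (hi_b - lo_b) * rng.random(len(bounds))
        if variant != "null":
            draw[1] = math.exp(rng.uniform(math.log(5.0), math.log(min(3000.0, 3 * (hi - lo)))))
        base.append(draw)
    return base


def fit_cline(data: ClineData, variant: str = "II",
              bounds: Sequence[tuple[float, float]] | None = None,
              n_starts: int = 8, seed: int | None = 0,
              fixed: dict | None = None,
              compute_support: bool = True,
              support_params: Sequence[str] | None = None) -> ClineFitResult:
    """Bounded multi-start maximum-likelihood cline fit.

    ``fixed`` supplies the end frequencies for variant I (defaults to the
    observed frequencies at the two range-end sites).  Support limits are
    2-unit profile-likelihood intervals (see :func:`support_interval`);
    computing them re-optimizes the remaining parameters on a grid, so pass
    ``compute_support=False`` in tight simulation loops.
    """
    if variant not in VARIANT_PARAMS:
        raise ValueError(f"unknown variant {variant!r}")
    n_sites = len(np.unique(data.distance_km))
    if n_sites < (2 if variant == "null" else 3):
        raise ValueError("too few distinct distances for this variant")
    fixed = dict(fixed or {})
    if variant == "I" and ("p_min" not in fixed or "p_max" not in fixed):
        order = np.argsort(data.distance_km)
        f = data.successes / data.totals
        lo_f, hi_f = f[order][0], f[order][-1]
        fixed.setdefault("p_min", float(min(lo_f, hi_f)))
        fixed.setdefault("p_max", float(max(lo_f, hi_f)))
    bounds = list(bounds) if bounds is not None else _default_bounds(data, variant)
    rng = np.random.default_rng(seed)

    def nll(theta: np.ndarray) -> float:
        try:
            model = _model_from_vector(theta, variant, fixed)
        except ValueError:
            return 1e12
        return -cline_loglik(model, data)

    best = None
    n_conv = 0
    for x0 in _starts(data, variant, bounds, n_starts, rng):
        res = optimize.minimize(nll, x0, method="L-BFGS-B", bounds=bounds)
        if np.isfinite(res.fun):
            n_conv += 1
            if best is None or res.fun < best.fun:
                best = res
    if best is None:
        raise RuntimeError(f"cline fit failed to converge from {n_starts} starts")
    model = _model_from_vector(best.x, variant, fixed)
    logl = -best.fun
    k = len(VARIANT_PARAMS[variant])
    fit = ClineFitResult(model=model, log_lik=logl, aic=2 * k - 2 * logl,
                         n_params=k, variant=variant, n_starts=n_starts,
                         n_converged=n_conv, seed=seed, fixed=fixed, data=data)
    if compute_support:
        names = support_params or VARIANT_PARAMS[variant]
        for name in names:
            fit.support[name] = profile_support(fit, name)
    return fit


def select_cline_model(fits: dict) -> str:
    """Lowest-AIC variant; ties broken toward fewer free parameters."""
    if not fits:
        raise ValueError("no fitted variants supplied")
    def key(item):
        variant, fit = item
        aic = fit.aic if hasattr(fit, "aic") else float(fit)
        k = len(VARIANT_PARAMS[variant])
        return (aic, k)
    return min(fits.items(), key=key)[0]


@dataclass
class SupportInterval:
    low: float
    high: float
    clipped_low: bool = False
    clipped_high: bool = False
    unbounded: bool = False

    def __iter__(self):
        return iter((self.low, self.high))

    def __contains__(self, value: float) -> bool:
        return self.low <= value <= self.high


def support_interval(profile: Callable[[float], float], mle: float,
                     bounds: tuple[float, float], drop: float = 2.0,
                     tol: float = 1e-6) -> SupportInterval:
    """Widest contiguous interval around *mle* whose profile log-likelihood
    stays within *drop* units of its maximum.

    *profile* maps a parameter value to its profile log-likelihood.  The
    interval is found by stepping outward (doubling) then bisecting the
    crossing; ends clipped at *bounds* are flagged.
    """
    lmax = profile(mle)
    target = lmax - drop

    def edge(direction: int, bound: float) -> tuple[float, bool]:
        step = max(abs(mle) * 1e-3, 1e-3)
        inner = mle
        while True:
            cand = inner + direction * step
            if (direction > 0 and cand >= bound) or (direction < 0 and cand <= bound):
                if profile(bound) >= target:
                    return bound, True
                cand = bound
                break
            if profile(cand) < target:
                break
            inner = cand
            step *= 2.0
        outer = cand
        while abs(outer - inner) > tol * max(1.0, abs(mle)):
            mid = 0.5 * (inner + outer)
            if profile(mid) >= target:
                inner = mid
            else:
                outer = mid
        return inner, False

    lo, clip_lo = edge(-1, bounds[0])
    hi, clip_hi = edge(+1, bounds[1])
    return SupportInterval(lo, hi, clip_lo, clip_hi,
                           unbounded=clip_lo and clip_hi)


def profile_support(fit: ClineFitResult, name: str, drop: float = 2.0) -> SupportInterval:
    """2-unit support limits for one parameter of a fitted cline, profiling
    out the remaining free parameters."""
    names = list(VARIANT_PARAMS[fit.variant])
    if name not in names:
        raise ValueError(f"{name!r} is not a free parameter of variant {fit.variant}")
    idx = names.index(name)
    bounds = _default_bounds(fit.data, fit.variant)
    mle_vec = np.array([getattr(fit.model, n) if n != "p" else fit.model.p_min
                        for n in names])
    others = [i for i in range(len(names)) if i != idx]

    def profile(value: float) -> float:
        if not others:
            theta = np.array([value])
            return -_nll_static(theta, fit, names)
        def nll_sub(sub: np.ndarray) -> float:
            theta = np.empty(len(names))
            theta[idx] = value
            theta[others] = sub
            return _nll_static(theta, fit, names)
        res = optimize.minimize(nll_sub, mle_vec[others], method="L-BFGS-B",
                                bounds=[bounds[i] for i in others])
        return -float(res.fun)

    return support_interval(profile, float(mle_vec[idx]),
                            (bounds[idx][0], bounds[idx][1]), drop=drop)


def _nll_static(theta: np.ndarray, fit: ClineFitResult, names) -> float:
    try:
        model = _model_from_vector(theta, fit.variant, fit.fixed)
    except ValueError:
        return 1e12
    return -cline_loglik(model, fit.data)


# ---------------------------------------------------------------------------
# neutral cline width

def neutral_cline_width(T: float, sigma: float) -> float:
    """Width (km) of a neutral diffusion cline after *T* generations of
    secondary contact with per-generation dispersal *sigma* (km):
    w = sigma * sqrt(2 pi T)."""
    if T <= 0 or sigma <= 0:
        raise ValueError("T and sigma must be positive")
    return sigma * math.sqrt(2.0 * math.pi * T)


def time_since_contact(width: float, sigma: float) -> float:
    """Inversion of :func:`neutral_cline_width`: T = (w / (sqrt(2 pi) sigma))^2."""
    if width <= 0 or sigma <= 0:
        raise ValueError("width and sigma must be positive")
    return (width / (math.sqrt(2.0 * math.pi) * sigma)) ** 2


# ---------------------------------------------------------------------------
# concordance / coincidence test (scaled-logit shape)

def _logit_cline(x, centre, width, p_min, p_max):
    """Scaled-logit cline: identical central sigmoid, no tails."""
    z = np.clip(4.0 * (np.asarray(x, float) - centre) / width, -700.0, 700.0)
    s = 1.0 / (1.0 + np.exp(-z))
    return p_min + (p_max - p_min) * s


def _logit_nll(x, k, n, centre, width, p_min, p_max):
    if width <= 0 or not (0 <= p_min <= 1 and 0 <= p_max <= 1):
        return 1e12
    if p_min > p_max:
        p_min, p_max = p_max, p_min
    p = np.clip(_logit_cline(x, centre, width, p_min, p_max), _PCLAMP, 1 - _PCLAMP)
    return -float(np.sum(k * np.log(p) + (n - k) * np.log1p(-p)))


@dataclass
class ConcordanceResult:
    log_lik_free: float
    log_lik_constrained: float
    chi2: float
    df: int
    p_value: float
    free_params: pd.DataFrame | None = None
    constrained_centre: float = float("nan")
    constrained_width: float = float("nan")
    degenerate: bool = False


def concordance_test(datasets: Sequence[ClineData], n_starts: int = 6,
                     seed: int | None = 0) -> ConcordanceResult:
    """Likelihood-ratio test of cline concordance and coincidence.

    Free model: per-locus centre, width and end frequencies (4L parameters).
    Constrained model: one shared centre and width, per-locus end
    frequencies (2 + 2L).  chi^2 = 2 (logL_free - logL_constrained) with
    2(L - 1) degrees of freedom.
    """
    L = len(datasets)
    if L < 1:
        raise ValueError("need at least one locus")
    if L == 1:
        fit = _fit_logit_single(datasets[0], n_starts, seed)
        return ConcordanceResult(fit[0], fit[0], 0.0, 0, 1.0, degenerate=True)
    rng = np.random.default_rng(seed)
    cons = _fit_logit_constrained(datasets, n_starts, rng)
    free_rows = []
    logl_free = 0.0
    for li, data in enumerate(datasets):
        warm = (cons["centre"], cons["width"],
                cons["pmin"][li], cons["pmax"][li])
        logl, params = _fit_logit_single(data, n_starts,
                                         int(rng.integers(2 ** 31)), warm=warm)
        logl_free += logl
        free_rows.append({"locus": li, "centre": params[0], "width": params[1],
                          "p_min": params[2], "p_max": params[3], "log_lik": logl})
    chi2 = max(0.0, 2.0 * (logl_free - cons["logl"]))
    df = 2 * (L - 1)
    p = float(sps.chi2.sf(chi2, df))
    return ConcordanceResult(logl_free, cons["logl"], chi2, df, p,
                             pd.DataFrame(free_rows), cons["centre"], cons["width"])


def _fit_logit_single(data: ClineData, n_starts: int, seed,
                      warm: tuple | None = None) -> tuple[float, np.ndarray]:
    x, k, n = data.distance_km, data.successes, data.totals
    lo, hi = x.min(), x.max()
    bounds = [(lo - 200, hi + 200), (1.0, 3000.0), (0.0, 1.0), (0.0, 1.0)]
    rng = np.random.default_rng(seed)
    f = k / n
    starts = [np.array([x[np.argsort(x)][len(x) // 2], (hi - lo) / 4, f.min(), f.max()])]
    if warm is not None:
        starts.append(np.asarray(warm, dtype=float))
    while len(starts) < n_starts:
        starts.append(np.array([rng.uniform(lo, hi),
                                math.exp(rng.uniform(math.log(5), math.log(3000))),
                                rng.random(), rng.random()]))
    best = None
    for x0 in starts:
        res = optimize.minimize(lambda t: _logit_nll(x, k, n, *t), x0,
                                method="L-BFGS-B", bounds=bounds)
        if best is None or res.fun < best.fun:
            best = res
    params = best.x.copy()
    if params[2] > params[3]:
        params[2], params[3] = params[3], params[2]
    return -float(best.fun), params


def _fit_logit_constrained(datasets: Sequence[ClineData], n_starts: int,
                           rng: np.random.Generator) -> dict:
    L = len(datasets)
    all_x = np.concatenate([d.distance_km for d in datasets])
    lo, hi = all_x.min(), all_x.max()
    bounds = [(lo - 200, hi + 200), (1.0, 3000.0)] + [(0.0, 1.0)] * (2 * L)

    def nll(theta):
        c, w = theta[0], theta[1]
        total = 0.0
        for li, d in enumerate(datasets):
            total += _logit_nll(d.distance_km, d.successes, d.totals,
                                c, w, theta[2 + 2 * li], theta[3 + 2 * li])
        return total

    starts = []
    f0 = [(d.successes / d.totals) for d in datasets]
    base = [np.median(all_x), (hi - lo) / 4]
    for f in f0:
        base.extend([float(f.min()), float(f.max())])
    starts.append(np.array(base))
    while len(starts) < n_starts:
        draw = [rng.uniform(lo, hi),
                math.exp(rng.uniform(math.log(5), math.log(3000)))]
        for f in f0:
            draw.extend([float(f.min()), float(f.max())])
        starts.append(np.array(draw))
    best = None
    for x0 in starts:
        res = optimize.minimize(nll, x0, method="L-BFGS-B", bounds=bounds)
        if best is None or res.fun < best.fun:
            best = res
    pmin = [min(best.x[2 + 2 * i], best.x[3 + 2 * i]) for i in range(L)]
    pmax = [max(best.x[2 + 2 * i], best.x[3 + 2 * i]) for i in range(L)]
    return {"logl": -float(best.fun), "centre": float(best.x[0]),
            "width": float(best.x[1]), "pmin": pmin, "pmax": pmax}


# ---------------------------------------------------------------------------
# reporting

def fit_report(fits_by_locus: dict) -> pd.DataFrame:
    """Table of per-locus best-model parameters with support limits and the
    AIC of every fitted variant (the shape of a published cline table)."""
    rows = []
    for locus, fits in fits_by_locus.items():
        best = select_cline_model(fits)
        fit = fits[best]
        row = {"locus": locus, "best_model": best,
               "centre": fit.model.centre, "width": fit.model.width,
               "p_min": fit.model.p_min, "p_max": fit.model.p_max}
        for pname in ("centre", "width"):
            si = fit.support.get(pname)
            if si is not None:
                row[f"{pname}_low"], row[f"{pname}_high"] = si.low, si.high
        for variant, f in fits.items():
            row[f"aic_{variant}"] = f.aic
        rows.append(row)
    return pd.DataFrame(rows)
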