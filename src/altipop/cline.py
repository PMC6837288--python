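"""Equilibrium sigmoid clines in allele frequency along an elevational axis.

The core model is the hybrid-zone tanh cline: the expected frequency of the
focal allele at position ``x`` (here metres above sea level) is

    p(x) = pmin + (pmax - pmin) * (1 + tanh(2 (x - c) / w)) / 2

with center ``c`` (position of the frequency midpoint) and width ``w``
(inverse of the maximal slope).  Model variants optionally fix the scaling
to (0, 1) and/or replace the sigmoid beyond ``c - deltaL`` / ``c + deltaR``
with exponential tails of relative slope ``tau`` (the Szymura-Barton
parameterization used by hzar).  Observed allele counts are binomial, and
the posterior over parameters (flat priors within bounds) is sampled with a
Gaussian random-walk Metropolis-Hastings chain on transformed parameters,
with proposal scales adapted during burn-in.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ClineDataset",
    "ClineParams",
    "ClinePosterior",
    "CLINE_VARIANTS",
    "cline_frequency",
    "cline_loglik",
    "fit_cline_mcmc",
    "select_cline_model",
    "read_cline_tsv",
    "write_cline_tsv",
    "pearson_r2",
]

# variant -> (free_scaling, tails) with tails in {none,left,right,mirror,both}
CLINE_VARIANTS = {
    "fixed_none": (False, "none"),
    "fixed_left": (False, "left"),
    "fixed_right": (False, "right"),
    "fixed_mirror": (False, "mirror"),
    "fixed_both": (False, "both"),
    "free_none": (True, "none"),
    "free_left": (True, "left"),
    "free_right": (True, "right"),
    "free_mirror": (True, "mirror"),
    "free_both": (True, "both"),
}


@dataclass
class ClineDataset:
    """Per-locality elevation, focal-allele count and total allele count."""

    elevation: np.ndarray
    k: np.ndarray          # focal (high-altitude) allele count
    n_alleles: np.ndarray  # total alleles sampled (2 * diploids)
    locality: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.elevation = np.asarray(self.elevation, dtype=float)
        self.k = np.asarray(self.k, dtype=float)
        self.n_alleles = np.asarray(self.n_alleles, dtype=float)
        if not (self.elevation.shape == self.k.shape == self.n_alleles.shape):
            raise ValueError("elevation, k, n_alleles must align")
        if ((self.k < 0) | (self.k > self.n_alleles)).any():
            raise ValueError("allele counts must satisfy 0 <= k <= n")
        if not self.locality:
            self.locality = [f"loc{i}" for i in range(self.elevation.size)]

    @property
    def frequency(self) -> np.ndarray:
        return self.k / self.n_alleles

    @property
    def n_localities(self) -> int:
        return int(self.elevation.size)


@dataclass
class ClineParams:
    center: float
    width: float
    pmin: float = 0.0
    pmax: float = 1.0
    delta_l: float = 0.0
    tau_l: float = 1.0
    delta_r: float = 0.0
    tau_r: float = 1.0

    def __post_init__(self):
        if self.width <= 0:
            raise ValueError("width must be positive")
        if not (0.0 <= self.pmin <= self.pmax <= 1.0):
            raise ValueError("need 0 <= pmin <= pmax <= 1")
        if self.delta_l < 0 or self.delta_r < 0:
            raise ValueError("tail distances must be >= 0")
        for tau in (self.tau_l, self.tau_r):
            if not 0.0 < tau <= 1.0:
                raise ValueError("tail slope ratios must be in (0, 1]")


@dataclass
class ClinePosterior:
    variant: str
    param_names: list[str]
    samples: np.ndarray          # (n_kept, n_params)
    logpost: np.ndarray
    acceptance_rate: float
    map_params: ClineParams
    map_loglik: float
    ci: dict[str, tuple[float, float]]
    aicc: float
    seed: int | None

    def map_dict(self) -> dict[str, float]:
        i = int(np.argmax(self.logpost))
        return dict(zip(self.param_names, self.samples[i]))


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------

def _core(x, c, w):
    return 0.5 * (1.0 + np.tanh(2.0 * (x - c) / w))


def cline_frequency(x, params: ClineParams, tails: str = "none"):
    """Expected focal-allele frequency at position(s) ``x``.

    ``tails`` selects which side(s) of the center get exponential tails
    beyond ``c -/+ delta``; the tails join the sigmoid continuously and
    decay at a rate controlled by the slope-ratio parameter ``tau``.
    """
    x = np.asarray(x, dtype=float)
    c, w = params.center, params.width
    y = _core(x, c, w)
    if tails in ("left", "mirror", "both"):
        d, tau = params.delta_l, params.tau_l
        t = math.tanh(2.0 * d / w)
        yd = 0.5 * (1.0 - t)
        rate = 4.0 * tau / (w * (1.0 + t))
        left = x < c - d
        y = np.where(left, yd * np.exp(rate * (x - (c - d))), y)
    if tails in ("right", "mirror", "both"):
        if tails == "mirror":
            d, tau = params.delta_l, params.tau_l
        else:
            d, tau = params.delta_r, params.tau_r
        t = math.tanh(2.0 * d / w)
        yd = 0.5 * (1.0 - t)
        rate = 4.0 * tau / (w * (1.0 + t))
        right = x > c + d
        y = np.where(right, 1.0 - yd * np.exp(-rate * (x - (c + d))), y)
    p = params.pmin + (params.pmax - params.pmin) * y
    return p if p.ndim else float(p)


_EPS = 1e-9


def cline_loglik(data: ClineDataset, params: ClineParams,
                 tails: str = "none") -> float:
    """Binomial log-likelihood of allele counts under the cline."""
    p = np.clip(cline_frequency(data.elevation, params, tails), _EPS, 1 - _EPS)
    return float(np.sum(data.k * np.log(p)
                        + (data.n_alleles - data.k) * np.log1p(-p)))


# ---------------------------------------------------------------------------
# MCMC
# ---------------------------------------------------------------------------

def _variant_params(variant: str) -> list[str]:
    free, tails = CLINE_VARIANTS[variant]
    names = ["center", "width"]
    if free:
        names += ["pmin", "pmax"]
    if tails in ("left", "mirror", "both"):
        names += ["delta_l", "tau_l"]
    if tails in ("right", "both"):
        names += ["delta_r", "tau_r"]
    return names


def _default_bounds(data: ClineDataset) -> dict[str, tuple[float, float]]:
    lo, hi = float(data.elevation.min()), float(data.elevation.max())
    span = max(hi - lo, 1.0)
    return {
        "center": (lo - 0.5 * span, hi + 0.5 * span),
        "width": (1e-3 * span, 10.0 * span),
        "pmin": (0.0, 1.0),
        "pmax": (0.0, 1.0),
        "delta_l": (1e-3 * span, 2.0 * span),
        "tau_l": (1e-3, 1.0),
        "delta_r": (1e-3 * span, 2.0 * span),
        "tau_r": (1e-3, 1.0),
    }

_LOG_SCALE = {"width", "delta_l", "delta_r"}
_LOGIT_SCALE = {"pmin", "pmax", "tau_l", "tau_r"}


def _transform(name, v, lo, hi):
    if name in _LOG_SCALE:
        return math.log(v)
    if name in _LOGIT_SCALE:
        z = (v - lo) / (hi - lo)
        z = min(max(z, 1e-12), 1 - 1e-12)
        return math.log(z / (1 - z))
    return v


def _back(name, z, lo, hi):
    if name in _LOG_SCALE:
        return math.exp(z)
    if name in _LOGIT_SCALE:
        return lo + (hi - lo) / (1.0 + math.exp(-z))
    return z


def _log_jacobian(name, v, lo, hi):
    # d(natural)/d(transformed): flat prior on the natural scale needs this
    # factor in the MH ratio when proposing on the transformed scale
    if name in _LOG_SCALE:
        return math.log(v)
    if name in _LOGIT_SCALE:
        z = (v - lo) / (hi - lo)
        z = min(max(z, 1e-12), 1 - 1e-12)
        return math.log(z * (1 - z) * (hi - lo))
    return 0.0


def _make_params(names, values, tails) -> ClineParams | None:
    d = dict(zip(names, values))
    kwargs = {"center": d["center"], "width": d["width"]}
    if "pmin" in d:
        if d["pmin"] > d["pmax"]:
            return None
        kwargs["pmin"], kwargs["pmax"] = d["pmin"], d["pmax"]
    for k in ("delta_l", "tau_l", "delta_r", "tau_r"):
        if k in d:
            kwargs[k] = d[k]
    try:
        return ClineParams(**kwargs)
    except ValueError:
        return None


def fit_cline_mcmc(data: ClineDataset, variant: str = "free_none",
                   chain_length: int = 100_000, burn_in: int = 10_000,
                   proposal_scales: dict | None = None, rng=None,
                   bounds: dict | None = None, thin: int = 1) -> ClinePosterior:
    """Random-walk Metropolis-Hastings fit of a cline variant.

    Proposals are Gaussian on transformed parameters (log width and tail
    distances, logit bounded fractions); priors are flat on the natural
    scale within bounds, so the Hastings ratio carries the transform
    Jacobian.  Scales adapt toward 20-40%% acceptance during burn-in and are
    then frozen.  Returns posterior samples, the MAP, equal-tail 95%%
    credible intervals and the AICc of the MAP fit.
    """
    if variant not in CLINE_VARIANTS:
        raise ValueError(f"unknown variant {variant!r}")
    if chain_length <= burn_in:
        raise ValueError("chain_length must exceed burn_in")
    if data.n_localities < 3 or np.unique(data.elevation).size < 3:
        raise ValueError("need >= 3 localities with distinct positions")
    _, tails = CLINE_VARIANTS[variant]
    names = _variant_params(variant)
    bnds = _default_bounds(data)
    if bounds:
        bnds.update(bounds)
    seed = rng if isinstance(rng, (int, np.integer)) else None
    rng = np.random.default_rng(rng)

    # start from a moment guess: center where the observed frequency first
    # crosses the midpoint of its range (along increasing elevation)
    order = np.argsort(data.elevation)
    fs = data.frequency[order]
    xs = data.elevation[order]
    mid = 0.5 * (fs.min() + fs.max())
    above = np.nonzero(fs >= mid)[0]
    c0 = float(xs[above[0]]) if above.size else float(np.median(xs))
    init = {
        "center": c0,
        "width": float(np.ptp(data.elevation) / 2.0 or 1.0),
        "pmin": max(float(data.frequency.min()), 0.01),
        "pmax": min(float(data.frequency.max()), 0.99),
        "delta_l": float(np.ptp(data.elevation) / 4.0 or 1.0),
        "tau_l": 0.5,
        "delta_r": float(np.ptp(data.elevation) / 4.0 or 1.0),
        "tau_r": 0.5,
    }
    if init["pmin"] > init["pmax"]:
        init["pmin"], init["pmax"] = init["pmax"], init["pmin"]
    z = np.array([_transform(n, init[n], *bnds[n]) for n in names])
    span = float(np.ptp(data.elevation)) or 1.0
    default_scale = {"center": 0.1 * span}
    scales = np.array([(proposal_scales or {}).get(
        n, default_scale.get(n, 0.4)) for n in names])

    def posterior(zvec):
        vals = [_back(n, zi, *bnds[n]) for n, zi in zip(names, zvec)]
        for n, v in zip(names, vals):
            lo, hi = bnds[n]
            if not lo <= v <= hi:
                return None, -np.inf
        p = _make_params(names, vals, tails)
        if p is None:
            return None, -np.inf
        ll = cline_loglik(data, p, tails)
        lj = sum(_log_jacobian(n, v, *bnds[n]) for n, v in zip(names, vals))
        return p, ll + lj

    cur_p, cur_lp = posterior(z)
    if not np.isfinite(cur_lp):  # pragma: no cover - defensive
        raise RuntimeError("invalid initial state")

    kept = []
    kept_lp = []
    kept_ll = []
    n_accept = 0
    n_prop = 0
    k_par = len(names)
    adapt_window = max(50 * k_par, burn_in // 20)
    win_prop = np.zeros(k_par)
    win_acc = np.zeros(k_par)
    normal = rng.standard_normal
    for it in range(chain_length):
        j = it % k_par  # cycle single-coordinate updates
        zprop = z.copy()
        zprop[j] += scales[j] * normal()
        prop_p, prop_lp = posterior(zprop)
        n_prop += 1
        win_prop[j] += 1
        if np.log(rng.random()) < prop_lp - cur_lp:
            z = zprop
            cur_p, cur_lp = prop_p, prop_lp
            n_accept += 1
            win_acc[j] += 1
        if it < burn_in and (it + 1) % adapt_window == 0:
            # per-coordinate adaptation toward 20-40% acceptance
            rate = win_acc / np.maximum(win_prop, 1)
            scales = np.where(rate < 0.20, scales * 0.6, scales)
            scales = np.where(rate > 0.40, scales * 1.6, scales)
            win_prop[:] = 0
            win_acc[:] = 0
        if it >= burn_in and (it - burn_in) % thin == 0:
            vals = [_back(n, zi, *bnds[n]) for n, zi in zip(names, z)]
            kept.append(vals)
            kept_lp.append(cur_lp)
            kept_ll.append(cline_loglik(data, cur_p, tails))

    samples = np.array(kept)
    logpost = np.array(kept_lp)
    loglik = np.array(kept_ll)
    acc = n_accept / n_prop
    flagged = acc == 0.0
    if flagged:
        warnings.warn("MCMC accepted no proposals; posterior is degenerate")
    # MAP by maximum likelihood among samples (flat prior: posterior mode)
    i_map = int(np.argmax(loglik))
    map_params = _make_params(names, samples[i_map], tails)
    map_ll = float(loglik[i_map])
    ci = {n: (float(np.percentile(samples[:, i], 2.5)),
              float(np.percentile(samples[:, i], 97.5)))
          for i, n in enumerate(names)}
    k = len(names)
    n_loc = data.n_localities
    aicc = _aicc(map_ll, k, n_loc)
    return ClinePosterior(
        variant=variant, param_names=names, samples=samples, logpost=loglik,
        acceptance_rate=acc, map_params=map_params, map_loglik=map_ll,
        ci=ci, aicc=aicc, seed=seed)


def _aicc(ll: float, k: int, n: int) -> float:
    if n - k - 1 <= 0:
        return math.inf
    return -2.0 * ll + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def select_cline_model(data: ClineDataset, variants=None,
                       chain_length: int = 20_000, burn_in: int = 4_000,
                       rng=None):
    """Fit several variants and rank them by AICc (ascending).

    Variants with too few localities for their parameter count are skipped
    with a warning.  Ties keep stable variant-name order.  Returns a pandas
    DataFrame with variant, k, map_loglik, aicc, delta_aicc.
    """
    import pandas as pd

    if variants is None:
        variants = list(CLINE_VARIANTS)
    if not variants:
        raise ValueError("no variants requested")
    rng = np.random.default_rng(rng)
    rows = []
    for v in sorted(variants):
        k = len(_variant_params(v))
        if data.n_localities <= k + 1:
            warnings.warn(f"variant {v!r} skipped: needs more localities "
                          f"than parameters + 1")
            continue
        post = fit_cline_mcmc(data, v, chain_length=chain_length,
                              burn_in=burn_in,
                              rng=int(rng.integers(0, 2**31 - 1)))
        rows.append({"variant": v, "k": k, "map_loglik": post.map_loglik,
                     "aicc": post.aicc})
    df = pd.DataFrame(rows).sort_values(
        ["aicc", "variant"], kind="stable").reset_index(drop=True)
    df["delta_aicc"] = df["aicc"] - df["aicc"].min()
    return df


# ---------------------------------------------------------------------------
# I/O and small utilities
# ---------------------------------------------------------------------------

def read_cline_tsv(path) -> ClineDataset:
    """Read a locality table: locality, elevation_m, allele_H_count, total_alleles."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"locality", "elevation_m", "allele_H_count", "total_alleles"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"cline TSV missing columns: {sorted(missing)}")
    return ClineDataset(
        elevation=df["elevation_m"].to_numpy(float),
        k=df["allele_H_count"].to_numpy(float),
        n_alleles=df["total_alleles"].to_numpy(float),
        locality=df["locality"].astype(str).tolist(),
    )


def write_cline_tsv(data: ClineDataset, path) -> None:
    import pandas as pd

    pd.DataFrame({
        "locality": data.locality,
        "elevation_m": data.elevation,
        "allele_H_count": data.k.astype(int),
        "total_alleles": data.n_alleles.astype(int),
    }).to_csv(path, sep="\t", index=False)


def pearson_r2(x, y) -> float:
    """Squared Pearson correlation between two vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 paired observations")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)
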