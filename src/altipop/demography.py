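"""Folded 2D-SFS demographic inference by Monte-Carlo composite likelihood.

The observed spectrum is built from genotypes by per-population missingness
filtering, hypergeometric projection to a common haploid sample size, and
minor-allele folding.  Model fitting maximizes a Poisson random-field
composite likelihood in which the expected spectrum comes not from a
diffusion solver but from the structured-coalescent branch-length estimator
(:func:`altipop.coalescent.expected_sfs_mc`) with common random numbers
across evaluations, and the overall mutation scale theta is profiled
analytically.

Model families for a two-deme split from an ancestral population:

``no_mig``          nu1, nu2, T
``one_mig``         nu1, nu2, T, M
``two_mig_classes`` nu1, nu2, T, M_high, M_low, P

with nu the deme size relative to the ancestral size, T the split time in
units of ``2 N_anc`` generations, and M the scaled migration rate
``2 N_anc m`` (so diploid migrant individuals per generation = M/2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats
from scipy.special import gammaln

from . import coalescent

__all__ = [
    "Folded2DSFS",
    "FitResult",
    "CalibratedEstimates",
    "build_folded_2dsfs",
    "composite_loglik",
    "profile_theta",
    "expected_model_sfs",
    "fit_demography",
    "likelihood_ratio",
    "calibrate",
    "bootstrap_ci",
    "write_sfs",
    "read_sfs",
    "MODEL_FAMILIES",
]

# parameter names per family; bounds follow the reported uniform priors
MODEL_FAMILIES = {
    "no_mig": ("nu1", "nu2", "T"),
    "one_mig": ("nu1", "nu2", "T", "M"),
    "two_mig_classes": ("nu1", "nu2", "T", "M_high", "M_low", "P"),
}

DEFAULT_BOUNDS = {
    "nu1": (0.1, 10.0),
    "nu2": (0.1, 10.0),
    "T": (0.005, 5.0),     # 2N_anc units; prior 0.01 < 2Nt < 10 => T in (0.005, 5)
    "M": (1e-3, 10.0),
    "M_high": (1e-3, 10.0),
    "M_low": (1e-3, 10.0),
    "P": (0.5, 1.0),
}

_REF_N = 10_000.0  # arbitrary diploid reference size for simulation units


@dataclass
class Folded2DSFS:
    """Folded joint spectrum over minor-allele-count pairs."""

    counts: np.ndarray            # (n1+1, n2+1), folded, fractional allowed
    n1: int                       # haploid projection size, population A
    n2: int
    l_callable: float | None = None
    pop_a: str = "pop1"
    pop_b: str = "pop2"

    @property
    def mask(self) -> np.ndarray:
        """True for cells carrying no information (fixed or fold-redundant)."""
        m = np.zeros_like(self.counts, dtype=bool)
        tot = self.n1 + self.n2
        for i in range(self.n1 + 1):
            for j in range(self.n2 + 1):
                if (i, j) in ((0, 0), (self.n1, self.n2)):
                    m[i, j] = True
                elif 2 * (i + j) > tot:
                    m[i, j] = True
                elif 2 * (i + j) == tot and (i, j) > (self.n1 - i, self.n2 - j):
                    m[i, j] = True
        return m

    @property
    def n_sites(self) -> float:
        return float(self.counts[~self.mask].sum())


@dataclass
class FitResult:
    family: str
    params: dict[str, float]
    theta: float
    loglik: float
    converged: bool
    restart_index: int
    seed: int | None = None
    n_restarts: int = 1
    restarts: list = field(default_factory=list, repr=False)


@dataclass
class CalibratedEstimates:
    n_anc: float
    deme_sizes: dict[str, float]
    split_time_generations: float
    migrants_per_generation: dict[str, float]
    ci: dict[str, tuple[float, float]] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# observed SFS construction
# ---------------------------------------------------------------------------

def _projection_weights(n_from: int, k: int, n_to: int) -> np.ndarray:
    """Hypergeometric weights spreading an allele count over a smaller sample.

    Probability of drawing j of the k alternate alleles when sampling
    ``n_to`` of ``n_from`` haploid copies without replacement.
    """
    j = np.arange(n_to + 1)
    return stats.hypergeom.pmf(j, n_from, k, n_to)


def build_folded_2dsfs(gm, pop_a: str, pop_b: str, projection,
                       max_missing_frac: float = 0.25) -> Folded2DSFS:
    """Folded joint SFS from a :class:`~altipop.popgen_core.GenotypeMatrix`.

    Sites with more than ``max_missing_frac`` missing genotypes in either
    population are dropped; remaining sites are projected down to
    ``projection = (n1, n2)`` haploid copies with hypergeometric weights
    (fractional cell counts), then folded onto minor-allele counts.
    """
    from .popgen_core import allele_counts

    n1p, n2p = (int(x) for x in projection)
    da = gm.dosages[gm.pop_index(pop_a), :]
    db = gm.dosages[gm.pop_index(pop_b), :]
    if n1p > 2 * da.shape[0] or n2p > 2 * db.shape[0]:
        raise ValueError("projection larger than available alleles")
    ca_n, ca_alt, _ = allele_counts(da)
    cb_n, cb_alt, _ = allele_counts(db)
    keep = ((da.shape[0] - ca_n) <= max_missing_frac * da.shape[0]) & \
           ((db.shape[0] - cb_n) <= max_missing_frac * db.shape[0]) & \
           (2 * ca_n >= n1p) & (2 * cb_n >= n2p)

    sfs = np.zeros((n1p + 1, n2p + 1))
    cache: dict[tuple, np.ndarray] = {}
    for na, ka, nb, kb in zip(2 * ca_n[keep], ca_alt[keep],
                              2 * cb_n[keep], cb_alt[keep]):
        wa = cache.setdefault((na, ka, n1p), _projection_weights(na, ka, n1p))
        wb = cache.setdefault((nb, kb, n2p), _projection_weights(nb, kb, n2p))
        sfs += np.outer(wa, wb)
    folded = coalescent.fold_sfs(sfs)
    out = Folded2DSFS(counts=folded, n1=n1p, n2=n2p, pop_a=pop_a, pop_b=pop_b)
    out.counts[out.mask] = 0.0
    return out


# ---------------------------------------------------------------------------
# composite likelihood
# ---------------------------------------------------------------------------

def composite_loglik(obs: Folded2DSFS, expected_normalized: np.ndarray,
                     theta: float) -> float:
    """Poisson composite log-likelihood of the observed spectrum.

    ``E = theta * expected_normalized`` per cell; cells are treated as
    independent Poisson counts.  Fractional observed counts are supported
    through the log-gamma function.  Cells with E = 0 but n > 0 yield -inf.
    """
    if theta <= 0:
        raise ValueError("theta must be positive")
    exp = np.asarray(expected_normalized, dtype=float)
    if exp.shape != obs.counts.shape:
        raise ValueError("expected SFS shape mismatch")
    mask = obs.mask
    n = obs.counts[~mask]
    e = theta * exp[~mask]
    ll = np.where(
        e > 0,
        n * np.log(np.where(e > 0, e, 1.0)) - e - gammaln(n + 1),
        np.where(n > 0, -np.inf, 0.0),
    )
    return float(ll.sum())


def profile_theta(obs: Folded2DSFS, expected_normalized: np.ndarray) -> float:
    """Analytic Poisson MLE of theta: sum(n) / sum(expected)."""
    mask = obs.mask
    denom = np.asarray(expected_normalized)[~mask].sum()
    if denom <= 0:
        raise ValueError("expected SFS has no mass on unmasked cells")
    return float(obs.counts[~mask].sum() / denom)


# ---------------------------------------------------------------------------
# model-expected SFS
# ---------------------------------------------------------------------------

def _family_model(family: str, params: dict, rate_class_mix=True):
    """Translate scaled parameters into a DemographicModel (2 demes)."""
    na = _REF_N
    nu1, nu2, T = params["nu1"], params["nu2"], params["T"]
    t_gen = T * 2.0 * na
    if family == "no_mig":
        mh = ml = 0.0
        p_high = 1.0
    elif family == "one_mig":
        mh = ml = params["M"] / 2.0
        p_high = 1.0
    elif family == "two_mig_classes":
        mh = params["M_high"] / 2.0
        ml = params["M_low"] / 2.0
        p_high = params["P"]
    else:
        raise ValueError(f"unknown model family {family!r}")

    def mat(m):
        return [[0.0, m], [m, 0.0]]

    return coalescent.DemographicModel(
        deme_names=["pop1", "pop2"],
        sizes=[nu1 * na, nu2 * na],
        splits=[(t_gen, 1, 0)],
        mig_high=mat(mh),
        mig_low=mat(ml),
        p_high=p_high,
        ancestral_size=na,
    )


def expected_model_sfs(family: str, params: dict, n1: int, n2: int,
                       n_sims: int, rng, return_variance: bool = False):
    """Normalized folded 2D-SFS expected under a model family.

    For ``two_mig_classes`` the two rate-class spectra are mixed with
    weights (P, 1-P).  With ``return_variance=True`` also returns the
    per-cell squared relative Monte-Carlo standard error of the mixture.
    """
    model = _family_model(family, params)
    if family == "two_mig_classes":
        rng = np.random.default_rng(rng)
        p = params["P"]
        hi = coalescent.expected_sfs_mc(model, (n1, n2), n_sims, fold=True,
                                        rng=rng, rate_class="high",
                                        return_variance=return_variance)
        lo = coalescent.expected_sfs_mc(model, (n1, n2), n_sims, fold=True,
                                        rng=rng, rate_class="low",
                                        return_variance=return_variance)
        if return_variance:
            (mh, vh), (ml, vl) = hi, lo
            sfs = p * mh + (1 - p) * ml
            absvar = (p * mh) ** 2 * vh + ((1 - p) * ml) ** 2 * vl
            tot = sfs.sum()
            sfs = sfs / tot if tot > 0 else sfs
            with np.errstate(divide="ignore", invalid="ignore"):
                relvar = np.where(sfs > 0,
                                  absvar / (tot * sfs) ** 2, 0.0)
            return sfs, relvar
        sfs = p * hi + (1 - p) * lo
        tot = sfs.sum()
        return sfs / tot if tot > 0 else sfs
    return coalescent.expected_sfs_mc(model, (n1, n2), n_sims, fold=True,
                                      rng=rng, rate_class="high",
                                      return_variance=return_variance)


# ---------------------------------------------------------------------------
# optimization
# ---------------------------------------------------------------------------

def fit_demography(obs: Folded2DSFS, model_family: str, n_restarts: int = 25,
                   bounds: dict | None = None, mc_sims_per_eval: int = 500,
                   rng=None, maxiter: int = 200, start: dict | None = None,
                   ftol: float = 1e-3, n_coarse: int = 15,
                   simplex_step: float = 0.5, refine_sims: int | None = None,
                   refine_maxiter: int = 50,
                   pool_min_count: float | None = None) -> FitResult:
    """Maximize the composite likelihood over a model family.

    Each restart first scores ``n_coarse`` parameter draws from the uniform
    priors (plus ``start`` if given, for the first restart) and then runs a
    Nelder-Mead search in log-parameter space from the best draw, with a
    deliberately wide initial simplex (``simplex_step`` in log units) so the
    search is not defeated by small-scale Monte-Carlo roughness.  Within a
    restart every likelihood evaluation reuses one random-number stream
    (common random numbers), making the objective deterministic; theta is
    profiled analytically at every evaluation.

    Two defenses against Monte-Carlo noise in the expected spectrum are
    applied: a first-order bias correction of ``n ln(E)`` using the
    per-cell Monte-Carlo variance, and (with ``pool_min_count``) pooling of
    sparse cells — cells whose *observed* count is below the threshold are
    merged into one Poisson class, so no log ever sees a tiny, noisily
    estimated expectation.  ``refine_sims`` adds a final polish of the best
    point on a higher-precision surface.
    """
    if model_family not in MODEL_FAMILIES:
        raise ValueError(f"unknown model family {model_family!r}")
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    names = MODEL_FAMILIES[model_family]
    bnds = dict(DEFAULT_BOUNDS)
    if bounds:
        bnds.update(bounds)
    lo = np.array([bnds[n][0] for n in names])
    hi = np.array([bnds[n][1] for n in names])

    seed = rng if isinstance(rng, (int, np.integer)) else None
    master = np.random.default_rng(rng)
    restart_seeds = master.integers(0, 2**31 - 1, size=n_restarts + 1)

    n_unmasked = obs.counts[~obs.mask]
    if pool_min_count is not None:
        pool = n_unmasked < pool_min_count
        if (~pool).sum() < 2:
            raise ValueError("pool_min_count leaves fewer than 2 cells")
    else:
        pool = np.zeros(n_unmasked.shape, dtype=bool)
    n_main = n_unmasked[~pool]
    n_pool = n_unmasked[pool].sum()

    def make_neg_ll(crn_seed, n_sims):
        def neg_ll(z):
            x = np.exp(z)
            if np.any(x < lo) or np.any(x > hi):
                return 1e12
            params = dict(zip(names, x))
            exp, relvar = expected_model_sfs(
                model_family, params, obs.n1, obs.n2, n_sims,
                rng=crn_seed, return_variance=True)
            if exp[~obs.mask].sum() <= 0:
                return 1e12
            theta = profile_theta(obs, exp)
            ev = theta * exp[~obs.mask]
            e_main = ev[~pool]
            e_pool = ev[pool].sum()
            with np.errstate(divide="ignore", invalid="ignore"):
                ll = float(np.sum(n_main * np.log(e_main) - e_main
                                  - gammaln(n_main + 1)))
            if pool.any():
                ll += (n_pool * np.log(e_pool) - e_pool
                       - gammaln(n_pool + 1)) if e_pool > 0 else (
                           0.0 if n_pool == 0 else -np.inf)
            # first-order correction of the Monte-Carlo bias of n*ln(E):
            # E[ln Ehat] = ln E - relvar/2, so add back n*relvar/2 (capped;
            # without this the noisy objective systematically favors models
            # whose small cells happen to be better resolved)
            ll += 0.5 * np.sum(n_main
                               * np.minimum(relvar[~obs.mask][~pool], 1.0))
            return -ll if np.isfinite(ll) else 1e12
        return neg_ll

    def run_nm(neg_ll, z0, iters, step):
        simplex = [z0] + [z0 + step * np.eye(len(z0))[i]
                          for i in range(len(z0))]
        return optimize.minimize(
            neg_ll, z0, method="Nelder-Mead",
            options={"maxiter": iters, "fatol": ftol, "xatol": 1e-3,
                     "initial_simplex": np.array(simplex)})

    results = []
    for r in range(n_restarts):
        r_seed = int(restart_seeds[r])
        draw = np.random.default_rng(r_seed + 1)
        neg_ll = make_neg_ll(r_seed, mc_sims_per_eval)
        # starts are drawn log-uniformly across the prior box: the
        # composite-likelihood surface is multimodal along the size/time
        # ridge, and log-spacing covers the small-T basins that a uniform
        # draw rarely visits
        starts = [np.exp(np.log(lo) + (np.log(hi) - np.log(lo))
                         * draw.random(len(names)))
                  for _ in range(n_coarse)]
        if r == 0 and start is not None:
            starts.insert(0, np.array([start[n] for n in names]))
        scored = sorted((neg_ll(np.log(x)), tuple(x)) for x in starts)
        z0 = np.log(np.array(scored[0][1]))
        res = run_nm(neg_ll, z0, maxiter, simplex_step)
        x = np.exp(res.x)
        params = dict(zip(names, x))
        exp = expected_model_sfs(model_family, params, obs.n1, obs.n2,
                                 mc_sims_per_eval, rng=r_seed)
        theta = profile_theta(obs, exp)
        results.append(FitResult(
            family=model_family, params=params, theta=theta,
            loglik=-neg_ll(res.x),
            converged=bool(res.success), restart_index=r, seed=seed,
            n_restarts=n_restarts))

    if refine_sims is not None:
        # re-score every restart's optimum on one common high-precision
        # surface (fair comparison between near-tied modes), then polish
        # the winner there, where the residual Monte-Carlo roughness no
        # longer drowns weak directions
        refine_seed = int(restart_seeds[-1])
        neg_ll = make_neg_ll(refine_seed, refine_sims)
        rescored = [-neg_ll(np.log(np.array([f.params[n] for n in names])))
                    for f in results]
        best = results[int(np.argmax(rescored))]
    else:
        best = max(results, key=lambda r: r.loglik)
    best.restarts = [(r.restart_index, r.loglik, r.converged) for r in results]
    if not any(r.converged for r in results):
        best.converged = False

    if refine_sims is not None:
        z0 = np.log(np.array([best.params[n] for n in names]))
        res = run_nm(neg_ll, z0, refine_maxiter, 0.5 * simplex_step)
        x = np.exp(res.x)
        params = dict(zip(names, x))
        exp = expected_model_sfs(model_family, params, obs.n1, obs.n2,
                                 refine_sims, rng=refine_seed)
        refined = FitResult(
            family=model_family, params=params,
            theta=profile_theta(obs, exp), loglik=-neg_ll(res.x),
            converged=best.converged, restart_index=best.restart_index,
            seed=seed, n_restarts=n_restarts)
        refined.restarts = best.restarts
        best = refined
    return best


def likelihood_ratio(fit_simple: FitResult, fit_complex: FitResult,
                     df: int) -> tuple[float, float]:
    """Naive likelihood-ratio test between nested composite-likelihood fits.

    Returns (2 * dLL, chi-square upper-tail p with ``df`` degrees of
    freedom).  No correction for the composite nature of the likelihood is
    applied, so the p-value is anti-conservative and should be read as a
    heuristic ranking device.
    """
    order = ["no_mig", "one_mig", "two_mig_classes"]
    if (fit_simple.family not in order or fit_complex.family not in order
            or order.index(fit_simple.family) >= order.index(fit_complex.family)):
        raise ValueError("families are not nested simple -> complex")
    dll = fit_complex.loglik - fit_simple.loglik
    tol = 1e-6 * max(1.0, abs(fit_simple.loglik))
    if dll < -tol:
        raise ValueError("complex model fits worse than simple beyond "
                         "optimizer tolerance")
    stat = max(2.0 * dll, 0.0)
    return stat, float(stats.chi2.sf(stat, df))


def calibrate(theta: float, mu: float, l_callable: float,
              relative_params: dict) -> CalibratedEstimates:
    """Convert scaled parameters to physical units.

    ``N_anc = theta / (4 mu L)``; deme sizes are ``nu * N_anc``; split time
    is ``T * 2 N_anc`` generations; migrants/generation per class is
    ``M / 2`` (with M the scaled rate ``2 N_anc m``).
    """
    if min(theta, mu, l_callable) <= 0:
        raise ValueError("theta, mu and L must be positive")
    n_anc = theta / (4.0 * mu * l_callable)
    sizes = {k: v * n_anc for k, v in relative_params.items()
             if k.startswith("nu")}
    t_gen = relative_params.get("T", 0.0) * 2.0 * n_anc
    mig = {k: v / 2.0 for k, v in relative_params.items()
           if k.startswith("M")}
    return CalibratedEstimates(
        n_anc=n_anc, deme_sizes=sizes, split_time_generations=t_gen,
        migrants_per_generation=mig)


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------

def _spaced_pool(positions, min_spacing_bp: float) -> np.ndarray:
    """Greedy left-to-right thinning to a pool of sites >= spacing apart."""
    pool = []
    last_chrom, last_pos = None, -math.inf
    for i, (chrom, pos) in enumerate(positions):
        if chrom != last_chrom or pos - last_pos >= min_spacing_bp:
            pool.append(i)
            last_chrom, last_pos = chrom, pos
    return np.array(pool, dtype=int)


def bootstrap_ci(gm, pop_a: str, pop_b: str, projection, model_family: str,
                 point_estimate: FitResult, n_boot: int = 100,
                 min_spacing_bp: float = 10_000.0, n_restarts: int = 5,
                 mc_sims_per_eval: int = 500, max_missing_frac: float = 0.25,
                 rng=None, maxiter: int = 100):
    """Percentile bootstrap CIs by SNP resampling with a spacing rule.

    Each replicate samples, with replacement, as many SNPs as the spaced
    pool contains, rebuilds the folded spectrum and refits with a reduced
    number of restarts, the first seeded at the point estimate.  Returns
    ``(ci_dict, fits)`` with 2.5/97.5 percentile bounds per parameter.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    positions = [(s[0], s[1]) for s in gm.site_ids]
    pool = _spaced_pool(positions, min_spacing_bp)
    if pool.size < 2:
        raise ValueError("too few SNPs satisfy the spacing rule")
    rng = np.random.default_rng(rng)
    fits = []
    for b in range(n_boot):
        take = rng.choice(pool, size=pool.size, replace=True)
        sub = type(gm)(
            dosages=gm.dosages[:, take],
            sample_ids=gm.sample_ids,
            pop_labels=gm.pop_labels,
            site_ids=[gm.site_ids[i] for i in take],
        )
        obs = build_folded_2dsfs(sub, pop_a, pop_b, projection,
                                 max_missing_frac=max_missing_frac)
        fits.append(fit_demography(
            obs, model_family, n_restarts=n_restarts,
            mc_sims_per_eval=mc_sims_per_eval,
            rng=int(rng.integers(0, 2**31 - 1)),
            start=point_estimate.params, maxiter=maxiter))
    names = MODEL_FAMILIES[model_family]
    ci = {}
    for n in names:
        vals = np.array([f.params[n] for f in fits])
        lo_b, hi_b = np.percentile(vals, [2.5, 97.5])
        ci[n] = (float(lo_b), float(hi_b))
    return ci, fits


# ---------------------------------------------------------------------------
# flat-text SFS serialization (dadi dialect)
# ---------------------------------------------------------------------------

def write_sfs(obs: Folded2DSFS, path) -> None:
    """Write the spectrum in the dadi flat-text dialect.

    First line: shape and the word 'folded'; second line: row-major cell
    values; third line: mask (1 = masked).
    """
    with open(path, "w") as fh:
        fh.write(f"{obs.n1 + 1} {obs.n2 + 1} folded\n")
        fh.write(" ".join(f"{v:.10g}" for v in obs.counts.ravel()) + "\n")
        fh.write(" ".join("1" if m else "0"
                          for m in obs.mask.ravel()) + "\n")


def read_sfs(path) -> Folded2DSFS:
    with open(path) as fh:
        header = fh.readline().split()
        shape = (int(header[0]), int(header[1]))
        vals = np.array([float(x) for x in fh.readline().split()])
        fh.readline()  # mask recomputed from shape
    counts = vals.reshape(shape)
    return Folded2DSFS(counts=counts, n1=shape[0] - 1, n2=shape[1] - 1)
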