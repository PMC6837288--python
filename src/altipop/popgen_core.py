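"""Per-site and multi-site population-genetic statistics.

Implements the building blocks of a demographically-informed selection scan:
the Weir & Cockerham (1984) two-population theta estimator from genotype
counts, the population branch statistic (PBS) of Yi et al., genotype-dosage
linkage disequilibrium (r^2), the Levene/Wigginton exact test of
Hardy-Weinberg proportions, empirical-distribution quantile thresholds, and
upper-tail hypergeometric (one-sided Fisher) enrichment.

Conventions
-----------
* Genotypes are diploid dosages in {0, 1, 2}; ``MISSING`` (-1) marks an
  uncalled genotype.  Missing genotypes are dropped per site per population
  (complete case).
* Per-site theta is ``a / (a + b + c)``; it is *undefined* (NaN) when the
  denominator is zero, i.e. when the site is monomorphic across the pair.
* Negative theta is floored at 0 before the PBS log transform and theta is
  capped at ``1 - 1e-12`` to keep branch lengths finite; PBS itself is never
  clamped and may be negative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

MISSING: int = -1

_THETA_CAP = 1.0 - 1e-12

__all__ = [
    "MISSING",
    "GenotypeMatrix",
    "FstComponents",
    "ScanRecord",
    "allele_counts",
    "weir_fst_components",
    "weir_fst_site",
    "multi_site_fst",
    "branch_length",
    "pbs",
    "pbs_from_theta",
    "ld_r2",
    "hwe_exact_test",
    "quantile_threshold",
    "hypergeom_enrichment",
    "scan_pbs",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class GenotypeMatrix:
    """Diploid dosage matrix [samples x sites] with population labels.

    ``dosages`` holds alternate-allele dosages in {0, 1, 2} or ``MISSING``.
    ``site_ids`` is a list of (chrom, pos, ref, alt) tuples, 1-based
    positions as in VCF.
    """

    dosages: np.ndarray
    sample_ids: list[str]
    pop_labels: list[str]
    site_ids: list[tuple] = field(default_factory=list)

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D [samples x sites]")
        n, m = self.dosages.shape
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length != number of rows")
        if len(self.pop_labels) != n:
            raise ValueError("pop_labels length != number of rows")
        if len(set(self.sample_ids)) != n:
            raise ValueError("duplicated sample_ids")
        if self.site_ids and len(self.site_ids) != m:
            raise ValueError("site_ids length != number of sites")
        ok = (self.dosages == MISSING) | (
            (self.dosages >= 0) & (self.dosages <= 2)
        )
        if not ok.all():
            raise ValueError("dosages must be in {0,1,2} or MISSING")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_sites(self) -> int:
        return self.dosages.shape[1]

    @property
    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.pop_labels:
            seen.setdefault(p)
        return list(seen)

    def pop_index(self, pop: str) -> np.ndarray:
        idx = np.array([i for i, p in enumerate(self.pop_labels) if p == pop])
        if idx.size == 0:
            raise KeyError(f"population {pop!r} not present")
        return idx


@dataclass(frozen=True)
class FstComponents:
    """Weir & Cockerham variance components for one site, one pair."""

    a: float
    b: float
    c: float

    @property
    def theta(self) -> float:
        s = self.a + self.b + self.c
        return self.a / s if s != 0.0 else float("nan")


@dataclass(frozen=True)
class ScanRecord:
    site_id: tuple
    fst_ab: float
    fst_ac: float
    fst_bc: float
    pbs: float
    is_outlier: bool = False

    @property
    def t_ab(self) -> float:
        return branch_length(self.fst_ab)

    @property
    def t_ac(self) -> float:
        return branch_length(self.fst_ac)

    @property
    def t_bc(self) -> float:
        return branch_length(self.fst_bc)


# ---------------------------------------------------------------------------
# allele counts
# ---------------------------------------------------------------------------

def allele_counts(dosages: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-site (n_called, alt_count, het_count) from a dosage block.

    ``dosages`` is [samples x sites] for one population.  Returns three
    integer vectors of length n_sites.
    """
    d = np.asarray(dosages)
    called = d != MISSING
    n_called = called.sum(axis=0)
    alt = np.where(called, d, 0).sum(axis=0)
    het = (d == 1).sum(axis=0)
    return n_called, alt, het


def _validate_counts(n, alt, het):
    n = np.asarray(n, dtype=float)
    alt = np.asarray(alt, dtype=float)
    het = np.asarray(het, dtype=float)
    if (n < 0).any() or (alt < 0).any() or (het < 0).any():
        raise ValueError("negative counts")
    if (alt > 2 * n).any():
        raise ValueError("alt_allele_count exceeds 2*n_called")
    if (het > n).any():
        raise ValueError("het_count exceeds n_called")
    if (het > alt).any() or (het > 2 * n - alt).any():
        raise ValueError("het_count inconsistent with allele count")
    return n, alt, het


# ---------------------------------------------------------------------------
# Weir & Cockerham theta (r = 2 populations)
# ---------------------------------------------------------------------------

def weir_fst_components(n1, alt1, het1, n2, alt2, het2):
    """Vectorized W&C (1984) variance components a, b, c for two populations.

    Inputs are per-site diploid sample sizes, alternate-allele counts and
    heterozygote counts; arrays broadcast elementwise.  Sites where either
    population has no called diploid, or where the pooled pair of samples is
    too small for the estimator (mean sample size <= 1), yield NaN
    components.
    """
    n1, alt1, het1 = _validate_counts(n1, alt1, het1)
    n2, alt2, het2 = _validate_counts(n2, alt2, het2)

    with np.errstate(divide="ignore", invalid="ignore"):
        p1 = alt1 / (2 * n1)
        p2 = alt2 / (2 * n2)
        h1 = het1 / n1
        h2 = het2 / n2

        nbar = (n1 + n2) / 2.0
        nc = 2.0 * nbar - (n1**2 + n2**2) / (2.0 * nbar)
        pbar = (n1 * p1 + n2 * p2) / (2.0 * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / nbar
        hbar = (n1 * h1 + n2 * h2) / (2.0 * nbar)

        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - s2 / 2.0 - hbar / 4.0) / (nbar - 1.0)
        )
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1 - pbar)
            - s2 / 2.0
            - (2.0 * nbar - 1.0) / (4.0 * nbar) * hbar
        )
        c = hbar / 2.0

    bad = (n1 < 1) | (n2 < 1) | (nbar <= 1.0) | (nc <= 0)
    a = np.where(bad, np.nan, a)
    b = np.where(bad, np.nan, b)
    c = np.where(bad, np.nan, c)
    return a, b, c


def weir_fst_site(n1, alt1, het1, n2, alt2, het2) -> FstComponents:
    """Scalar W&C components for a single site; theta is NaN when undefined."""
    a, b, c = weir_fst_components(n1, alt1, het1, n2, alt2, het2)
    return FstComponents(float(a), float(b), float(c))


def theta_from_components(a, b, c):
    """Per-site theta a/(a+b+c), NaN when the denominator vanishes."""
    a = np.asarray(a, dtype=float)
    denom = a + b + c
    with np.errstate(divide="ignore", invalid="ignore"):
        theta = a / denom
    return np.where(denom == 0, np.nan, theta)


def multi_site_fst(components) -> tuple[float, float, float]:
    """Summarize FST over sites: (mean_theta, sem_theta, weighted_theta).

    ``components`` is an iterable of :class:`FstComponents` or an (a, b, c)
    array triple.  The headline estimate is the mean +/- SEM of per-site
    theta over sites where theta is defined; the ratio-of-sums estimator
    sum(a)/sum(a+b+c) is returned as a third value.
    """
    if isinstance(components, tuple) and len(components) == 3:
        a, b, c = (np.asarray(x, dtype=float) for x in components)
    else:
        comps = list(components)
        a = np.array([x.a for x in comps], dtype=float)
        b = np.array([x.b for x in comps], dtype=float)
        c = np.array([x.c for x in comps], dtype=float)
    theta = theta_from_components(a, b, c)
    ok = np.isfinite(theta)
    if not ok.any():
        raise ValueError("no sites with defined theta")
    t = theta[ok]
    mean = float(t.mean())
    sem = float(t.std(ddof=1) / np.sqrt(t.size)) if t.size > 1 else 0.0
    denom = (a + b + c)[ok]
    weighted = float(a[ok].sum() / denom.sum())
    return mean, sem, weighted


# ---------------------------------------------------------------------------
# PBS
# ---------------------------------------------------------------------------

def branch_length(fst):
    """T = -ln(1 - FST) with FST floored at 0 and capped below 1."""
    f = np.asarray(fst, dtype=float)
    if np.any(f[np.isfinite(f)] > 1.0):
        raise ValueError("FST above 1")
    f = np.clip(f, 0.0, _THETA_CAP)
    return -np.log1p(-f)


def pbs(fst_ab, fst_ac, fst_bc):
    """Population branch statistic for focal population A.

    PBS = (T_AB + T_AC - T_BC) / 2 with T = -ln(1 - FST).  Accepts scalars
    or arrays; NaN propagates.  Negative PBS values are retained.
    """
    t_ab = branch_length(fst_ab)
    t_ac = branch_length(fst_ac)
    t_bc = branch_length(fst_bc)
    return (t_ab + t_ac - t_bc) / 2.0


def pbs_from_theta(theta_ab, theta_ac, theta_bc):
    """PBS from raw per-site theta estimates (NaN where any pair undefined).

    Unlike :func:`pbs`, estimator output slightly outside [0, 1] is clamped
    rather than rejected: the Weir-Cockerham per-site estimate can stray
    marginally above 1 (negative ``b`` component) or below 0.
    """
    clip = lambda t: np.minimum(np.asarray(t, dtype=float), 1.0)
    return pbs(clip(theta_ab), clip(theta_ac), clip(theta_bc))


# ---------------------------------------------------------------------------
# LD, HWE, quantiles, enrichment
# ---------------------------------------------------------------------------

def ld_r2(dosages_a, dosages_b) -> float:
    """Squared Pearson correlation of dosages over pairwise-complete samples.

    Returns NaN if fewer than 2 complete pairs or either site is
    monomorphic among complete pairs.
    """
    a = np.asarray(dosages_a, dtype=float)
    b = np.asarray(dosages_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("dosage vectors must have equal length")
    ok = (a != MISSING) & (b != MISSING)
    a, b = a[ok], b[ok]
    if a.size < 2 or a.std() == 0 or b.std() == 0:
        return float("nan")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact two-sided test of Hardy-Weinberg proportions (Levene/Wigginton).

    Conditional on the observed allele counts, sums the probabilities of all
    heterozygote counts (same parity) whose conditional probability does not
    exceed that of the observed count.
    """
    for x in (n_AA, n_Aa, n_aa):
        if x < 0 or int(x) != x:
            raise ValueError("genotype counts must be nonnegative integers")
    n = n_AA + n_Aa + n_aa
    if n < 1:
        raise ValueError("at least one diploid required")
    n_rare = 2 * min(n_AA, n_aa) + n_Aa  # minor allele count
    # possible het counts share parity with n_rare, range [parity, min(n_rare, 2n-n_rare)]
    het_max = min(n_rare, 2 * n - n_rare)
    hets = np.arange(n_rare % 2, het_max + 1, 2)
    if hets.size == 0:
        return 1.0
    # log P(het) ~ choose terms; compute unnormalized log-probs
    from scipy.special import gammaln

    homr = (n_rare - hets) // 2
    homc = n - hets - homr
    logp = (
        hets * np.log(2.0)
        - gammaln(homr + 1)
        - gammaln(hets + 1)
        - gammaln(homc + 1)
    )
    logp -= logp.max()
    p = np.exp(logp)
    p /= p.sum()
    p_obs = p[hets == n_Aa]
    if p_obs.size == 0:
        raise ValueError("heterozygote count inconsistent with allele counts")
    return float(min(1.0, p[p <= p_obs[0] * (1 + 1e-12)].sum()))


def quantile_threshold(values, q: float) -> float:
    """Smallest observed value v with ecdf(v) >= q (left-continuous ecdf).

    This is the value at rank ceil(q * n) of the sorted sample, matching the
    step-function ecdf convention rather than an interpolated quantile.
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size == 0:
        raise ValueError("empty value vector")
    if not 0.0 < q < 1.0:
        raise ValueError("q must be in (0, 1)")
    v = np.sort(v)
    k = int(np.ceil(q * v.size)) - 1
    return float(v[max(k, 0)])


def hypergeom_enrichment(overlap: int, set_size: int, category_size: int,
                         universe_size: int) -> float:
    """Upper-tail hypergeometric P(X >= overlap): one-sided Fisher test."""
    if overlap > min(set_size, category_size):
        raise ValueError("overlap exceeds set or category size")
    if set_size > universe_size or category_size > universe_size:
        raise ValueError("set or category larger than universe")
    if min(overlap, set_size, category_size, universe_size) < 0:
        raise ValueError("negative counts")
    return float(stats.hypergeom.sf(
        overlap - 1, universe_size, category_size, set_size))


# ---------------------------------------------------------------------------
# whole-matrix scan
# ---------------------------------------------------------------------------

def scan_pbs(gm: GenotypeMatrix, focal: str, out1: str, out2: str,
             max_missing_frac: float = 0.5,
             threshold: float | None = None,
             threshold_q: float | None = None):
    """Per-SNP pairwise FST and PBS scan for a focal population.

    Sites are usable when each population has >= 1 called diploid and the
    per-population missing fraction is at most ``max_missing_frac``.
    Returns a pandas DataFrame with per-site theta for the three pairs, PBS,
    and an outlier flag (against ``threshold`` if given, else against the
    empirical ``threshold_q`` quantile of the defined PBS values).
    """
    import pandas as pd

    blocks = {}
    for pop in (focal, out1, out2):
        blocks[pop] = gm.dosages[gm.pop_index(pop), :]
    counts = {p: allele_counts(d) for p, d in blocks.items()}
    usable = np.ones(gm.n_sites, dtype=bool)
    for p, d in blocks.items():
        n_called = counts[p][0]
        usable &= n_called >= 1
        usable &= (d.shape[0] - n_called) <= max_missing_frac * d.shape[0]

    def pair_theta(p, q):
        a, b, c = weir_fst_components(*counts[p], *counts[q])
        return theta_from_components(a, b, c)

    th_ab = pair_theta(focal, out1)
    th_ac = pair_theta(focal, out2)
    th_bc = pair_theta(out1, out2)
    pbs_vals = pbs_from_theta(th_ab, th_ac, th_bc)
    pbs_vals = np.where(usable, pbs_vals, np.nan)

    if threshold is None and threshold_q is not None:
        defined = pbs_vals[np.isfinite(pbs_vals)]
        threshold = quantile_threshold(defined, threshold_q)
    outlier = np.isfinite(pbs_vals) & (
        pbs_vals > (threshold if threshold is not None else np.inf))

    site_ids = gm.site_ids or [("?", i + 1, "N", "N") for i in range(gm.n_sites)]
    df = pd.DataFrame({
        "chrom": [s[0] for s in site_ids],
        "pos": [s[1] for s in site_ids],
        "fst_ab": th_ab,
        "fst_ac": th_ac,
        "fst_bc": th_bc,
        "pbs": pbs_vals,
        "outlier": outlier,
    })
    df.attrs["threshold"] = threshold
    return df
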