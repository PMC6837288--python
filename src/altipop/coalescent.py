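"""Structured-coalescent simulation for multi-deme demographic models.

Simulates single-locus genealogies backwards in time under a model with an
arbitrary number of demes, instantaneous population splits (lineage merges,
looking backwards), and symmetric migration with two genome-wide rate
classes (a proportion ``p_high`` of loci migrates at the high rates, the
rest at the low rates).  Each locus is an independent genealogy with one
segregating site (ms ``-s 1`` semantics, no recombination).

Units
-----
* Time is in generations; deme sizes are *diploid* effective sizes.
* Migration is specified as diploid migrant individuals per generation
  between a pair of demes (``N*m``); the backward per-lineage hop rate out
  of deme ``i`` toward ``j`` is ``M[i][j] / N_i`` per generation.
* Within a deme of size ``N`` each lineage pair coalesces at rate
  ``1/(2N)`` per generation.

The per-SNP outputs feed the Weir-Cockerham FST / PBS machinery in
:mod:`altipop.popgen_core` to build neutral null distributions, and the
branch-length accumulator provides Monte-Carlo expected site-frequency
spectra for composite-likelihood demographic fitting.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from . import popgen_core

__all__ = [
    "DemographicModel",
    "Genealogy",
    "SnpSample",
    "NullDistribution",
    "simulate_genealogy",
    "sample_snp",
    "simulate_null_pbs",
    "expected_sfs_mc",
    "three_population_model",
]


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------

@dataclass
class DemographicModel:
    """Deme sizes, ordered splits, and two symmetric migration-rate classes.

    ``splits`` is a list of ``(time_generations, derived_deme, parent_deme)``
    tuples with strictly increasing times toward the past; looking backwards,
    all lineages of the derived deme move into the parent at the split time.
    After the last split a single ancestral deme of size ``ancestral_size``
    (default: the root deme's own size) remains.  ``mig_high``/``mig_low``
    are symmetric matrices of diploid migrants per generation; a proportion
    ``p_high`` of loci draws the high class.
    """

    deme_names: list[str]
    sizes: list[float]
    splits: list[tuple[float, int, int]] = field(default_factory=list)
    mig_high: np.ndarray | None = None
    mig_low: np.ndarray | None = None
    p_high: float = 1.0
    ancestral_size: float | None = None

    def __post_init__(self):
        d = len(self.deme_names)
        if len(self.sizes) != d:
            raise ValueError("sizes length != number of demes")
        if any(s <= 0 for s in self.sizes):
            raise ValueError("deme sizes must be positive")
        if not 0.0 <= self.p_high <= 1.0:
            raise ValueError("p_high must be in [0, 1]")
        times = [t for t, *_ in self.splits]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("split times must be strictly increasing")
        if len(self.splits) != d - 1:
            raise ValueError("need exactly n_demes - 1 splits to reach a "
                             "single ancestral deme")
        # verify the split sequence leaves one deme
        alive = set(range(d))
        for _, der, par in self.splits:
            if der not in alive or par not in alive or der == par:
                raise ValueError("invalid split (derived/parent not active)")
            alive.discard(der)
        if len(alive) != 1:
            raise ValueError("splits do not reduce to one ancestral deme")
        self._root = alive.pop()
        for attr in ("mig_high", "mig_low"):
            m = getattr(self, attr)
            if m is None:
                m = np.zeros((d, d))
            m = np.asarray(m, dtype=float)
            if m.shape != (d, d):
                raise ValueError(f"{attr} must be {d}x{d}")
            if (m < 0).any():
                raise ValueError("migration rates must be >= 0")
            if not np.allclose(m, m.T):
                raise ValueError("migration matrices must be symmetric")
            setattr(self, attr, m)

    @property
    def n_demes(self) -> int:
        return len(self.deme_names)

    def migration_matrix(self, rate_class: str) -> np.ndarray:
        if rate_class == "high":
            return self.mig_high
        if rate_class == "low":
            return self.mig_low
        raise ValueError("rate_class must be 'high' or 'low'")

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "deme_names": list(self.deme_names),
            "sizes": [float(s) for s in self.sizes],
            "splits": [[float(t), int(a), int(b)] for t, a, b in self.splits],
            "mig_high": self.mig_high.tolist(),
            "mig_low": self.mig_low.tolist(),
            "p_high": float(self.p_high),
            "ancestral_size": (None if self.ancestral_size is None
                               else float(self.ancestral_size)),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DemographicModel":
        return cls(
            deme_names=list(d["deme_names"]),
            sizes=list(d["sizes"]),
            splits=[tuple(s) for s in d.get("splits", [])],
            mig_high=d.get("mig_high"),
            mig_low=d.get("mig_low"),
            p_high=d.get("p_high", 1.0),
            ancestral_size=d.get("ancestral_size"),
        )

    @classmethod
    def from_config(cls, path) -> "DemographicModel":
        """Load a model from a YAML or JSON config file."""
        with open(path) as fh:
            text = fh.read()
        try:
            data = json.loads(text)
        except json.JSONDecodeError:
            import yaml

            data = yaml.safe_load(text)
        return cls.from_dict(data)


def three_population_model(
    sizes=(368_000, 220_000, 371_000),
    split_old=217_000.0,
    split_young=190_000.0,
    m_high=(1.75, 2.07),
    m_low=(0.08, 0.08),
    p_high=0.85,
    deme_names=("MtEvans", "Lincoln", "Merced"),
) -> DemographicModel:
    """Stitched three-population null model for the altitudinal scan.

    The focal highland deme (index 0) is flanked by two lowland demes that
    split from its lineage at ``split_old`` (deme 1) and ``split_young``
    (deme 2) generations ago.  Migration connects each lowland deme with the
    highland deme only (no direct lowland-lowland gene flow);
    ``m_high``/``m_low`` give (deme0-deme1, deme0-deme2) diploid migrants
    per generation for the two rate classes.
    """
    d = 3

    def mat(pair):
        m = np.zeros((d, d))
        m[0, 1] = m[1, 0] = pair[0]
        m[0, 2] = m[2, 0] = pair[1]
        return m

    return DemographicModel(
        deme_names=list(deme_names),
        sizes=list(sizes),
        splits=[(split_young, 2, 0), (split_old, 1, 0)],
        mig_high=mat(m_high),
        mig_low=mat(m_low),
        p_high=p_high,
    )


# ---------------------------------------------------------------------------
# genealogy containers
# ---------------------------------------------------------------------------

@dataclass
class Genealogy:
    """Branches of a single-locus genealogy.

    ``lengths[i]`` is the i-th branch length in generations and
    ``leaf_counts[i]`` the number of sampled haploid leaves it subtends in
    each deme; ``births[i]`` is the time (generations ago) at which the
    branch begins (toward the present).  ``coal_times`` are the n-1
    coalescence times; ``n_migrations`` counts lineage hops.
    """

    lengths: np.ndarray
    leaf_counts: np.ndarray
    births: np.ndarray
    coal_times: np.ndarray
    n_migrations: int
    sample_sizes: tuple[int, ...]

    @property
    def tmrca(self) -> float:
        return float(self.coal_times[-1])

    @property
    def total_length(self) -> float:
        return float(self.lengths.sum())


@dataclass
class SnpSample:
    """Derived-allele counts for one segregating site."""

    sample_sizes: tuple[int, ...]
    derived: tuple[int, ...]
    rate_class: str

    def __post_init__(self):
        tot = sum(self.derived)
        if not 0 < tot < sum(self.sample_sizes):
            raise ValueError("site must segregate in the total sample")
        if any(d < 0 or d > n for d, n in zip(self.derived, self.sample_sizes)):
            raise ValueError("derived count outside [0, sample size]")


@dataclass
class NullDistribution:
    pbs: np.ndarray
    model: DemographicModel
    n_snps: int
    seed: int | None
    estimator: str = "wc"

    def quantile(self, q: float) -> float:
        return popgen_core.quantile_threshold(self.pbs, q)


# ---------------------------------------------------------------------------
# core simulation
# ---------------------------------------------------------------------------

def simulate_genealogy(model: DemographicModel, samples, rate_class="high",
                       rng=None) -> Genealogy:
    """Draw one genealogy from the structured coalescent.

    ``samples`` gives the number of sampled haploid lineages per deme.
    Raises if the configuration cannot coalesce (no lineages).
    """
    rng = np.random.default_rng(rng)
    samples = tuple(int(s) for s in samples)
    if len(samples) != model.n_demes:
        raise ValueError("samples length != number of demes")
    n_total = sum(samples)
    if n_total < 2 or sum(1 for s in samples if s >= 1) < 1:
        raise ValueError("need at least two sampled lineages")

    D = model.n_demes
    mig = model.migration_matrix(rate_class)
    sizes = [float(s) for s in model.sizes]
    splits = list(model.splits) + [(math.inf, -1, -1)]

    # lineage store: birth time and per-deme subtended leaf counts; closed
    # branches accumulate (birth, death, counts) records
    births: list[float] = []
    counts: list[tuple] = []
    closed: list[tuple[float, float, tuple]] = []
    active: list[list[int]] = [[] for _ in range(D)]
    for d in range(D):
        for _ in range(samples[d]):
            lid = len(births)
            births.append(0.0)
            v = [0] * D
            v[d] = 1
            counts.append(tuple(v))
            active[d].append(lid)

    alive = set(range(D))
    # per-lineage migration rate out of each deme, for the current epoch
    def mig_rows():
        rows = [0.0] * D
        for i in range(D):
            if i not in alive:
                continue
            tot = 0.0
            for j in range(D):
                if j in alive and j != i:
                    tot += mig[i, j] / sizes[i]
            rows[i] = tot
        return rows

    mrow = mig_rows()
    coal_times: list[float] = []
    n_mig = 0
    t = 0.0
    split_idx = 0
    next_split = splits[0][0]
    k_live = n_total
    rand = rng.random

    while k_live > 1:
        # event rates
        total = 0.0
        crates = []
        mrates = []
        for d_i in range(D):
            k = len(active[d_i])
            cr = k * (k - 1) / (4.0 * sizes[d_i]) if k > 1 else 0.0
            mr = k * mrow[d_i]
            crates.append(cr)
            mrates.append(mr)
            total += cr + mr
        if total <= 0.0:
            if next_split is math.inf:
                raise RuntimeError("non-coalescing configuration: isolated "
                                   "lineages with no ancestral merge")
            t = next_split
        else:
            t = t - math.log(rand()) / total
        if t >= next_split:
            # apply split: derived lineages move to parent
            t = next_split
            _, der, par = splits[split_idx]
            active[par].extend(active[der])
            active[der] = []
            alive.discard(der)
            split_idx += 1
            next_split = splits[split_idx][0]
            if next_split is math.inf and model.ancestral_size is not None:
                sizes[par] = float(model.ancestral_size)
            mrow = mig_rows()
            continue
        # choose event
        u = rand() * total
        for d_i in range(D):
            if u < crates[d_i]:
                # coalescence in deme d_i: pick two distinct lineages
                lst = active[d_i]
                k = len(lst)
                i1 = int(rand() * k)
                i2 = int(rand() * (k - 1))
                if i2 >= i1:
                    i2 += 1
                l1, l2 = lst[i1], lst[i2]
                # swap-remove both (higher index first)
                if i1 < i2:
                    i1, i2 = i2, i1
                lst[i1] = lst[-1]; lst.pop()
                lst[i2] = lst[-1]; lst.pop()
                closed.append((births[l1], t, counts[l1]))
                closed.append((births[l2], t, counts[l2]))
                new_id = len(births)
                births.append(t)
                counts.append(tuple(a + b for a, b in
                                    zip(counts[l1], counts[l2])))
                lst.append(new_id)
                coal_times.append(t)
                k_live -= 1
                break
            u -= crates[d_i]
            if u < mrates[d_i]:
                # migration: pick lineage, pick destination
                lst = active[d_i]
                k = len(lst)
                idx = int(rand() * k)
                lid = lst[idx]
                v = rand() * mrow[d_i]
                dest = -1
                for j in range(D):
                    if j in alive and j != d_i:
                        r = mig[d_i, j] / sizes[d_i]
                        if v < r:
                            dest = j
                            break
                        v -= r
                if dest < 0:
                    dest = next(j for j in alive if j != d_i)
                lst[idx] = lst[-1]; lst.pop()
                active[dest].append(lid)
                n_mig += 1
                break
            u -= mrates[d_i]
        else:  # pragma: no cover - floating point guard
            continue

    lengths = np.array([b - a for a, b, _ in closed], dtype=float)
    births_arr = np.array([a for a, _, _ in closed], dtype=float)
    lc = np.array([c for _, _, c in closed], dtype=np.int64)
    return Genealogy(
        lengths=lengths,
        leaf_counts=lc,
        births=births_arr,
        coal_times=np.array(coal_times),
        n_migrations=n_mig,
        sample_sizes=samples,
    )


def sample_snp(genealogy: Genealogy, rng=None) -> SnpSample:
    """Place one mutation on a branch chosen proportionally to its length."""
    rng = np.random.default_rng(rng)
    total = genealogy.total_length
    if total <= 0:
        raise ValueError("genealogy has zero total branch length")
    u = rng.random() * total
    cum = np.cumsum(genealogy.lengths)
    idx = int(np.searchsorted(cum, u, side="right"))
    idx = min(idx, len(cum) - 1)
    derived = tuple(int(x) for x in genealogy.leaf_counts[idx])
    return SnpSample(sample_sizes=genealogy.sample_sizes, derived=derived,
                     rate_class="high")


def _diploid_counts(n_hap: int, n_derived: int, scratch: np.ndarray,
                    rng) -> tuple[int, int]:
    """Random pairing of haplotypes into diploids -> (alt_count, het_count)."""
    arr = scratch[:n_hap]
    arr[:] = 0
    arr[:n_derived] = 1
    rng.shuffle(arr)
    het = int(np.count_nonzero(arr[0::2] != arr[1::2]))
    return n_derived, het


def simulate_null_pbs(model: DemographicModel, n_snps: int,
                      sample_diploids, rng=None,
                      fst_estimator: str = "wc") -> NullDistribution:
    """Neutral PBS null distribution for the focal deme (index 0).

    For each SNP a migration-rate class is drawn Bernoulli(``p_high``), one
    genealogy is simulated with ``2 * sample_diploids`` haploid lineages per
    deme, one mutation is placed, haplotypes are randomly paired into
    diploids, and pairwise FST (Weir-Cockerham by default, Hudson optional)
    feeds the PBS.  Bit-reproducible for a fixed integer seed.
    """
    if model.n_demes != 3:
        raise ValueError("PBS null requires exactly 3 demes")
    if n_snps < 1:
        raise ValueError("n_snps must be >= 1")
    seed = rng if isinstance(rng, (int, np.integer)) else None
    rng = np.random.default_rng(rng)
    dip = tuple(int(x) for x in sample_diploids)
    hap = tuple(2 * x for x in dip)
    scratch = np.zeros(max(hap), dtype=np.int8)

    alt = np.empty((3, n_snps), dtype=np.int64)
    het = np.empty((3, n_snps), dtype=np.int64)
    for s in range(n_snps):
        rc = "high" if rng.random() < model.p_high else "low"
        g = simulate_genealogy(model, hap, rate_class=rc, rng=rng)
        snp = sample_snp(g, rng=rng)
        for d in range(3):
            a, h = _diploid_counts(hap[d], snp.derived[d], scratch, rng)
            alt[d, s] = a
            het[d, s] = h

    n = [np.full(n_snps, dip[d]) for d in range(3)]
    if fst_estimator == "wc":
        def pair(i, j):
            a, b, c = popgen_core.weir_fst_components(
                n[i], alt[i], het[i], n[j], alt[j], het[j])
            return popgen_core.theta_from_components(a, b, c)
    elif fst_estimator == "hudson":
        def pair(i, j):
            return _hudson_fst(hap[i], alt[i], hap[j], alt[j])
    else:
        raise ValueError("fst_estimator must be 'wc' or 'hudson'")

    th01 = pair(0, 1)
    th02 = pair(0, 2)
    th12 = pair(1, 2)
    pbs = popgen_core.pbs_from_theta(th01, th02, th12)
    pbs = np.where(np.isfinite(pbs), pbs, 0.0)
    return NullDistribution(pbs=pbs, model=model, n_snps=n_snps, seed=seed,
                            estimator=fst_estimator)


def _hudson_fst(n1_hap, alt1, n2_hap, alt2):
    """Hudson's FST estimator (Bhatia et al. 2013) from haploid counts."""
    p1 = alt1 / n1_hap
    p2 = alt2 / n2_hap
    num = ((p1 - p2) ** 2
           - p1 * (1 - p1) / (n1_hap - 1)
           - p2 * (1 - p2) / (n2_hap - 1))
    den = p1 * (1 - p2) + p2 * (1 - p1)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = num / den
    return np.where(den == 0, np.nan, f)


# ---------------------------------------------------------------------------
# Monte-Carlo expected SFS
# ---------------------------------------------------------------------------

def fold_sfs(sfs: np.ndarray) -> np.ndarray:
    """Fold a 1-D or 2-D spectrum onto minor-allele counts.

    Cell ``x`` and its complement ``n - x`` are summed into whichever lies
    on the minor side; cells exactly on the fold line keep their own mass.
    Fixed corner cells (all-0 / all-n) are zeroed.
    """
    s = np.asarray(sfs, dtype=float)
    ns = tuple(d - 1 for d in s.shape)  # haploid sample sizes
    total = sum(ns)
    out = np.zeros_like(s)
    for idx in np.ndindex(s.shape):
        da = sum(idx)
        comp = tuple(n - i for n, i in zip(ns, idx))
        if da * 2 < total:
            out[idx] = s[idx] + s[comp]
        elif da * 2 == total:
            if idx == comp:
                out[idx] = s[idx]
            elif idx < comp:  # lexicographic tie-break on the fold line
                out[idx] = s[idx] + s[comp]
    # mask fixed classes
    out[tuple(0 for _ in ns)] = 0.0
    out[tuple(ns)] = 0.0
    return out


try:
    from numba import njit as _njit
except ImportError:  # pragma: no cover - numba is a hard dependency
    _njit = None


def _make_branch_kernel():
    """Compiled inner loop accumulating per-genealogy folded cell masses.

    Simulates ``n_sims`` genealogies of the structured coalescent and adds,
    for each, the branch mass landing in every frequency cell (and its
    square) into ``acc``/``acc2``.  All model structure arrives as flat
    arrays; the fold is applied through a precomputed flat index map.
    """

    def kernel(n_sims, seed, D, sizes0, anc_size, split_times, split_der,
               split_par, mig, samples, strides, fmap, acc, acc2):
        np.random.seed(seed)
        n_tot = 0
        for d in range(D):
            n_tot += samples[d]
        max_nodes = 2 * n_tot
        n_cells = acc.shape[0]
        counts = np.zeros((max_nodes, D), dtype=np.int64)
        birth = np.zeros(max_nodes)
        act = np.zeros((D, n_tot), dtype=np.int64)
        k = np.zeros(D, dtype=np.int64)
        alive = np.zeros(D, dtype=np.int64)
        sizes = np.zeros(D)
        mrow = np.zeros(D)
        xloc = np.zeros(n_cells)
        n_splits = split_times.shape[0]

        for _ in range(n_sims):
            # reset state
            for c in range(n_cells):
                xloc[c] = 0.0
            nid = 0
            for d in range(D):
                sizes[d] = sizes0[d]
                alive[d] = 1
                k[d] = 0
            for d in range(D):
                for _i in range(samples[d]):
                    for dd in range(D):
                        counts[nid, dd] = 0
                    counts[nid, d] = 1
                    birth[nid] = 0.0
                    act[d, k[d]] = nid
                    k[d] += 1
                    nid += 1
            # per-lineage migration rate rows
            for d in range(D):
                tot = 0.0
                if alive[d] == 1:
                    for j in range(D):
                        if j != d and alive[j] == 1:
                            tot += mig[d, j] / sizes[d]
                mrow[d] = tot
            t = 0.0
            split_idx = 0
            k_live = n_tot
            while k_live > 1:
                total = 0.0
                for d in range(D):
                    kd = k[d]
                    if kd > 1:
                        total += kd * (kd - 1) / (4.0 * sizes[d])
                    total += kd * mrow[d]
                if split_idx < n_splits:
                    next_split = split_times[split_idx]
                else:
                    next_split = 1e300
                if total <= 0.0:
                    t_new = next_split
                else:
                    t_new = t - np.log(np.random.random()) / total
                if t_new >= next_split:
                    t = next_split
                    der = split_der[split_idx]
                    par = split_par[split_idx]
                    for i in range(k[der]):
                        act[par, k[par]] = act[der, i]
                        k[par] += 1
                    k[der] = 0
                    alive[der] = 0
                    split_idx += 1
                    if split_idx == n_splits:
                        sizes[par] = anc_size
                    for d in range(D):
                        tot = 0.0
                        if alive[d] == 1:
                            for j in range(D):
                                if j != d and alive[j] == 1:
                                    tot += mig[d, j] / sizes[d]
                        mrow[d] = tot
                    continue
                t = t_new
                u = np.random.random() * total
                done = False
                for d in range(D):
                    kd = k[d]
                    cr = kd * (kd - 1) / (4.0 * sizes[d]) if kd > 1 else 0.0
                    if u < cr:
                        i1 = int(np.random.random() * kd)
                        i2 = int(np.random.random() * (kd - 1))
                        if i2 >= i1:
                            i2 += 1
                        l1 = act[d, i1]
                        l2 = act[d, i2]
                        if i1 < i2:
                            tmp = i1
                            i1 = i2
                            i2 = tmp
                        act[d, i1] = act[d, kd - 1]
                        kd -= 1
                        act[d, i2] = act[d, kd - 1]
                        kd -= 1
                        # close both branches into cells
                        for l in (l1, l2):
                            flat = 0
                            for dd in range(D):
                                flat += counts[l, dd] * strides[dd]
                            xloc[fmap[flat]] += t - birth[l]
                        for dd in range(D):
                            counts[nid, dd] = counts[l1, dd] + counts[l2, dd]
                        birth[nid] = t
                        act[d, kd] = nid
                        kd += 1
                        nid += 1
                        k[d] = kd
                        k_live -= 1
                        done = True
                        break
                    u -= cr
                    mr = kd * mrow[d]
                    if u < mr:
                        idx = int(np.random.random() * kd)
                        lid = act[d, idx]
                        v = np.random.random() * mrow[d]
                        dest = -1
                        for j in range(D):
                            if j != d and alive[j] == 1:
                                rj = mig[d, j] / sizes[d]
                                if v < rj:
                                    dest = j
                                    break
                                v -= rj
                        if dest < 0:
                            for j in range(D):
                                if j != d and alive[j] == 1:
                                    dest = j
                                    break
                        act[d, idx] = act[d, kd - 1]
                        k[d] = kd - 1
                        act[dest, k[dest]] = lid
                        k[dest] += 1
                        done = True
                        break
                    u -= mr
                if not done:
                    continue
            for c in range(n_cells):
                xc = xloc[c]
                acc[c] += xc
                acc2[c] += xc * xc

    return _njit(cache=True)(kernel) if _njit is not None else kernel


_branch_kernel = _make_branch_kernel()


def _fold_map(shape: tuple[int, ...]) -> np.ndarray:
    """Flat index map sending each unfolded cell to its folded destination."""
    ns = tuple(d - 1 for d in shape)
    total = sum(ns)
    out = np.empty(int(np.prod(shape)), dtype=np.int64)
    for flat, idx in enumerate(np.ndindex(shape)):
        comp = tuple(n - i for n, i in zip(ns, idx))
        da = sum(idx)
        if da * 2 > total or (da * 2 == total and idx > comp):
            dest = comp
        else:
            dest = idx
        out[flat] = np.ravel_multi_index(dest, shape)
    return out


def expected_sfs_mc(model: DemographicModel, samples, n_sims: int,
                    fold: bool = False, rng=None,
                    rate_class: str = "high",
                    return_variance: bool = False):
    """Monte-Carlo expected site-frequency spectrum, frequency-normalized.

    Accumulates, over ``n_sims`` independent genealogies, each branch's
    length into the frequency cell indexed by its subtended leaf counts (the
    Rao-Blackwellized estimator of the expected SFS under an infinite-sites
    mutation process).  Returns a 1-D or 2-D array over derived (or folded,
    minor) allele counts with fixed classes masked to zero, normalized to
    sum to 1.

    With ``return_variance=True`` also returns the per-cell squared
    relative Monte-Carlo standard error of the mean, which downstream
    composite-likelihood code uses for first-order bias correction.
    """
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    rng = np.random.default_rng(rng)
    samples = tuple(int(s) for s in samples)
    if sum(samples) < 2:
        raise ValueError("need at least two sampled lineages")
    shape = tuple(s + 1 for s in samples)
    n_cells = int(np.prod(shape))
    fmap = (_fold_map(shape) if fold
            else np.arange(n_cells, dtype=np.int64))
    acc = np.zeros(n_cells, dtype=float)
    acc2 = np.zeros(n_cells, dtype=float)

    D = model.n_demes
    mig = np.asarray(model.migration_matrix(rate_class), dtype=float)
    split_times = np.array([s[0] for s in model.splits], dtype=float)
    split_der = np.array([s[1] for s in model.splits], dtype=np.int64)
    split_par = np.array([s[2] for s in model.splits], dtype=np.int64)
    anc = float(model.ancestral_size
                if model.ancestral_size is not None
                else model.sizes[model._root])
    strides = np.array(
        [int(np.prod(shape[d + 1:])) for d in range(D)], dtype=np.int64)
    seed = int(rng.integers(0, 2**31 - 1))
    _branch_kernel(n_sims, seed, D, np.asarray(model.sizes, dtype=float),
                   anc, split_times, split_der, split_par, mig,
                   np.asarray(samples, dtype=np.int64), strides, fmap,
                   acc, acc2)
    mean = (acc / n_sims).reshape(shape)
    # mask fixed corners (no branch maps there by construction, but be safe)
    mean[tuple(0 for _ in samples)] = 0.0
    mean[tuple(samples)] = 0.0
    tot = mean.sum()
    norm = mean / tot if tot > 0 else mean
    if not return_variance:
        return norm
    var_mean = (acc2 / n_sims - (acc / n_sims) ** 2) / max(n_sims - 1, 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        relvar = var_mean.reshape(shape) / mean**2
    relvar = np.where(mean > 0, relvar, 0.0)
    relvar[tuple(0 for _ in samples)] = 0.0
    relvar[tuple(samples)] = 0.0
    return norm, relvar
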