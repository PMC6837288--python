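"""Gene-set expression-shift testing against a permutation null.

Pipeline: library-size filtering of low-expression genes, TMM (trimmed mean
of M-values) between-sample normalization, genotype-contrast log2
fold-changes from normalized group means, a signed two-sample
Kolmogorov-Smirnov statistic comparing a candidate gene set's fold-change
distribution with the transcriptome background, and a null distribution of
D statistics from random gene sets of equal size with a 99%-quantile
decision rule.

The per-gene quasi-likelihood GLM machinery of count-based differential
expression packages is deliberately not reproduced: fold-changes here are
normalized group-mean ratios with a prior count, which preserves the
distribution-shift test while keeping the package self-contained.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .popgen_core import quantile_threshold

__all__ = [
    "ExpressionCounts",
    "GeneSetShiftResult",
    "filter_low_expression",
    "tmm_factors",
    "normalized_counts",
    "log_fold_change",
    "ks_shift",
    "permutation_null",
    "geneset_shift_test",
    "directional_contrast",
    "bh_fdr",
]

GENOTYPES = ("LL", "HL", "HH")


@dataclass
class ExpressionCounts:
    """Integer count matrix [genes x samples] with genotype labels."""

    counts: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]
    genotypes: list[str]

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        g, s = self.counts.shape
        if len(self.gene_ids) != g:
            raise ValueError("gene_ids length != rows")
        if len(self.sample_ids) != s or len(self.genotypes) != s:
            raise ValueError("sample_ids/genotypes length != columns")
        if (self.counts < 0).any():
            raise ValueError("counts must be nonnegative")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def library_sizes(self) -> np.ndarray:
        return self.counts.sum(axis=0).astype(float)

    def group_index(self, genotype: str) -> np.ndarray:
        idx = np.array([i for i, g in enumerate(self.genotypes)
                        if g == genotype])
        if idx.size == 0:
            raise KeyError(f"no samples with genotype {genotype!r}")
        return idx

    def subset_genes(self, keep: np.ndarray) -> "ExpressionCounts":
        return ExpressionCounts(
            counts=self.counts[keep, :],
            gene_ids=[g for g, k in zip(self.gene_ids, keep) if k]
            if keep.dtype == bool else [self.gene_ids[i] for i in keep],
            sample_ids=self.sample_ids,
            genotypes=self.genotypes,
        )


@dataclass
class GeneSetShiftResult:
    set_name: str
    set_size: int
    contrast: tuple[str, str]
    d_statistic: float
    shift_sign: int
    ks_pvalue: float
    null_d: np.ndarray = field(repr=False)
    null_q99: float = 0.0
    permutation_p: float = 1.0
    exceeds_q99: bool = False
    dropped_ids: list[str] = field(default_factory=list)
    seed: int | None = None


# ---------------------------------------------------------------------------
# filtering and normalization
# ---------------------------------------------------------------------------

def filter_low_expression(ec: ExpressionCounts,
                          min_mean_norm: float = 10.0) -> ExpressionCounts:
    """Drop genes below a mean library-size-normalized count threshold.

    A gene is retained when the mean over samples of
    ``count / library_size * mean(library_size)`` is at least
    ``min_mean_norm`` (default 10 normalized reads per individual).
    """
    lib = ec.library_sizes
    if (lib == 0).any():
        raise ValueError("empty library")
    norm = ec.counts / lib * lib.mean()
    keep = norm.mean(axis=1) >= min_mean_norm
    if not keep.any():
        raise ValueError("no genes pass the expression filter")
    return ec.subset_genes(keep)


def tmm_factors(ec: ExpressionCounts, logratio_trim: float = 0.30,
                abundance_trim: float = 0.05) -> np.ndarray:
    """Trimmed-mean-of-M-values scaling factors (Robinson & Oshlack 2010).

    The reference sample is the one whose upper-quartile (of nonzero
    library-size-normalized counts) is closest to the mean upper quartile.
    M and A values are computed on library-size-normalized counts over
    genes expressed in both sample and reference; the upper and lower
    ``logratio_trim`` (by M) and ``abundance_trim`` (by A) fractions are
    removed and the remaining M values averaged with precision weights.
    Factors are normalized to geometric mean 1.
    """
    counts = ec.counts.astype(float)
    if counts.shape[1] < 2:
        raise ValueError("TMM requires >= 2 samples")
    lib = ec.library_sizes
    frac = counts / lib
    uq = np.array([np.quantile(f[f > 0], 0.75) if (f > 0).any() else 0.0
                   for f in frac.T])
    ref = int(np.argmin(np.abs(uq - uq.mean())))

    factors = np.ones(counts.shape[1])
    fr = frac[:, ref]
    for s in range(counts.shape[1]):
        if s == ref:
            continue
        fs = frac[:, s]
        both = (fs > 0) & (fr > 0)
        if not both.any():
            import warnings

            warnings.warn(f"sample {ec.sample_ids[s]} shares no expressed "
                          "genes with the reference; factor set to 1")
            continue
        m = np.log2(fs[both] / fr[both])
        a = 0.5 * np.log2(fs[both] * fr[both])
        # delta-method precision weights (asymptotic binomial variance of M)
        var = ((lib[s] - counts[both, s]) / (lib[s] * counts[both, s])
               + (lib[ref] - counts[both, ref]) / (lib[ref] * counts[both, ref]))
        w = 1.0 / np.maximum(var, 1e-12)
        # value-based trimming (invariant to gene ordering under ties)
        m_lo, m_hi = np.quantile(m, [logratio_trim, 1 - logratio_trim])
        a_lo, a_hi = np.quantile(a, [abundance_trim, 1 - abundance_trim])
        keep = (m >= m_lo) & (m <= m_hi) & (a >= a_lo) & (a <= a_hi)
        if keep.any():
            factors[s] = 2.0 ** (np.sum(w[keep] * m[keep]) / np.sum(w[keep]))
    factors /= np.exp(np.mean(np.log(factors)))
    return factors


def normalized_counts(ec: ExpressionCounts,
                      factors: np.ndarray | None = None) -> np.ndarray:
    """Counts rescaled by effective library size (library x TMM factor)."""
    if factors is None:
        factors = tmm_factors(ec)
    eff = ec.library_sizes * factors
    return ec.counts / eff * eff.mean()


def log_fold_change(ec: ExpressionCounts, contrast: tuple[str, str],
                    prior_count: float = 0.5,
                    factors: np.ndarray | None = None) -> np.ndarray:
    """Per-gene log2 fold-change of normalized group means, group_a over group_b."""
    ga, gb = contrast
    ia, ib = ec.group_index(ga), ec.group_index(gb)
    norm = normalized_counts(ec, factors)
    ma = norm[:, ia].mean(axis=1)
    mb = norm[:, ib].mean(axis=1)
    return np.log2((ma + prior_count) / (mb + prior_count))


# ---------------------------------------------------------------------------
# K-S machinery
# ---------------------------------------------------------------------------

def ks_shift(candidate_lfc, background_lfc) -> tuple[float, int, float]:
    """Signed two-sample K-S comparison of fold-change distributions.

    Returns ``(D, sign, p)`` where D is the supremum ECDF distance, sign is
    the sign of the candidate-minus-background median difference, and p the
    asymptotic two-sample K-S p-value.  The background must exclude the
    candidate genes (checked by the caller on ids; here only emptiness is
    validated).
    """
    c = np.asarray(candidate_lfc, dtype=float)
    b = np.asarray(background_lfc, dtype=float)
    if c.size == 0 or b.size == 0:
        raise ValueError("empty sample")
    res = stats.ks_2samp(c, b, method="asymp")
    sign = int(np.sign(np.median(c) - np.median(b)))
    return float(res.statistic), sign, float(res.pvalue)


def _ks_d_only(is_cand_sorted, n_c, n_b) -> float:
    # D over the pooled pre-sorted sample: max |F_c - F_b|
    cum_c = np.cumsum(is_cand_sorted) / n_c
    cum_b = np.cumsum(~is_cand_sorted) / n_b
    return float(np.abs(cum_c - cum_b).max())


def permutation_null(lfc: np.ndarray, set_size: int, n_perm: int = 1000,
                     rng=None) -> tuple[np.ndarray, float]:
    """Null D distribution from random gene sets of a given size.

    Each draw partitions the genes into a random set of ``set_size`` and
    the complementary background and records the K-S D.  Returns the D
    vector and its 99% quantile (left-continuous ecdf convention).
    """
    lfc = np.asarray(lfc, dtype=float)
    n = lfc.size
    if not 0 < set_size < n:
        raise ValueError("set_size must be in (0, n_genes)")
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    rng = np.random.default_rng(rng)
    order = np.argsort(lfc, kind="stable")
    ranks = np.empty(n, dtype=np.int64)
    ranks[order] = np.arange(n)
    n_b = n - set_size
    ds = np.empty(n_perm)
    flags = np.zeros(n, dtype=bool)
    for i in range(n_perm):
        pick = rng.choice(n, size=set_size, replace=False)
        flags[:] = False
        flags[ranks[pick]] = True
        ds[i] = _ks_d_only(flags, set_size, n_b)
    q99 = quantile_threshold(ds, 0.99)
    return ds, q99


def geneset_shift_test(ec: ExpressionCounts, candidate_ids,
                       contrast: tuple[str, str] = ("HH", "LL"),
                       n_perm: int = 1000, min_mean_norm: float = 10.0,
                       prior_count: float = 0.5, rng=None,
                       set_name: str = "candidate") -> GeneSetShiftResult:
    """Full candidate-set shift test: filter, TMM, LFC, K-S, permutation null.

    The decision flag is ``D > q99`` of the equal-size random-set null.
    Candidate genes absent after filtering are reported in ``dropped_ids``.
    """
    seed = rng if isinstance(rng, (int, np.integer)) else None
    rng = np.random.default_rng(rng)
    kept = filter_low_expression(ec, min_mean_norm)
    id_index = {g: i for i, g in enumerate(kept.gene_ids)}
    cand = sorted(set(candidate_ids))
    present = [g for g in cand if g in id_index]
    dropped = [g for g in cand if g not in id_index]
    if len(present) < 2:
        raise ValueError("fewer than 2 candidate genes retained after "
                         "filtering")
    lfc = log_fold_change(kept, contrast, prior_count)
    cidx = np.array([id_index[g] for g in present])
    cmask = np.zeros(kept.n_genes, dtype=bool)
    cmask[cidx] = True
    d, sign, p = ks_shift(lfc[cmask], lfc[~cmask])
    # draw null sets over the id-sorted universe so results do not depend
    # on the storage order of genes
    id_order = np.argsort(np.asarray(kept.gene_ids))
    null_d, q99 = permutation_null(lfc[id_order], cmask.sum(), n_perm, rng)
    perm_p = float((np.count_nonzero(null_d >= d) + 1) / (n_perm + 1))
    return GeneSetShiftResult(
        set_name=set_name, set_size=int(cmask.sum()), contrast=contrast,
        d_statistic=d, shift_sign=sign, ks_pvalue=p, null_d=null_d,
        null_q99=q99, permutation_p=perm_p, exceeds_q99=bool(d > q99),
        dropped_ids=dropped, seed=seed)


def directional_contrast(lfc_by_gene: dict, positive_ids, negative_ids,
                         n_perm: int = 10_000, rng=None):
    """Mean fold-change contrast between positive and negative regulators.

    Returns ``((mean_pos, se_pos), (mean_neg, se_neg), p)`` with p a
    two-sided permutation p-value from label shuffles between the two sets.
    """
    pos = sorted(set(positive_ids))
    neg = sorted(set(negative_ids))
    if set(pos) & set(neg):
        raise ValueError("positive and negative sets overlap")
    if len(pos) < 2 or len(neg) < 2:
        raise ValueError("each set needs >= 2 genes")
    a = np.array([lfc_by_gene[g] for g in pos], dtype=float)
    b = np.array([lfc_by_gene[g] for g in neg], dtype=float)

    def mse(v):
        return float(v.mean()), float(v.std(ddof=1) / np.sqrt(v.size))

    obs = abs(a.mean() - b.mean())
    rng = np.random.default_rng(rng)
    pool = np.concatenate([a, b])
    n_a = a.size
    hits = 0
    for _ in range(n_perm):
        rng.shuffle(pool)
        if abs(pool[:n_a].mean() - pool[n_a:].mean()) >= obs - 1e-15:
            hits += 1
    p = (hits + 1) / (n_perm + 1)
    return mse(a), mse(b), float(p)


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    return stats.false_discovery_control(np.asarray(pvalues, dtype=float),
                                         method="bh")


def per_gene_de(ec: ExpressionCounts, contrast: tuple[str, str],
                factors: np.ndarray | None = None):
    """Naive per-gene differential-expression screen (utility only).

    For each gene, an exact two-sided Poisson means test compares the
    group totals of effective-library-normalized counts between the two
    contrast groups.  This ignores biological overdispersion and is NOT
    equivalent to a quasi-likelihood negative-binomial GLM — it is provided
    as a quick screen; treat its p-values as anti-conservative.  Returns a
    pandas DataFrame with lfc, p, and BH-adjusted q per gene.
    """
    import pandas as pd

    ga, gb = contrast
    ia, ib = ec.group_index(ga), ec.group_index(gb)
    norm = normalized_counts(ec, factors)
    ta = norm[:, ia].sum(axis=1)
    tb = norm[:, ib].sum(axis=1)
    pvals = np.array([
        stats.poisson_means_test(int(round(a)), ia.size,
                                 int(round(b)), ib.size).pvalue
        for a, b in zip(ta, tb)])
    lfc = log_fold_change(ec, contrast, factors=factors)
    return pd.DataFrame({"gene": ec.gene_ids, "lfc": lfc, "p": pvals,
                         "q": bh_fdr(pvals)})
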