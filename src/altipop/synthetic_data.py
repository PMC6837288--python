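"""Synthetic-data generators mirroring the statistical structure of the study.

Three generators produce the inputs the analysis modules consume, so the
whole pipeline can be exercised and calibrated without raw sequencing data:

* :func:`gen_scan_dataset` — diploid genotypes at neutral SNPs drawn from a
  structured-coalescent model, plus "selected" SNPs created by displacing
  the focal-deme allele frequency of a neutral draw and re-sampling
  genotypes binomially (frequency displacement is what the branch statistic
  responds to, so no selection coefficient is needed).
* :func:`gen_cline_dataset` — binomially sampled allele counts along an
  elevational sigmoid cline.
* :func:`gen_expression_counts` — negative-binomial RNA-seq-like counts
  with log-normal gene means, in which a designated candidate gene set
  carries a concerted log2 fold-change between genotype groups.  Default
  group sizes (3 LL, 8 HL, 8 HH) mirror the adrenal-tissue design of the
  study population.

All generators are bit-reproducible given an integer seed and record their
configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import coalescent
from .cline import ClineDataset, ClineParams, cline_frequency
from .geneset_shift import ExpressionCounts
from .popgen_core import GenotypeMatrix

__all__ = [
    "SyntheticScanConfig",
    "SyntheticExpressionConfig",
    "gen_scan_dataset",
    "gen_cline_dataset",
    "gen_expression_counts",
]


@dataclass
class SyntheticScanConfig:
    model: coalescent.DemographicModel
    sample_diploids: tuple[int, ...]
    n_neutral_snps: int = 1000
    n_selected_snps: int = 0
    displacement: float = 0.5
    seed: int | None = None

    def __post_init__(self):
        if self.n_neutral_snps < 0 or self.n_selected_snps < 0:
            raise ValueError("SNP counts must be >= 0")
        if not 0.0 <= self.displacement <= 1.0:
            raise ValueError("displacement must be in [0, 1]")


@dataclass
class SyntheticExpressionConfig:
    n_genes: int = 5000
    group_sizes: dict = field(default_factory=lambda: {"LL": 3, "HL": 8, "HH": 8})
    log_mean: float = 4.0          # log-normal location of gene means (ln scale)
    log_sd: float = 1.5
    dispersion: float = 0.1        # NB dispersion (1/size)
    candidate_size: int = 79
    shift: float = 0.0             # injected log2 FC per copy of the H allele
    seed: int | None = None

    def __post_init__(self):
        if self.n_genes < 1 or any(v < 1 for v in self.group_sizes.values()):
            raise ValueError("sizes must be >= 1")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        if not 0 < self.candidate_size < self.n_genes:
            raise ValueError("candidate_size must be in (0, n_genes)")


def _genotypes_from_freq(p: np.ndarray, n_dip: int, rng) -> np.ndarray:
    """Diploid dosages [n_dip x n_sites] from per-site allele frequencies."""
    return rng.binomial(2, p[None, :], size=(n_dip, p.size)).astype(np.int8)


def gen_scan_dataset(config: SyntheticScanConfig):
    """Genotype matrix of neutral + frequency-displaced SNPs with truth labels.

    Neutral SNPs: one segregating site per independent genealogy, haplotypes
    paired into diploids.  Selected SNPs: the per-deme sample frequencies of
    a fresh neutral draw are taken as population frequencies, the focal deme
    (index 0) frequency is displaced toward fixation of the rarer-side
    allele by ``displacement`` (clipped to [0, 1]), and genotypes are
    re-sampled binomially.  Returns ``(GenotypeMatrix, labels)`` where
    labels is a string array with 'neutral' / 'selected' per site.
    """
    rng = np.random.default_rng(config.seed)
    model = config.model
    dip = tuple(config.sample_diploids)
    hap = tuple(2 * d for d in dip)
    n_demes = model.n_demes

    pop_labels = []
    for d, nd in enumerate(dip):
        pop_labels += [model.deme_names[d]] * nd
    n_samples = sum(dip)

    cols = []
    labels = []

    def neutral_freqs():
        rc = "high" if rng.random() < model.p_high else "low"
        g = coalescent.simulate_genealogy(model, hap, rate_class=rc, rng=rng)
        snp = coalescent.sample_snp(g, rng=rng)
        return np.array(snp.derived) / np.array(hap)

    for _ in range(config.n_neutral_snps):
        rc = "high" if rng.random() < model.p_high else "low"
        g = coalescent.simulate_genealogy(model, hap, rate_class=rc, rng=rng)
        snp = coalescent.sample_snp(g, rng=rng)
        col = np.empty(n_samples, dtype=np.int8)
        ofs = 0
        for d in range(n_demes):
            arr = np.zeros(hap[d], dtype=np.int8)
            arr[:snp.derived[d]] = 1
            rng.shuffle(arr)
            col[ofs:ofs + dip[d]] = arr[0::2] + arr[1::2]
            ofs += dip[d]
        cols.append(col)
        labels.append("neutral")

    for _ in range(config.n_selected_snps):
        p = neutral_freqs()
        direction = 1.0 if p[0] <= 0.5 else -1.0
        p[0] = float(np.clip(p[0] + direction * config.displacement, 0.0, 1.0))
        col = np.empty(n_samples, dtype=np.int8)
        ofs = 0
        for d in range(n_demes):
            col[ofs:ofs + dip[d]] = rng.binomial(2, p[d], size=dip[d])
            ofs += dip[d]
        cols.append(col)
        labels.append("selected")

    dosages = (np.stack(cols, axis=1) if cols
               else np.empty((n_samples, 0), dtype=np.int8))
    site_ids = [("chrS", i + 1, "A", "G") for i in range(dosages.shape[1])]
    gm = GenotypeMatrix(
        dosages=dosages,
        sample_ids=[f"s{i}" for i in range(n_samples)],
        pop_labels=pop_labels,
        site_ids=site_ids,
    )
    return gm, np.array(labels)


def gen_cline_dataset(params: ClineParams, elevations, alleles_per_site,
                      seed=None, tails: str = "none") -> ClineDataset:
    """Binomial allele counts along a sigmoid cline: k ~ Bin(2n, p(x))."""
    rng = np.random.default_rng(seed)
    x = np.asarray(elevations, dtype=float)
    n = np.broadcast_to(np.asarray(alleles_per_site, dtype=int), x.shape)
    p = np.asarray(cline_frequency(x, params, tails), dtype=float)
    k = rng.binomial(n, p)
    return ClineDataset(elevation=x, k=k, n_alleles=n.copy())


def gen_expression_counts(config: SyntheticExpressionConfig):
    """NB expression counts with a concerted candidate-set shift.

    Gene means are log-normal; counts are negative binomial with constant
    dispersion.  Candidate genes have their mean multiplied by
    ``2 ** (shift * code)`` with genotype codes LL=0, HL=0.5, HH=1, so
    ``shift`` is the injected log2 fold-change of the HH-vs-LL contrast
    (heterozygotes sit halfway, an additive allele effect).  Returns
    ``(ExpressionCounts, candidate_ids)``.
    """
    rng = np.random.default_rng(config.seed)
    n_genes = config.n_genes
    genotypes = []
    for g, n in sorted(config.group_sizes.items()):
        genotypes += [g] * n
    n_samples = len(genotypes)
    dose = np.array([{"LL": 0.0, "HL": 0.5, "HH": 1.0}[g]
                     for g in genotypes])

    means = rng.lognormal(config.log_mean, config.log_sd, size=n_genes)
    cand = rng.choice(n_genes, size=config.candidate_size, replace=False)
    cand_mask = np.zeros(n_genes, dtype=bool)
    cand_mask[cand] = True

    mu = np.tile(means[:, None], (1, n_samples))
    mu[cand_mask, :] *= 2.0 ** (config.shift * dose[None, :])

    size = 1.0 / config.dispersion
    p = size / (size + mu)
    counts = rng.negative_binomial(size, p)
    gene_ids = [f"g{i:05d}" for i in range(n_genes)]
    ec = ExpressionCounts(counts=counts, gene_ids=gene_ids,
                          sample_ids=[f"m{i}" for i in range(n_samples)],
                          genotypes=genotypes)
    return ec, [gene_ids[i] for i in np.flatnonzero(cand_mask)]
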