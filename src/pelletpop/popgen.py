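"""Population-genetic statistics: Weir-Cockerham F_ST, Watterson's theta, pi.

F_ST between two populations is estimated with the Weir & Cockerham (1984)
variance-components estimator (their theta-hat) on multi-allelic diploid
genotypes, combining loci and alleles as a ratio of sums
``sum(a) / sum(a + b + c)`` — the convention hierfstat's WC84 mode uses —
where per allele `a` is the among-population, `b` the among-individual
(within population) and `c` the within-individual component.  Confidence
intervals come from a percentile bootstrap over loci; significance means
the interval excludes zero.

Diversity per locus is summarized by Watterson's theta
``theta_W = S / (a_n * L)`` and nucleotide diversity ``pi`` (mean pairwise
proportion of differing sites), both per site.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .seqdata import AlignedLocus, GenotypeTable

logger = logging.getLogger("pelletpop")


class MonomorphicDataError(ValueError):
    """All loci monomorphic: the F_ST ratio is 0/0 and undefined."""


@dataclass
class FstResult:
    """Weir-Cockerham F_ST for one population pair, with optional bootstrap CI."""

    pop_pair: tuple[str, str]
    theta_hat: float
    ci_low: float | None = None
    ci_high: float | None = None
    n_boot: int = 0
    significant: bool | None = None
    #: per-locus (a, b, c) component sums (summed over alleles)
    per_locus_components: dict[str, tuple[float, float, float]] = field(default_factory=dict)
    n_dropped_replicates: int = 0
    seed: int | None = None
    degenerate_ci: bool = False

    @property
    def per_locus_theta_mean(self) -> float:
        """Mean of per-locus ratios (diagnostic only; never fed to results)."""
        vals = [a / (a + b + c) for a, b, c in self.per_locus_components.values()
                if a + b + c != 0]
        return float(np.mean(vals)) if vals else float("nan")


def _wc84_locus_components(genotypes_by_pop: list[list[tuple[int, int]]]) -> tuple[float, float, float]:
    """Summed (a, b, c) over alleles at one locus.

    ``genotypes_by_pop`` holds, per population, the unordered diploid code
    pairs of the individuals typed at this locus.
    """
    r = len(genotypes_by_pop)
    n = np.array([len(g) for g in genotypes_by_pop], dtype=float)
    if np.any(n < 2):
        raise ValueError("each population needs >= 2 typed individuals at the locus")
    nbar = n.mean()
    nsum = n.sum()
    nc = (nsum - (n ** 2).sum() / nsum) / (r - 1)
    alleles = sorted({c for pop in genotypes_by_pop for pair in pop for c in pair})
    a_tot = b_tot = c_tot = 0.0
    for u in alleles:
        p = np.array([
            sum(pair.count(u) for pair in pop) / (2 * len(pop))
            for pop in genotypes_by_pop
        ])
        # observed frequency of heterozygotes carrying allele u
        h = np.array([
            sum(1 for pair in pop if (pair[0] == u) != (pair[1] == u)) / len(pop)
            for pop in genotypes_by_pop
        ])
        pbar = (n * p).sum() / (r * nbar)
        s2 = (n * (p - pbar) ** 2).sum() / ((r - 1) * nbar)
        hbar = (n * h).sum() / (r * nbar)
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2
        a_tot += a
        b_tot += b
        c_tot += c
    return a_tot, b_tot, c_tot


def wc84_fst(genotypes: GenotypeTable, pops: tuple[str, str]) -> FstResult:
    """Point estimate of Weir-Cockerham F_ST between two populations.

    Individuals missing a locus are excluded locus-wise.  Loci at which
    either population has fewer than two typed individuals are skipped with
    a warning.  Monomorphic-everywhere data raise
    :class:`MonomorphicDataError` rather than propagating 0/0.
    """
    pop_a, pop_b = pops
    members = {
        lab: [i for i in genotypes.individuals if genotypes.populations[i] == lab]
        for lab in pops
    }
    for lab, mem in members.items():
        if not mem:
            raise ValueError(f"population {lab!r} has no individuals")
    per_locus: dict[str, tuple[float, float, float]] = {}
    for locus in genotypes.loci:
        by_pop = [
            [genotypes.codes[(i, locus)] for i in members[lab]
             if (i, locus) in genotypes.codes]
            for lab in pops
        ]
        if any(len(g) < 2 for g in by_pop):
            logger.warning("locus %s: fewer than 2 typed individuals in a population; "
                           "excluded from F_ST", locus)
            continue
        per_locus[locus] = _wc84_locus_components(by_pop)
    if not per_locus:
        raise ValueError(f"no usable loci shared by populations {pops}")
    comp = np.array(list(per_locus.values()))
    denom = comp.sum(axis=0).sum()
    if denom == 0.0:
        raise MonomorphicDataError(
            f"populations {pops}: all loci monomorphic, F_ST undefined (0/0)")
    theta = float(comp[:, 0].sum() / denom)
    if theta < -0.5:
        logger.warning("pathological F_ST estimate %.4f < -0.5 for %s", theta, pops)
    return FstResult(pop_pair=pops, theta_hat=theta, per_locus_components=per_locus)


def bootstrap_fst_ci(genotypes: GenotypeTable, pops: tuple[str, str],
                     n_boot: int = 100_000, alpha: float = 0.05,
                     seed: int | None = None) -> FstResult:
    """Percentile bootstrap-over-loci CI for Weir-Cockerham F_ST.

    Loci are resampled with replacement and the ratio-of-sums theta-hat is
    recomputed per replicate from the cached per-locus component sums.
    Replicates whose resampled loci are all monomorphic (zero denominator)
    are dropped and counted.  Significance = the CI excludes zero.
    """
    if n_boot < 100:
        logger.warning("n_boot=%d is very small; CI will be unstable", n_boot)
    res = wc84_fst(genotypes, pops)
    comp = np.array(list(res.per_locus_components.values()))  # (L, 3)
    n_loci = comp.shape[0]
    if n_loci < 2:
        logger.warning("only one usable locus: bootstrap CI degenerates to the point estimate")
        return FstResult(pop_pair=pops, theta_hat=res.theta_hat, ci_low=res.theta_hat,
                         ci_high=res.theta_hat, n_boot=n_boot, significant=None,
                         per_locus_components=res.per_locus_components, seed=seed,
                         degenerate_ci=True)
    rng = np.random.default_rng(seed)
    a = comp[:, 0]
    abc = comp.sum(axis=1)
    idx = rng.integers(0, n_loci, size=(n_boot, n_loci))
    num = a[idx].sum(axis=1)
    den = abc[idx].sum(axis=1)
    ok = den != 0
    n_dropped = int((~ok).sum())
    thetas = num[ok] / den[ok]
    lo, hi = np.quantile(thetas, [alpha / 2, 1 - alpha / 2])
    return FstResult(pop_pair=pops, theta_hat=res.theta_hat, ci_low=float(lo),
                     ci_high=float(hi), n_boot=n_boot,
                     significant=bool(lo > 0 or hi < 0),
                     per_locus_components=res.per_locus_components,
                     n_dropped_replicates=n_dropped, seed=seed)


# ---------------------------------------------------------------------------
# diversity

def harmonic_number(n: int) -> float:
    """a_n = sum_{i=1}^{n-1} 1/i, the Watterson denominator."""
    return float(sum(1.0 / i for i in range(1, n)))


def segregating_sites(seqs: list[str]) -> int:
    arr = np.array([list(s) for s in seqs])
    return int(sum(len(set(arr[:, j])) > 1 for j in range(arr.shape[1])))


def theta_from_sequences(seqs: list[str]) -> float:
    """Watterson's theta per site from a list of aligned allele sequences."""
    n = len(seqs)
    if n < 2:
        raise ValueError(f"need >= 2 alleles, got {n}")
    return segregating_sites(seqs) / (harmonic_number(n) * len(seqs[0]))


def pi_from_sequences(seqs: list[str]) -> float:
    """Nucleotide diversity per site: mean pairwise difference proportion."""
    n = len(seqs)
    if n < 2:
        raise ValueError(f"need >= 2 alleles, got {n}")
    arr = np.array([[ord(c) for c in s] for s in seqs], dtype=np.uint8)
    total = 0
    for i, j in combinations(range(n), 2):
        total += int((arr[i] != arr[j]).sum())
    n_pairs = n * (n - 1) // 2
    return total / (n_pairs * len(seqs[0]))


def watterson_theta(locus: AlignedLocus, subset=None) -> float:
    """Watterson's theta per site: S / (a_n * L) over the subset's alleles."""
    return theta_from_sequences(locus.allele_sequences(subset))


def nucleotide_diversity_pi(locus: AlignedLocus, subset=None) -> float:
    """Nucleotide diversity per site over the subset's alleles."""
    return pi_from_sequences(locus.allele_sequences(subset))


@dataclass
class DiversityStats:
    """Per-population diversity over a set of loci."""

    population: str
    #: locus -> (S, n alleles, L bp, theta_w per site, pi per site)
    per_locus: dict[str, tuple[int, int, int, float, float]]
    theta_mean: float
    pi_mean: float


def diversity_stats(population: str, loci: list[AlignedLocus], subset,
                    length_weighted: bool = False) -> DiversityStats:
    """Watterson's theta and pi per locus plus their across-locus means.

    Means are unweighted by default; ``length_weighted=True`` weights each
    locus by its cleaned length.
    """
    per_locus = {}
    for locus in loci:
        seqs = locus.allele_sequences(subset)
        if len(seqs) < 2:
            logger.warning("locus %s: < 2 alleles in population %s; skipped",
                           locus.locus_name, population)
            continue
        S = segregating_sites(seqs)
        tw = watterson_theta(locus, subset)
        pi = nucleotide_diversity_pi(locus, subset)
        per_locus[locus.locus_name] = (S, len(seqs), locus.length, tw, pi)
    if not per_locus:
        raise ValueError(f"population {population!r}: no locus with >= 2 alleles")
    vals = np.array([(v[3], v[4], v[2]) for v in per_locus.values()])
    if length_weighted:
        w = vals[:, 2] / vals[:, 2].sum()
        theta_mean, pi_mean = (vals[:, 0] * w).sum(), (vals[:, 1] * w).sum()
    else:
        theta_mean, pi_mean = vals[:, 0].mean(), vals[:, 1].mean()
    return DiversityStats(population=population, per_locus=per_locus,
                          theta_mean=float(theta_mean), pi_mean=float(pi_mean))
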