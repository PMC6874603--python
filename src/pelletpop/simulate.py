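"""Synthetic datasets with the statistical structure the analysis assumes.

The generator emulates a museum/owl-pellet study design: a handful of short
intron loci (153-229 bp) with phased diploid genotypes from two or more
populations exchanging migrants, plus group-structured 16-landmark mandible
configurations in which one group differs in size but not shape, and sample
degradation (locus dropout increasing with sample age; some mandibles
retaining only the two coronoid-height landmarks).

Two sequence-generating modes are offered:

* **coalescent** — per locus, a Kingman coalescent genealogy on the 2n
  sampled lineages with infinite-sites mutations.  Time is scaled so that k
  lineages coalesce at rate k(k-1)/2 and mutations arrive at theta_locus/2
  per lineage per unit time, giving the textbook E[S] = theta * a_n.
  Optional symmetric migration connects demes at rate migration_rate/2 per
  lineage.
* **frequency** (Balding-Nichols) — a panmictic ancestral allele pool is
  drawn once per locus; per-population allele frequencies follow a
  Dirichlet with parameter p*(1-F)/F so the true F_ST equals ``fst_target``
  in closed form, which makes parameter-recovery tests possible.

All randomness flows from one generator seeded by ``SimConfig.seed``.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .morpho import LandmarkConfiguration, write_tps
from .seqdata import AlignedLocus, write_phased_fasta

logger = logging.getLogger("pelletpop")

BASES = np.array(list("ACGT"))

#: default locus lengths, spanning the short-intron range used in practice
DEFAULT_LOCUS_LENGTHS = (153, 168, 181, 196, 214, 229)


def _default_mean_shape() -> np.ndarray:
    """A stylized 16-landmark half-mandible in mm.

    Landmark 1 sits at the lower border below the coronoid process and
    landmark 7 at the coronoid tip, 5.0 mm apart, so the baseline group's
    coronoid height falls in the mid-size range.
    """
    t = np.linspace(0.15 * np.pi, 1.85 * np.pi, 14)
    outline = np.c_[5.5 * np.cos(t), 2.2 * np.sin(t) + 1.0]
    pts = np.zeros((16, 2))
    pts[0] = (0.0, 0.0)
    pts[6] = (0.0, 5.0)
    rest = [i for i in range(16) if i not in (0, 6)]
    pts[rest] = outline
    return pts


@dataclass
class SimConfig:
    """Study-design parameters for the synthetic generator."""

    n_populations: int = 2
    n_individuals_per_pop: int = 25
    n_loci: int = 6
    locus_lengths: tuple[int, ...] = DEFAULT_LOCUS_LENGTHS
    theta_per_site: float = 0.002          # 4Nu per site, intron-scale diversity
    fst_target: float | None = None        # frequency-model mode
    migration_rate: float | None = 10.0    # 4Nm, coalescent mode (high gene flow)
    dropout_rate_per_decade: float = 0.1
    landmark_mean_shapes: tuple[np.ndarray, ...] | None = None  # per group; default shared
    size_factors: tuple[float, ...] = (1.0, 1.15)
    landmark_sd: float = 0.03              # mm, digitizing + individual variation
    image_scale: float = 0.02              # mm per coordinate unit in TPS output
    max_age_years: float = 50.0            # pellets span the last half-century
    reference_year: int = 2019
    n_ancestral_alleles: int = 2           # pool size in frequency mode
    min_loci_per_individual: int = 4
    partial_config_rate: float = 0.09      # fraction reduced to landmarks 1 and 7
    group_names: tuple[str, ...] | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_loci != len(self.locus_lengths):
            # allow n_loci to drive truncation/cycling of the default lengths
            reps = -(-self.n_loci // len(self.locus_lengths))
            self.locus_lengths = tuple((list(self.locus_lengths) * reps)[: self.n_loci])
        for L in self.locus_lengths:
            if not 50 <= L <= 10000:
                raise ValueError(f"locus length {L} outside [50, 10000]")
        if self.n_individuals_per_pop < 2:
            raise ValueError("need at least 2 individuals per population")
        if self.n_populations < 1:
            raise ValueError("need at least 1 population")
        if (self.fst_target is None) == (self.migration_rate is None):
            raise ValueError("exactly one of fst_target / migration_rate must be set")
        if self.fst_target is not None and not (0 <= self.fst_target < 1):
            raise ValueError("fst_target must lie in [0, 1)")
        for name, v in [("theta_per_site", self.theta_per_site),
                        ("dropout_rate_per_decade", self.dropout_rate_per_decade),
                        ("landmark_sd", self.landmark_sd)]:
            if v < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.dropout_rate_per_decade > 1:
            raise ValueError("dropout_rate_per_decade must lie in [0, 1]")
        if len(self.size_factors) < self.n_populations:
            raise ValueError("need one size factor per population")
        if self.landmark_mean_shapes is not None:
            for m in self.landmark_mean_shapes:
                if not np.isfinite(np.asarray(m, dtype=float)).all():
                    raise ValueError("mean shapes must be finite")
        self._rng = np.random.default_rng(self.seed)

    @property
    def rng(self) -> np.random.Generator:
        """The single RNG all stochastic operations draw from."""
        return self._rng

    @property
    def mode(self) -> str:
        return "frequency" if self.fst_target is not None else "coalescent"

    @property
    def groups(self) -> list[str]:
        if self.group_names is not None:
            return list(self.group_names[: self.n_populations])
        return [f"pop{i + 1}" for i in range(self.n_populations)]

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d.pop("_rng", None)
        if d.get("landmark_mean_shapes") is not None:
            d["landmark_mean_shapes"] = [np.asarray(m).tolist()
                                         for m in d["landmark_mean_shapes"]]
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d


@dataclass
class SyntheticDataset:
    """In-memory bundle of one simulated study."""

    loci: list[AlignedLocus]
    samples: pd.DataFrame
    landmarks: list[LandmarkConfiguration] | None = None
    group_labels: dict[str, str] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# coalescent machinery

def simulate_coalescent_locus(rng: np.random.Generator, n_per_deme: list[int],
                              theta_locus: float, length: int,
                              migration_rate: float = 0.0) -> list[str]:
    """Haplotype sequences from a (structured) Kingman coalescent.

    Returns ``sum(n_per_deme)`` sequences, deme-0 lineages first.  With one
    deme or ``migration_rate == 0`` the demes coalesce independently and
    share the ancestral sequence at the root(s).  Mutations follow the
    infinite-sites model: each mutation hits a previously unhit site (sites
    are resampled on collision) and replaces the base with a different one.
    """
    n_total = int(sum(n_per_deme))
    if n_total < 1 or length < 1:
        raise ValueError("need at least one lineage and positive length")
    parent = {}
    node_time = {i: 0.0 for i in range(n_total)}
    demes = []
    nid = 0
    for d, n in enumerate(n_per_deme):
        demes += [d] * n
    active = [(i, demes[i]) for i in range(n_total)]
    next_id = n_total
    t = 0.0
    n_demes = len(n_per_deme)
    while len(active) > 1:
        k_by_deme = np.zeros(n_demes)
        for _, d in active:
            k_by_deme[d] += 1
        coal_rates = k_by_deme * (k_by_deme - 1) / 2.0
        mig_rate = (migration_rate / 2.0) * len(active) if n_demes > 1 else 0.0
        total = coal_rates.sum() + mig_rate
        if total == 0:
            break  # isolated demes fully coalesced
        t += rng.exponential(1.0 / total)
        if rng.random() < coal_rates.sum() / total:
            d = rng.choice(n_demes, p=coal_rates / coal_rates.sum())
            members = [i for i, (_, dd) in enumerate(active) if dd == d]
            ia, ib = rng.choice(members, size=2, replace=False)
            (na, _), (nb, _) = active[ia], active[ib]
            parent[na] = next_id
            parent[nb] = next_id
            node_time[next_id] = t
            active = [x for i, x in enumerate(active) if i not in (ia, ib)]
            active.append((next_id, d))
            next_id += 1
        else:
            i = rng.integers(len(active))
            nd, dd = active[i]
            others = [x for x in range(n_demes) if x != dd]
            active[i] = (nd, int(rng.choice(others)))
    # drop mutations on branches
    ancestral = rng.choice(BASES, size=length)
    used_sites: set[int] = set()
    mutations: dict[int, list[tuple[int, str]]] = {}
    for node, par in parent.items():
        blen = node_time[par] - node_time[node]
        n_mut = rng.poisson(theta_locus / 2.0 * blen)
        for _ in range(n_mut):
            if len(used_sites) >= length:
                logger.warning("infinite-sites saturation: locus length %d exhausted", length)
                break
            site = int(rng.integers(length))
            while site in used_sites:
                site = int(rng.integers(length))
            used_sites.add(site)
            new_base = rng.choice(BASES[BASES != ancestral[site]])
            mutations.setdefault(node, []).append((site, str(new_base)))
    # leaf sequences: apply all mutations on the leaf-to-root path
    seqs = []
    for leaf in range(n_total):
        seq = ancestral.copy()
        node = leaf
        while True:
            for site, base in mutations.get(node, []):
                seq[site] = base
            if node not in parent:
                break
            node = parent[node]
        seqs.append("".join(seq))
    return seqs


def _balding_nichols_locus(rng: np.random.Generator, config: SimConfig,
                           length: int) -> list[list[tuple[int, int]]]:
    """Per-population diploid genotypes (allele indices) under Balding-Nichols."""
    K = config.n_ancestral_alleles
    F = config.fst_target
    p = rng.dirichlet(np.full(K, 2.0))
    genos = []
    for _ in range(config.n_populations):
        if F == 0:
            pi = p
        else:
            pi = rng.dirichlet(p * (1 - F) / F)
        draws = rng.choice(K, size=(config.n_individuals_per_pop, 2), p=pi)
        genos.append([tuple(g) for g in draws])
    return genos


def _allele_pool_sequences(rng: np.random.Generator, K: int, length: int) -> list[str]:
    """K distinct sequences: the ancestral plus K-1 single-site variants."""
    if length < K - 1:
        raise ValueError("locus too short for the requested allele pool")
    ancestral = rng.choice(BASES, size=length)
    pool = ["".join(ancestral)]
    for j in range(K - 1):
        var = ancestral.copy()
        var[j] = rng.choice(BASES[BASES != ancestral[j]])
        pool.append("".join(var))
    return pool


# ---------------------------------------------------------------------------
# dataset generation

def _sample_ids(config: SimConfig) -> dict[str, list[str]]:
    return {
        grp: [f"{grp}_{i + 1:03d}" for i in range(config.n_individuals_per_pop)]
        for grp in config.groups
    }


def simulate_sequences(config: SimConfig, out_dir=None) -> SyntheticDataset:
    """Simulate per-locus phased diploid alignments plus a sample table.

    Coalescent mode draws genealogies with migration; frequency mode draws
    Balding-Nichols population allele frequencies from an ancestral pool.
    If ``out_dir`` is given, one FASTA per locus, a samples TSV and a YAML
    echo of the configuration are written there.
    """
    rng = config.rng
    ids_by_group = _sample_ids(config)
    all_ids = [i for grp in config.groups for i in ids_by_group[grp]]
    group_of = {i: grp for grp in config.groups for i in ids_by_group[grp]}
    loci = []
    for li, L in enumerate(config.locus_lengths):
        name = f"locus{li + 1}"
        alleles: dict[str, tuple[str, str]] = {}
        if config.mode == "coalescent":
            n_hap = [2 * config.n_individuals_per_pop] * config.n_populations
            seqs = simulate_coalescent_locus(
                rng, n_hap, config.theta_per_site * L, L,
                migration_rate=config.migration_rate or 0.0)
            pos = 0
            for grp in config.groups:
                for ind in ids_by_group[grp]:
                    alleles[ind] = (seqs[pos], seqs[pos + 1])
                    pos += 2
        else:
            pool = _allele_pool_sequences(rng, config.n_ancestral_alleles, L)
            genos = _balding_nichols_locus(rng, config, L)
            for grp, pop_genos in zip(config.groups, genos):
                for ind, (g1, g2) in zip(ids_by_group[grp], pop_genos):
                    alleles[ind] = (pool[g1], pool[g2])
        loci.append(AlignedLocus(locus_name=name, alleles=alleles))
    ages = rng.uniform(0.0, config.max_age_years, size=len(all_ids))
    samples = pd.DataFrame({
        "sample_id": all_ids,
        "group": [group_of[i] for i in all_ids],
        "lon": rng.uniform(-7.0, 2.0, size=len(all_ids)).round(4),
        "lat": rng.uniform(41.5, 43.8, size=len(all_ids)).round(4),
        "year": (config.reference_year - ages).astype(int),
    })
    ds = SyntheticDataset(loci=loci, samples=samples, group_labels=group_of)
    if out_dir is not None:
        write_dataset(ds, config, out_dir)
    return ds


def simulate_landmarks(config: SimConfig) -> tuple[list[LandmarkConfiguration], dict[str, str]]:
    """Simulate group-structured 16-landmark configurations.

    Each configuration is its group's mean shape times the group size
    factor, plus i.i.d. Gaussian landmark noise, then randomly rotated and
    translated so the Procrustes fit has work to do.  The TPS scale is
    recorded so the coronoid height is recoverable in mm.
    """
    rng = config.rng
    if config.landmark_mean_shapes is not None:
        means = [np.asarray(m, dtype=float) for m in config.landmark_mean_shapes]
    else:
        means = [_default_mean_shape()] * config.n_populations
    ids_by_group = _sample_ids(config)
    configs = []
    labels = {}
    for g, grp in enumerate(config.groups):
        mean = means[g] * config.size_factors[g]
        for ind in ids_by_group[grp]:
            pts = mean + rng.normal(0.0, config.landmark_sd, size=mean.shape)
            theta = rng.uniform(0, 2 * np.pi)
            R = np.array([[np.cos(theta), -np.sin(theta)],
                          [np.sin(theta), np.cos(theta)]])
            pts = pts @ R.T + rng.uniform(-20, 20, size=2)
            configs.append(LandmarkConfiguration(
                sample_id=ind, points=pts / config.image_scale,
                scale=config.image_scale))
            labels[ind] = grp
    return configs, labels


def apply_degradation(dataset: SyntheticDataset, config: SimConfig) -> SyntheticDataset:
    """Age-dependent locus dropout plus partial landmark configurations.

    Each (individual, locus) is dropped independently with probability
    ``1 - (1 - rate)^(age / 10)``; a ``partial_config_rate`` fraction of
    landmark configurations is reduced to landmarks 1 and 7 only; and
    individuals retaining fewer than ``min_loci_per_individual`` loci are
    flagged for exclusion in the sample table.
    """
    rng = config.rng
    rate = config.dropout_rate_per_decade
    ages = {
        row.sample_id: config.reference_year - row.year
        for row in dataset.samples.itertuples()
    }
    new_loci = []
    for locus in dataset.loci:
        kept = {}
        for ind, pair in locus.alleles.items():
            p_drop = 1.0 - (1.0 - rate) ** (ages.get(ind, 0.0) / 10.0)
            if rng.random() >= p_drop:
                kept[ind] = pair
        new_loci.append(AlignedLocus(locus_name=locus.locus_name, alleles=kept))
    n_kept = {
        ind: sum(1 for loc in new_loci if ind in loc.alleles)
        for ind in dataset.samples["sample_id"]
    }
    samples = dataset.samples.copy()
    samples["n_loci"] = samples["sample_id"].map(n_kept)
    samples["excluded"] = samples["n_loci"] < config.min_loci_per_individual
    n_excl = int(samples["excluded"].sum())
    if n_excl:
        logger.info("degradation: %d of %d individuals retain < %d loci",
                    n_excl, len(samples), config.min_loci_per_individual)
    landmarks = dataset.landmarks
    if landmarks is not None:
        landmarks = []
        for cfg in dataset.landmarks:
            if rng.random() < config.partial_config_rate:
                pts = np.full_like(cfg.points, np.nan)
                pts[0] = cfg.points[0]
                pts[6] = cfg.points[6]
                landmarks.append(LandmarkConfiguration(
                    sample_id=cfg.sample_id, points=pts, scale=cfg.scale))
            else:
                landmarks.append(cfg)
    return SyntheticDataset(loci=new_loci, samples=samples, landmarks=landmarks,
                            group_labels=dict(dataset.group_labels))


def simulate_dataset(config: SimConfig, degrade: bool = False,
                     out_dir=None) -> SyntheticDataset:
    """Sequences + landmarks (+ optional degradation) in one call."""
    ds = simulate_sequences(config)
    ds.landmarks, labels = simulate_landmarks(config)
    ds.group_labels.update(labels)
    if degrade:
        ds = apply_degradation(ds, config)
    if out_dir is not None:
        write_dataset(ds, config, out_dir)
    return ds


def write_dataset(ds: SyntheticDataset, config: SimConfig, out_dir) -> None:
    """Write FASTAs (one per locus), samples TSV, TPS and a config echo."""
    import pathlib

    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for locus in ds.loci:
        write_phased_fasta(locus, out / f"{locus.locus_name}.fasta")
    ds.samples.to_csv(out / "samples.tsv", sep="\t", index=False)
    if ds.landmarks is not None:
        write_tps(ds.landmarks, out / "landmarks.tps")
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
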