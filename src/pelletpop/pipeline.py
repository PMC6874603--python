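"""End-to-end orchestration: clean -> classify -> encode -> F_ST -> trees.

`run_pipeline` composes the analysis stages on a set of per-locus phased
FASTAs, a TPS landmark file and a sample table, and writes a structured
report (JSON) plus TSV/newick artifacts.  Every filter logs counts in/out,
and the report carries provenance (inputs, seed, package version) so a
rerun with the same seed is byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import pathlib
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .morpho import (DEFAULT_THRESHOLDS, classify_taxon, coronoid_height,
                     procrustes_fit, read_tps, shape_pca)
from .phylo import (build_distance_tree, collapse_to_genealogy,
                    distance_matrix_diploid, midpoint_root, write_newick)
from .popgen import MonomorphicDataError, bootstrap_fst_ci, diversity_stats
from .seqdata import (build_genotype_table, clean_alignment,
                      individual_heterozygosity, read_phased_fasta)

logger = logging.getLogger("pelletpop")


class PipelineError(RuntimeError):
    """Explicit abort: the inputs cannot support the requested analysis."""


@dataclass
class PipelineConfig:
    """All analysis choices, explicit and serializable.

    Group definitions are an analytical input, never inferred from data.
    """

    loci_fastas: list[str]
    samples_tsv: str
    tps_path: str | None = None
    grouping_column: str = "group"
    coronoid_thresholds: tuple[float, float, float] = DEFAULT_THRESHOLDS
    min_loci_per_individual: int = 4
    n_boot: int = 100_000
    alpha: float = 0.05
    seed: int | None = None
    out_dir: str | None = None
    distance_mode: str = "length_weighted"

    def __post_init__(self) -> None:
        t1, t2, t3 = self.coronoid_thresholds
        if not (t1 < t2 <= t3):
            raise ValueError("coronoid thresholds must be increasing")
        if self.min_loci_per_individual < 1:
            raise ValueError("min_loci_per_individual must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "coronoid_thresholds" in raw:
            raw["coronoid_thresholds"] = tuple(raw["coronoid_thresholds"])
        return cls(**raw)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis; returns (and optionally writes) the report."""
    out = pathlib.Path(config.out_dir) if config.out_dir else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "provenance": {
            "package": f"pelletpop {__version__}",
            "seed": config.seed,
            "inputs": {
                "loci_fastas": [str(p) for p in config.loci_fastas],
                "samples_tsv": str(config.samples_tsv),
                "tps_path": str(config.tps_path) if config.tps_path else None,
            },
            "config": {k: (list(v) if isinstance(v, tuple) else v)
                       for k, v in dataclasses.asdict(config).items()},
        },
        "counts": {},
    }

    samples = pd.read_csv(config.samples_tsv, sep="\t")
    if config.grouping_column not in samples.columns:
        raise PipelineError(f"grouping column {config.grouping_column!r} missing "
                            f"from {config.samples_tsv}")
    populations = dict(zip(samples["sample_id"].astype(str),
                           samples[config.grouping_column].astype(str)))
    report["counts"]["samples_read"] = len(samples)

    # --- sequences: read and clean --------------------------------------
    loci = []
    for path in config.loci_fastas:
        raw = read_phased_fasta(path)
        try:
            cleaned = clean_alignment(raw)
        except Exception as exc:  # a locus failing cleaning is excluded, not fatal
            logger.warning("locus %s excluded: %s", path, exc)
            continue
        loci.append(cleaned)
    if not loci:
        raise PipelineError("zero usable loci after cleaning; aborting")
    report["counts"]["loci_used"] = len(loci)
    report["loci"] = {
        l.locus_name: {"length_bp": l.length, "n_individuals": len(l.alleles)}
        for l in loci
    }

    # --- morphometrics ----------------------------------------------------
    if config.tps_path:
        configs = read_tps(config.tps_path)
        report["counts"]["landmark_configs_read"] = len(configs)
        classif = []
        for cfg in configs:
            try:
                ch = coronoid_height(cfg)
                taxon = classify_taxon(ch, config.coronoid_thresholds)
            except ValueError:
                ch, taxon = float("nan"), "unmeasurable"
            classif.append({"sample_id": cfg.sample_id, "coronoid_height_mm":
                            round(ch, 4) if np.isfinite(ch) else None,
                            "taxon": taxon, "complete": cfg.complete})
        class_df = pd.DataFrame(classif)
        tax_counts = class_df["taxon"].value_counts().to_dict()
        report["morphometrics"] = {
            "classification_counts": {k: int(v) for k, v in sorted(tax_counts.items())},
            "n_partial": int((~class_df["complete"]).sum()),
        }
        complete = [c for c in configs if c.complete]
        report["counts"]["landmark_configs_complete"] = len(complete)
        if len(complete) >= 3:
            proc = procrustes_fit(complete)
            pca = shape_pca(proc)
            report["morphometrics"]["procrustes"] = {
                "iterations": proc.iterations,
                "converged": bool(proc.converged),
                "centroid_size_mean_mm": round(float(proc.centroid_sizes.mean()), 4),
            }
            report["morphometrics"]["pca_variance_fractions"] = [
                round(float(v), 6) for v in pca.variance_fractions[:5]
            ]
            if out is not None:
                pd.DataFrame({
                    "sample_id": pca.sample_ids,
                    **{f"PC{i + 1}": np.round(pca.scores[:, i], 6)
                       for i in range(min(5, pca.scores.shape[1]))},
                }).to_csv(out / "pca_scores.tsv", sep="\t", index=False)
        if out is not None:
            class_df.to_csv(out / "classification.tsv", sep="\t", index=False)

    # --- genotypes and filters -------------------------------------------
    labelled = [i for i in populations]
    table = build_genotype_table(loci, populations,
                                 subset=labelled)
    report["counts"]["individuals_genotyped"] = len(table.individuals)
    table = table.filter_min_loci(config.min_loci_per_individual)
    report["counts"]["individuals_passing_min_loci"] = len(table.individuals)
    if not table.individuals:
        raise PipelineError(
            f"zero usable individuals: none retain >= {config.min_loci_per_individual} "
            "loci; aborting")
    analysis_inds = list(table.individuals)
    # re-encode over the analysis subset so allele counts refer to it
    table = build_genotype_table(loci, populations, subset=analysis_inds)
    report["genotypes"] = {
        "alleles_per_locus": dict(sorted(table.allele_counts.items())),
        "total_alleles": table.total_alleles(),
        "mean_alleles_per_locus": round(table.total_alleles() / len(loci), 2),
        "total_bp": int(sum(
            l.length * len(l.allele_sequences(analysis_inds)) for l in loci)),
    }
    if out is not None:
        table.to_frame().to_csv(out / "genotypes.tsv", sep="\t", index=False)

    # --- heterozygosity ---------------------------------------------------
    het = {ind: individual_heterozygosity(ind, loci) for ind in analysis_inds}
    by_pop: dict[str, list[float]] = {}
    for ind, h in het.items():
        by_pop.setdefault(populations[ind], []).append(h)
    report["heterozygosity"] = {
        "per_population_mean": {p: round(float(np.mean(v)), 6)
                                for p, v in sorted(by_pop.items())},
        "overall_mean": round(float(np.mean(list(het.values()))), 6),
    }
    if out is not None:
        pd.DataFrame({"sample_id": list(het), "het_per_bp":
                      [round(v, 6) for v in het.values()]}).to_csv(
            out / "heterozygosity.tsv", sep="\t", index=False)

    # --- F_ST -------------------------------------------------------------
    pops_present = sorted({populations[i] for i in analysis_inds})
    report["fst"] = {}
    for pa, pb in combinations(pops_present, 2):
        na = sum(1 for i in analysis_inds if populations[i] == pa)
        nb = sum(1 for i in analysis_inds if populations[i] == pb)
        if na < 2 or nb < 2:
            logger.warning("skipping F_ST %s vs %s: too few individuals", pa, pb)
            continue
        try:
            res = bootstrap_fst_ci(table, (pa, pb), n_boot=config.n_boot,
                                   alpha=config.alpha, seed=config.seed)
        except MonomorphicDataError as exc:
            report["fst"][f"{pa}|{pb}"] = {"undefined": True, "reason": str(exc)}
            continue
        report["fst"][f"{pa}|{pb}"] = {
            "theta_hat": round(res.theta_hat, 6),
            "ci_95": [round(res.ci_low, 6), round(res.ci_high, 6)],
            "significant": res.significant,
            "n_boot": res.n_boot,
        }

    # --- diversity ---------------------------------------------------------
    report["diversity"] = {}
    for pop in pops_present:
        members = [i for i in analysis_inds if populations[i] == pop]
        try:
            ds = diversity_stats(pop, loci, members)
        except ValueError as exc:
            logger.warning("diversity for %s unavailable: %s", pop, exc)
            continue
        report["diversity"][pop] = {
            "theta_mean": round(ds.theta_mean, 6),
            "pi_mean": round(ds.pi_mean, 6),
            "per_locus": {
                name: {"S": S, "n": n, "L": L,
                       "theta_w": round(tw, 6), "pi": round(pi, 6)}
                for name, (S, n, L, tw, pi) in sorted(ds.per_locus.items())
            },
        }

    # --- distance tree ------------------------------------------------------
    tree_inds = [i for i in analysis_inds if any(i in l.alleles for l in loci)]
    if len(tree_inds) >= 3:
        try:
            dm = distance_matrix_diploid(tree_inds, loci, mode=config.distance_mode)
            tree = midpoint_root(build_distance_tree(dm))
            report["tree"] = {"n_leaves": len(tree_inds)}
            if out is not None:
                write_newick(tree, out / "distance_tree.nwk")
                pd.DataFrame(dm.d, index=dm.labels, columns=dm.labels).to_csv(
                    out / "distance_matrix.tsv", sep="\t")
        except ValueError as exc:
            logger.warning("distance tree unavailable: %s", exc)
            report["tree"] = {"error": str(exc)}

    # --- haplotype genealogies ----------------------------------------------
    report["genealogies"] = {}
    for locus in loci:
        gen = collapse_to_genealogy(locus, populations, subset=analysis_inds)
        report["genealogies"][locus.locus_name] = {
            "n_haplotypes": len(gen.nodes),
            "total_alleles": gen.total_alleles,
        }
        if out is not None:
            pd.DataFrame([
                {"hap_id": n.hap_id, "frequency": n.frequency,
                 **{f"n_{g}": c for g, c in sorted(n.group_counts.items())}}
                for n in gen.nodes
            ]).to_csv(out / f"genealogy_{locus.locus_name}_nodes.tsv",
                      sep="\t", index=False)
            pd.DataFrame(gen.edges, columns=["hap_a", "hap_b", "steps"]).to_csv(
                out / f"genealogy_{locus.locus_name}_edges.tsv", sep="\t", index=False)

    if out is not None:
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
            fh.write("\n")
    return report
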