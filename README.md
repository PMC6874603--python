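# pelletpop

Combined geometric-morphometric and multilocus population-genetic analysis
of degraded small-mammal samples, built around the study design of Eurasian
water shrews (*Neomys*) recovered from barn-owl pellets: skulls collected
over decades, measured from photographs, and genotyped at a handful of
short intron loci that still amplify from old, fragmented DNA.

The package answers two questions about such material:

1. **Morphology** — does a group differ in *size*, in *shape*, or both?
   Mandibles are described by 16 two-dimensional landmarks with a physical
   scale. The coronoid height (distance between landmarks 1 and 7, in mm)
   classifies specimens into taxa by published bands
   (≤ 4.70 mm → *N. anomalus*; 4.80–5.35 mm → *N. f. fodiens*;
   > 5.35 mm → *N. f. niethammeri*; the open gap is reported as
   ambiguous). A generalized Procrustes fit removes translation, scale and
   rotation; centroid size CS = √Σ‖xᵢ − x̄‖² carries the size signal, and a
   PCA of the covariance matrix of Procrustes coordinates carries the
   shape signal.
2. **Population genetics** — are morphological groups genetically
   differentiated, and how diverse is each? Phased diploid allele pairs per
   intron are cleaned (every column containing a gap or non-ACGT symbol is
   removed), numbered into a multi-allelic genotype table, and analysed
   with the Weir–Cockerham (1984) variance-components F_ST estimator
   θ̂ = Σa / Σ(a+b+c) (ratio of sums over loci and alleles), with a
   percentile bootstrap over loci for the 95% CI — significance means the
   interval excludes zero. Diversity per locus is Watterson's
   θ_W = S/(a_n·L) and nucleotide diversity π; individual heterozygosity
   pools heterozygous positions across loci and divides by the summed
   locus lengths. Relationships are visualised with a midpoint-rooted
   distance tree (all four allele-pair Jukes–Cantor distances per locus,
   d = −(3/4)ln(1−4p/3), length-weighted across loci; NJ topology with
   least-squares branch lengths) and per-locus haplotype genealogies
   (frequency-weighted minimum-spanning networks).

A first-class synthetic-data generator (`pelletpop.simulate`) reproduces
the statistical structure of such a study — a structured Kingman
coalescent with infinite-sites mutation and symmetric migration, or a
Balding–Nichols frequency model with a closed-form true F_ST; landmark
configurations in which groups differ in size but not shape; and
age-dependent locus dropout — so the whole pipeline is testable without
any real data.

## Worked example

```python
import glob
import pelletpop as pp

# a degraded two-group study: 6 introns (153-229 bp), high gene flow
cfg = pp.SimConfig(seed=7, n_individuals_per_pop=15,
                   group_names=("fodiens", "niethammeri"))
pp.simulate_dataset(cfg, degrade=True, out_dir="demo/data")

pipe = pp.PipelineConfig(
    loci_fastas=sorted(glob.glob("demo/data/locus*.fasta")),
    samples_tsv="demo/data/samples.tsv",
    tps_path="demo/data/landmarks.tps",
    n_boot=10_000, seed=1, out_dir="demo/out")
report = pp.run_pipeline(pipe)
print(report["morphometrics"]["classification_counts"])
print(report["fst"]["fodiens|niethammeri"])
print(report["heterozygosity"]["per_population_mean"])
```

prints

```
{'fodiens': 15, 'niethammeri': 15}
{'theta_hat': 0.120441, 'ci_95': [0.027504, 0.169902], 'significant': True, 'n_boot': 10000}
{'fodiens': 0.002237, 'niethammeri': 0.002054}
```

All 30 specimens are classified into the two size bands. The
Weir–Cockerham F_ST between the groups is modest — six short loci from
only 15 diploids per group give a noisy estimate even under high gene
flow, and whether the bootstrap CI excludes zero varies between draws,
which is exactly the regime the significance rule is for. The
per-population heterozygosities
are the average number of heterozygous positions per base. `demo/out/`
additionally contains the classification and PCA-score tables, the
midpoint-rooted distance tree in newick, per-locus haplotype genealogies
as node/edge TSVs, and `report.json` with full provenance; rerunning with
the same seed reproduces it byte for byte.

The same pipeline runs on real data: one FASTA per locus with
`<sample>_a1`/`<sample>_a2` phased-allele headers, a TPS landmark file and
a tab-separated sample table with a grouping column.

There is also a CLI: `pelletpop simulate`, `pelletpop morpho`,
`pelletpop popgen`, `pelletpop tree`, `pelletpop run-all`.

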