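# karyoploid

Karyotype morphometrics, flow-cytometric genome-size estimation and ploidy
inference for plant cytogenetics.

The package is aimed at plant cytogeneticists working on groups — such as
Old World *Astragalus* with base chromosome number x = 8 — where species
diversity involves whole-genome duplication. It turns the three routine
desk analyses of such a study into reproducible code:

1. **Karyotype morphometrics.** From per-chromosome short/long arm lengths
   (q, p, in µm) of a metaphase plate it computes the Levan centromere
   classes from the arm ratio r = p/q (M: r ≤ 1.05, m: ≤ 1.7, sm: ≤ 3,
   st: ≤ 7, else t), the karyotype formula (e.g. `1M + 6m + 1sm`), the
   asymmetry indices

   TF% = 100·Σq/Σ(q+p),  AsK% = 100·Σp/Σ(q+p),  Syi% = 100·q̄/p̄,

   the shortest/longest ratio S%, mean arm ratio R, mean centromeric index
   Ci = q/(q+p), and the two-way Stebbins symmetry class.

2. **Genome size by flow cytometry.** A propidium-iodide fluorescence
   histogram containing the sample G1 peak and a co-processed internal
   standard (*Zea mays*, 5.43 pg/2C by default) yields

   2C_sample = 2C_standard · (mean sample peak / mean standard peak),

   with peak detection, Gaussian peak statistics, CV% quality flags, and
   G2-doublet/debris handling.

3. **Ploidy inference.** The monoploid genome size Cx is calibrated as
   half the mean 2C of chromosome-counted diploids; each 2C value is then
   assigned the allowed ploidy level (2x/4x/6x/8x) with the smallest
   relative deviation, or left indeterminate beyond a 15% tolerance.
   Assignments are reconciled with chromosome counts (2n = level·x) to
   flag possible cytotype variation, aggregated per level, and can be
   painted onto a Newick phylogeny as tip annotations. A scikit-learn
   style `PloidyClassifier` (fit on diploid 2C values, predict levels)
   exposes the same procedure for pipeline use.

A synthetic-data module generates karyotypes, two-peak histograms (with
debris and G2 components) and species tables with known ground truth, so
the whole pipeline is testable offline; two packaged reference tables (a
17-species karyotype table and a 64-individual genome-size table) provide
real published-style inputs.

## Worked example

```python
import karyoploid as kp

# karyotype of 8 chromosomes with q = 1.44, p = 1.95 µm
k = kp.MetaphaseKaryotype("demo", tuple(kp.ArmPair(1.44, 1.95) for _ in range(8)), two_n=16)
row = kp.summarize_karyotype(k).report_row()
print(row["tf_pct"], row["ask_pct"], row["syi_pct"], row["kf"])
# 42 57 74 8m      -> a fairly symmetric all-metacentric diploid complement

# genome size: sample peak at channel 41.55, maize standard at 103.79
print(round(kp.estimate_2c(41.55, 103.79), 2))
# 2.17             -> 2C = 2.17 pg, a diploid-sized genome

# ploidy: calibrate Cx from the packaged chromosome-counted diploids
table = kp.datasets.load_genome_size_table()
cal = kp.calibrate_cx(kp.datasets.counted_diploid_two_c(table))
print(round(cal.cx, 4))
# 1.1414           -> monoploid genome size in pg
a = kp.assign_ploidy(2.21, cal)
print(a.label, a.expected_2n)
# 2x 16            -> diploid-sized; an observed count of 2n = 32 would be
#                     flagged as possible cytotype variation
```

The same steps are available from the shell:

```
karyoploid fixtures --out-dir fixtures/
karyoploid ploidy records.csv --out assignments.csv
karyoploid simulate --kind histogram --true-two-c 4.46 --seed 9 --out hist.csv
karyoploid flowsize hists/ --standard-hint 500 --out sizes.csv
karyoploid annotate-tree tree.nwk records.csv --out annotated.nwk
```

`karyoploid ploidy` prints the Cx calibration, a per-level 2C summary
(n, mean, population sd, range) and the list of count/genome-size
discordances.

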