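# cotasm

Structural analysis of **cotranslational protein-complex assembly**: from
multi-chain structures, compute pairwise buried interfaces and their
translational build-up, identify first/last translated interfaces of
multi-interface subunits, map ribosome-profiling assembly onsets to
interfaces, predict interface assembly order, and run the nonparametric
inference layer over cohorts of subunits.

## The scientific question

Many protein complexes begin to assemble while at least one subunit is
still being synthesised on the ribosome. Because translation is vectorial
(N- to C-terminal), an interface whose residues emerge early has more time
to capture a partner. If cotranslational assembly is adaptive, first
translated interfaces of multi-interface subunits should tend to be
*larger* than last translated ones. Testing that requires a small set of
reproducible structural primitives, which this package implements:

- **Buried surface area (BSA).** For chains *a, b*, the per-residue
  interface area is ΔASA = ASA(residue | *a* isolated) − ASA(residue | *a*
  with *b*), with solvent-accessible surface area from a deterministic
  Shrake–Rupley sphere-point method (probe 1.4 Å). Interfaces with
  BSA ≤ 400 Å² are treated as not biologically significant.
- **Interface midpoint** *i*: the first residue at which the N→C
  cumulative per-residue BSA reaches half the interface total, and its
  relative location `(i − 1)/(L − 1)` for a protein of length *L*.
- **First/last translated interfaces**: the interfaces exposing the most
  N-terminal and most C-terminal interface residues, compared through
  `relative translational distance = (f_last − f_first)/L` and
  `relative size difference = (BSA_first − BSA_last)/(BSA_first + BSA_last)`.
- **Assembly-onset mapping**: onsets (minus 30 residues for the ribosome
  exit tunnel) map to the nearest interface midpoint; nearest-homomeric
  mappings are discarded.
- **Assembly order**: greedy agglomeration of subunits by largest gained
  pairwise BSA (interface-size additivity), normalised per interface to a
  0–1 scale; steps ≤ 0.5 are "early".
- **Inference**: Wilcoxon rank-sum/signed-rank tests with effect size
  r = |Z|/√n, Dunn's test with Holm–Bonferroni correction, Fisher's exact
  test with sample odds ratio, stratum-preserving bootstrap (10⁴
  resamples, add-one finite-sampling correction) and 68% Jeffreys binomial
  intervals.

A synthetic-data module generates coarse-grained bead complexes with
planned contact windows and statistical cohorts with known effect sizes,
so every stage is tested against ground truth without downloads.

## Worked example

The numbered drivers under `analysis/` run the pipeline end to end on
synthetic structures and cohorts, writing tables to `results/`:

```bash
python analysis/01_simulate_complexes.py   # bead complexes -> scratch/structures
python analysis/02_interface_metrics.py    # interfaces.tsv, subunit_profiles.tsv
python analysis/03_assembly_order.py       # assembly_order.tsv
python analysis/04_map_onsets.py           # cohort.tsv, onset_mapping.tsv
python analysis/05_statistics.py           # statistics.tsv
```

The final driver prints, among others:

```
early/late contingency: OR 1.70, early fraction 67% (68% Jeffreys CI 63.8-69.5%), p 1.74e-04
sequential-assembly subunits with a larger first interface: 5/5
cohort first vs last: first larger in 63% (68% Jeffreys CI 59-66%), one-tailed signed-rank p 2.74e-04, effect size r 0.28
operon-stratified bootstrap: mean difference 145 Å², p 0.0024 (10000 resamples, strata {'False': 72, 'True': 78})
```

Reading: interfaces that form cotranslationally are 1.7× as likely to sit
in the early half of predicted assembly pathways (67% early); all five
published yeast subunits known to assemble sequentially have a larger
first translated interface; and on a synthetic cohort generated with the
first interface 15% larger on average, the pipeline recovers the effect
(first larger in 63% of subunits, signed-rank p < 10⁻³), including within
operon strata under bootstrap resampling.

There is also a thin CLI over the same functions
(`cotasm interfaces|profile|assembly-order|map-onsets|compare|bootstrap|simulate --help`).

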