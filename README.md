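# gilakit

Desk-reproducible analysis toolkit for a morphologically plastic freshwater
fish species complex (the roundtail chub group, *Gila robusta* / *G. nigra* /
*G. intermedia*). The package bundles:

- **`gilakit.simulate`** — synthetic data generators with known truth: a
  four-taxon quartet simulator with an admixture pulse, a multi-population
  RADseq genotype simulator with negative-binomial depth and dropout, a
  clock-like mtDNA alignment simulator on random ultrametric trees, and a
  morphometric specimen simulator in the overlapping-variation regime.
- **`gilakit.morphometrics`** — "times-into" standardization (reference
  length ÷ measurement), character diagnosability from [min, max] range
  envelopes, and proportion-based assignment of specimens to name-bearing
  type series.
- **`gilakit.rad_filtering`** — the RAD locus-retention cascade: MNP
  decomposition, indel removal, mtDNA-contig exclusion, an 85% missingness
  rule, read-level haplotype collapsing with error pruning and paralog
  flagging, and a joint depth/completeness rule (depth ≥ 20 in ≥ 14 of 19
  individuals by default).
- **`gilakit.introgression`** — frequency-weighted ABBA–BABA counting,
  Patterson's D, the F_d admixture-fraction estimator, and delete-one block
  jackknife significance with the |Z| ≥ 3 convention.
- **`gilakit.phylo`** — uncorrected p-distances with pairwise deletion,
  neighbor joining, outgroup rooting, monophyly checks, Robinson–Foulds
  concordance, and a strict molecular clock (2 %/Myr pairwise by default).
- **`gilakit.reference_tables`** — packaged CSV transcriptions of the
  published type-series ranges, fresh-material ranges, and the 17-specimen
  assignment-proportion table.
- **`gilakit.pipeline`** + the **`gilakit`** command-line tool — end-to-end
  orchestration from a single seed, with byte-deterministic artifacts.

## Worked example

Simulate 5,000 quartet loci with a 30% admixture pulse from P3 into P2, then
run the ABBA–BABA analysis, and average the packaged per-specimen assignment
proportions:

```python
from gilakit import introgression, morphometrics, reference_tables, simulate

cfg = simulate.SimConfig(n_loci=5000, admixture_pulses=[("P3", "P2", 0.3)], seed=1)
data = simulate.simulate_quartet_loci(cfg)
seqs, locus_ids = data.concatenated()
table = introgression.run_abba_baba(
    seqs, [("P1", "P2", "P3", "O")],
    guide_tree=cfg.population_tree, locus_ids=locus_ids,
)
print(table.round(4).to_string(index=False))

averages = morphometrics.average_assignment_proportions(reference_tables.assignment_results())
print(averages)
```

Output:

```text
       quartet   ABBA  BABA      D    F_d     SE       Z   p  significant reason
((P1,P2),P3);O 4083.0  32.0 0.9844 0.2703 0.0026 374.746 0.0         True

{'intermedia': 0.49, 'nigra': 0.61, 'robusta': 0.29, 'unclassified': 0.19}
```

The F_d estimate (0.270) recovers the simulated admixture fraction (0.3)
within the generator's expected bias (see `docs/methods.md`), and the
assignment-table averages match the published row means.

The same analyses are available from the command line, e.g.:

```bash
$ gilakit phylo clock --distance 0.02
1.000000
$ gilakit pipeline run --seed 7 --out pipeline_out
report written to pipeline_out/report.json (5 sections)
```

## Layout

```
src/gilakit/          the package (data tables under src/gilakit/data/)
tests/                unit, property and acceptance tests
scripts/acceptance.py headline-quantity report
docs/methods.md       methods note: models, parameter choices, limitations
```
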