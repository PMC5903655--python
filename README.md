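# hbcube

Genotype-hypercube analysis of hemoglobin function. The package takes raw
assay curves (O2-saturation curves, stopped-flow absorbance traces,
autoxidation absorbance-ratio series) through fitted functional parameters
(P50/n50 by Hill-equation regression, monoexponential rates) to combinatorial
genotype-phenotype statistics: mutational pathway trajectories over the 2^k
genotype lattice, per-background effect sizes, double-mutant-cycle epistasis,
reversion symmetry, parsimony polarization of substitutions on a species
tree, and pleiotropy correlation screens. A seeded synthetic-data generator
with planted ground truth makes every stage testable offline.

## Modules

| module | purpose |
|---|---|
| `hbcube.oxyfit` | Hill-equation fitting of O2-saturation curves; P50/n50, replicate summaries, anion-sensitivity indices |
| `hbcube.kinetics` | monoexponential fitting of dissociation traces (s^-1) and autoxidation ratio series (h^-1) |
| `hbcube.landscape` | hypercube/pathway enumeration, per-background mutation effects, largest-effect ranking, reversion symmetry, double-mutant cycles, exact interaction decomposition |
| `hbcube.ancestry` | Fitch (minimum-change) parsimony with exact MPR state sets, branch substitution assignment, ancestral genotypes |
| `hbcube.pleiotropy` | Pearson correlation screens between trait changes under explicit pairing conventions |
| `hbcube.simulate` | seeded generators for curves, traces, landscapes and trees, each with recorded truth |
| `hbcube.io` / `hbcube.pipeline` / `hbcube.cli` | CSV/newick/YAML I/O, stage orchestration, text report, CLI |
| `hbcube.datasets` | bundled reference fixture: transcribed published goose-hemoglobin summary tables plus an emulated Anserinae tree/site matrix |

## CLI

```bash
# generate synthetic data for every stage (bit-reproducible per seed)
hbcube simulate --seed 1 --out-dir out/sim

# fit stages
hbcube fit-equilibria out/sim/saturation.csv --out-dir out/fits
hbcube fit-kinetics out/sim/traces.csv --out-dir out/fits

# landscape / ancestry / pleiotropy on a genotype-phenotype table
hbcube pathways --config config.yaml --out-dir out
hbcube cycles   --config config.yaml --out-dir out
hbcube ancestry --tree tree.nwk --matrix states.csv --ancestor-node AncAnser --out-dir out
hbcube pleiotropy --config config.yaml --out-dir out

# everything configured, plus the text report
hbcube run-all --config config.yaml --out-dir out
```

A config is a YAML file validated against `hbcube.io.PipelineConfig`
(unknown keys rejected), e.g.

```yaml
sites:
  - [alpha18, G, S]
  - [alpha63, A, V]
  - [alpha119, P, A]
gp_csv: gp.csv
tree_newick: tree.nwk
site_matrix_csv: states.csv
ancestor_node: AncAnser
seed: 1
```

CSV dialects are documented in `hbcube/io.py`; every output file carries a
`#` header with the package version, seed and config hash. Logs go to
stderr, results to files.

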