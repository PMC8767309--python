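# bondprop

Detect functionally coupled (allosteric-candidate) sites on proteins by
propagating a perturbation through an energy-weighted atomistic graph.

A protein structure is converted into a graph whose nodes are atoms and
whose edges are covalent and non-covalent bonds weighted by interaction
energies (kJ/mol).  A set of source edges — the bonds of the orthosteric
residues, or the ligand–protein contact bonds of an orthosteric ligand —
perturbs the graph, and every other bond receives a propensity via the
edge-to-edge transfer matrix `M = ½·W·Bᵀ·L⁺·B` (computed with one sparse
Laplacian solve per source edge, never a dense pseudoinverse).  Because
propensities decay with distance from the source, each bond and residue
is ranked against its distance peers by linear quantile regression of
log-propensity on distance, producing quantile scores in [0, 1].  A
candidate site is then evaluated with six statistical measures: mean
bond/residue score against a 95% bootstrap confidence interval from
1,000 structurally matched surrogate sites, the proportions of bonds and
residues scoring above 0.95 (expected 5%), and mean bond/residue scores
against a user-supplied reference ensemble (expected 0.5).  Structures
with several candidate sites are judged on the per-measure averages.

## Layout

| module | role |
|---|---|
| `bondprop.structure_io` | PDB parsing, cleaning, protonation checks, site resolution, score-annotated PDB output |
| `bondprop.graph_construction` | residue-template covalent bonds, hydrogen-bond / hydrophobic / electrostatic / π-stacking detection, graph assembly, incidence matrix |
| `bondprop.propensity_core` | weighted Laplacian, solve-based propensities, normalization, residue propensities, source distances |
| `bondprop.quantile_scoring` | quantile-regression models over a p-grid, intrinsic and reference quantile scores |
| `bondprop.site_statistics` | six measures, surrogate-site sampler, percentile bootstrap, verdicts, multi-site averaging |
| `bondprop.pipeline` | single-run and batch orchestration |
| `bondprop.fixtures` | synthetic peptides, random weighted graphs, planted-decay samples (no downloads needed) |

All energy constants and geometric detection criteria live in
`EnergyParameters` and can be overridden from YAML.

## CLI

```sh
# generate a synthetic structure to play with
bondprop fixtures --kind mini_pdb --sequence AAGAAAGAAAGAAAAA --with-ligand --out demo/

# score a candidate site (perturbation source = orthosteric residues)
bondprop run demo/fixture.pdb \
    --orthosteric-residues A:14,A:15 \
    --allosteric-residues A:2,A:3 \
    --out demo/results/

# batch over a YAML manifest of run configs
bondprop batch manifest.yaml --out batch.csv
```

`run` writes per-bond and per-residue CSVs, the fitted quantile-model
tables, a PDB whose B-factor column carries residue scores ×100 (for
coloring in a viewer), and a measure report with verdicts.  Condition
flags (`--source ligand|residues`, `--remove-allosteric-ligand`,
`--keep-ligands`, seeds) make every run regime explicit and
reproducible.

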