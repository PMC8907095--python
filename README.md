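# ensdock

Ensemble-docking benchmarking pipeline: discretize a conformational
trajectory with multiple clustering schemes, aggregate per-conformation
docking scores into per-ligand predictions, and evaluate the resulting rank
orderings against experimental affinities with Kendall's τ and a
random-permutation null.

Because docking engines and MD packages are external, the package ships a
first-class synthetic-data module: toy proteins, Markov-switching
conformational trajectories (metastable states deforming a binding loop,
optional rigid-body jitter), and docking-score matrices with a planted
affinity ordering. Every downstream stage is testable offline.

## Modules

| module                | contents |
|-----------------------|----------|
| `ensdock.synthetic`   | toy protein builder, Markov trajectory simulator, planted-affinity score matrices, pseudo-experimental pIC50 tables |
| `ensdock.structures`  | trajectory data model, multi-model PDB I/O, backbone / Cα / binding-atom selections, Kabsch superposition, pairwise RMSD, RMSF, position featurization, subsampling |
| `ensdock.dimred`      | PCA and TICA with variance cutoffs, cross-validated VAMP2 feature-set scoring |
| `ensdock.clustering`  | k-means (+ medoid frame extraction), GROMOS neighbor clustering, cutoff selection criteria, cluster populations, centroid export |
| `ensdock.ranking`     | minimum / average / population-weighted score aggregation, tie-aware Kendall τ, analytic and simulated permutation nulls, Pearson diagnostic, τ evaluation grid |
| `ensdock.pipeline` / `ensdock.cli` | end-to-end orchestration from a YAML config |

## CLI

```bash
ensdock synthesize --config config.yaml        # write synthetic inputs
ensdock cluster    --config config.yaml        # clustering stage only
ensdock rank       --config config.yaml        # clustering + τ grid
ensdock all        --config config.yaml --seed 7   # full run + report
```

A minimal config:

```yaml
seed: 7
output_dir: run_out
trajectory_synthetic:
  n_residues: 24
  n_states: 3
  n_frames: 900
  state_displacement: 4.0
  noise_sigma: 0.08
  rigid_body_jitter: true
feature_sets: [backbone, binding-atoms]
lag: 1
variance_cutoff: 0.95
k: 3
gromos_cutoffs: [0.2, 0.3, 0.5, 0.8, 1.2]
stride: 3
scores_synthetic: {n_ligands: 50, noise_sigma: 0.0}
null_samples: 10000
```

Instead of the synthetic blocks you may point `trajectory_path` /
`ligand_pose_path` at multi-model PDB files, `scores_path` at per-method
score CSVs (header `ligand_id,<conf ids...>`, empty cell = missing), and
`affinity_path` at a `ligand_id,pIC50` CSV.

The run writes per-method centroid PDBs and manifests, cluster label CSVs,
a pairwise-RMSD matrix over {reference + centroids}, per-method RMSF, the
τ grid (`tau_grid.csv`, rows = Minimum / W. Avg. / Avg., columns = method),
the permutation-null summary, and a checksummed run manifest.

## Conventions

- Docking scores: lower = better. pIC50: higher = better. τ is computed
  between best-first rankings, so perfect prediction gives τ = +1.
- Coordinates in Å; residue numbers 1-based; atom indices 0-based.
- Missing scores are explicit mask entries, never numeric placeholders;
  the weighted average renormalizes populations over each ligand's present
  scores.
- All generators and stages are deterministic functions of config + seed.
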