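# coldadapt

Comparative conformational-ensemble analysis for cold- versus warm-adapted
enzymes.

Psychrophilic (cold-adapted) enzymes are often hypothesised to buy catalytic
activity at low temperature with increased structural flexibility, yet for
many homolog pairs the static crystal structures alone cannot explain the
adaptive traits. The standard way to probe this is to compare replicated
molecular-dynamics ensembles of the cold and warm homologs. `coldadapt`
packages that comparison pipeline for structural bioinformaticians:

* **Sampling assessment** — are independent replicates exploring the same
  conformational space? Quantified by the root mean square inner product
  (RMSIP) of the essential PCA subspaces, and by the Jensen–Shannon
  divergence (JSD) between full ensemble distributions via clustering-based
  (CES) and dimensionality-reduction-based (DRES) ensemble similarity.
* **Flexibility profiling** — per-residue Cα root mean square fluctuation
  (RMSF) over non-overlapping time windows, averaged across replicates, plus
  the covariance-matrix trace as a scalar flexibility metric and the
  cold-minus-warm difference profile.
* **Protein structure networks (PSN)** — residues as nodes, noncovalent
  interactions (hydrophobic, hydrogen bond, salt bridge) as edges weighted
  by *persistence*, the fraction of frames in which the geometric criterion
  holds; hub detection, interaction clusters, and edge-level network
  comparison between the two enzymes.
* **Sequence-level classification** — given a multiple sequence alignment
  with per-sequence temperature labels, classify each substitution between
  the two target homologs as a cold-adaptation *candidate* (each thermal
  group conserves a different residue), *drift*, or *indeterminate*, and
  tabulate amino-acid composition differences.

Because published MD trajectories are rarely deposited, the package ships a
first-class synthetic-data module that generates ensembles and alignments
with known ground truth (harmonic fluctuations with prescribed covariance,
multi-basin mixtures with prescribed weights, toy peptides with interactions
planted at an exact persistence, alignments with planted candidate columns),
so every stage has a parameter-recovery test.

## Core quantities

For PCA eigenvector sets {vᵢ}, {wⱼ} the subspace overlap over the first
D = 10 components is

    RMSIP = sqrt( (1/D) Σᵢ Σⱼ (vᵢ·wⱼ)² )  ∈ [0, 1]

with 1 for completely overlapping sampling and 0 for uncorrelated sampling.
CES pools all frames, clusters the pairwise Cα-RMSD matrix with affinity
propagation (similarity −RMSD, preference −10), turns each ensemble into a
cluster-population vector P, and reports the discrete JSD in nats,

    JSD(P, Q) = H((P+Q)/2) − H(P)/2 − H(Q)/2  ∈ [0, ln 2 ≈ 0.693],

0 for identical distributions and ln 2 for non-overlapping ones. DRES
embeds the same RMSD matrix into 6 dimensions with stochastic proximity
embedding, estimates each ensemble's density by Gaussian KDE and evaluates
the same divergence by Monte-Carlo sampling. PSN edges use the standard
cutoffs: side-chain COM < 0.65 nm (hydrophobic), donor–acceptor ≤ 0.35 nm
with donor–H–acceptor angle > 120° (H-bond), charged-group COM < 0.45 nm
(salt bridge); a hub is a node with more than four edges. All coordinates
are handled in nm.

## Worked example

Generate a synthetic two-system fixture and run the pipeline:

```
$ coldadapt simulate --outdir demo --seed 1 --n-frames 150 --n-residues 15
fixture written to demo (config.yaml + PDB ensembles)
$ coldadapt run --config demo/config.yaml
{
  "config_hash": "0a7c14b31959",
  "seed": 1,
  "stages": {
    "similarity": {
      "cold:rmsip": "demo/results/similarity_cold_rmsip.png",
      "cold:ces": "demo/results/similarity_cold_ces.png",
      ...
    },
    "flexibility": {
      "cold:rmsf": "demo/results/rmsf_cold.tsv",
      "warm:rmsf": "demo/results/rmsf_warm.tsv",
      "rmsf_difference": "demo/results/rmsf_difference_cold_minus_warm.tsv"
    }
  }
}
$ head -4 demo/results/rmsf_cold.tsv
# coldadapt config=0a7c14b31959 seed=1
residue rmsf_nm sd_nm
1       0.04431211329233489     0.0010142380371441619
2       0.0486583407551588      0.00155629616153348
```

The "cold" system was simulated with isotropic fluctuation σ = 0.03 nm, so
its per-residue RMSF sits near the analytic value σ√3 ≈ 0.052 nm (the small
deficit is the rigid-body degrees of freedom absorbed by fitting); the `sd`
column is the across-replicate spread. From the library, the CES endpoint
behaviour on two ensembles confined to disjoint basins:

```python
>>> import numpy as np, coldadapt as ca
>>> refs = ca.make_basin_references(2, 10, separation=5.0, seed=11)
>>> spec = ca.BasinSpec(refs, [np.array([1., 0.]), np.array([0., 1.])],
...                     intra_basin_sigma=0.05, min_separation=4.0,
...                     n_frames=500, seed=7)
>>> m = ca.ces([ca.gen_basin_mixture(spec, 0), ca.gen_basin_mixture(spec, 1)])
>>> m.to_frame().round(4)
        e0      e1
e0  0.0000  0.6931
e1  0.6931  0.0000
```

0.6931 = ln 2: the two ensembles share no conformational space. Identical
ensembles give exactly 0.

## Documentation

`docs/methods.md` describes the models, the synthetic-data conditions, the
numerical choices (fitting conventions, affinity-propagation and SPE
settings, KDE bandwidth) and the known limitations.
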