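# morphorate

Branch-wise morphological diversification rates from 2-D landmark data on
time-calibrated phylogenies.

## The problem

Comparative morphologists often want to know *when* in a clade's history a
structure changed shape, and *how fast*. Given digitized outlines or fixed
landmarks for many specimens (e.g. beetle mandibles, pronota, elytra,
hindwings), a grouping of specimens into terminal taxa with known feeding
ecologies, and a dated phylogeny of those taxa, `morphorate`:

1. resamples digitized curves into equally spaced semi-landmarks and treats
   them as fixed landmarks;
2. superimposes all configurations by Generalized Procrustes Analysis (GPA)
   and projects them to the tangent space at the consensus;
3. ordinates shapes by PCA, and discriminates groups by canonical variate
   analysis (CVA) with pairwise Mahalanobis distances and confusion-matrix
   classification rates;
4. reconstructs ancestral shapes at every internal node by
   branch-length-weighted squared-change parsimony (the maximum-likelihood
   estimate under Brownian motion), and ancestral feeding types by
   Fitch/Sankoff parsimony or an equal-rates Mk model;
5. scores every branch with a **deformation ratio**

   DR = d(parent, child) / Δt,

   the morphological distance between the parent and child node shapes
   (Mahalanobis in CVA space, or Euclidean in Procrustes units) per million
   years of the branch, and every lineage with **sequential growth rates**

   SGR_i = (DR_{i+1} − DR_i) / DR_i,

   the relative change between consecutive DR values along each
   root-to-tip path.

A synthetic-data module simulates multivariate Brownian shape evolution on
dated trees (with optional branch-specific rate shifts, specimen-level
digitization noise, and a Markov feeding-type character) and emits the
pipeline's own input formats with full ground truth, so every stage is
testable without external data.

## Worked example

```bash
morphorate simulate --n-tips 8 --landmarks 16 --specimens-per-tip 20 --seed 1 demo_fixture
```

writes `character.tps` (160 specimen blocks), `tree.nwk` (a dated 8-tip tree
with `[&age=...]` annotations), `groups.csv`, and `truth.json`. Then with
`demo.yaml`:

```yaml
tree_path: demo_fixture/tree.nwk
groups_path: demo_fixture/groups.csv
out_dir: demo_out
windows: [[30, 80]]
characters:
  character:
    tps_path: demo_fixture/character.tps
```

```bash
morphorate run --config demo.yaml
# artifacts written to demo_out
```

`demo_out/character/edges.csv` then holds one row per branch, e.g.

```
parent,child,parent_age,child_age,...,dt,dr_mahalanobis,dr_euclidean
Node1,Node2,150,100,...,50,0.9276,0.003299
Node2,Node3,100,50,...,50,0.8606,0.003540
Node3,T1,50,0,...,50,1.3259,0.005532
```

`dr_euclidean` is shape change in Procrustes units per Ma; `dr_mahalanobis`
is the same change measured in the CVA space of the terminal specimens
(within-group standard deviations per Ma), which is the variant used for
step charts by default. `character/sgr.csv` lists the relative DR changes
along each lineage, and `sgr_window_summary.csv` reports, per age window,
the spread (max − min) of SGR values per character — the quantity used to
compare how strongly different characters respond in the same interval.
Classification quality is summarized in
`character/confusion_summary.json` (resubstitution and leave-one-out rates,
both labeled). Each stage is also available separately
(`morphorate prep/ordinate/ancestral/deform/report`) on the previous
stage's CSV outputs.

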