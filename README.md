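# histoslice

Deformable registration of stand-alone 2D histology sections to 3D
post-mortem MRI volumes through two photographic intermediaries (tissue
block photographs and whole brain-slab photographs).

The pipeline has four stages, all driven by the modality-independent
neighbourhood descriptor (MIND) similarity:

1. **Stage 1** — histology → block photo: rotation search, similarity
   and affine steps (bounded derivative-free optimisation), then a dense
   displacement field refined by diffusion-regularised Gauss–Newton
   iterations over a resolution pyramid.
2. **Stage 2** — block photo → brain-slab photo: sampling sites are
   detected automatically by registering serial slab photographs,
   binarizing and XOR-ing them (components smaller than 1 cm² or
   narrower than 4 mm are discarded); the block is initialised at every
   site over a rotation/translation grid, the best candidates refined,
   and the winner fine-tuned with the stage-1 sequence under automatic
   10 %-threshold masks.
3. **Stage 3** — slab photo → MRI volume: the photo is embedded in 3D
   and optimised in four steps (rigid search inside a configurable slab
   prior with interim candidate ranking, 3D affine, in-plane
   control-point displacements, full 3D control-point displacements with
   Gaussian-RBF interpolation).
4. **Stage 4** — direct histology → MRI refinement: the composed
   stage 1–3 mapping is reparameterised as a light chain (sparse 3D
   control-point field + rigid), then fine-tuned with the perpendicular
   travel bounded to ±2 mm; non-linear steps are switchable.

Everything is built on a transformation-chain engine (`histoslice.core`)
with composable, serialisable parameterised transforms, per-point
Jacobians and polar-decomposition vector reorientation, and a synthetic
phantom generator (`histoslice.synthetic`) that makes every stage
testable without external data, including analytically defined planar and
quadratic slice surfaces with exact ground truth and the MRE/MCD
evaluation metrics.

## Tests

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` reproduces the published accuracy bounds on
desk-scale synthetic phantoms (sub-voxel slice-to-volume curvature
recovery, rigid planar accuracy, stage-2 site matching, stage-1
deformable accuracy) and takes several minutes; the remaining files are
fast unit/property tests.

## Command line

```sh
histoslice-reg phantom --seed 0 --out-dir phantom/          # synthetic data
histoslice-reg sites phantom/slab_intact.png phantom/slab_cut.png \
    --mm-per-pixel 0.2 --out sites.json
histoslice-reg stage1 HIST.png BLOCK.png --histology-mm 0.05 \
    --block-mm 0.2 --out stage1_chain.json
histoslice-reg stage2 BLOCK.png SLAB.png --sites sites.json \
    --block-mm 0.2 --slab-mm 0.2 --out stage2_chain.json
histoslice-reg stage3 SLAB.png MRI.nii --photo-mm 0.2 --out stage3_chain.json
histoslice-reg stage4 HIST.png MRI.nii --histology-mm 0.05 \
    --init-chain composed.json --out stage4_chain.json
histoslice-reg compose stage1_chain.json stage2_chain.json \
    stage3_chain.json --out composed.json
```

Each stage accepts `--config stage.yaml` (keys mirror the stage config
dataclasses; shipped defaults equal the published typical values) and
exits with code 2 on degenerate inputs. Chains are versioned JSON files
with bit-exact parameter round-trip; FLIRT 4×4 matrices can be appended
at composition time (`compose --flirt ... --flirt-source ... --flirt-target ...`).

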