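# coroseg

Automatic segmentation of the **aortic root** and **coronary arteries** from
CTA-like volumes, and automatic screening of the segmented geometry for
**anomalous aortic origin of a coronary artery (AAOCA)**.

AAOCA is a rare congenital variant in which a coronary ostium sits in an
abnormal position on the aorta; it is a leading cause of sudden cardiac death
in young athletes and is easy to miss on routine reads. `coroseg` implements
a two-part workflow for contrast-enhanced CT angiography:

1. **Segmentation** — three identical 2D attention U-Nets, one per
   orthogonal plane (axial, sagittal, coronal), each mapping a slice to
   per-class probability maps for background, aortic root and coronary
   artery. The three single-view predictions are reassembled into 3D and
   **integrated by voxel-wise averaging** (a 2D+ approach: 2D training
   speed, 3D-coherent output). Per-class thresholds fitted on a validation
   set binarize the averaged maps; voxels above both thresholds go to the
   class with the larger probability.
2. **Classification** — a geometric decision on the fused label volume:
   - *Connectivity rule*: a normal coronary tree forms exactly **two** 3D
     connected components (left and right trunks). One component (shared
     ostium) or three (separately arising left anterior descending and
     circumflex) is called anomalous outright.
   - *Origin angle*: with exactly two components, each trunk's ostium is
     the coronary voxel closest to the aorta. Both ostia are projected onto
     the axial plane halfway between their Z coordinates, and the angle α
     between the two centroid→ostium directions at the aortic centroid is
     thresholded by a decision stump (α < θ ⇒ anomalous; reference θ = 73°
     from clinical data). Anomalous origin angles cluster near 30°
     (quartiles 20–46°), normal ones near 135° (121–154°).

Because clinical CTA datasets are private, the package ships a **synthetic
vascular phantom generator**: a bright aortic cylinder plus one to three
thinner coronary tubes leaving its surface at controlled azimuths, with
contrast-lumen vs soft-tissue Hounsfield statistics and additive noise. Every
anatomical variant of the classifier's taxonomy (normal, close ostia, shared
ostium, three trunks, retroaortic) can be generated with known ground truth,
so the whole pipeline is trainable and testable at desk scale.

The neural-network engine (2D convolutions, max pooling, additive attention
gates, Adam, binary cross-entropy, backpropagation) is implemented in the
package on top of numpy and runs on a single CPU.

## Worked example

Classify phantom geometries with a stump fitted on synthetic training data:

```python
from coroseg import PhantomSpec, generate_phantom, classify_geometry, StumpModel

# a normal anatomy: two trunks 135 degrees apart
_, labels, truth = generate_phantom(
    PhantomSpec(variant="normal", ostium_azimuths_deg=[0.0, 135.0], noise_seed=9)
)
print(classify_geometry(labels, StumpModel(threshold_deg=73.0)).to_dict())
```

```
{'label': 'normal', 'reason': 'angle', 'n_components': 2,
 'alpha_deg': 135.889..., 'warnings': []}
```

The measured origin angle (135.9°) recovers the generative separation (135°)
to within the voxel quantization of the 64³ grid, and 135.9° ≥ 73° reads as
a normal origin. A shared-ostium phantom instead short-circuits at the
connectivity rule:

```python
_, labels, _ = generate_phantom(PhantomSpec(variant="anomalous_shared", noise_seed=12))
print(classify_geometry(labels).to_dict())
```

```
{'label': 'anomalous', 'reason': 'connectivity', 'n_components': 1,
 'alpha_deg': None, 'warnings': []}
```

End-to-end training on phantoms (three plane models, threshold calibration,
fusion) runs in ~10 minutes on one CPU:

```python
from coroseg.pipeline import segmentation_experiment
res = segmentation_experiment(n_train=30, n_val=5, n_test=5, seed=1)
print(res["mean_dsc_aorta"], res["mean_dsc_coronary"])
```

typically reaching Dice scores around 0.99 (aortic root) and 0.9 (coronary)
on held-out phantoms — phantom anatomy is far simpler than clinical CTA, so
these numbers characterise the pipeline's plumbing, not clinical accuracy.

There is also a CLI covering each stage (`coroseg generate / preprocess /
train / calibrate / predict / classify / evaluate / run`); for example

```bash
coroseg generate --n 10 --seed 0 --out data/
coroseg classify data/phantom_000_lab.nii.gz --threshold-deg 73
```

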