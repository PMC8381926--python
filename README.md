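# ctmotion

CT-based implant micromotion analysis. `ctmotion` measures the rigid
migration of an acetabular cup relative to the pelvic bone between two CT
examinations, in six degrees of freedom, using either tantalum fiducial
beads or the bone surface anatomy for the bone registration. It ships with
the companion statistics (double-examination precision with a small-sample
Student-t coverage factor), DLP-based effective-dose estimation, and a
digital hip phantom that generates paired volumes with exactly known
ground-truth motion — so every pipeline stage is testable without patient
data.

## How it works

1. **Segmentation** — threshold the HU volume (metal ≥ 2200 HU, bone ≥ 600
   HU by default), extract sub-voxel bead centroids as small connected
   metal components, and split them into bone vs implant beads by proximity
   to the cup.
2. **Bone registration** — either a matched-point (Kabsch/SVD) fit of the
   bone beads, or point-to-plane ICP on the sub-voxel bone isosurface
   (marching cubes), initialised by a symmetry-aware principal-axes sweep.
3. **Implant registration** — matched cup beads seed a point-to-plane ICP
   on the cup metal isosurface (thread + beads), with the bead centroids as
   annealed landmark anchors.
4. **Kinematics** — relative motion `bone⁻¹ ∘ implant`, decomposed about
   the implant centre of mass into three translations (mm) and three
   fixed-frame Cardan rotations (deg), optionally re-expressed in an
   RSA-like anatomical frame.
5. **Quality** — every registration carries a condition number (marker
   spread) and RMS mean error, gated at the conventional limits
   (CN < 100, ME < 0.30 mm); gate failures flag the result but do not
   discard it.

All world coordinates are millimetres in the scanner (DICOM/LPS) frame.
Supported volume formats: DICOM series (uncompressed explicit-VR CT
stacks), NIfTI-1, MetaImage.

## CLI

```bash
# generate a synthetic double examination with known migration
ctmotion simulate --out demo_pair --seed 1 --noise-hu 20 \
    --migration 0.5,0,0,0,0,1.0

# measure implant-vs-bone migration between two volumes
ctmotion migrate demo_pair/exam1.mha demo_pair/exam2.mha \
    --mode beads --out result.json --csv migrations.csv

# bead extraction, marker-table registration with quality gates
ctmotion segment demo_pair/exam1.mha --out beads.csv
ctmotion register demo_pair/beads.csv --structure bone

# precision over a table of double examinations; effective dose from DLP
ctmotion precision migrations.csv --out precision.csv
ctmotion dose --dlp 150

# manifest-driven batch study (YAML manifest: pairs, modes, overrides)
ctmotion study study.yaml

# reproducible end-to-end demo; verifies against its committed table
ctmotion demo --seed 1 --out demo_out
```

## Notes on scope

The pipeline analyses the acetabular cup only (no femoral stem), performs
no dose Monte-Carlo (DLP × conversion factor only), and does not handle 2-D
stereo radiographs — RSA-style marker tables are accepted directly as CSV
via `ctmotion register`.
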