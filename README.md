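# woundpatch

Design, slicing and validation of patient-specific wound-filling scaffolds
from CT-like volumes.

Volumetric-muscle-loss wounds and other deep soft-tissue defects have
irregular, patient-specific geometry. Flat manufactured sheets placed into
such a wound leave dead-space voids at the wound–material interface that
impair integration. This package implements the digital half of an
anatomically-fitted workflow: starting from a CT-like image of the wound, it
segments the cavity, designs a uniform-thickness patch that conforms to the
wound bed, slices the patch into extrusion toolpaths for a bioprinter,
quantifies geometric fidelity of a (simulated) printed part against the
design, and scores conformality — contact surface coverage and interfacial
void volume — of the placed patch.

Because real CT data cannot ship with a code repository, the package also
generates synthetic phantoms with exactly known ground truth: a limb-like
cylinder with a flat prepared wound site and an analytic crater (hemisphere
or superellipsoid), optional engineered interface voids of known volume, and
a bilateral (healthy/injured) pair for contralateral mirroring of missing
muscle volume. Every quantitative claim made by the test-suite is evaluated
against these analytic ground truths.

## Modules

| Module | Purpose |
| --- | --- |
| `core` | `VoxelVolume`, `BinaryMask`, `SurfaceMesh` primitives (world-mm voxel-center convention) |
| `io_formats` | NIfTI / NRRD volume I/O, STL meshes, G-code writing |
| `phantoms` | Analytic wound, implanted-patch and bilateral limb phantoms |
| `segmentation` | Thresholding (Otsu / fixed), connected components, cavity inversion |
| `patch_design` | Distance-transform shell offset, footprint trim, constrained smoothing, mask↔mesh |
| `contralateral` | Mirroring, boolean subtraction, exact volume-fraction mesh scaling |
| `toolpath` | Slicing: perimeters, rectilinear infill, region density modifiers, G-code + material/time estimate |
| `gauging` | Surface sampling, trimmed ICP alignment, point-to-surface deviation reports |
| `conformality` | Contact surface-area percentage, interfacial void detection, void statistics |
| `pipeline` | File-based end-to-end runner with resume and a checksum manifest |
| `cli` | `woundpatch` command-line interface over all of the above |

## Worked example

Run the whole chain — phantom, segmentation, patch design, slicing,
print-gauging and conformality — from one config:

```
$ cat demo.yaml
run_dir: /tmp/demo
phantom:
  preset: hemisphere
  spec:
    spacing: 0.7
gauge:
  samples: 5000

$ woundpatch run --config demo.yaml
pipeline artifacts in /tmp/demo
```

The run directory then contains the phantom volume (`phantom.nii`), ground
truth (`phantom.json`), segmentation masks, the designed patch
(`patch.stl`, `patch_mask.nii`), toolpaths (`patch.gcode`,
`print_estimate.json`), gauging (`gauge.json` plus CSV histograms), the
simulated implanted volume (`implanted.nii`), the conformality report
(`conform.json`) and a SHA-256 `manifest.json`. Real output from the run
above:

`conform.json` — the patch was placed unperturbed into the wound, the
implanted volume re-scanned, and contact scored as the surface-area ratio of
the patch's wound-facing surface to the wound bed over their common
footprint:

```json
{
  "sa_bottom_mm2": 1625.1806016827347,
  "sa_top_mm2": 1625.9232603244764,
  "contact_percent": 99.95432388109181,
  "n_bottom_faces": 9812,
  "n_top_faces": 9817,
  "void_set": {
    "count": 0,
    "total_volume_mm3": 0.0,
    "min_void_volume_mm3": 0.001,
    "voids": []
  }
}
```

`print_estimate.json` — volumetric bioink demand and print time for the
4 mm-thick patch at 0.16 mm layers, two perimeters, 40 % rectilinear infill:

```json
{
  "bioink_volume_ml": 5.286267822615251,
  "infill_volume_ml": 2.5000742717813633,
  "perimeter_volume_ml": 2.7081081178467827,
  "solid_volume_ml": 0.07808543298703177,
  "print_time_s": 4849.575023557318
}
```

`gauge.json` — the gauging stage perturbs the printed-part stand-in by a
known 5° / (2, 1, 0) mm pose error, re-aligns it with trimmed ICP and
reports the residual point-to-design-surface deviation:

```json
{
  "applied_perturbation": {"rotation_deg": 5.0, "translation_mm": [2.0, 1.0, 0.0]},
  "recovered_translation_mm": [-2.0089975756350604, -1.0175184084451994, 0.0101778947903437],
  "mean_abs_mm": 0.09915682797988003,
  "max_mm": 0.5132968286119706,
  "n_samples": 5000
}
```

(The residual ~0.1 mm reflects the 0.7 mm voxelization of this quick demo;
identical meshes gauge to exactly zero.)

Each stage is also available as its own subcommand (`woundpatch phantom`,
`segment`, `design`, `slice`, `gauge`, `conform`, `convert`,
`contralateral`); run `woundpatch --help` for options. Re-running `run` on
an existing directory resumes: finished stages are skipped and outputs are
bit-identical.

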