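# arcsag

Mechanical quality assurance of C-arm linear accelerators during arc
deliveries, measured with the machine's own megavoltage imager (EPID).

During a VMAT arc the multi-ton gantry, the EPID on its jointed support
arm and the two ~36 kg MLC leaf-bank carriages all flex under gravity.
`arcsag` analyses portal images of a simple five-ball-bearing phantom —
four tungsten-carbide balls rigidly mounted on the gantry head (*a*–*d*)
and one fixed at the isocentre on a couch-mounted rod (*e*) — acquired over
a full gantry rotation through an 18 × 18 cm² MLC-defined field, and
reports, per gantry angle θ relative to the gantry-zero reference:

* **EPID sag** `(e_X^θ − A·cos θ) − e_X^0` (cross-plane; in-plane with
  `B·sin θ`), where the amplitudes *A*, *B* are least-squares fits of the
  periodic signature that a set-up offset of ball *e* imprints on its
  projected track;
* **gantry sag** `⟨a,b,c,d⟩^θ − ⟨a,b,c,d⟩^0 − EPID sag^θ` per axis;
* **ΔSDD** `SDD⁰·(⟨a_X,c_X⟩^θ−⟨b_X,d_X⟩^θ)/(⟨a_X,c_X⟩^0−⟨b_X,d_X⟩^0) − SDD⁰`,
  the source-to-detector distance change from pair magnification;
* **skew** (yaw) `Ψ^θ = atan[(b_Y−a_Y)/(b_X−a_X)]^θ − atan[...]^0`;
* **tilt** (pitch/roll) from the differential apparent SDD of marker pairs
  on opposite sides of the beam axis;
* **MLC carriage sag** `⟨a,b,c,d⟩_X^θ − L_Edge^θ` (and R/G/T counterparts),
  the bulk drift of each leaf bank that per-leaf encoders cannot see.

All positions are detected with sub-pixel precision (matched filtering +
robust soft-edged disc fits for the balls; 50% penumbra crossings per leaf
row for the field edges) and scaled to the isocentre plane (SAD 1000 mm).
Summary statistics (range, between-replicate SD, CW-vs-CCW RMSD) and
TG-142 style tolerance verdicts (2 mm EPID, 1 mm gantry/MLC, 5 mm SDD)
complete the report.

A forward simulator (`arcsag.synthetic_phantom`) generates DICOM arcs of
the phantom under a parametric deformation model and doubles as the
ground-truth oracle: the analysis equations applied to its noiseless
projections reproduce the injected curves to machine precision.

## Worked example

Simulate a 37-image integrated-mode rotation of a machine with typical
gravity-driven deformations (1.0 mm in-plane EPID sag range, 0.7 mm gantry
sag, 1.7 mm SDD amplitude, 0.15° skew, 0.1° tilt, ≤ 1 mm carriage drifts,
a (0.8, −0.5) mm set-up offset of ball *e*), then analyse it:

```
arcsag simulate --config examples/simulation.yaml --out scratch/demo/arc
arcsag analyze  --input scratch/demo/arc --out scratch/demo/report
```

which prints

```
wrote 37 images and truth table to scratch/demo/arc
analyzed 37 images -> scratch/demo/report/metrics.csv; all tolerances met
```

`report/summary.json` then contains the fitted set-up offset and the
per-metric verdicts; for this machine:

```
misalignment_A_mm    0.799      (injected  0.8)
misalignment_B_mm   -0.500      (injected -0.5)
delta_sdd_mm     max_abs +1.718 vs 5.0 -> pass
epid_sag_y_mm    max_abs +1.001 vs 2.0 -> pass
gantry_sag_y_mm  max_abs +0.701 vs 1.0 -> pass
mlc_sag_L_mm     range   +0.820 vs 1.0 -> pass   (injected range 0.82)
...
```

i.e. every injected deformation is recovered at the 0.001–0.02 mm level
and judged against its mechanical tolerance.  `arcsag compare` produces
RMSD tables between runs (CW vs CCW, collimator 0 vs 90, replicates), and
`arcsag report --plots` renders per-metric curves.

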