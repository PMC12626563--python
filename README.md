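# vesselcad

Quantification of tumor–vessel involvement for pancreatic ductal
adenocarcinoma (PDAC) from co-registered 3D CT segmentation masks.

Whether a pancreatic tumor can be resected hinges on its relationship to the
five major peripancreatic vessels — celiac artery (CA), common hepatic artery
(CHA), superior mesenteric artery (SMA), portal vein (PV) and superior
mesenteric vein (SMV). Radiologists grade this by eye (NCCN abutment ≤ 180°
of circumferential contact vs. encasement > 180° or vascular deformation),
with substantial inter-observer variability. `vesselcad` computes that
assessment from segmentation masks instead: it skeletonizes each vessel,
profiles its radius and its distance to the tumor along the centerline, and
reduces the geometry to a small set of interpretable features and logistic
risk scores.

## What it computes

**14 anatomically designed tumor–vessel features** per vessel, from the masks
alone:

- `R_min, R_max, R_mean, R_range, R_std` — statistics of the inscribed
  radius sequence R<sub>n</sub> along a skeleton edge (population divisor);
- `theta_encase_deg` — the maximum fraction of a vessel cross-section's
  circumference within 3 voxels of the tumor, over all axial/coronal/sagittal
  slices, rendered in degrees;
- `D_min, D_max, D_mean, D_range, D_std, D_ratio` — statistics of
  D<sub>n</sub> = R<sub>n</sub> × (distance to tumor); `D_ratio` compares the
  mean product far from vs. near the tumor and rises under tumor-proximal
  narrowing;
- `C_area, C_length` — tumor-contact area on the vessel surface and contact
  length along the skeleton.

**Tumor morphology**: mesh surface and voxel volume, sphericity
π^⅓·(6V)^⅔ / A, compactness A/V, maximum 3D diameter, principal axis lengths
(4·√λ of the coordinate covariance) and flatness = major/medium axis (≥ 1).

**Published logistic risk scores**, shipped as a built-in model file:

    RS_deform = expit(−1.098 + 0.663·R_std − 1.086·D_max − 0.745·D_std + 2.395·D_ratio)   (standardized inputs)
    RS_tumor  = expit( 1.526 + 7.093·T_flat − 9.826·T_sphere)                              (raw scales)

**Per-vessel involvement models**: logistic regression on
{θ_encase, RS_tumor} for arteries and {θ_encase, RS_tumor, RS_deform} for
veins, with Fisher-score ranking, Wald inference and odds ratios, ROC/AUC
with DeLong confidence intervals and paired tests, McNemar and Cohen's kappa
comparisons, Hosmer–Lemeshow calibration, decision-curve net benefit, and
nomogram point tables.

**Phantoms**: digital tubes (straight/curved/Y, optional stenosis),
ellipsoidal tumors and angular wrap shells with exact geometric ground truth,
plus tabular simulation from the logistic scores — so the whole pipeline is
testable with no patient data.

## Worked example

```python
import vesselcad as vc

# synthetic scene: two vessels, tumor abutting the first, 40% stenosis
scene = vc.make_scene(n_vessels=2, stenosis=0.6, seed=7)
rows = vc.extract_case(scene.structures, case_id="demo")
for r in rows:
    if r.missing:
        continue
    a = r.anatomical
    dr = f"{a.D_ratio:.2f}" if a.D_ratio is not None else "undefined"
    print(f"{r.vessel}: theta_encase = {a.theta_encase_deg:.1f} deg, "
          f"R_mean = {a.R_mean:.2f}, R_std = {a.R_std:.2f}, "
          f"D_ratio = {dr}, C_area = {a.C_area}, C_length = {a.C_length}")
m = rows[0].morphology
print(f"tumor: volume = {m.T_volume:.0f} mm^3, sphericity = {m.T_sphere:.3f}, "
      f"flatness = {m.T_flat:.3f}")
print(f"RS_tumor = {vc.rs_tumor(m.T_flat, m.T_sphere):.3f}")
```

prints

```
CA: theta_encase = 30.0 deg, R_mean = 3.63, R_std = 0.61, D_ratio = 3.71, C_area = 1, C_length = 1
CHA: theta_encase = 0.0 deg, R_mean = 4.09, R_std = 0.19, D_ratio = undefined, C_area = 0, C_length = 0
tumor: volume = 1185 mm^3, sphericity = 0.994, flatness = 1.327
RS_tumor = 0.763
```

The tumor touches 30° of the CA circumference and barely reaches its surface
(one contact voxel); the stenosis near the tumor lowers `R_mean`, raises
`R_std` and pushes `D_ratio` well above 1 (the far/near product ratio that the
deformation score weights positively). The CHA, 15 voxels away, shows no
contact and an undefined `D_ratio` (its whole centerline lies outside the
near-tumor band, so the near-group mean does not exist; the score imputes the
neutral value 1.0 at modeling time). The moderately elongated tumor
(flatness 1.33) yields a tumor-shape risk score of 0.76.

## Command line

```bash
vesselcad extract case1.nii.gz --labels labels.json --out features.csv
vesselcad score features.csv --out scored.csv
vesselcad fit-eval scored.csv --label-col involved --out models/
vesselcad simulate --n 1000 --seed 1 --out simulated.csv
```

`labels.json` maps integer label codes to structure names, e.g.
`{"1": "tumor", "2": "PV", "3": "SMV"}`. Volumes may be NIfTI or NRRD and are
resampled to an isotropic 1 mm grid on load (so voxel-unit thresholds
coincide with millimetres).

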