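# tripoint

Landmark-based assessment of guided dental-implant placement accuracy.

Given the same anatomical landmarks digitized in a preoperative (planned,
space `P`) and a postoperative (real, space `R`) CBCT image, `tripoint`:

1. scores every landmark pair with a **triangle-congruence error** (relative
   edge-length discrepancies of the triangles each triple spans in the two
   images, plus a proportionality term),
2. iteratively eliminates the worst pair and keeps the three most mutually
   congruent pairs (the *basic triple*),
3. builds an orthonormal coordinate frame on the basic triple in each image —
   origin at the first point, X along the first edge, Y in-plane, Z normal —
   so both images land in one common system `N`,
4. reports a per-case **system error**: the residual distance between the two
   digitizations of the 4th-ranked (held-out) landmark pair after
   registration, and
5. computes **ten accuracy indicators** comparing the planned and the placed
   implant: HS (cover-screw height input), AD (angular deviation), CGD / CVD /
   CLD (coronal global, signed vertical, lateral deviation), AGD / AVD / ALD
   (same at the apex), and CRD / ARD (deviations after sliding the placed
   implant along its own axis to cancel the depth difference).

Sign convention: CVD/AVD are positive along the planned coronal→apical axis
(placed deeper than planned = positive). It is printed in every report.

A synthetic-case generator with a known ground-truth rigid transform,
configurable true implant deviations, and a heterogeneous landmark-noise
model makes the whole pipeline testable without clinical data and drives the
two factor sweeps (number of provided landmarks, landmark spread).

## Command line

```sh
# generate a synthetic case (writes case_landmarks.csv, case_implants.csv)
tripoint simulate --seed 7 --n-landmarks 8 --noise-sigma 0.1 \
    --deviation 5 0.5 1.0 --out case

# rank landmark pairs, show the basic triple and the system error
tripoint rank case_landmarks.csv

# implant endpoints expressed in the common system
tripoint register case_landmarks.csv case_implants.csv

# full JSON accuracy report (HS correction optional)
tripoint analyze case_landmarks.csv case_implants.csv --hs 0.5 --out report.json

# factor sweeps (tidy per-replicate CSV tables + printed summaries)
tripoint sweep-count  --seed 1 --noise-sigma 0.1 --replicates 100 --out counts.csv
tripoint sweep-spread --seed 1 --noise-sigma 0.1 --replicates 100 --out spread.csv
```

### File formats (CSV, UTF-8, coordinates in mm, `#` lines ignored)

- landmarks: header `label,px,py,pz,rx,ry,rz` — one landmark digitized in
  both image spaces per row;
- implants: header `role,end,x,y,z` with `role ∈ {planned, real}` and
  `end ∈ {coronal, apical}` — four rows.

## Python API

```python
from tripoint import (SyntheticConfig, generate_case, register_case,
                      compute_report)

case = generate_case(SyntheticConfig(noise_sigma=0.1, seed=1))
result = register_case(case.pairs, case.planned, case.real)
report = compute_report(result.planned_in_N, result.real_in_N,
                        system_error_mm=result.system_error_mm)
print(report.as_dict())
```

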