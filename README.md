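# nailguide

Single-view pose recovery and drill-targeting overlays for distal
interlocking of intramedullary nails.

From **one** cone-beam radiograph showing the two lens-shaped projections
of a nail's distal interlocking holes, `nailguide`:

1. detects the lens contours inside the nail silhouette and reduces each
   to a small set of significant landmarks (tips, arc apexes,
   quarter-points);
2. recovers the 6-DOF pose of the distal nail segment by matching these
   landmarks against virtual landmarks of a parametric nail model
   (damped least squares over all mirror-ambiguity branches);
3. emits per-hole guidance: two targeting ellipses for a two-ring drill
   jig plus a skin-incision landmark, drawn into the image.

No tracking or navigation hardware is modelled — only the radiograph and a
geometry configuration. A synthetic cone-beam radiograph generator
(ray-cast CSG of a cylinder pierced by two transverse hole cylinders, with
noise and ground truth) doubles as the test oracle and fixture source.

## CLI

```bash
# generate a synthetic fixture (image + ground-truth sidecar + config)
nailguide simulate --scenario mild-oblique --seed 5 --out fixture/

# one-button end-to-end run: detect -> solve -> overlay -> report
nailguide run --image fixture/image.png --config fixture/config.yaml --out run/

# individual stages
nailguide detect  --image fixture/image.png --config fixture/config.yaml --out lm.json
nailguide solve   --image fixture/image.png --config fixture/config.yaml --out sol.json
nailguide overlay --image fixture/image.png --config fixture/config.yaml \
                  --pose sol.json --out overlay.png
```

Scenarios: `aligned`, `mild-oblique`, `steep-oblique`, `one-screw-inserted`,
`shifted-frame-pair`. The run directory contains `report.json` (pose,
residuals, ambiguity branch, warnings, timings, config echo + hash),
`overlay.png` and `manifest.json`.

## Library layout

| module | contents |
|---|---|
| `nailguide.geometry` | cone-beam camera, 3-D circles, conics, exact circle projection, conic intersection |
| `nailguide.nail` | nail + hole parametrization, planar rim circles |
| `nailguide.contour` | lens contours, landmark extraction rules (conic- and polyline-based) |
| `nailguide.forward` | ray-cast radiograph renderer, analytic lens contours, pose sampling, fixture catalogue |
| `nailguide.detect` | lens region detection, subpixel edge refinement, landmark extraction, conic fitting, frame-shift estimation |
| `nailguide.solver` | closed-form circle pose, initialization, damped-least-squares 6-DOF solve, second-hole simulation |
| `nailguide.guide` | jig model, targeting overlays, alignment/clearance checks, overlay rendering |
| `nailguide.config` / `pipeline` / `cli` | configuration, end-to-end pipeline, command line |

Conventions: camera frame is right-handed with the source at the origin and
+z toward the detector; pixels are 0-based, u right / v down; lengths in
mm, angles in radians internally.

## Tests

```bash
python -m pytest tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (forward-model
oracle equivalence, degenerate-alignment invariant, parameter recovery,
ambiguity resolution, guidance closure, frame-shift correction, conic-fit
oracle) at their stated sizes; the noise-free recovery criterion is known
to exceed what the image scale supports and currently fails (see the test
docstrings). Everything else, including the unit/property suite, is green.
The suite uses only generated fixtures — no downloads, no binary assets.

## Physical limits worth knowing

- The lens exists only while the beam is within
  `atan(r_h / sqrt(R² − r_h²))` (≈ 23.6° at the default 10 mm nail with
  4 mm holes) of the hole axis; scenario sampling uses 5–20°.
- Two orthogonal holes can never both show a lens in one image; the
  two-hole solve therefore targets parallel (ML/ML or AP/AP) pairs, as
  imaged in practice. A lone visible hole yields a documented
  under-constrained error naming the free rotation direction.
- For two identical parallel holes, a single image cannot distinguish the
  two hole labels (180° nail flip symmetry).
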