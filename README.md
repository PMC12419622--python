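# arcmlc

MLC aperture conformity scoring and a dose-index panel for arc radiotherapy
plans, exercised end-to-end on a synthetic phantom — no clinical data needed.

The toolkit covers three workflows:

1. **MLC position comparison** — for every control point of an arc plan the
   zero-margin *reference* aperture is fitted to the target's beam's-eye-view
   silhouette, and the plan is scored with the intrusion-only
   *ratio of area difference*:
   `100 * sum(intrusion areas) / sum(reference open areas)`.
   A perfectly conformal plan scores 0 %, a fully blocked one 100 %; leaves
   retracted beyond the reference are neither credited nor penalized.
2. **Index comparison** — conformation number (coverage x selectivity),
   conformality index (prescription volume / target volume), homogeneity index
   (Dmax / Rx, with isodose-line normalization), and the gradient metrics
   R50% and D2cm with configurable minor-deviation thresholds
   (defaults 5.8 / 58.0).
3. **OAR dose comparison** — DVH metrics `D_xcc` (partial-volume
   interpolated) and `V_d` on arbitrary structures.

All of it runs against a built-in synthetic module: a small spherical GTV
(0.51 cc by default) expanded by directional margins into ITV and PTV,
conformal arc plans with *injected* intrusion (fixed-depth, sinusoidal, or
leaf-speed-limited), and an analytic plateau + radial-falloff dose field whose
isodose volumes have closed forms.

## CLI

```sh
# 1. build the phantom (GTV/ITV/PTV masks + volumes)
arcmlc phantom --out-dir out/phantom

# 2. generate synthetic arc plans against the ITV
arcmlc synth-plan --target out/phantom/itv.mask.gz --out out/clean.txt
arcmlc synth-plan --target out/phantom/itv.mask.gz --out out/wobble.txt \
    --intrusion sinusoidal --depth-mm 2
arcmlc synth-plan --target out/phantom/itv.mask.gz --out out/dca.txt \
    --preset conformal-arc

# 3. score plans against the zero-margin reference apertures
arcmlc compare --plan out/clean.txt --plan out/wobble.txt \
    --target out/phantom/itv.mask.gz --out-dir out/cmp

# 4. analytic dose + index panel
arcmlc synth-dose --ptv out/phantom/ptv.mask.gz --out out/dose.gz
arcmlc indices --dose out/dose.gz --target out/phantom/ptv.mask.gz \
    --oar "gtv:out/phantom/gtv.mask.gz:D0.03cc,V11.4" --out-dir out/idx

# 5. one merged markdown report
arcmlc report --compare-summary out/cmp/compare_summary.json \
    --indices-report out/idx/index_report.json --out out/report.md
```

Plans are accepted in the versioned `ARCPLAN-TEXT` dialect (see
`arcmlc/plans.py`) or as DICOM RT-PLAN (`*.dcm`); dose grids as `DOSETEXT`
gzip text or DICOM RT-DOSE. Exit codes: 0 success, 2 input error, 3 metric
undefined (errors also emitted as JSON on stderr). Outputs are byte-for-byte
reproducible for a fixed config + seed and embed a config hash for
provenance.

## Conventions

* Patient frame: +x left, +y posterior, +z superior (mm); gantry angle per
  IEC 61217 (0 deg anterior, clockwise from the couch foot), stored [0, 360).
* Leaf bands are half-open `[y_i, y_{i+1})`; `bank_a` is the negative-side
  bank; closed pairs sit at u = 0 with zero open area.
* Volume thresholds are closed (`>=`) everywhere.
* Default projection is divergent (point source at SAD = 1000 mm); parallel
  projection is available via `--projection parallel`.
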