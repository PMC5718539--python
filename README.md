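# epidiso

Automated EPID-based localization of a linac's radiation isocenter.

Monthly linac QA requires the room lasers to agree with the radiation
isocenter to within ±1 mm (TG-142).  `epidiso` implements an automated
Winston–Lutz-style procedure for this check: portal images of a cuboidal
phantom are acquired at several gantry and collimator angles, the software
finds the jaw and phantom edges, and it reports the 3-D couch shift that
places the phantom at radiation isocenter — in minutes, without film, and
independent of jaw calibration.

## The method

Each portal image shows a square open field (nominally 10×10 cm²) with the
phantom near its center.  Instead of trusting the center of the jaw
opening — jaw position indicators are only held to ±2 mm — every field
position is referenced to a **single jaw imaged twice with the collimator
rotated 180°** between exposures.  With d₁ and d₂ the distances from that
jaw's edge to the phantom center in the two images (mm at the isocenter
plane), the shift along the measured room axis is

    s_{r,i} = (d₁ − d₂) / 2

A constant jaw calibration error adds equally to d₁ and d₂ and cancels
exactly.  Pair shifts are averaged over the n gantry angles that can see
dimension r,

    S̄_r = Σᵢ s_{r,i} / n

which also averages gantry sag and rotational imperfections; the couch
shift equals S̄_r in magnitude with signs mapped to the machine's couch
convention.  Machines whose X jaws are MLC-formed (jagged edge) use only
the smooth Y2 jaw — 6 images minimum, 16 for a full cardinal-angle set;
dual-jaw machines measure one X and one Y jaw per image — 4 images
minimum, 8 full.

Edges are found with a five-stage Canny detector (Gaussian blur, Sobel
gradient, non-maximum suppression, double threshold, edge tracing) and
refined to subpixel precision as the 50%-intensity crossing averaged over
11 rays per edge.  A synthetic renderer with exact ground truth (projected
hollow cuboid, error-function penumbra, per-jaw calibration errors, noise)
and an independent star-shot analyzer close the validation loop.

## Worked example

Render a synthetic 8-image session with a known phantom offset of
(+1.2, −0.6, +0.8) mm and analyze it:

```sh
$ epidiso simulate demo/session --vendor varian --mode full --seed 42 --offset 1.2 -0.6 0.8
wrote 8 images to demo/session (truth offset (1.2, -0.6, 0.8) mm, seed 42)

$ epidiso analyze demo/session --report demo/report.txt
      lateral: S_bar =  -1.213 mm  couch shift =  -1.213 mm (n = 2)
 longitudinal: S_bar =  +0.577 mm  couch shift =  +0.577 mm (n = 4)
     vertical: S_bar =  -0.804 mm  couch shift =  -0.804 mm (n = 2)
report written to demo/report.txt
```

The reported couch shift is the move that centers the phantom: the
negative of the injected offset, recovered here to within ~0.02 mm
(1% image noise, 0.4 mm detector pitch).  `n` is the number of gantry
angles averaged per dimension — lateral from gantry 0/180, vertical from
90/270, longitudinal from all four.  The text report lists every
per-image jaw-to-phantom distance (the d values entering the pair
arithmetic) and a CSV twin feeds `epidiso trend`, which flags any stored
shift beyond the 1 mm monthly tolerance.

Other subcommands: `epidiso starshot film.tif --pixel-mm 0.2` analyses a
star-shot strip image, and `epidiso config machine.yaml` writes a
per-machine configuration template (geometry, jaw policy, per-view Canny
settings, couch sign convention).

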