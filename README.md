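# tankvision

Geometric-optics simulation of the water containers used to present visual
stimuli to small aquatic animals (zebrafish larvae and similar), and a
neural forward model showing how container optics corrupt
receptive-field-mapping and direction-selectivity experiments.

## The problem

An animal immersed in a water container does not see the stimulus the
experimenter displays.  At every air/wall/water interface light refracts
(Snell's law, `n_i sin ε_i = n_t sin ε_t`) and splits its power (Fresnel
equations; unpolarised reflectance `R_eff = (R_s + R_p)/2`, transmittance
`T = 1 − R_eff`).  Three consequences matter in practice:

* **Total internal reflection (TIR).**  Seen from underwater, the entire
  above-surface world compresses into *Snell's window*, elevations above
  `90° − arcsin(1/n) ≈ 41.4°`.  In a flat dish, rays entering the vertical
  side wall at incidence below ~62° strike the horizontal surfaces beyond
  the critical angle (`arcsin(1/1.333) = 48.6°`) and bounce repeatedly
  between the water surface and the dish bottom, so the equatorial visual
  field shows vertically mirrored copies of the stimulus.  Every mirror
  bounce flips perceived *vertical* motion while leaving horizontal motion
  intact.
* **Partial reflection.**  Even a filled spherical container returns ~4% of
  a near-normal beam from its far wall (polystyrene dish: ~5%), projecting
  a faint point-symmetric copy of a monocular stimulus onto the
  non-stimulated eye.
* **Occlusion and the free surface.**  The microscope objective, holder and
  water meniscus block or distort parts of the visual field; a low water
  level puts the mirror-like free surface right inside the field of view.

`tankvision` traces rays backward from the animal's eye through a container
scene (flat Petri-dish lid, cylinder, glass bulb, each with measured
dimensions and refractive indices), renders equirectangular panoramas of the
perceived stimulus with per-direction power/TIR/parity bookkeeping, and then
drives synthetic retinotopic, direction-tuned neurons with that *perceived*
stimulus to predict experimental artifacts: bipartite (double) receptive
fields under low water, suppressed vertical direction-selective cells in
flat dishes, and reversed retinotopy driven by the contralateral reflection.

## Worked example

Power accounting for a near-normal beam crossing the glass bulb
(air → glass n=1.473 → water → far wall):

```bash
$ tankvision reflectance --wall borosilicate
```

reports the labelled beam powers (percent of source): `R1 = 3.66`
(entry-face reflection), `T1 = 96.34`, `T2 = 96.10`, `T3 = 95.86` (the beam
entering the wall, the water, and the far wall), weak internal reflections
`R2 = 0.24`, `R3 = 0.23`, `R5 = 0.24`, far-face reflection `R4 = 3.51` with
its re-entry `T5 = 3.50`, and `contralateral_reflection = 0.0374`: ~4% of
the stimulus light returns toward the other eye.

Perceived-motion transport in the Petri-dish lid:

```bash
$ tankvision motion-field --preset petri_lid --direction 90 --resolution 180x90
{"inversion_fraction": 0.332, "consistency_index": 0.335}
$ tankvision motion-field --preset petri_lid --direction 0 --resolution 180x90
{"inversion_fraction": 0.0, "consistency_index": 1.0}
```

A third of the (solid-angle-weighted) field sees *upward* stimulus motion as
*downward*, while horizontal motion is delivered perfectly — which is why
vertically tuned direction-selective neurons disappear from recordings made
in flat dishes.

Receptive-field mapping of a 400-neuron synthetic population through bulb
optics (water 1 cm above the animal vs. filled to the rim):

```bash
$ tankvision rf-sim --preset bulb_10cm_low --n 400 --seed 1
{"n_neurons": 400, "n_with_rf": 198, "n_bipartite": 10, "n_small_rf": 198}
$ tankvision rf-sim --preset bulb_8cm_full --n 400 --seed 1
{"n_neurons": 400, "n_with_rf": 200, "n_bipartite": 0, "n_small_rf": 200}
```

With the free water surface in view, neurons whose receptive fields straddle
the waterline acquire a second, vertically aligned stimulus-response patch
(the TIR mirror image); filling the bulb removes the artifact completely.

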