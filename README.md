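# morphofold

Tools for deciphering how the folding pattern of a closed epithelial
surface encodes the 3D shape it deploys into when inflated.

Some insect organs — the horn of a rhinoceros beetle is the canonical
case — form as a densely folded epithelial sheet that balloons out under
hemolymph pressure within hours, with essentially no growth during
deployment. The final shape is therefore *written into the folds*:
circumferential pleats store elongation, furrow patterns biased to one
side store bending, and specific 2D furrow motifs (concentric
semicircles, parallel lines) store branches and overhangs. `morphofold`
provides the computational toolkit for reading that code on triangle
meshes:

* **Unfolding simulation** — quasi-static inflation of a folded mesh:
  edge-spring membrane energy + weak crease regularization − pressure ×
  volume, minimized monotonically (own L-BFGS / steepest descent) while
  recording a snapshot trajectory.
* **Correspondence analysis** — connectivity is frozen, so regions
  outlined on the inflated mesh are "rewound" to the folded state by
  vertex identity.
* **Furrow visualization** — signed normal distance to the HC-modified
  Laplacian smoothed mesh, classified into ridges / valleys / neutral
  and exportable as PLY vertex colors (red / blue / gray).
* **Furrow removal analysis** — smooth the furrows of a chosen region of
  the folded mesh, inflate both variants identically, and compare
  morphometrics to isolate that region's contribution.
* **Morphometrics** — extents, marched-slab centerlines, signed sagittal
  bend angle, super-level-set branch counts, groove opening angles, apex
  offset, discrete (angle-deficit) Gaussian curvature.
* **Synthetic fixtures** — seeded generators of folded meshes emulating
  each primordium structure (accordion stalk, ventrally biased base,
  furrowed-disk cone models, Yoshimura zigzag tube, branch-forming dome
  cap), since real primordium scans are not publicly deposited.

Everything runs in a fixed anatomical frame: +Z proximodistal (distal
up), +Y dorsal, +X left. See `docs/methods.md` for the model, its
assumptions, and all numerical choices.

## Worked example: the six-fold stalk

The elongating middle region of the horn primordium behaves like an
accordion: pleats parallel to the circumference store meridional arc.
The bundled stalk fixture has 12 pleats of slant length 0.25 folded into
an axial height of 1.0, so the stored meridian is 2 × 12 × 0.25 = 6.0 —
six times the folded height.

```python
from morphofold import shapes, inflate, MaterialParams
from morphofold.morphometry import axial_extent
from morphofold.mesh import surface_area

folded, masks = shapes.make_accordion_cylinder()   # 12 pleats, slant 0.25
traj = inflate(folded, MaterialParams())           # pressure ratio 0.05
unfolded = traj.final_mesh

print(f"folded height    {axial_extent(folded):.3f}")
print(f"unfolded height  {axial_extent(unfolded):.3f}")
print(f"elongation       {axial_extent(unfolded) / axial_extent(folded):.2f}x")
print(f"area change      {surface_area(unfolded) / surface_area(folded) - 1:+.1%}")
```

prints

```
folded height    1.000
unfolded height  5.540
elongation       5.54x
area change      +3.9%
```

The pleats deploy almost completely — the stalk elongates ~5.5× while
the membrane itself stretches only ~4% in area; the missing fraction of
the ideal 6× is the residual crimp that hoop inextensibility leaves in
any bellows. The same pipeline drives the other analyses: inflating the
ventrally furrow-biased base tips it ~+22° dorsally (smoothing the
furrows first drops that to ~+9°), the concentric-semicircle disk
inflates into an oblique overhanging cone while full circles give an
upright one, and the dome cap fixture deploys four branches, two of
which vanish when its medial furrow patches are flattened.

The same steps are scriptable from the shell:

```sh
morphofold generate accordion_cylinder stalk.ply --masks-dir masks/
morphofold inflate stalk.ply unfolded.ply
morphofold measure unfolded.ply --report report.json
morphofold visualize stalk.ply furrows.ply      # ridge/valley colored PLY
morphofold remove stalk.ply --region masks/ventral.txt --report removal.json
```

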