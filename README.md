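# asamesh

Chemo-mechanical simulation of **anchored self-assembly** (ASA) — the
process by which a contractile endothelial-cell/fibrin sheet, cast over an
array of rigid micropillars, pulls itself into an organized microvascular
mesh — together with the image-quantification statistics used to score the
vascularization such meshes produce in vivo.

The package is aimed at tissue-engineering and mechanobiology groups who
design micropillar substrates (pillar size, spacing, substrate area) and
want to (i) predict the contracted mesh morphology and its stress state
before fabricating anything, and (ii) quantify vessel density, perfusion
and mural-cell coverage from stained cross-sections in a reproducible,
scriptable way.

## The model

The tissue sheet is a compressible Neo-Hookean membrane with an active
contractile term acting in parallel, under plane stress.  Per unit
reference volume,

```
U(F) = μ/2 (I_C − 3 − 2 ln J) + λ/2 (ln J)² + U_a(J, η)
```

with `F` the deformation gradient, `C = FᵀF`, `I_C = tr C`, `J = det F`,
and `μ = E/2(1+ν)`, `λ = Eν/((1+ν)(1−2ν))` from the matrix moduli
(defaults `E = 1.9`, `ν = 0.3`, stresses in mN μm⁻²).  The activation
`η ∈ [0, 1]` scales the active part through the chemo-mechanical stiffness
`β = 2 mN μm⁻²`.  Two active terms are available:

* `active_pressure` (default): `U_a = η β (J − 1)`, i.e. a constant
  isotropic active Cauchy tension `σ_a = η β I` — activation drives
  contraction;
* `as_printed`: `U_a = η β (ln J)²`, which is minimised at `J = 1` and
  therefore predicts zero contraction at every activation level (kept as a
  documented reference form; see `docs/methods.md`).

The domain — the substrate rectangle minus the pillar disks — is meshed
with linear triangles (a symmetric-by-construction cross-split grid with
circle snapping), the out-of-plane stretch `λ₃` is condensed out per
element by a scalar plane-stress solve, the micropillars act through a
smoothed frictionless penalty on nodal gaps, and the activation is ramped
`0 → 1` with a Newton/line-search solve at each step.

The image module implements the standard vessel statistics on channel
masks: vessel density (lumens mm⁻²), vessel area %, blood-perfusion %
(perfused-marker ∧ vessel pixels over vessel pixels), and perivascular-cell
coverage (% of lumens whose perimeter ring is α-SMA-positive).  A seeded
synthetic-scene generator provides ground-truthed images for validation.

## Worked example

Design arithmetic for the 1 × 1 cm substrate (16 × 16 pillars of 400 μm
diameter, 200 μm height, 200 μm interval):

```python
>>> import asamesh as am
>>> layout = am.build_square_layout(16, 16, 400.0, 200.0,
...                                 (0, 0, 10_000.0, 10_000.0), height=200.0)
>>> round(am.interspace_volume(layout), 2)      # μL between the pillars
13.57
>>> am.seeded_cell_count(13.57, 8.0e6).two_sig  # cells at 8e6 per mL
110000.0
```

Contraction of the 4 × 4 benchmark and its contact morphology:

```python
>>> layout = am.build_square_layout(4, 4, 400.0, 200.0)
>>> domain = am.triangulate_domain(layout, 50.0)
>>> states = am.solve_contraction(domain, layout, am.MaterialParams())
>>> round(states[-1].max_displacement, 1)       # μm, at full activation
96.5
>>> rep = am.pillar_contact_report(states[-1], layout)
>>> rep.table.groupby("classification")["active_nodes"].sum()
classification
boundary    132
inner        16
```

The mesh hangs almost entirely from the 12 boundary pillars; the inner
pillars retain only a grazing wrap carrying < 1% of the contact load (see
`docs/methods.md` for why it does not vanish exactly).  Mid-strut
("contracted") regions carry ~1.9× the junction-region stress.

The same pipeline is scriptable from the shell:

```sh
asamesh design   --config run.toml --out design/
asamesh simulate --config run.toml --out run/
asamesh synth-image --out scene/ --seed 7
asamesh quantify scene/scene.tiff --pixel-size-um 2.0
```

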