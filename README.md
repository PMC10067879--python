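# ivusffr — virtual fractional flow reserve from IVUS pullbacks

`ivusffr` computes a virtual fractional flow reserve (vFFR) for a coronary
artery from an intravascular-ultrasound (IVUS) pullback: per-frame lumen
contours become a 1-D centerline model `A(s)`, stenoses are detected against
a robust healthy-lumen reference, side-branch flow losses are estimated with
bifurcation fractal laws, and a reduced-order pressure solver marches the
hyperemic pressure field from the aortic inlet to the distal vessel. The
distal value against the 0.80 cutoff gives the ischemia call that normally
requires an invasive pressure wire.

It is written for researchers in image-based computational hemodynamics who
want a fast, fully testable desk-scale implementation of this pipeline —
including the pieces that make it checkable without clinical data: a
synthetic vessel/IVUS phantom generator with exact ground truth, an
explicit-branch comparator model, an adversarial (segmentor/critic)
segmentation network, and the evaluation statistics of the field
(Bland–Altman, ROC/AUC, Dice/Jaccard/Hausdorff, 2×2 diagnostics).

## The model in brief

Pressure is marched proximal → distal at piecewise-constant flow `Q`:

    ΔP = ∫ 8πμ Q / A(s)² ds              (viscous, every segment)
       + (ρK_t/2)(Q/A_d)²(A_d/A_s − 1)²   (expansion loss, once per stenosis)

with `A_s` the throat and `A_d` the recovery-point area, μ = 0.0035 Pa·s,
ρ = 1050 kg/m³. At each labeled bifurcation the flow drops by the fractal
law's main-branch share — for the HK law, `Q_mb = Q_mov (D_mb/D_mov)^{7/3}`,
with the unimaged side-branch diameter solving
`D_mov^{7/3} = D_mb^{7/3} + D_sb^{7/3}` (Murray's cube law and Finet's
linear law, `D_mov = 0.678(D_mb + D_sb)`, are also available). Then
`vFFR(s) = P(s)/Pa`, with `Pa` the mean aortic pressure and the inlet
velocity taken from TIMI frame counting times a hyperemia factor.

See `docs/methods.md` for assumptions, parameter defaults, the comparator's
outflow closure, and what the phantoms do and do not establish.

## Worked example

`examples/fractal_laws.py` — how the three laws split 2 mL/s at a junction
where the pullback shows a 3.0 mm mother and a 2.4 mm main branch:

    law       D_sb (mm)  Q_mb (mL/s)  Q_sb (mL/s)  main share
    hk            2.038        1.188        0.812      59.4%
    murray        2.362        1.024        0.976      51.2%
    finet         2.025        1.085        0.915      54.2%

The HK law keeps the most flow in the main branch (smallest exponent), so
it predicts the largest distal pressure loss of the three.

`examples/full_pipeline.py` — phantom pullback → segmentation → detection →
vFFR, plus the explicit-branch comparator on the same vessel:

    detected stenoses:  1
      throat 22.0 mm, %DS 59.8
    distal vFFR (HK single-tube):   0.828
    distal vFFR (explicit branch):  0.828
    ischemic at 0.80 threshold:     False

The programmed lesion was 60 %DS at 22 mm: the detector recovered it, and
the fast single-tube method agrees with the explicitly branched network to
three decimals on this vessel. Other scripts in `examples/` cover the
Poiseuille closed-form check, stenosis detection under noise, the 20-vessel
method-agreement study (Pearson r = 0.998, mean |Δ| = 0.008) and the
adversarial-training overfit run.

A thin CLI wraps the same functions: `ivus-ffr phantom make`,
`ivus-ffr segan train|infer`, `ivus-ffr reconstruct`, `ivus-ffr detect`,
`ivus-ffr ffr compute|compare`, `ivus-ffr run`.

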