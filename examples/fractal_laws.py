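"""The three bifurcation fractal laws side by side.

Given the mother-vessel diameter and the main-branch diameter measured on
the IVUS pullback, each law implies a side-branch diameter and a flow split.
The HK law (exponent 7/3) sends more flow down the main branch than
Murray's cube law; Finet's linear law sits apart with its fixed 0.678
coefficient.
"""

from ivusffr.fractal import LAWS, infer_side_branch_diameter, junction_flow_split

d_mov, d_mb, q_mov = 3.0, 2.4, 2.0  # mm, mm, mL/s

print(f"mother D = {d_mov} mm, main branch D = {d_mb} mm, mother flow = {q_mov} mL/s\n")
print(f"{'law':8s} {'D_sb (mm)':>10s} {'Q_mb (mL/s)':>12s} {'Q_sb (mL/s)':>12s} {'main share':>11s}")
for law in ("hk", "murray", "finet"):
    d_sb = infer_side_branch_diameter(d_mov, d_mb, law)
    jf = junction_flow_split(q_mov, d_mov, d_mb, law)
    print(f"{law:8s} {d_sb:10.3f} {jf.q_mb:12.3f} {jf.q_sb:12.3f} {jf.q_mb / q_mov:10.1%}")

print("\nsymmetric solutions for D_mov = 3 mm (D_mb = D_sb):")
for law in ("hk", "murray", "finet"):
    print(f"  {law:8s} {LAWS[law].symmetric_daughter(3.0):.3f} mm")
print("Each triplet satisfies its law exactly; flow conservation is exact.")
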