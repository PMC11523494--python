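"""Wear a synthetic molar progressively and watch the metrics respond.

Worn molars have lower, rounder, flatter cusps: DNE, RFI, OPCR and 3D
surface area fall while PCV (sky exposure) rises.
"""

import molartopo as mt

base = mt.taubin_smooth(
    mt.make_molar(mt.cusped_molar_spec(seed=5, grid_n=48)), 0.9, -0.95, 10)
cfg = mt.TopoConfig()

print(f"{'wear':>5} {'DNE':>8} {'RFI':>8} {'OPCR':>7} {'SA3D':>7} {'PCV':>7}")
for wear in (0.0, 0.2, 0.4):
    r = mt.compute_all(mt.apply_wear(base, wear), cfg)
    print(f"{wear:5.1f} {r.dne_total:8.2f} {r.rfi:8.4f} {r.opcr:7.1f} "
          f"{r.sa3d:7.3f} {r.pcv:7.4f}")
print("down, down, down, down, up: the topographic signature of wear")
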