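"""Trabecular morphometry on analytic phantoms.

Each phantom carries its analytic reference in ``metadata``, so every line
printed here is a direct accuracy check of the index implementations:
BV/TV against the sphere volume, Tb.Th/Tb.Sp against plate dimensions, the
structure model index against its plate/rod/sphere limits, the degree of
anisotropy against isotropic and layered microstructures, and the
plate-model Tb.N relation evaluated on literature-style VOI inputs.
"""
from carposim import microct_morphometry as mm
from carposim.synthetic_data import phantom

sphere = phantom("sphere", {"size": 32, "radius": 12})
print(f"sphere BV/TV: {mm.bvtv(sphere):5.2f} %  (analytic {sphere.metadata['BVTV_ref_percent']:.2f} %)")

plates = phantom("plate", {"size": 64, "thickness": 8, "gap": 24})
tbth, tbsp = mm.tbth_tbsp(plates, periodic=True)
print(f"plate Tb.Th: {tbth:6.1f} um (built {plates.metadata['TbTh_ref_um']:.0f} um), "
      f"Tb.Sp: {tbsp:6.1f} um (built {plates.metadata['TbSp_ref_um']:.0f} um)")

for shape, params, ref in (
    ("plate", {"size": 48, "thickness": 8, "gap": 40}, 0.0),
    ("rod", {"size": 49, "diameter": 14}, 3.0),
    ("sphere", {"size": 48, "radius": 16}, 4.0),
):
    print(f"SMI of an ideal {shape:6s}: {mm.smi(phantom(shape, params)):5.2f}  (limit {ref:.0f})")

iso = phantom("isotropic_spheres", {"size": 64}, seed=3)
print(f"DA of an isotropic packing: {mm.degree_of_anisotropy(iso):.3f}  (0 = isotropy)")
print(f"DA of parallel plates:      {mm.degree_of_anisotropy(phantom('plate', {'size': 64})):.3f}")

# plate-model trabecular number from (BV/TV, Tb.Th) pairs, per mm
for bvtv_pct, tbth_um in ((40.76, 309.44), (35.4, 199.89)):
    print(f"Tb.N(BV/TV={bvtv_pct} %, Tb.Th={tbth_um} um) = {mm.tbn(bvtv_pct, tbth_um):.2f} /mm")

wedge = phantom("wedge_layer", {"size": 80, "t0": 6, "t1": 18})
mean, lo, hi = mm.cartilage_thickness(wedge)
print(f"wedge cartilage thickness: mean {mean:.0f} um, min {lo:.0f} um, max {hi:.0f} um")
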