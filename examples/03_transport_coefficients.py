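"""From gap geometry to membrane transport coefficients.

Computes the filtration coefficient L_p and diffusion membrane coefficient
C_M across vessel calibers, plus the gap Peclet number for a 100 Pa
transmembrane pressure drop.
"""

from endfeet import (
    ARTERIAL_GAP_FIT,
    FluidProperties,
    GapGeometry,
    eval_gap_fraction_fit,
    filtration_coefficient,
    membrane_diffusion_coefficient,
    peclet_number,
    renkin_hindrance,
    sheath_geometry_from_lumen,
)

water = FluidProperties(mu=0.7e-3, D=1e-9)

print("r_v um  r_o um  h_ES um  phi_g     L_p m/(Pa s)  C_M 1/m")
for r_v in (1.5, 2.0, 3.0, 6.0, 10.0):
    geo = sheath_geometry_from_lumen(r_v)
    r_o = min(max(geo.r_o_um, 2.5), 15.0)  # clamp into the fit range
    phi = eval_gap_fraction_fit(r_o, ARTERIAL_GAP_FIT)
    gap = GapGeometry(d_g_nm=20.0, l_g_um=geo.l_g_um, h_ES_um=geo.h_ES_um)
    lp = filtration_coefficient(phi, gap, water)
    cm = membrane_diffusion_coefficient(phi, gap)
    print(f"{r_v:5.1f} {geo.r_o_um:7.2f} {geo.h_ES_um:8.2f}  {phi:.5f}  "
          f"{lp:12.3e}  {cm:8.1f}")

pe = peclet_number(100.0, GapGeometry(d_g_nm=20.0, l_g_um=1.0), water)
print(f"\ngap Peclet number at 100 Pa: {pe:.2e}  (diffusion dominates, Pe << 1)")
print(f"hindrance for a solute 1/10 of the gap width: {renkin_hindrance(0.1):.3f}")

# capillaries are the most permeable (L_p ~ 2e-10 m/(Pa s), C_M ~ 4-6e3 1/m);
# large arterioles, with thicker sheaths and smaller gap fractions, are
# roughly an order of magnitude tighter.
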