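"""Tissue optical properties of the five-layer head model.

Builds the bundled per-tissue, per-wavelength table (absorption mu_a,
reduced scattering mu_s', anisotropy g, refractive index n, all in mm^-1)
and shows the un-reduction mu_s = mu_s'/(1-g) used by the physically
interpreted scattering mode.
"""

from nirsim import build_tissue_table, mus_from_reduced
from nirsim.volumes import TISSUE_NAMES

table = build_tissue_table()

print("tissue            wl[nm]  mu_a[/mm]  mu_s'[/mm]   g      n")
for code in range(1, 6):
    for wl in (690, 780, 800, 830):
        p = table.get(code, wl)
        print(f"{TISSUE_NAMES[code]:<16}  {wl:>5}   {p.mu_a:<9.4f}  "
              f"{p.mu_s_reduced:<9.3f}  {p.g_hg:.2f}  {p.n_refr:.2f}")

p = table.get("scalp", 800)
mu_s = mus_from_reduced(p.mu_s_reduced, p.g_hg)
print(f"\nScalp at 800 nm: mu_s' = {p.mu_s_reduced} /mm with g = {p.g_hg}")
print(f"un-reduced scattering rate mu_s = mu_s'/(1-g) = {mu_s:.2f} /mm")
print("-> 'as-paper' transport scatters at mu_s'; 'physical' mode at mu_s.")
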