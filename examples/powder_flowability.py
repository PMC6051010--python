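"""Flow indices, repose angle, size moments and microsphere loading.

Computes the standard powder characterisation set: Hausner ratio and
Carr's index from replicate bulk/tapped densities, the static angle of
repose from a pile silhouette, volume-moment diameters and specific
surface area from a size distribution, and the microsphere load from a
counting-chamber calibration.
"""

from pelletcoat import powder
from pelletcoat.synthetic import gen_pile_silhouette, gen_size_distribution

# flow indices from replicate densities (free-flowing carrier pellets)
pellets = powder.DensitySet(bulk_g_cm3=[0.68, 0.69, 0.70],
                            tapped_g_cm3=[0.73, 0.74, 0.75])
flow = powder.replicate_flow_indices(pellets)
print(f"Hausner ratio {flow.hausner:.3f} ± {flow.hausner_sd:.3f}, "
      f"Carr's index {flow.carr_pct:.1f} ± {flow.carr_sd:.1f} % "
      f"-> {flow.classification}")

# angle of repose from a jittered pile silhouette of known angle
mask, truth = gen_pile_silhouette(20.9, base_width_px=300, noise_px=1.0, seed=1)
angle = powder.angle_of_repose(mask)
print(f"angle of repose {angle:.1f} deg (truth {truth['angle_deg']} deg)")

# size moments of a log-normal microsphere distribution
dist = gen_size_distribution(median_um=4.5, gsd=1.3)
print(f"D4,3 = {powder.d43(dist):.2f} um, D3,2 = {powder.d32(dist):.2f} um, "
      f"SSA = {powder.ssa(dist, 1.461):.3f} m2/g at true density 1.461 g/cm3")

# loading from a counting-chamber calibration
curve = powder.fit_calibration([10, 100, 250, 500, 750],
                               [32, 310, 770, 1540, 2310])
conc = powder.concentration_from_count(curve, 865.0)
load = powder.loading(conc, dispersion_volume_mL=10.0, pellet_mass_g=0.1)
print(f"inverted concentration {conc:.0f} ug/mL -> load {load:.1f} mg/g, "
      f"load yield {powder.load_yield(load, 30.0):.1f} % of the 30 mg/g target")
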