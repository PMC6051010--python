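"""Release profiles, f2 similarity and microsphere detachment.

Builds two first-order-with-burst release profiles, corrects sampled
aliquot concentrations to cumulative release, compares the profiles
with the similarity factor f2, and tracks microsphere detachment from
coated pellets over reciprocating-cylinder dips.
"""

import numpy as np

from pelletcoat import dissolution as ds
from pelletcoat.synthetic import gen_release_profile

times = np.array([5, 10, 15, 30, 45, 60, 90, 120], dtype=float)

before = gen_release_profile(times, f_burst=15, k_per_min=0.03, plateau=65,
                             noise_sd=1.0, seed=10)
after = gen_release_profile(times, f_burst=22, k_per_min=0.035, plateau=60,
                            noise_sd=1.0, seed=11)

value = ds.f2(before, after)
print(f"f2(before coating, after coating) = {value:.2f} "
      f"-> {ds.classify_similarity(value)}")
# f2 = 100 means identical profiles; 50 is the conventional similarity
# boundary, so values just below it indicate a modest burst-release shift.

# cumulative release from sampled aliquots (paddle vessel, replacement)
conc = np.array([0.002, 0.005, 0.008, 0.010, 0.011])  # mg/mL
profile = ds.cumulative_release(conc, times_min=[5, 15, 30, 60, 120],
                                vessel_volume_mL=900, aliquot_volume_mL=10,
                                dose_mg=12, replacement=True)
print("cumulative release (%):",
      np.round(profile.cumulative_pct, 1).tolist())

# detachment over dips: counts of newly detached microspheres per sample
detach = ds.detachment_profile(
    counts_per_dip=[420, 260, 150, 80, 45, 25, 12, 5, 2, 1],
    total_load_count=1000,
)
for dip, pct in zip(detach.dips, detach.detached_pct):
    print(f"  dip {dip:2d}: {pct:5.1f} % detached")
# rapid early detachment reflects the fast-dissolving polymer film
# releasing the microspheres within the first few dips.
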