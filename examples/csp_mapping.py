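"""Map a phosphate-style binding site from chemical-shift perturbations.

Simulates HSQC tables for a 40-residue helix under two buffer conditions with
a 6-residue binding patch perturbed by (0.03 ppm 1H, 0.20 ppm 15N), computes
the combined perturbation delta = sqrt(ddH^2 + (ddN/5)^2), tiers residues at
the inclusive 0.015 / 0.020 ppm thresholds, and shows that the hits form a
spatially compact patch.
"""

import numpy as np

from hbondnmr import csp
from hbondnmr.synthdata import make_ideal_helix, simulate_csp_pair

model, _ = make_ideal_helix(40)
patch = [10, 11, 12, 13, 14, 15]
ref, perturbed, truth = simulate_csp_pair(model, patch, noise_sd_ppm=0.002, seed=3)

result = csp.compute_csp(perturbed, ref)
moderate_plus, strong = csp.perturbed_residues(result.records)
print(f"residues compared: {len(result.records)}")
print(f"delta >= 0.015 ppm (moderate+): {moderate_plus}")
print(f"delta >= 0.020 ppm (strong):    {strong}")

_, extent = csp.patch_compactness(strong, model)
rng = np.random.default_rng(0)
random_extents = [
    csp.patch_compactness(list(rng.choice(np.arange(1, 41), 6, replace=False)), model)[1]
    for _ in range(500)
]
print(f"max C-alpha spread of hits: {extent:.1f} A")
print(f"median spread of random 6-residue sets: {np.median(random_extents):.1f} A")
print("-> the perturbed residues cluster on a contiguous surface, as a real")
print("   binding site would, rather than scattering over the structure")
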