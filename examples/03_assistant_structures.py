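"""Derive the six assistant structures AS1-AS6 around a phantom PTV.

The preliminary structure is the 40% isodose of a parallel-opposed
setup-beam dose; ring shells at 0.5-1.5 cm (0.5 cm steps) and 1.5-4.5 cm
(1 cm steps) then split it into six disjoint shells used to control the
dose fall-off during optimization.
"""

from eulplan import (
    build_phantom,
    generate_assistant_structures,
    preliminary_as,
    simulate_ap_pa_dose,
)

masks = build_phantom(seed=0)
dose = simulate_ap_pa_dose(masks, rx_gy=59.4)
prelim = preliminary_as(dose, masks["body"], rx_gy=59.4)
asset = generate_assistant_structures(masks["PTV"], prelim)
asset.validate(masks["PTV"])

print(f"preliminary AS: {prelim.n_voxels} voxels ({prelim.volume_cm3:.0f} cm3)")
for name, mask in asset.as_dict().items():
    print(f"{name}: {mask.n_voxels:6d} voxels  ({mask.volume_cm3:8.1f} cm3)")

# The six structures are pairwise disjoint and none touches the PTV
# expanded by 0.5 cm (validate() would raise otherwise).
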