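"""Predict achievable organ mean doses from geometry with the shipped models.

The published bladder and rectum models (a = 1) map an organ's equivalent
uniform length (EUL, the mean distance of its voxels to the PTV, in cm) to
the gEUD (here: mean dose) a good plan achieves for it.
"""

from eulplan import load_published, predict_eud

for organ in ("bladder", "rectum"):
    model = load_published(organ, a=1)
    print(f"{organ}: EUD = {model.intercept_gy:.2f} "
          f"{model.slope_gy_per_cm:+.2f} * EUL   (n={model.n}, R2={model.r2:.2f})")
    for eul_cm in (0.0, 1.0, 2.0, 3.0):
        print(f"  EUL = {eul_cm:.1f} cm -> predicted EUD = "
              f"{predict_eud(model, eul_cm):.2f} Gy")

# An organ touching the target (EUL = 0) is predicted to receive the
# intercept; every centimetre of separation spares |slope| gray of mean dose.
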