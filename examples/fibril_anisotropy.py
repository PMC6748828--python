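"""Texture anisotropy of a synthetic fibril array, plus the per-cell score.

Generates oriented textures of increasing coherence (stand-ins for cortical
microtubule images), measures their nematic orientation/anisotropy, and
shows the per-cell normalisation applied to extreme anisotropy readings.
"""

from wallmech.morphometrics import (nematic_orientation_anisotropy,
                                    normalized_cell_anisotropy)
from wallmech.synthetic import make_fibril_texture

print("coherence   est. angle (deg)   anisotropy")
for coherence in (0.0, 0.25, 0.5, 0.75, 1.0):
    img, truth = make_fibril_texture(angle=30.0, coherence=coherence,
                                     noise_sd=0.05, seed=1)
    score = nematic_orientation_anisotropy(img)
    print(f"{coherence:9.2f}   {score.angle:16.2f}   {score.anisotropy:.3f}")

print()
print("The generator lays fibrils at 30 degrees; the estimator recovers the")
print("angle once the texture is coherent, and the anisotropy (eigenvalue")
print("difference of the gradient nematic tensor, 0 = random, 1 = parallel)")
print("rises monotonically with coherence.")
print()
a_max, a_min = 0.3, 0.1
print(f"per-cell normalisation (Amax={a_max}, Amin={a_min}): "
      f"{normalized_cell_anisotropy(a_max, a_min):.2f}")
print("equal extremes (0.25, 0.25) ->",
      normalized_cell_anisotropy(0.25, 0.25))
print("zero minimum   (0.3, 0)     ->",
      normalized_cell_anisotropy(0.3, 0.0))
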