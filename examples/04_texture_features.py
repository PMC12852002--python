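"""Extract the 70 gray-level texture features from a spectrogram image.

GLCM/GLRLM features are averaged over the four directions; GLSZM and GLDM
are direction-free.
"""

import numpy as np

from pcgstack import extract_texture_features
from pcgstack.gammatone import gammatonegram_image
from pcgstack.simulate import SimulationConfig, SubjectEffects, simulate_recording
from pcgstack.preprocess import preprocess_recording

cfg = SimulationConfig(duration_s=5.0, seed=6)
rec = preprocess_recording(simulate_recording(1, SubjectEffects(), cfg, seed=7))
img = gammatonegram_image(rec.samples, rec.fs, out_shape=(64, 64))

features = extract_texture_features(img, ng=32)
print(f"{len(features)} features; a few examples:")
for name in ("glcm_contrast", "glcm_joint_entropy", "glrlm_run_percentage",
             "glszm_zone_entropy", "gldm_dependence_entropy"):
    print(f"  {name:28s} = {features[name]:.4f}")
# Higher joint/zone entropies mean a more heterogeneous spectrogram;
# run percentage near 1 means mostly very short constant-gray runs.
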