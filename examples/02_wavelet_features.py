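"""Three-level wavelet decomposition of one denoised phantom.

Shows the subband pyramid a 256x256 slice decomposes into, the energy
split between approximation and detail subbands, and the 1024-entry
feature vector the cascade feeds to PPCA.
"""

import numpy as np

from pathobrain.preprocessing import wiener_filter
from pathobrain.synthetic import PhantomSpec, generate_dataset
from pathobrain.wavelet import extract_features, wavedec2

images, labels = generate_dataset(PhantomSpec(n_images=1, seed=0))
img = wiener_filter(images[0])

res = wavedec2(img, "haar", levels=3)
print(f"decomposition of a 256x256 slice: {res.n_subbands} subbands")
for lev, (lh, hl, hh) in enumerate(res.details, start=1):
    print(f"  level {lev}: LH/HL/HH of shape {lh.shape}")
print(f"  level 3 approximation (LL): {res.approx.shape}")

total = np.sum(img**2)
print(f"energy in the deepest LL subband: "
      f"{np.sum(res.approx**2) / total:.1%} of the image energy")

feats = extract_features(img, "haar", levels=3)
print(f"feature vector length: {feats.shape[0]} (= 32 x 32)")
print("The LL subband concentrates the coarse anatomy; its flattened "
      "coefficients are the primary features of the classifier.")
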