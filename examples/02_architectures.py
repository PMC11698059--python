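"""Build the two segmentation architectures and audit them.

The V-Net (three pooling levels) maps a 7-channel, 800-sample window (40 s
at 20 Hz) to per-timestep probabilities over 7 behaviors through 15
convolutional layers; the U-Net (four levels) maps a 6-channel, 224-sample
window to 6 classes through 23.  The printed census counts every layer that
performs a learned convolution, including up-convolutions and the
segmentation head; each output row is a probability distribution (softmax),
so the per-timestep sums are exactly 1.
"""

import numpy as np

from ethoseg import ArchitectureSpec, build_model

for family, ws, nb_desc, nb_beh in (("vnet", 800, 7, 7), ("unet", 224, 6, 6)):
    spec = ArchitectureSpec(family, ws=ws, nb_desc=nb_desc,
                            nb_behaviors=nb_beh, depth=32)
    model = build_model(spec, seed=0)
    x = np.random.default_rng(0).normal(size=(1, nb_desc, ws)).astype("f4")
    probs = model.predict_proba(x)
    n_params = sum(p.value.size for p in model.parameters())
    print(f"{family.upper():<5} ws={ws:<4} {nb_desc} channels -> "
          f"{nb_beh} classes | conv layers: {model.conv_layer_count:>2} | "
          f"output {probs.shape[1]}x{probs.shape[2]} | "
          f"{n_params:,} weights | "
          f"prob sum at t=100: {probs[0, 100].sum():.9f}")
    print(f"      parameter groups: {', '.join(model.groups)}")
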