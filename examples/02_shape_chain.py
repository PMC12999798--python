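"""Walk the tensor shape chain of the classifier architectures.

Builds the backbone on the canonical 96x112x96 grid, derives a feature
extractor, assembles the multiclass model, and prints every contracted
tensor shape along the way.
"""

import numpy as np

from fdgpet.nets import (CANONICAL_GRID, build_backbone,
                         build_feature_extractor, build_multiclass_model,
                         make_model_spec)

spec = make_model_spec("AD-HC_suvr", grid=CANONICAL_GRID)
backbone = build_backbone(spec, seed=0)
x = np.random.default_rng(0).standard_normal(
    (1, 1, *CANONICAL_GRID)).astype(np.float32)

features = backbone.features(x)
print(f"input grid            : {CANONICAL_GRID}")
print(f"pre-pooling features  : {features.shape[1:]}   (128 x 6 x 7 x 6)")
print(f"binary logits         : {backbone(x).shape[1:]}  (128 -> 2 linear)")

extractor = build_feature_extractor(backbone, seed=1)
print(f"extractor output      : {extractor(x).shape[1:]}   (128 x 3 x 3 x 3)")

extractors = [build_feature_extractor(backbone, seed=i) for i in range(6)]
multiclass = build_multiclass_model(extractors, seed=0)
multiclass.set_training(False)
logits = multiclass(x, x)
print(f"concatenated features : {multiclass._concat.shape[1:]}   (768 x 3 x 3 x 3)")
print(f"multiclass logits     : {logits.shape[1:]}  (768 -> 384 -> 50 -> 3)")
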