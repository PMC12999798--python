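"""Model architectures: binary backbone, feature extractor, multiclass head.

The backbone is a small 3D CNN: five sequential convolution stages
(kernel 3, stride schedule (2,2,2,2,1), each followed by instance
normalization and ReLU) ending at 128 channels, a multi-branch dilated
"context" module that preserves shape while aggregating multi-scale
spatial context, global average pooling, and a final 128 -> 2 linear
layer.  On the canonical 96x112x96 grid (2 mm MNI-like) the feature map
entering pooling is 128 x (6, 7, 6).

A feature extractor is a trained backbone truncated after the context
module plus one fresh 3x3x3 stride-2 convolution to 128 channels
(per-axis padding 1 on even axes, 0 on odd, so 6x7x6 -> 3x3x3).  The
multiclass model concatenates six extractor outputs (three fed the SUVR
image, three the SRP image) to 768 x 3 x 3 x 3, pools to a 768-vector and
applies linear layers 768 -> 384 -> 50 -> 3 with dropout (rate 0.5)
after the 384 and 50 layers; the three logits are AD, DLB, Mixed.

Weight initialization is He throughout; a previously trained bundle can
optionally stand in for all layers except the final linear, which is
always He-initialized fresh.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from . import nn
from .io import ModelBundle

CANONICAL_GRID = (96, 112, 96)
DEFAULT_CHANNELS = (16, 32, 64, 128, 128)
DEFAULT_STRIDES = (2, 2, 2, 2, 1)
DEFAULT_DILATIONS = (1, 2, 4)
EXTRACTOR_CHANNELS = 128
HEAD_DIMS = (384, 50)
DROPOUT_RATE = 0.5

# model vocabulary: name -> (class tuple, image types consumed)
MODEL_TABLE = {
    "AD-HC_suvr": (("AD", "HC"), ("suvr",)),
    "DLB-HC_suvr": (("DLB", "HC"), ("suvr",)),
    "Mixed-HC_suvr": (("Mixed", "HC"), ("suvr",)),
    "AD-HC_srp": (("AD", "HC"), ("srp",)),
    "DLB-HC_srp": (("DLB", "HC"), ("srp",)),
    "Mixed-HC_srp": (("Mixed", "HC"), ("srp",)),
    "AD-Mixed_suvr": (("AD", "Mixed"), ("suvr",)),
    "AD-DLB-Mixed_suvr_srp": (("AD", "DLB", "Mixed"), ("suvr", "srp")),
}

BINARY_MODEL_NAMES = tuple(n for n in MODEL_TABLE if n != "AD-DLB-Mixed_suvr_srp")
MULTICLASS_MODEL_NAME = "AD-DLB-Mixed_suvr_srp"

# fixed extractor order feeding the multiclass model
EXTRACTOR_ORDER = ("AD-HC_suvr", "DLB-HC_suvr", "Mixed-HC_suvr",
                   "AD-HC_srp", "DLB-HC_srp", "Mixed-HC_srp")


def make_model_spec(name: str, grid=CANONICAL_GRID, channels=DEFAULT_CHANNELS,
                    strides=DEFAULT_STRIDES, dilations=DEFAULT_DILATIONS) -> dict:
    """JSON-able architecture + task description for one model."""
    if name not in MODEL_TABLE:
        raise ValueError(f"unknown model name {name!r}; one of {sorted(MODEL_TABLE)}")
    classes, image_types = MODEL_TABLE[name]
    return {
        "name": name,
        "classes": list(classes),
        "image_types": list(image_types),
        "kind": "multiclass" if name == MULTICLASS_MODEL_NAME else "binary",
        "grid": list(grid),
        "channels": list(channels),
        "strides": list(strides),
        "dilations": list(dilations),
    }


def conv_stage_shape(spatial, stride) -> tuple[int, ...]:
    """Output shape of one kernel-3, padding-1 stage: ceil(n / stride)."""
    return tuple((n + 2 - 3) // stride + 1 for n in spatial)


def backbone_feature_shape(grid, strides=DEFAULT_STRIDES) -> tuple[int, ...]:
    """Spatial shape of the pre-pooling feature map."""
    spatial = tuple(grid)
    for s in strides:
        spatial = conv_stage_shape(spatial, s)
    return spatial


def added_conv_padding(spatial) -> tuple[int, ...]:
    """Per-axis padding of the extractor's stride-2 convolution: 1 on even
    axes, 0 on odd, giving output floor(n/2); reproduces (1, 0, 1) and
    6x7x6 -> 3x3x3 on the canonical grid."""
    return tuple(1 if n % 2 == 0 else 0 for n in spatial)


def _check_grid(grid, strides):
    factor = int(np.prod([s for s in strides]))
    for g in grid:
        if g % factor != 0:
            raise ValueError(
                f"grid {tuple(grid)} not divisible by {factor} in every axis")


class ContextModule(nn.Module):
    """Shape-preserving multi-scale block: parallel dilated 3x3x3 branches
    (dilations 1, 2, 4 by default, each to channels/2) merged by a 1x1x1
    convolution back to the input channel count."""

    def __init__(self, channels: int, dilations=DEFAULT_DILATIONS, rng=None):
        rng = rng if rng is not None else np.random.default_rng(0)
        branch_ch = max(channels // 2, 1)
        self.branches = [
            nn.Sequential(
                nn.Conv3d(channels, branch_ch, kernel_size=3, stride=1,
                          padding=d, dilation=d, rng=rng),
                nn.InstanceNorm3d(branch_ch),
                nn.ReLU(),
            )
            for d in dilations
        ]
        self.merge = nn.Conv3d(branch_ch * len(dilations), channels,
                               kernel_size=1, stride=1, padding=0, rng=rng)
        self._branch_ch = branch_ch

    def forward(self, x):
        if x.shape[1] != self.branches[0].modules[0].in_channels:
            raise ValueError(
                f"context module expects "
                f"{self.branches[0].modules[0].in_channels} channels, "
                f"got {x.shape[1]}")
        outs = [b(x) for b in self.branches]
        cat = np.concatenate(outs, axis=1)
        return self.merge(cat)

    def backward(self, dy):
        dcat = self.merge.backward(dy)
        dx = None
        for i, b in enumerate(self.branches):
            chunk = dcat[:, i * self._branch_ch:(i + 1) * self._branch_ch]
            dxi = b.backward(np.ascontiguousarray(chunk))
            dx = dxi if dx is None else dx + dxi
        return dx


class Backbone(nn.Module):
    """Binary classifier: conv stages + context module + GAP + linear to 2."""

    def __init__(self, spec: dict, seed: int = 0):
        grid, channels = spec["grid"], spec["channels"]
        strides, dilations = spec["strides"], spec["dilations"]
        _check_grid(grid, strides)
        if len(channels) != len(strides):
            raise ValueError("one stride per convolution stage required")
        rng = np.random.default_rng([int(seed), 1])
        stages = []
        in_c = 1
        for out_c, s in zip(channels, strides):
            stages += [nn.Conv3d(in_c, out_c, kernel_size=3, stride=s,
                                 padding=1, rng=rng),
                       nn.InstanceNorm3d(out_c), nn.ReLU()]
            in_c = out_c
        self.stages = nn.Sequential(*stages)
        self.context = ContextModule(channels[-1], dilations, rng=rng)
        self.gap = nn.GlobalAvgPool3d()
        self.fc = nn.Linear(channels[-1], len(spec["classes"]), rng=rng)
        self.spec = dict(spec)
        self._features = None

    def features(self, x):
        """Pre-pooling feature map (the context-module output)."""
        self._features = self.context(self.stages(x))
        return self._features

    def forward(self, x):
        return self.fc(self.gap(self.features(x)))

    def backward(self, dlogits):
        return self.stages.backward(self.context.backward(
            self.backward_to_features(dlogits)))

    def backward_to_features(self, dlogits):
        """Gradient of the loss w.r.t. the pre-pooling feature map."""
        return self.gap.backward(self.fc.backward(dlogits))


def build_backbone(spec: dict, init: str = "he_random", seed: int = 0,
                   pretrained_bundle: ModelBundle | None = None) -> Backbone:
    """Construct a backbone.

    ``init='he_random'`` He-initializes every layer.  With
    ``init='pretrained_bundle'`` all layers except the final linear are
    loaded from the provided bundle and the final linear is He-initialized
    fresh (the bundle's architecture must match).
    """
    model = Backbone(spec, seed=seed)
    if init == "he_random":
        return model
    if init != "pretrained_bundle":
        raise ValueError(f"unknown init {init!r}")
    if pretrained_bundle is None:
        raise ValueError("init='pretrained_bundle' requires a bundle")
    donor_spec = pretrained_bundle.spec
    for key in ("grid", "channels", "strides", "dilations"):
        if list(donor_spec.get(key, [])) != list(spec[key]):
            raise ValueError(f"bundle/spec mismatch on {key!r}")
    donor = Backbone(donor_spec, seed=seed)
    donor.load_state_arrays(pretrained_bundle.weights)
    n_fc = len(model.fc.params())
    trunk_params = model.params()[:-n_fc]
    donor_trunk = donor.params()[:-len(donor.fc.params())]
    if len(trunk_params) != len(donor_trunk):
        raise ValueError("bundle/spec mismatch: trunk parameter count differs")
    for p, q in zip(trunk_params, donor_trunk):
        p.data = q.data.copy()
    return model


class FeatureExtractor(nn.Module):
    """Trained backbone trunk (through the context module) plus a fresh
    3x3x3 stride-2 convolution to 128 channels, with ReLU."""

    def __init__(self, backbone: Backbone, seed: int = 0):
        rng = np.random.default_rng([int(seed), 2])
        self.stages = copy.deepcopy(backbone.stages)
        self.context = copy.deepcopy(backbone.context)
        feat_shape = backbone_feature_shape(backbone.spec["grid"],
                                            backbone.spec["strides"])
        padding = added_conv_padding(feat_shape)
        self.added = nn.Conv3d(backbone.spec["channels"][-1],
                               EXTRACTOR_CHANNELS, kernel_size=3, stride=2,
                               padding=padding, rng=rng)
        self.relu = nn.ReLU()
        self.spec = dict(backbone.spec)
        self.spec["added_padding"] = list(padding)

    def forward(self, x):
        return self.relu(self.added(self.context(self.stages(x))))

    def backward(self, dy, stop_at_trunk: bool = False):
        d = self.added.backward(self.relu.backward(dy))
        if stop_at_trunk:
            return None
        return self.stages.backward(self.context.backward(d))

    def output_shape(self) -> tuple[int, ...]:
        feat = backbone_feature_shape(self.spec["grid"], self.spec["strides"])
        return (EXTRACTOR_CHANNELS,) + tuple(n // 2 for n in feat)

    def trainable_params(self):
        """Parameters trained during multiclass training when the trunk is
        frozen: the added convolution only."""
        return self.added.params()


def build_feature_extractor(backbone: Backbone, seed: int = 0) -> FeatureExtractor:
    """Copy a (trained) backbone's trunk and append the fresh stride-2
    convolution; the discarded final linear layer plays no role."""
    return FeatureExtractor(backbone, seed=seed)


class MulticlassModel(nn.Module):
    """Six feature extractors -> channel concat -> GAP -> 384 -> 50 -> 3.

    Extractor order is fixed to :data:`EXTRACTOR_ORDER`; the first three
    consume the SUVR image, the last three the SRP image.  Dropout (0.5)
    follows the 384 and 50 layers.
    """

    def __init__(self, extractors: list[FeatureExtractor], seed: int = 0,
                 freeze_extractors: bool = True):
        if len(extractors) != 6:
            raise ValueError(f"exactly six extractors required, got {len(extractors)}")
        rng = np.random.default_rng([int(seed), 3])
        self.extractors = list(extractors)
        concat_ch = EXTRACTOR_CHANNELS * 6
        self.gap = nn.GlobalAvgPool3d()
        self.head = nn.Sequential(
            nn.Linear(concat_ch, HEAD_DIMS[0], rng=rng),
            nn.ReLU(),
            nn.Dropout(DROPOUT_RATE, rng=np.random.default_rng([int(seed), 4])),
            nn.Linear(HEAD_DIMS[0], HEAD_DIMS[1], rng=rng),
            nn.ReLU(),
            nn.Dropout(DROPOUT_RATE, rng=np.random.default_rng([int(seed), 5])),
            nn.Linear(HEAD_DIMS[1], 3, rng=rng),
        )
        self.freeze_extractors = bool(freeze_extractors)
        self.spec = dict(extractors[0].spec)
        self.spec.update(make_model_spec(MULTICLASS_MODEL_NAME,
                                         grid=self.spec["grid"],
                                         channels=self.spec["channels"],
                                         strides=self.spec["strides"],
                                         dilations=self.spec["dilations"]))
        self._concat = None

    def forward(self, suvr, srp):
        feats = [e(suvr) for e in self.extractors[:3]]
        feats += [e(srp) for e in self.extractors[3:]]
        self._concat = np.concatenate(feats, axis=1)
        if self._concat.shape[1] != EXTRACTOR_CHANNELS * 6:
            raise ValueError("concatenated feature must have 768 channels")
        return self.head(self.gap(self._concat))

    __call__ = forward

    def backward(self, dlogits):
        dcat = self.gap.backward(self.head.backward(dlogits))
        c = EXTRACTOR_CHANNELS
        for i, e in enumerate(self.extractors):
            chunk = np.ascontiguousarray(dcat[:, i * c:(i + 1) * c])
            e.backward(chunk, stop_at_trunk=self.freeze_extractors)

    def trainable_params(self):
        params = self.head.params()
        if self.freeze_extractors:
            for e in self.extractors:
                params += e.trainable_params()
        else:
            for e in self.extractors:
                params += e.params()
        return params


def build_multiclass_model(extractors: list[FeatureExtractor], seed: int = 0,
                           freeze_extractors: bool = True) -> MulticlassModel:
    return MulticlassModel(extractors, seed=seed,
                           freeze_extractors=freeze_extractors)


def head_linear_param_count() -> int:
    """Closed-form parameter count of the multiclass head's linear stack."""
    d0, d1 = HEAD_DIMS
    c = EXTRACTOR_CHANNELS * 6
    return c * d0 + d0 + d0 * d1 + d1 + d1 * 3 + 3


# ---------------------------------------------------------------------------
# Bundle round trips
# ---------------------------------------------------------------------------

def bundle_from_model(model, preprocessing_stats=None, history=None) -> ModelBundle:
    return ModelBundle(spec=dict(model.spec),
                       weights=[p.data.copy() for p in model.params()],
                       preprocessing_stats=preprocessing_stats or {},
                       history=history or {})


def model_from_bundle(bundle: ModelBundle, seed: int = 0,
                      freeze_extractors: bool = True):
    """Rebuild the module tree named by a bundle's spec and load weights."""
    spec = bundle.spec
    if spec.get("kind") == "multiclass":
        base = make_model_spec(EXTRACTOR_ORDER[0], grid=spec["grid"],
                               channels=spec["channels"], strides=spec["strides"],
                               dilations=spec["dilations"])
        extractors = [FeatureExtractor(Backbone(base, seed=seed), seed=seed)
                      for _ in range(6)]
        model = MulticlassModel(extractors, seed=seed,
                                freeze_extractors=freeze_extractors)
    else:
        model = Backbone(spec, seed=seed)
        model.spec = dict(spec)
    model.load_state_arrays(bundle.weights)
    return model
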