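"""Baseline classifier architectures for the four fragment representations.

* ``pointnet_like`` — shared per-point encoder + symmetric max pooling +
  classifier head, for raw-coordinate and surface-vertex point clouds;
* ``voxnet_prelu`` — a compact 3D CNN for 32^3 density grids with
  parametric rectifiers (single trainable slope each);
* ``voxnet_small`` — a downscaled variant (input average-pooled 4x) for
  CPU-budget experiments;
* ``resnet18_1ch`` — a single-input-channel residual CNN with the standard
  18-layer layout, for 128 x 128 Hilbert images.

Convolution weights use He-normal initialization.
"""

from __future__ import annotations

import numpy as np

from .core import (AvgPool3d, BatchNorm, Conv2d, Conv3d, Flatten,
                   GlobalAvgPool2d, Layer, Linear, MaxOverPoints,
                   MaxPool2d, MaxPool3d, PReLU, ReLU, Sequential)

__all__ = ["ARCHITECTURES", "build_model"]


class PointNetLike(Sequential):
    """Per-point MLP (64-128-256), max pool over points, MLP head."""

    input_kind = "points"

    def __init__(self, rng, n_classes: int, widths=(64, 128, 256),
                 head=(128,)):
        layers: list[Layer] = []
        c = 3
        for w in widths:
            layers += [Linear(rng, c, w), ReLU()]
            c = w
        layers.append(MaxOverPoints())
        for w in head:
            layers += [Linear(rng, c, w), ReLU()]
            c = w
        layers.append(Linear(rng, c, n_classes))
        super().__init__(*layers)


class VoxNetPReLU(Sequential):
    """3D CNN for 32^3 grids: two valid convolutions, pool, dense head."""

    input_kind = "voxels"

    def __init__(self, rng, n_classes: int, channels=(32, 32), dense=128):
        c1, c2 = channels
        super().__init__(
            Conv3d(rng, 1, c1, 5, stride=2),  # 32 -> 14
            PReLU(),
            Conv3d(rng, c1, c2, 3),           # 14 -> 12
            PReLU(),
            MaxPool3d(2),                     # 12 -> 6
            Flatten(),
            Linear(rng, c2 * 6 ** 3, dense),
            PReLU(),
            Linear(rng, dense, n_classes),
        )


class VoxNetSmall(Sequential):
    """CPU-budget voxel classifier: 4x average-pooled input, two convs."""

    input_kind = "voxels"

    def __init__(self, rng, n_classes: int, channels=(16, 32), dense=64):
        c1, c2 = channels
        super().__init__(
            AvgPool3d(4),                     # 32 -> 8
            Conv3d(rng, 1, c1, 3),            # 8 -> 6
            PReLU(),
            Conv3d(rng, c1, c2, 3),           # 6 -> 4
            PReLU(),
            MaxPool3d(2),                     # 4 -> 2
            Flatten(),
            Linear(rng, c2 * 2 ** 3, dense),
            PReLU(),
            Linear(rng, dense, n_classes),
        )


class _BasicBlock(Layer):
    """Two 3x3 convolutions with a (possibly projected) residual shortcut."""

    def __init__(self, rng, c_in, c_out, stride=1):
        self.conv1 = Conv2d(rng, c_in, c_out, 3, stride=stride, padding=1)
        self.bn1 = BatchNorm(c_out)
        self.relu1 = ReLU()
        self.conv2 = Conv2d(rng, c_out, c_out, 3, stride=1, padding=1)
        self.bn2 = BatchNorm(c_out)
        self.relu2 = ReLU()
        if stride != 1 or c_in != c_out:
            self.proj = Conv2d(rng, c_in, c_out, 1, stride=stride)
            self.bn_proj = BatchNorm(c_out)
        else:
            self.proj = None

    def params(self):
        out = (self.conv1.params() + self.bn1.params()
               + self.conv2.params() + self.bn2.params())
        if self.proj is not None:
            out += self.proj.params() + self.bn_proj.params()
        return out

    def set_mode(self, train):
        for m in (self.bn1, self.bn2) + ((self.bn_proj,)
                                         if self.proj is not None else ()):
            m.set_mode(train)

    def forward(self, x):
        out = self.relu1.forward(self.bn1.forward(self.conv1.forward(x)))
        out = self.bn2.forward(self.conv2.forward(out))
        if self.proj is not None:
            short = self.bn_proj.forward(self.proj.forward(x))
        else:
            short = x
        return self.relu2.forward(out + short)

    def backward(self, grad):
        grad = self.relu2.backward(grad)
        g_main = self.conv1.backward(self.bn1.backward(self.relu1.backward(
            self.conv2.backward(self.bn2.backward(grad)))))
        if self.proj is not None:
            g_short = self.proj.backward(self.bn_proj.backward(grad))
        else:
            g_short = grad
        return g_main + g_short


class ResNet18(Sequential):
    """Standard 18-layer residual network with one input channel."""

    input_kind = "images"

    def __init__(self, rng, n_classes: int, base_width: int = 64):
        w = base_width
        layers: list[Layer] = [
            Conv2d(rng, 1, w, 7, stride=2, padding=3),  # 128 -> 64
            BatchNorm(w),
            ReLU(),
            MaxPool2d(2),                               # 64 -> 32
        ]
        plan = [(w, 1), (w, 1), (2 * w, 2), (2 * w, 1),
                (4 * w, 2), (4 * w, 1), (8 * w, 2), (8 * w, 1)]
        c = w
        for c_out, stride in plan:
            layers.append(_BasicBlock(rng, c, c_out, stride))
            c = c_out
        layers += [GlobalAvgPool2d(), Linear(rng, c, n_classes)]
        super().__init__(*layers)


ARCHITECTURES = {
    "pointnet_like": PointNetLike,
    "voxnet_prelu": VoxNetPReLU,
    "voxnet_small": VoxNetSmall,
    "resnet18_1ch": ResNet18,
}


def build_model(arch: str, n_classes: int, seed: int = 0, **kwargs):
    """Instantiate a baseline classifier by architecture name."""
    if arch not in ARCHITECTURES:
        raise ValueError(f"unknown architecture {arch!r}; "
                         f"choose from {sorted(ARCHITECTURES)}")
    if n_classes < 2:
        raise ValueError("need at least 2 classes")
    rng = np.random.default_rng(seed)
    return ARCHITECTURES[arch](rng, n_classes, **kwargs)
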