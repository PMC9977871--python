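"""Rotation-equivariant 3D convolution machinery and a small U-Net.

The symmetry group is the 24-element orientation-preserving cube group,
realized exactly as signed axis permutations of the voxel grid — no
interpolation, so equivariance holds to floating-point round-off and can be
tested numerically.  Feature maps carry an explicit orientation axis of
length 24; spatial down/up-sampling never touches that axis, which is only
collapsed by the final orientation max-pool.

All tensors are numpy float32; convolution is implemented with
``sliding_window_view`` + BLAS matmul, which is fast enough for desk-scale
volumes and keeps the package free of deep-learning frameworks.
"""

from __future__ import annotations

import logging
import pickle
import warnings
from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import ndimage

logger = logging.getLogger(__name__)

__all__ = [
    "RotationGroup",
    "enumerate_group",
    "rotate_volume",
    "rotate_kernel",
    "lift_convolution",
    "group_convolution",
    "orientation_pool",
    "EquivariantUNet",
    "build_equivariant_unet",
    "predict_probability",
    "fallback_probability",
    "train_head",
]

GROUP_ORDER = 24


@dataclass(frozen=True)
class RotationGroup:
    """The 24 orientation-preserving cube symmetries.

    ``elements[g]`` is a 3x3 signed permutation matrix with determinant +1
    acting on (z, y, x) coordinate offsets.  ``cayley[g, h]`` is the index
    of ``elements[g] @ elements[h]``; ``inverse[g]`` the index of the
    inverse.  Element 0 is the identity.
    """

    elements: np.ndarray  # (24, 3, 3) int
    cayley: np.ndarray  # (24, 24) int
    inverse: np.ndarray  # (24,) int

    def __len__(self) -> int:
        return len(self.elements)


def enumerate_group() -> RotationGroup:
    """Enumerate all signed 3x3 permutation matrices with determinant +1,
    identity first, remaining elements in a fixed lexicographic order."""
    mats = []
    for perm in ([0, 1, 2], [0, 2, 1], [1, 0, 2], [1, 2, 0], [2, 0, 1], [2, 1, 0]):
        for signs in np.ndindex(2, 2, 2):
            m = np.zeros((3, 3), dtype=int)
            for row, (col, s) in enumerate(zip(perm, signs)):
                m[row, col] = 1 - 2 * s
            if round(np.linalg.det(m)) == 1:
                mats.append(m)
    mats.sort(key=lambda m: (not np.array_equal(m, np.eye(3, dtype=int)), m.ravel().tolist()))
    elements = np.stack(mats)
    assert len(elements) == GROUP_ORDER

    index = {e.tobytes(): i for i, e in enumerate(elements)}
    cayley = np.empty((GROUP_ORDER, GROUP_ORDER), dtype=int)
    inverse = np.empty(GROUP_ORDER, dtype=int)
    for g in range(GROUP_ORDER):
        for h in range(GROUP_ORDER):
            prod = elements[g] @ elements[h]
            cayley[g, h] = index[prod.astype(int).tobytes()]
        inv = np.linalg.inv(elements[g]).round().astype(int)
        inverse[g] = index[inv.tobytes()]
    return RotationGroup(elements=elements, cayley=cayley, inverse=inverse)


_GROUP: RotationGroup | None = None


def get_group() -> RotationGroup:
    global _GROUP
    if _GROUP is None:
        _GROUP = enumerate_group()
    return _GROUP


def _source_indices(matrix: np.ndarray, n: int) -> tuple[np.ndarray, ...]:
    """Voxel source indices realizing out[p] = in[g^{-1}(p - c) + c]."""
    inv = np.linalg.inv(matrix).round().astype(int)
    c = (n - 1) / 2.0
    idx = np.indices((n, n, n), dtype=float) - c
    src = np.einsum("ab,b...->a...", inv.astype(float), idx) + c
    src = src.round().astype(int)
    return tuple(src)


def rotate_volume(g: int | np.ndarray, v: np.ndarray, group: RotationGroup | None = None) -> np.ndarray:
    """Apply group element ``g`` (index or 3x3 matrix) to the last three
    (cubic) axes of ``v``.  Exact: rotate(identity) is the identity and
    rotate(g, rotate(h, v)) == rotate(cayley[g, h], v)."""
    matrix = (group or get_group()).elements[g] if np.isscalar(g) else np.asarray(g)
    z, y, x = v.shape[-3:]
    if not (z == y == x):
        raise ValueError(f"spatial extents must be cubic, got {(z, y, x)}; pad first")
    sz, sy, sx = _source_indices(matrix, z)
    return v[..., sz, sy, sx]


def rotate_kernel(g: int, k: np.ndarray, group: RotationGroup | None = None) -> np.ndarray:
    """Rotate the trailing cubic axes of a (…, k, k, k) kernel."""
    return rotate_volume(g, k, group)


def _conv3d_same(x: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Cross-correlation with 'same' zero padding.

    x: (C_in, z, y, x); weights: (C_out, C_in, k, k, k) -> (C_out, z, y, x).
    """
    k = weights.shape[-1]
    if k % 2 == 0:
        raise ValueError(f"kernel size must be odd, got {k}")
    r = k // 2
    xp = np.pad(np.asarray(x, dtype=np.float32), ((0, 0), (r, r), (r, r), (r, r)))
    win = sliding_window_view(xp, (k, k, k), axis=(1, 2, 3))  # (C_in, z, y, x, k, k, k)
    c_in = x.shape[0]
    n_vox = int(np.prod(x.shape[1:]))
    # im2col copy, then a single GEMM
    cols = np.ascontiguousarray(win.transpose(0, 4, 5, 6, 1, 2, 3)).reshape(c_in * k**3, n_vox)
    w = np.ascontiguousarray(weights, dtype=np.float32).reshape(weights.shape[0], c_in * k**3)
    out = w @ cols
    return out.reshape(weights.shape[0], *x.shape[1:])


def lift_convolution(
    x: np.ndarray, kernels: np.ndarray, group: RotationGroup | None = None
) -> np.ndarray:
    """Lift a plain feature map to the group.

    x: (C_in, z, y, x); kernels: (C_out, C_in, k, k, k).
    Output slot g is the convolution of ``x`` with the g-rotated kernel,
    giving a (24, C_out, z, y, x) group feature map.  Equivariance:
    ``lift(rotate(g, x))[s] == rotate(g, lift(x)[inverse(g) o s])``.
    """
    grp = group or get_group()
    if kernels.shape[-1] % 2 == 0:
        raise ValueError("even kernel size: rotation about the center is undefined")
    rotated = np.stack([rotate_kernel(g, kernels, grp) for g in range(len(grp))])
    # one big conv: stack the 24 rotated kernel banks along the output axis
    big = rotated.reshape(-1, *kernels.shape[1:])
    out = _conv3d_same(x, big)
    return out.reshape(len(grp), kernels.shape[0], *x.shape[1:])


def group_convolution(
    f: np.ndarray, kernels: np.ndarray, group: RotationGroup | None = None
) -> np.ndarray:
    """Group-to-group convolution.

    f: (24, C_in, z, y, x); kernels: (C_out, C_in, 24, k, k, k) base bank.
    Output slot g sums over input slots h the convolution of slot h with the
    kernel indexed by g^{-1} o h, spatially rotated by g.  Same equivariance
    contract (joint spatial rotation + slot permutation) as the lift layer.
    """
    grp = group or get_group()
    n = len(grp)
    if f.shape[0] != n:
        raise ValueError(f"orientation axis must be {n}, got {f.shape[0]}")
    if kernels.shape[2] != n:
        raise ValueError(f"kernel orientation axis must be {n}, got {kernels.shape[2]}")
    c_out, c_in = kernels.shape[0], kernels.shape[1]
    k = kernels.shape[-1]
    x = f.reshape(n * c_in, *f.shape[2:])
    # big weight bank: W[g*c_out + o, h*c_in + i] = rotate_g(K[o, i, inv(g) o h])
    big = np.empty((n * c_out, n * c_in, k, k, k), dtype=np.float32)
    for g in range(n):
        ginv = grp.inverse[g]
        # kernel slot for each input slot h
        slot = grp.cayley[ginv, np.arange(n)]
        bank = kernels[:, :, slot]  # (c_out, c_in, n, k,k,k)
        bank = rotate_kernel(g, bank, grp)
        big[g * c_out : (g + 1) * c_out] = (
            bank.transpose(0, 2, 1, 3, 4, 5).reshape(c_out, n * c_in, k, k, k)
        )
    out = _conv3d_same(x, big)
    return out.reshape(n, c_out, *f.shape[2:])


def orientation_pool(f: np.ndarray) -> np.ndarray:
    """Per-voxel maximum over the 24 orientation slots: (24, C, z, y, x) ->
    (C, z, y, x).  Collapsing the slot axis makes an equivariant stack
    invariant (up to spatial rotation) to input rotation."""
    if f.shape[0] != GROUP_ORDER:
        raise ValueError(f"orientation axis must be {GROUP_ORDER}, got {f.shape[0]}")
    return f.max(axis=0)


def _maxpool2(x: np.ndarray) -> np.ndarray:
    s = x.shape
    v = x.reshape(*s[:-3], s[-3] // 2, 2, s[-2] // 2, 2, s[-1] // 2, 2)
    return v.max(axis=(-5, -3, -1))


def _upsample2(x: np.ndarray) -> np.ndarray:
    return x.repeat(2, axis=-3).repeat(2, axis=-2).repeat(2, axis=-1)


@dataclass
class EquivariantUNet:
    """Small rotation-equivariant U-Net (numpy forward pass).

    Entry lift layer, group convolutions with ReLU elsewhere, 2x max-pool /
    nearest-neighbor upsample on spatial axes only, concatenation skips, and
    an orientation max-pool + logistic head producing per-voxel membrane
    probabilities.  Defaults: depth 3, 4 base group-channels, 3^3 kernels.
    """

    depth: int
    base_channels: int
    kernel_size: int = 3
    seed: int = 0
    params: dict = field(default_factory=dict)
    head_weights: np.ndarray | None = None
    head_bias: float = 0.0
    version: str = "tricell-unet-1"

    TILE_Z = 16

    def __post_init__(self) -> None:
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if not self.params:
            self._init_params()

    def _init_params(self) -> None:
        rng = np.random.default_rng(self.seed)
        k = self.kernel_size

        def he(*shape):
            fan_in = int(np.prod(shape[1:]))
            return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)

        chans = [self.base_channels * (2**i) for i in range(self.depth)]
        p: dict[str, np.ndarray] = {"lift": he(chans[0], 1, k, k, k)}
        for lvl in range(1, self.depth):
            p[f"down{lvl}"] = he(chans[lvl], chans[lvl - 1], GROUP_ORDER, k, k, k)
        for lvl in range(self.depth - 2, -1, -1):
            p[f"up{lvl}"] = he(chans[lvl], chans[lvl + 1] + chans[lvl], GROUP_ORDER, k, k, k)
        self.params = p
        self.head_weights = (rng.standard_normal(chans[0]) * 0.1).astype(np.float32)
        self.head_bias = 0.0

    # -- forward -----------------------------------------------------------

    def features(self, x: np.ndarray, group: RotationGroup | None = None) -> np.ndarray:
        """Pooled rotation-invariant feature map (C, z, y, x) for a
        (z, y, x) tile whose spatial dims are divisible by 2**(depth-1)."""
        grp = group or get_group()
        factor = 2 ** (self.depth - 1)
        if any(s % factor for s in x.shape):
            raise ValueError(f"tile shape {x.shape} not divisible by {factor}")
        f = np.maximum(lift_convolution(x[None].astype(np.float32), self.params["lift"], grp), 0.0)
        skips = [f]
        for lvl in range(1, self.depth):
            f = _maxpool2(f)
            f = np.maximum(group_convolution(f, self.params[f"down{lvl}"], grp), 0.0)
            skips.append(f)
        for lvl in range(self.depth - 2, -1, -1):
            f = _upsample2(f)
            f = np.concatenate([f, skips[lvl]], axis=1)
            f = np.maximum(group_convolution(f, self.params[f"up{lvl}"], grp), 0.0)
        return orientation_pool(f)

    def forward(self, x: np.ndarray) -> np.ndarray:
        """Per-voxel membrane probability in [0, 1] for a (z, y, x) tile."""
        feats = self.features(x)
        logits = np.tensordot(self.head_weights, feats, axes=(0, 0)) + self.head_bias
        return 1.0 / (1.0 + np.exp(-logits))

    __call__ = forward

    def n_parameters(self) -> int:
        """Trainable parameter count: base kernels are stored once; rotated
        copies are derived, never trained independently."""
        return sum(int(v.size) for v in self.params.values()) + self.head_weights.size + 1

    # -- persistence -------------------------------------------------------

    def save(self, path) -> None:
        state = {
            "version": self.version,
            "depth": self.depth,
            "base_channels": self.base_channels,
            "kernel_size": self.kernel_size,
            "seed": self.seed,
            "params": self.params,
            "head_weights": self.head_weights,
            "head_bias": self.head_bias,
        }
        with open(path, "wb") as fh:
            pickle.dump(state, fh)

    @classmethod
    def load(cls, path) -> "EquivariantUNet":
        with open(path, "rb") as fh:
            state = pickle.load(fh)
        if state.get("version") != "tricell-unet-1":
            raise ValueError(f"unsupported checkpoint version {state.get('version')!r}")
        net = cls(
            depth=state["depth"],
            base_channels=state["base_channels"],
            kernel_size=state["kernel_size"],
            seed=state["seed"],
            params=state["params"],
        )
        net.head_weights = state["head_weights"]
        net.head_bias = state["head_bias"]
        return net


def build_equivariant_unet(depth: int = 3, base_channels: int = 4, seed: int = 0) -> EquivariantUNet:
    return EquivariantUNet(depth=depth, base_channels=base_channels, seed=seed)


def _pad_to(x: np.ndarray, shape: tuple[int, int, int]) -> np.ndarray:
    pads = [(0, t - s) for s, t in zip(x.shape, shape)]
    return np.pad(x, pads, mode="reflect") if any(p[1] for p in pads) else x


def predict_probability(net: EquivariantUNet, stack: np.ndarray) -> np.ndarray:
    """Run the net over a full stack by tiling into 16-slice z-windows with
    4-slice overlap and averaging the overlaps.  Output matches the input
    shape with values in [0, 1]."""
    z, y, x = stack.shape
    factor = 2 ** (net.depth - 1)
    tz = net.TILE_Z
    ty = -(-y // factor) * factor
    tx = -(-x // factor) * factor
    if z < tz:
        logger.info("input has %d z-slices; reflection-padding to %d", z, tz)
    step = tz - 4
    starts = sorted({min(s, max(z - tz, 0)) for s in range(0, max(z - tz, 0) + step, step)})
    acc = np.zeros((z, y, x), dtype=np.float64)
    cnt = np.zeros((z, y, x), dtype=np.float64)
    for s in starts:
        tile = stack[s : s + tz]
        nz = tile.shape[0]
        tile = _pad_to(tile, (tz, ty, tx))
        pred = net.forward(tile)[:nz, :y, :x]
        acc[s : s + nz] += pred
        cnt[s : s + nz] += 1.0
    return (acc / cnt).astype(np.float32)


def fallback_probability(stack: np.ndarray, smooth_sigma: float = 1.0) -> np.ndarray:
    """Training-free membrane probability: Gaussian-smoothed intensity,
    min-max normalized to [0, 1] (membrane-bright convention)."""
    sm = ndimage.gaussian_filter(np.asarray(stack, dtype=np.float64), smooth_sigma)
    lo, hi = sm.min(), sm.max()
    if hi - lo < 1e-12:
        warnings.warn("constant input stack; returning all-zero probability map")
        return np.zeros_like(sm, dtype=np.float32)
    return ((sm - lo) / (hi - lo)).astype(np.float32)


def train_head(
    net: EquivariantUNet,
    tiles: list[tuple[np.ndarray, np.ndarray]],
    epochs: int = 5,
    lr: float = 0.5,
) -> EquivariantUNet:
    """Smoke-scale training: fit the logistic output head on pooled
    equivariant features by full-batch gradient descent against binary
    membrane masks (voxel-wise cross-entropy).  Base kernels stay fixed;
    this is deliberately tiny and deterministic."""
    feats = []
    targets = []
    for x, m in tiles:
        f = net.features(x.astype(np.float32))
        feats.append(f.reshape(f.shape[0], -1))
        targets.append(np.asarray(m, dtype=np.float32).ravel())
    F = np.concatenate(feats, axis=1)  # (C, V)
    t = np.concatenate(targets)
    scale = max(float(np.abs(F).max()), 1e-8)
    F = F / scale
    w = net.head_weights.astype(np.float64) * scale
    b = float(net.head_bias)
    for _ in range(epochs * 100):  # an "epoch" = 100 full-batch steps
        p = 1.0 / (1.0 + np.exp(-(w @ F + b)))
        err = p - t
        w -= lr * (F @ err) / t.size
        b -= lr * float(err.mean())
    net.head_weights = (w / scale).astype(np.float32)  # fold normalization back in
    net.head_bias = b
    return net
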