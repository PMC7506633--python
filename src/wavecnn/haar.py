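"""Multilevel 2D Haar wavelet decomposition.

The single decomposition level convolves each image channel with four 2x2
filters (approximation LL and details LH, HL, HH) at stride 2, producing
four half-resolution subbands per channel.  Stacking the subbands of all
channels gives a parameter-free "wavelet pooling" operator: downsampling by
2 while retaining the high-frequency content an average pool would discard.
Repeating the transform on the LL channels yields a multiresolution pyramid
whose levels feed the spectral branch of the network at matched resolutions.

Three filter normalizations are exposed:

``raw``
    integer +/-1 entries; on a 2x2 block ``[[1, 2], [3, 4]]`` the four
    responses are exactly 10, 4, 2, 0.
``orthonormal``
    raw kernels scaled by 1/2, making the four flattened kernels an
    orthonormal basis of R^4 so the transform preserves total energy
    (Parseval).  This is the network default: activation scale is stable
    across levels.
``average``
    like ``orthonormal`` but with the LL kernel rescaled to entries 1/4, so
    the LL subband is exactly 2x2/stride-2 average pooling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import DimensionError, InputError

SUBBAND_ORDER = ("LL", "LH", "HL", "HH")

MODES = ("raw", "orthonormal", "average")

# 2x2 filter bank, rows top-to-bottom, unnormalized (+/-1 entries).
_RAW_KERNELS = {
    "LL": np.array([[1.0, 1.0], [1.0, 1.0]]),
    "LH": np.array([[-1.0, -1.0], [1.0, 1.0]]),
    "HL": np.array([[-1.0, 1.0], [-1.0, 1.0]]),
    "HH": np.array([[1.0, -1.0], [-1.0, 1.0]]),
}


@dataclass(frozen=True)
class HaarFilterBank:
    """The four 2x2 Haar analysis kernels under a given normalization."""

    mode: str = "orthonormal"

    def __post_init__(self):
        if self.mode not in MODES:
            raise InputError(f"unknown filter-bank mode {self.mode!r}; expected one of {MODES}")

    def _scale(self, name: str) -> float:
        if self.mode == "raw":
            return 1.0
        if self.mode == "average" and name == "LL":
            return 0.25
        return 0.5

    def kernel(self, name: str) -> np.ndarray:
        """Return the 2x2 kernel for one subband (copy)."""
        return _RAW_KERNELS[name] * self._scale(name)

    @property
    def w_ll(self) -> np.ndarray:
        return self.kernel("LL")

    @property
    def w_lh(self) -> np.ndarray:
        return self.kernel("LH")

    @property
    def w_hl(self) -> np.ndarray:
        return self.kernel("HL")

    @property
    def w_hh(self) -> np.ndarray:
        return self.kernel("HH")

    def stacked(self) -> np.ndarray:
        """All four kernels as one (4, 2, 2) array in subband order."""
        return np.stack([self.kernel(n) for n in SUBBAND_ORDER])


@dataclass(frozen=True)
class SubbandStack:
    """One decomposition level: 4 subbands per input channel at half size.

    ``data`` has shape ``(H/2, W/2, 4*C)`` with channels blocked per input
    channel in input order: for channel ``c`` the four planes ``4c .. 4c+3``
    are (LL, LH, HL, HH).
    """

    data: np.ndarray
    level: int
    mode: str
    n_input_channels: int

    @property
    def channel_order(self) -> tuple[str, ...]:
        return tuple(
            f"c{c}:{name}" for c in range(self.n_input_channels) for name in SUBBAND_ORDER
        )

    def subband(self, name: str, channel: int = 0) -> np.ndarray:
        """One subband plane of one input channel."""
        return self.data[:, :, 4 * channel + SUBBAND_ORDER.index(name)]

    def ll_channels(self) -> np.ndarray:
        """The LL planes of all input channels, shape (H/2, W/2, C)."""
        return self.data[:, :, 0::4]


@dataclass(frozen=True)
class WaveletPyramid:
    """Levels 1..L of the decomposition; level l decomposes level l-1's LL."""

    levels: tuple[SubbandStack, ...] = field(default_factory=tuple)

    def __len__(self) -> int:
        return len(self.levels)

    def __getitem__(self, i: int) -> SubbandStack:
        return self.levels[i]


def _as_image(image) -> np.ndarray:
    arr = np.asarray(image, dtype=float)
    if arr.size == 0:
        raise InputError("empty input image")
    if arr.ndim == 2:
        arr = arr[:, :, None]
    if arr.ndim != 3:
        raise DimensionError(f"expected an HxW or HxWxC array, got ndim={arr.ndim}")
    if not np.all(np.isfinite(arr)):
        raise InputError("image contains non-finite values")
    return arr


def dwt_level(image, bank: HaarFilterBank | None = None, level: int = 1) -> SubbandStack:
    """One level of the 2D Haar transform over non-overlapping 2x2 blocks.

    Each output plane is the stride-2 valid correlation of an input channel
    with one 2x2 kernel; blocks are anchored at even indices from the
    top-left corner.  Output shape is ``(H/2, W/2, 4*C)``.
    """
    bank = bank or HaarFilterBank()
    arr = _as_image(image)
    h, w, c = arr.shape
    for axis, dim in (("rows", h), ("columns", w)):
        if dim % 2 != 0:
            raise DimensionError(f"image {axis} dimension {dim} is odd; even size required")
    kernels = bank.stacked()  # (4, 2, 2)
    blocks = arr.reshape(h // 2, 2, w // 2, 2, c)
    # out[i, j, c, k] = sum_{a,b} blocks[i, a, j, b, c] * kernels[k, a, b]
    out = np.einsum("iajbc,kab->ijck", blocks, kernels)
    out = out.reshape(h // 2, w // 2, 4 * c)
    return SubbandStack(data=out, level=level, mode=bank.mode, n_input_channels=c)


def max_levels(shape) -> int:
    """Largest L such that both spatial dims are divisible by 2**L."""
    h, w = int(shape[0]), int(shape[1])
    n = 0
    while h % 2 == 0 and w % 2 == 0 and h > 0 and w > 0:
        n += 1
        h //= 2
        w //= 2
    return n


def dwt_pyramid(image, levels: int, bank: HaarFilterBank | None = None) -> WaveletPyramid:
    """Multilevel decomposition: level l transforms the LL channels of l-1."""
    bank = bank or HaarFilterBank()
    arr = _as_image(image)
    if levels < 1:
        raise InputError(f"levels must be >= 1, got {levels}")
    feasible = max_levels(arr.shape)
    if levels > feasible:
        raise DimensionError(
            f"image of shape {arr.shape[:2]} supports at most {feasible} "
            f"decomposition levels; {levels} requested"
        )
    stacks = []
    current = arr
    for lvl in range(1, levels + 1):
        stack = dwt_level(current, bank, level=lvl)
        stacks.append(stack)
        current = stack.ll_channels()
    return WaveletPyramid(levels=tuple(stacks))


def subband_energy(stack: SubbandStack) -> np.ndarray:
    """Sum of squared coefficients of every subband plane, shape (4*C,)."""
    return np.sum(np.square(stack.data), axis=(0, 1))


def detail_energy(stack: SubbandStack) -> float:
    """Total energy of the LH, HL, HH planes across all channels."""
    energies = subband_energy(stack)
    mask = np.ones(energies.shape[0], dtype=bool)
    mask[0::4] = False  # drop LL planes
    return float(energies[mask].sum())
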