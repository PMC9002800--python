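"""Local quinary pattern (LQP) encoding and its rotation-invariant variants.

An LQP code compares a centre pixel ``I_c`` with ``P`` neighbours sampled on a
circle of radius ``R`` and quantises each difference into five levels
``{-2, -1, 0, 1, 2}`` using two thresholds ``tau1 < tau2``.  The quinary
string is split into four binary sub-patterns (one per non-zero level), and
each sub-pattern is encoded with one of three schemes:

``basic``
    The bit string read as a plain binary number (not rotation invariant).
``riu2``
    Classic rotation-invariant uniform coding: patterns with at most two
    circular 0/1 transitions are coded by their popcount, everything else is
    collapsed into a single "non-uniform" code ``P + 1``.
``riu4``
    The extended coding implemented here: additionally, every pattern with
    exactly four transitions -- i.e. two distinct circular runs of ones with
    lengths ``X <= Y`` -- receives its own code ``P + index(X, Y)``.  All
    remaining patterns share one unified code.  This keeps the descriptor
    rotation invariant while preserving the two-run "thin stripe"
    microstructures that riu2 collapses.

Per sub-pattern the riu4 alphabet has ``(P + 2) + floor((P - 2)^2 / 4)``
codes: ``P + 1`` uniform codes, ``floor((P - 2)^2 / 4)`` two-run codes and
one unified code.  With the default multiscale configuration
``(R, P) = (2, 10), (4, 14), (8, 18)`` and four sub-patterns the full
descriptor has ``4 * (28 + 52 + 84) = 656`` channels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "NeighborhoodSpec",
    "ThresholdRule",
    "CodeImageSet",
    "DEFAULT_SCALES",
    "quinary_level",
    "split_subpatterns",
    "sample_circle",
    "transition_count",
    "riu4_index",
    "riu4_code",
    "riu2_code",
    "lqp_basic_code",
    "per_channel_dim",
    "code_table",
    "encode_image",
]

VARIANTS = ("riu4", "riu2", "basic")


@dataclass(frozen=True)
class NeighborhoodSpec:
    """Circular sampling geometry: ``n_points`` samples on radius ``radius``."""

    radius: float
    n_points: int

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if self.n_points < 4:
            raise ValueError("need at least 4 neighbours")


#: Multiscale default: three (R, P) pairs.
DEFAULT_SCALES: tuple[NeighborhoodSpec, ...] = (
    NeighborhoodSpec(2, 10),
    NeighborhoodSpec(4, 14),
    NeighborhoodSpec(8, 18),
)


@dataclass(frozen=True)
class ThresholdRule:
    """Adaptive quinary thresholds as fractions of the centre intensity.

    ``tau1 = p1 * I_c`` and ``tau2 = p2 * I_c`` (defaults 2% and 7%).
    """

    p1: float = 0.02
    p2: float = 0.07

    def __post_init__(self) -> None:
        if not 0 < self.p1 < self.p2:
            raise ValueError("require 0 < p1 < p2")


def quinary_level(diff, tau1, tau2):
    """Five-level quantisation of an intensity difference.

    Piecewise: 2 if ``tau2 <= x``; 1 if ``tau1 <= x < tau2``; 0 if
    ``-tau1 <= x < tau1``; -1 if ``-tau2 <= x < -tau1``; -2 if ``x < -tau2``.
    Accepts scalars or broadcastable arrays (per-pixel thresholds).

    Degenerate thresholds (``tau1 == tau2 == 0``, i.e. a zero centre
    intensity under the adaptive rule) collapse the bands; we then assign
    level 0 to a zero difference and ``+/-2`` by sign.
    """
    diff = np.asarray(diff, dtype=np.float64)
    tau1 = np.asarray(tau1, dtype=np.float64)
    tau2 = np.asarray(tau2, dtype=np.float64)
    out = np.select(
        [diff >= tau2, diff >= tau1, diff >= -tau1, diff >= -tau2],
        [2, 1, 0, -1],
        default=-2,
    )
    degenerate = (tau1 == 0) & (tau2 == 0)
    if np.any(degenerate):
        out = np.where(degenerate, 2 * np.sign(diff).astype(np.int64), out)
    if out.ndim == 0:
        return int(out)
    return out.astype(np.int8)


def split_subpatterns(levels: Sequence[int]) -> np.ndarray:
    """Split a quinary level sequence into the four binary sub-patterns.

    Returns a ``(4, P)`` uint8 array; row ``i`` marks levels
    ``2, 1, -1, -2`` respectively.  At each position at most one row is set,
    and exactly one row is set where the level is non-zero.
    """
    levels = np.asarray(levels)
    if levels.ndim != 1:
        raise ValueError("levels must be one-dimensional")
    if not np.isin(levels, (-2, -1, 0, 1, 2)).all():
        raise ValueError("levels must lie in {-2,-1,0,1,2}")
    targets = np.array([2, 1, -1, -2])
    return (levels[None, :] == targets[:, None]).astype(np.uint8)


def _as_bits(bits) -> np.ndarray:
    if isinstance(bits, str):
        if set(bits) - {"0", "1"}:
            raise ValueError("bit string must contain only 0/1")
        return np.frombuffer(bits.encode(), dtype=np.uint8) - ord("0")
    arr = np.asarray(bits, dtype=np.uint8)
    if arr.ndim != 1 or not np.isin(arr, (0, 1)).all():
        raise ValueError("bits must be a 1-D 0/1 sequence")
    return arr


def transition_count(bits) -> int:
    """Number of circular 0/1 transitions, wraparound included. Always even."""
    b = _as_bits(bits).astype(np.int8)
    if b.size < 2:
        raise ValueError("need at least 2 bits")
    return int(np.abs(np.diff(b)).sum() + abs(int(b[-1]) - int(b[0])))


def per_channel_dim(P: int, variant: str = "riu4") -> int:
    """Number of distinct codes per (scale, sub-pattern) channel.

    riu4: ``(P + 2) + floor((P - 2)^2 / 4)``, which equals
    ``ceil((P^2 + 11) / 4)`` for even P; riu2: ``P + 2``; basic: ``2**P``.
    """
    if P < 4:
        raise ValueError("P must be >= 4")
    if variant == "riu4":
        return (P + 2) + (P - 2) ** 2 // 4
    if variant == "riu2":
        return P + 2
    if variant == "basic":
        return 1 << P
    raise ValueError(f"unknown variant {variant!r}")


def riu4_index(x: int, y: int, P: int) -> int:
    """Index of the two-run pattern with 1-run lengths ``x <= y``.

    Enumerates ``{(X, Y): 1 <= X <= Y, X + Y <= P - 2}`` starting from 1:
    (1,1) -> 1, (1,2) -> 2, ...  Closed form of the cumulative sum
    ``sum_{n=1}^{X-1} (P - 3 - 2(n-1)) + (Y - X + 1)``.
    """
    if not (1 <= x <= y and x + y <= P - 2):
        raise ValueError("require 1 <= X <= Y and X + Y <= P - 2")
    return (x - 1) * (P - 1 - x) + y - x + 1


def _run_lengths(b: np.ndarray) -> list[int]:
    """Circular run lengths of ones in a bit array (unordered)."""
    P = b.size
    if b.all():
        return [P]
    if not b.any():
        return []
    # rotate so position 0 is a zero, then runs are non-circular
    start = int(np.argmin(b))
    rolled = np.roll(b, -start)
    runs, count = [], 0
    for v in rolled:
        if v:
            count += 1
        elif count:
            runs.append(count)
            count = 0
    if count:
        runs.append(count)
    return runs


def riu4_code(bits, P: int | None = None) -> int:
    """Rotation-invariant uniform code with the extended T = 4 class.

    T in {0, 2} -> popcount; T = 4 -> ``P + index(X, Y)`` where X, Y are the
    two circular 1-run lengths (X <= Y); otherwise the unified code
    ``per_channel_dim(P) - 1``.
    """
    b = _as_bits(bits)
    P = b.size if P is None else P
    if P != b.size:
        raise ValueError("P does not match bit string length")
    T = transition_count(b)
    if T <= 2:
        return int(b.sum())
    if T == 4:
        runs = sorted(_run_lengths(b))
        return P + riu4_index(runs[0], runs[1], P)
    return per_channel_dim(P, "riu4") - 1


def riu2_code(bits, P: int | None = None) -> int:
    """Classic rotation-invariant uniform code: popcount if T <= 2 else P+1."""
    b = _as_bits(bits)
    P = b.size if P is None else P
    if P != b.size:
        raise ValueError("P does not match bit string length")
    return int(b.sum()) if transition_count(b) <= 2 else P + 1


def lqp_basic_code(bits) -> int:
    """Plain binary code: the written bit string read MSB-first.

    '00111100' -> 60, '00001111' -> 15.
    """
    b = _as_bits(bits)
    if b.size > 30:
        raise ValueError("basic codes limited to P <= 30")
    return int(b.dot(1 << np.arange(b.size - 1, -1, -1, dtype=np.int64)))


def _rot1(v: np.ndarray, P: int, mask: int) -> np.ndarray:
    return ((v >> 1) | (v << (P - 1))) & mask


@lru_cache(maxsize=16)
def code_table(P: int, variant: str = "riu4") -> np.ndarray:
    """Lookup table mapping every packed P-bit pattern to its code.

    Patterns are packed MSB-first (first sampled neighbour = most
    significant bit).  Cached per (P, variant); the riu4 table is built with
    vectorised circular erosions to find the longest 1-run.
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}")
    if variant == "basic":
        if P > 24:
            raise ValueError("basic lookup table limited to P <= 24")
        return np.arange(1 << P, dtype=np.uint32)
    n = 1 << P
    mask = n - 1
    v = np.arange(n, dtype=np.uint32)
    T = np.bitwise_count(v ^ _rot1(v, P, mask))
    pc = np.bitwise_count(v)
    if variant == "riu2":
        return np.where(T <= 2, pc, P + 1).astype(np.uint32)
    dim = per_channel_dim(P, "riu4")
    out = np.full(n, dim - 1, dtype=np.uint32)
    uniform = T <= 2
    out[uniform] = pc[uniform]
    two_run = T == 4
    # longest circular 1-run via iterated erosion: e_k != 0 iff a run >= k
    longest = np.zeros(n, dtype=np.int64)
    e = v.copy()
    for k in range(1, P + 1):
        alive = e != 0
        if not alive.any():
            break
        longest[alive] = k
        e = e & _rot1(e, P, mask)
    y = longest[two_run]
    x = pc[two_run].astype(np.int64) - y
    index = (x - 1) * (P - 1 - x) + y - x + 1
    out[two_run] = P + index
    return out


def sample_circle(
    image: np.ndarray,
    mask: np.ndarray | None,
    centre: tuple[int, int],
    spec: NeighborhoodSpec,
) -> tuple[np.ndarray, bool]:
    """Bilinearly sample ``P`` neighbours on a circle around ``centre``.

    Samples start at the upper-left diagonal of the centre and proceed
    clockwise.  Returns ``(values, valid)``; ``valid`` is False if any sample
    needs support pixels outside the image or outside the mask.
    """
    image = np.asarray(image, dtype=np.float64)
    if mask is None:
        mask = np.ones(image.shape, dtype=bool)
    r0, c0 = centre
    if not mask[r0, c0]:
        raise ValueError("centre must lie inside the mask")
    vals, ok = _sample_many(
        image, np.asarray(mask, bool), np.array([r0]), np.array([c0]), spec
    )
    return vals[:, 0], bool(ok[0])


def _circle_offsets(spec: NeighborhoodSpec) -> tuple[np.ndarray, np.ndarray]:
    # start at the top-left diagonal, clockwise on screen (rows grow down)
    angles = 5 * np.pi / 4 + 2 * np.pi * np.arange(spec.n_points) / spec.n_points
    return spec.radius * np.sin(angles), spec.radius * np.cos(angles)


def _sample_many(image, mask, rows, cols, spec):
    """Sample circles around many centres at once.

    Returns ``(values, valid)`` with shapes ``(P, n)`` and ``(n,)``.  A
    sample is supported by up to four grid pixels; support pixels with zero
    bilinear weight (exact grid hits) are not required to be inside.
    """
    H, W = image.shape
    d_row, d_col = _circle_offsets(spec)
    rr = rows[None, :] + d_row[:, None]
    cc = cols[None, :] + d_col[:, None]
    fr = np.floor(rr)
    fc = np.floor(cc)
    wr = rr - fr
    wc = cc - fc
    r0 = fr.astype(np.int64)
    c0 = fc.astype(np.int64)
    vals = np.zeros(rr.shape, dtype=np.float64)
    ok = np.ones(rr.shape, dtype=bool)
    eps = 1e-12
    for dr, dc, w in (
        (0, 0, (1 - wr) * (1 - wc)),
        (0, 1, (1 - wr) * wc),
        (1, 0, wr * (1 - wc)),
        (1, 1, wr * wc),
    ):
        r = r0 + dr
        c = c0 + dc
        inside = (r >= 0) & (r < H) & (c >= 0) & (c < W)
        rs = np.clip(r, 0, H - 1)
        cs = np.clip(c, 0, W - 1)
        supported = inside & mask[rs, cs]
        needed = w > eps
        ok &= supported | ~needed
        vals += np.where(needed & supported, w * image[rs, cs], 0.0)
    return vals, ok.all(axis=0)


@dataclass
class CodeImageSet:
    """Per-pixel codes, one ``(scale, sub-pattern)`` plane per channel group.

    ``codes`` has shape ``(n_scales, 4, H, W)``; entries are meaningful only
    where the matching ``valid[scale]`` plane is True.  The channel map
    enumerates ``(scale, sub-pattern, code)`` triples in a fixed order:
    scales outer, sub-patterns middle, code values inner.
    """

    codes: np.ndarray
    valid: np.ndarray
    specs: tuple[NeighborhoodSpec, ...]
    variant: str
    mask: np.ndarray

    @property
    def n_scales(self) -> int:
        return len(self.specs)

    @property
    def channel_dims(self) -> tuple[int, ...]:
        return tuple(per_channel_dim(s.n_points, self.variant) for s in self.specs)

    @property
    def total_dim(self) -> int:
        return 4 * sum(self.channel_dims)

    def channel_index(self, scale: int, sub: int, code: int) -> int:
        """Flat channel index of (scale 0-based, sub-pattern 0-based, code)."""
        dims = self.channel_dims
        if not 0 <= scale < self.n_scales:
            raise KeyError("scale out of range")
        if not 0 <= sub < 4:
            raise KeyError("sub-pattern out of range")
        if not 0 <= code < dims[scale]:
            raise KeyError("code out of range for this scale")
        return 4 * sum(dims[:scale]) + sub * dims[scale] + code

    def channels(self) -> Iterable[tuple[int, int, int]]:
        """Iterate (scale, sub, code) in flat channel order."""
        for s, dim in enumerate(self.channel_dims):
            for i in range(4):
                for c in range(dim):
                    yield s, i, c

    def channel_names(self) -> list[str]:
        return [
            f"scale{s + 1}_sub{i + 1}_code{c}" for s, i, c in self.channels()
        ]

    def plane(self, scale: int, sub: int) -> tuple[np.ndarray, np.ndarray]:
        """Return (codes, valid) arrays for one (scale, sub-pattern) plane."""
        return self.codes[scale, sub], self.valid[scale]


def encode_image(
    image: np.ndarray,
    mask: np.ndarray | None,
    specs: Sequence[NeighborhoodSpec] = DEFAULT_SCALES,
    rule: ThresholdRule = ThresholdRule(),
    variant: str = "riu4",
) -> CodeImageSet:
    """Encode every maskable pixel of ``image`` at all scales.

    A pixel is encoded at a given scale only when all ``P`` circle samples
    (and their bilinear support pixels) lie inside the mask; this prevents
    background intensities from leaking into breast-region codes.  The
    quinary thresholds are adaptive per pixel: ``tau = p * I_c``.
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}")
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2:
        raise ValueError("image must be 2-D")
    if mask is None:
        mask = np.ones(image.shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != image.shape:
        raise ValueError("mask shape must match image shape")
    if not mask.any():
        raise ValueError("empty mask: nothing to encode")
    specs = tuple(specs)
    H, W = image.shape
    rows, cols = np.nonzero(mask)
    codes = np.zeros((len(specs), 4, H, W), dtype=np.uint32)
    valid = np.zeros((len(specs), H, W), dtype=bool)
    any_valid = False
    for si, spec in enumerate(specs):
        P = spec.n_points
        lut = code_table(P, variant)
        samples, ok = _sample_many(image, mask, rows, cols, spec)
        if not ok.any():
            continue
        any_valid = True
        centre = image[rows, cols]
        diffs = samples[:, ok] - centre[ok]
        tau1 = rule.p1 * centre[ok]
        tau2 = rule.p2 * centre[ok]
        levels = quinary_level(diffs, tau1[None, :], tau2[None, :])
        weights = (1 << np.arange(P - 1, -1, -1, dtype=np.uint64))[:, None]
        targets = (2, 1, -1, -2)
        for i, target in enumerate(targets):
            bits = (levels == target).astype(np.uint64)
            packed = (bits * weights).sum(axis=0)
            codes[si, i, rows[ok], cols[ok]] = lut[packed]
        valid[si, rows[ok], cols[ok]] = True
    if not any_valid:
        raise ValueError("no pixel has a fully in-mask neighbourhood")
    return CodeImageSet(codes=codes, valid=valid, specs=specs, variant=variant, mask=mask)
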