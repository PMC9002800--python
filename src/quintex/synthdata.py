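"""Deterministic synthetic fixtures: texture phantoms and point patterns.

The phantom generator emulates the *structure* of a screening-mammogram
dataset — a bright breast-shaped region on a dark background, per-image
density class, two images per woman — without attempting realistic
mammographic grey-level statistics.  Density class k in 1..4 monotonically
scales the amount of bright "dense tissue" microstructure: blob-like focal
densities and thin stripes standing in for fibroglandular strands.  These
give the texture encoder genuinely different spot/edge/stripe microstructure
per class.

Point-pattern generators provide the three canonical spatial regimes used to
validate the K-function: complete spatial randomness (Poisson), parent-
offspring clustering, and hard-core (minimum-distance) inhibition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .kspatial import PointPattern

__all__ = [
    "PhantomSpec",
    "make_phantom",
    "make_point_pattern",
    "make_dataset",
    "write_dataset",
]


@dataclass(frozen=True)
class PhantomSpec:
    """Recipe for one synthetic mammogram-like image.

    ``density_class`` (1..4) controls the fraction of bright microstructure;
    the same seed always yields byte-identical output.
    """

    density_class: int
    size: int = 128
    seed: int = 0
    woman_id: str = "W0000"
    base_intensity: float = 90.0
    background: float = 4.0
    noise_sd: float = 4.0
    blobs_per_class: int = 6
    stripes_per_class: int = 3
    blob_contrast: float = 60.0
    add_label_artifact: bool = False

    def __post_init__(self) -> None:
        if not 1 <= self.density_class <= 4:
            raise ValueError("density_class must be in 1..4")
        if self.size < 32:
            raise ValueError("size must be >= 32")


def _half_ellipse_mask(size: int) -> np.ndarray:
    """Breast-like window: half-ellipse attached to the left image edge."""
    rr, cc = np.mgrid[0:size, 0:size]
    cy = size / 2.0
    a = 0.92 * size  # horizontal semi-axis (chest wall at column 0)
    b = 0.46 * size
    return (cc / a) ** 2 + ((rr - cy) / b) ** 2 <= 1.0


def make_phantom(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray, int, str]:
    """Render one phantom: (image, mask, label, woman_id).

    The breast interior holds a smooth intensity ramp plus Gaussian noise;
    class-k phantoms receive ``k * blobs_per_class`` bright discs and
    ``k * stripes_per_class`` thin bright stripes, all confined to the mask.
    """
    rng = np.random.default_rng(spec.seed)
    size = spec.size
    mask = _half_ellipse_mask(size)
    rr, cc = np.mgrid[0:size, 0:size]
    ramp = 1.0 - 0.35 * cc / size  # tissue thins toward the nipple side
    image = np.full((size, size), spec.background, dtype=np.float64)
    image[mask] = spec.base_intensity * ramp[mask]
    image += rng.normal(0.0, spec.noise_sd, size=image.shape)

    k = spec.density_class
    inner_rows, inner_cols = np.nonzero(mask)
    for _ in range(k * spec.blobs_per_class):
        j = rng.integers(len(inner_rows))
        r0, c0 = inner_rows[j], inner_cols[j]
        radius = rng.uniform(2.0, 3.5 + 0.5 * k)
        dist2 = (rr - r0) ** 2 + (cc - c0) ** 2
        bump = spec.blob_contrast * np.exp(-dist2 / (2 * radius**2))
        image += np.where(mask, bump, 0.0)
    for _ in range(k * spec.stripes_per_class):
        j = rng.integers(len(inner_rows))
        r0, c0 = float(inner_rows[j]), float(inner_cols[j])
        theta = rng.uniform(0, np.pi)
        length = rng.uniform(0.2, 0.5) * size
        # signed distance to the stripe's centre line, thickness ~1.5 px
        d_line = (rr - r0) * np.cos(theta) - (cc - c0) * np.sin(theta)
        along = (rr - r0) * np.sin(theta) + (cc - c0) * np.cos(theta)
        stripe = (np.abs(d_line) < 1.5) & (np.abs(along) < length / 2)
        image += np.where(mask & stripe, 0.8 * spec.blob_contrast, 0.0)
    if spec.add_label_artifact:
        s = max(size // 12, 4)
        image[2 : 2 + s, size - s - 2 : size - 2] = spec.base_intensity * 1.5
    image = np.clip(image, 0.0, None)
    return image, mask, spec.density_class, spec.woman_id


def make_point_pattern(
    kind: str,
    intensity: float,
    window: np.ndarray,
    seed: int,
    cluster_parent_fraction: float = 0.05,
    cluster_radius: float = 5.0,
    hardcore_radius: float = 5.0,
    max_attempts: int = 200_000,
) -> PointPattern:
    """Sample a point pattern with a known spatial regime inside ``window``.

    ``poisson``: CSR with expected count ``intensity * |W|``;
    ``cluster``: Matern-style parent/offspring aggregation with the same
    expected count; ``hardcore``: sequential inhibition with minimum
    pairwise distance ``hardcore_radius`` (raises if the target count cannot
    be placed within ``max_attempts`` proposals).
    """
    window = np.asarray(window, dtype=bool)
    if not window.any():
        raise ValueError("window is empty")
    rng = np.random.default_rng(seed)
    area = float(window.sum())
    H, W = window.shape

    def uniform_in_window(count: int) -> np.ndarray:
        out = np.empty((0, 2))
        while len(out) < count:
            cand = rng.uniform(0, (H, W), size=(max(count * 2, 64), 2))
            idx = np.floor(cand).astype(int)
            cand = cand[window[idx[:, 0], idx[:, 1]]]
            out = np.vstack([out, cand])
        return out[:count]

    if kind == "poisson":
        n = rng.poisson(intensity * area)
        pts = uniform_in_window(n)
    elif kind == "cluster":
        n_parents = max(1, rng.poisson(cluster_parent_fraction * intensity * area))
        parents = uniform_in_window(n_parents)
        mean_offspring = intensity * area / n_parents
        pts_list = []
        for p in parents:
            m = rng.poisson(mean_offspring)
            ang = rng.uniform(0, 2 * np.pi, m)
            rad = cluster_radius * np.sqrt(rng.uniform(0, 1, m))
            child = p + np.column_stack([rad * np.sin(ang), rad * np.cos(ang)])
            keep = (
                (child[:, 0] >= 0)
                & (child[:, 0] < H)
                & (child[:, 1] >= 0)
                & (child[:, 1] < W)
            )
            child = child[keep]
            idx = np.floor(child).astype(int)
            pts_list.append(child[window[idx[:, 0], idx[:, 1]]])
        pts = np.vstack(pts_list) if pts_list else np.empty((0, 2))
    elif kind == "hardcore":
        target = int(round(intensity * area))
        accepted: list[np.ndarray] = []
        attempts = 0
        while len(accepted) < target:
            attempts += 1
            if attempts > max_attempts:
                raise RuntimeError(
                    "hardcore intensity too high for the requested radius"
                )
            cand = uniform_in_window(1)[0]
            if all(np.hypot(*(cand - q)) >= hardcore_radius for q in accepted):
                accepted.append(cand)
        pts = np.array(accepted)
    else:
        raise ValueError("kind must be 'poisson', 'cluster' or 'hardcore'")
    return PointPattern(points=pts, window=window)


def make_dataset(
    n_per_class: int,
    classes: tuple[int, ...] = (1, 2, 3, 4),
    seed: int = 0,
    size: int = 128,
) -> list[dict]:
    """Balanced labelled phantom set with woman IDs, two images per woman.

    ``n_per_class`` must be even so every synthetic woman contributes a
    left/right pair with a shared density class.  Records carry keys
    ``image``, ``mask``, ``label``, ``woman_id``, ``view``.
    """
    if n_per_class % 2 != 0:
        raise ValueError("n_per_class must be even (two images per woman)")
    ss = np.random.SeedSequence(seed)
    records = []
    woman_counter = 0
    for label in classes:
        for _ in range(n_per_class // 2):
            woman_counter += 1
            woman = f"W{woman_counter:04d}"
            for side in ("L", "R"):
                child_seed = int(ss.spawn(1)[0].generate_state(1)[0] % (2**31))
                image, mask, _, _ = make_phantom(
                    PhantomSpec(
                        density_class=label, size=size, seed=child_seed, woman_id=woman
                    )
                )
                records.append(
                    {
                        "image": image,
                        "mask": mask,
                        "label": label,
                        "woman_id": woman,
                        "view": "MLO",
                        "side": side,
                    }
                )
    return records


def write_dataset(records: list[dict], directory: str | Path) -> list[Path]:
    """Write a phantom dataset as PGM images + JSON sidecars (MIAS layout)."""
    from . import io as qio

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, rec in enumerate(records):
        path = directory / f"phantom_{i:03d}.pgm"
        qio.write_pgm(path, rec["image"])
        qio.write_sidecar(
            path,
            {
                "label": int(rec["label"]),
                "woman_id": rec["woman_id"],
                "view": rec.get("view", "MLO"),
                "side": rec.get("side", ""),
                "synthetic": True,
            },
        )
        paths.append(path)
    return paths
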