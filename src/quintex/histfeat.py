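"""Fixed-length histogram feature vectors from code images.

One bin per (scale, sub-pattern, code) channel, ordered scales outer,
sub-patterns middle, codes inner — the same ordering as the channel map of a
:class:`~quintex.encoder.CodeImageSet` — so histogram and K-spectrum blocks
align entry-for-entry and can be concatenated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["FeatureVector", "histogram_vector", "concat_features", "features_to_frame"]


@dataclass
class FeatureVector:
    """Ordered, named feature values with named blocks.

    Names carry a block tag prefix ("hist:..." / "kspec:...") so concatenated
    vectors remain unambiguous.
    """

    values: np.ndarray
    names: list[str]
    blocks: dict[str, slice] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64).ravel()
        if len(self.names) != self.values.size:
            raise ValueError("names and values must have equal length")
        if len(set(self.names)) != len(self.names):
            raise ValueError("feature names must be unique")

    def __len__(self) -> int:
        return self.values.size

    def stripped_names(self) -> list[str]:
        """Channel names without their block tag."""
        return [n.split(":", 1)[-1] for n in self.names]


def histogram_vector(codes, normalize: bool = True) -> FeatureVector:
    """Code histogram over all (scale, sub-pattern) planes.

    Raw bin values are pixel counts; with ``normalize=True`` each plane is
    L1-normalised separately, making the block invariant to breast-region
    size.  Length is 656 under the default three-scale riu4 configuration.
    """
    chunks: list[np.ndarray] = []
    names: list[str] = []
    for s, dim in enumerate(codes.channel_dims):
        plane_codes = codes.codes[s]
        valid = codes.valid[s]
        if not valid.any():
            raise ValueError("plane has no valid pixels")
        for i in range(4):
            counts = np.bincount(plane_codes[i][valid], minlength=dim).astype(np.float64)
            if counts.size != dim:
                raise AssertionError("code outside channel alphabet")
            if normalize:
                total = counts.sum()
                if total > 0:
                    counts = counts / total
            chunks.append(counts)
            names.extend(f"hist:scale{s + 1}_sub{i + 1}_code{c}" for c in range(dim))
    values = np.concatenate(chunks)
    return FeatureVector(values=values, names=names, blocks={"hist": slice(0, len(names))})


def concat_features(hist: FeatureVector, kspec: FeatureVector) -> FeatureVector:
    """Concatenate histogram and K-spectrum blocks (656 + 656 -> 1312).

    The two vectors must describe the same channel map; an empty second
    vector is allowed and returns the first unchanged.
    """
    if len(kspec) == 0:
        return hist
    if len(hist) == 0:
        return kspec
    if hist.stripped_names() != kspec.stripped_names():
        raise ValueError("feature vectors have mismatched channel maps")
    values = np.concatenate([hist.values, kspec.values])
    names = list(hist.names) + list(kspec.names)
    blocks = {}
    offset = 0
    for fv in (hist, kspec):
        for tag, sl in fv.blocks.items():
            blocks[tag] = slice(sl.start + offset, sl.stop + offset)
        offset += len(fv)
    return FeatureVector(values=values, names=names, blocks=blocks)


def features_to_frame(records) -> pd.DataFrame:
    """Tabulate (FeatureVector, label, woman_id) records, one row per image.

    Column order is the feature order; `label` and `woman_id` come last.
    All rows must share one feature name sequence.
    """
    rows = []
    names = None
    labels, women = [], []
    for fv, label, woman in records:
        if names is None:
            names = list(fv.names)
        elif list(fv.names) != names:
            raise ValueError("inconsistent feature names across records")
        rows.append(fv.values)
        labels.append(label)
        women.append(woman)
    frame = pd.DataFrame(np.vstack(rows), columns=names)
    frame["label"] = labels
    frame["woman_id"] = women
    return frame
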