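"""Concatenated, normalized structural feature matrices.

Each sequence window contributes one smoothed profile per scale; profiles
are min-max normalized to [0, 1] using the scale's own theoretical extrema
(so construction is deterministic and train/test-identical) and
concatenated feature-by-feature into a ``samples x (n_scales * window)``
matrix with a dimension -> (feature, TSS-relative position) index.
"""

from __future__ import annotations

from collections.abc import Sequence
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .datasets import PROMOTER, LabeledSequenceSet
from .profiles import WINDOW_UPSTREAM, PropertyScale, profile_matrix

__all__ = ["FeatureMatrix", "build_matrix", "dims_for_feature"]


@dataclass
class FeatureMatrix:
    """Normalized samples x dimensions matrix with labels and a dim index."""

    X: np.ndarray
    y: np.ndarray
    index: list[tuple[str, int]]
    ids: list[str]
    normalization: dict

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=bool)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D")
        if self.X.shape[0] != self.y.shape[0]:
            raise ValueError("X and y disagree on sample count")
        if self.X.shape[1] != len(self.index):
            raise ValueError("index length must equal dimension count")
        if len(self.ids) != self.X.shape[0]:
            raise ValueError("ids length must equal sample count")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_dims(self) -> int:
        return self.X.shape[1]

    @property
    def feature_names(self) -> list[str]:
        seen: dict[str, None] = {}
        for feat, _ in self.index:
            seen.setdefault(feat)
        return list(seen)

    def dim_of(self, feature: str, position: int) -> int:
        try:
            return self.index.index((feature, position))
        except ValueError as exc:
            raise KeyError(f"no dimension for ({feature!r}, {position})") from exc

    def to_frame(self) -> pd.DataFrame:
        cols = [f"{feat}@{pos:+d}" for feat, pos in self.index]
        df = pd.DataFrame(self.X, index=self.ids, columns=cols)
        df["label"] = np.where(self.y, PROMOTER, "non-promoter")
        return df

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="id")


def build_matrix(
    seq_set: LabeledSequenceSet,
    scales: Sequence[PropertyScale],
    up: int = WINDOW_UPSTREAM,
) -> FeatureMatrix:
    """Build the concatenated normalized matrix for a labelled window set.

    Scales are processed in the given order; each contributes a contiguous
    block of window-length columns scaled by ``(v - vmin) / (vmax - vmin)``
    with the bounds taken from the scale itself.
    """
    if not scales:
        raise ValueError("need at least one scale")
    ids = seq_set.ids()
    if len(ids) < 2:
        raise ValueError("need at least two samples")
    y = np.array([seq_set.labels[i] == PROMOTER for i in ids], dtype=bool)
    if y.all() or (~y).all():
        raise ValueError("both classes must be present")
    seqs = [seq_set.sequences[i] for i in ids]
    window = len(seqs[0])

    blocks: list[np.ndarray] = []
    index: list[tuple[str, int]] = []
    norm: dict[str, tuple[float, float]] = {}
    positions = np.arange(-up, window - up)
    for scale in scales:
        if scale.vmax <= scale.vmin:
            raise ValueError(
                f"scale {scale.name!r} is degenerate (vmin == vmax); "
                "cannot normalize"
            )
        block = profile_matrix(seqs, scale, window_length=window)
        block = (block - scale.vmin) / (scale.vmax - scale.vmin)
        np.clip(block, 0.0, 1.0, out=block)  # guard float round-off only
        blocks.append(block)
        index.extend((scale.name, int(p)) for p in positions)
        norm[scale.name] = (scale.vmin, scale.vmax)
    X = np.concatenate(blocks, axis=1)
    return FeatureMatrix(
        X=X,
        y=y,
        index=index,
        ids=ids,
        normalization={"method": "scale-minmax", "bounds": norm},
    )


def dims_for_feature(fm: FeatureMatrix, feature: str) -> np.ndarray:
    """Contiguous dimension indices of one feature's column block."""
    dims = np.array([d for d, (feat, _) in enumerate(fm.index) if feat == feature])
    if dims.size == 0:
        raise KeyError(f"unknown feature {feature!r}")
    return dims
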