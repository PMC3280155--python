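"""Structural property scales and per-position structural profiles.

A :class:`PropertyScale` maps every k-mer (k = 2 or 3) over ``ACGT`` to a
real-valued biophysical quantity.  Sliding the mapping along a DNA sequence
yields a raw numeric vector; after right-edge padding and moving-average
smoothing (window 3, step 1) each promoter window of 251 nt becomes a
251-long :class:`StructuralProfile` anchored on TSS-relative coordinates
-200..+50.
"""

from __future__ import annotations

import functools
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

__all__ = [
    "DEFAULT_FEATURE_ORDER",
    "WINDOW_UPSTREAM",
    "WINDOW_DOWNSTREAM",
    "WINDOW_LENGTH",
    "PropertyScale",
    "StructuralProfile",
    "load_scale",
    "load_default_scales",
    "raw_profile",
    "smooth",
    "convert_sequence",
    "average_profile",
    "profile_matrix",
]

BASES = "ACGT"
_BASE_CODE = {b: i for i, b in enumerate(BASES)}

#: Promoter window geometry: 200 bases upstream, the TSS base, 50 downstream.
WINDOW_UPSTREAM = 200
WINDOW_DOWNSTREAM = 50
WINDOW_LENGTH = WINDOW_UPSTREAM + WINDOW_DOWNSTREAM + 1

#: Fraction of ambiguous (non-ACGT) bases above which a sequence is rejected.
MAX_AMBIGUOUS_FRACTION = 0.10

#: Canonical ordering of the thirteen bundled structural features.
DEFAULT_FEATURE_ORDER = (
    "a_philicity",
    "b_dna_twist",
    "bendability",
    "stacking_energy",
    "dna_bending_stiffness",
    "dna_denaturation",
    "duplex_free_energy",
    "duplex_disrupt_energy",
    "nucleosome_position",
    "propeller_twist",
    "protein_deformation",
    "protein_dna_twist",
    "z_dna",
)


@dataclass(frozen=True)
class PropertyScale:
    """A complete k-mer -> value conversion schema for one structural feature.

    Parameters
    ----------
    name:
        Feature identifier (e.g. ``"duplex_free_energy"``).
    k:
        k-mer order, 2 or 3.
    values:
        Total mapping from all ``4**k`` k-mers over ``ACGT`` to floats.
    """

    name: str
    k: int
    values: Mapping[str, float]
    vmin: float = field(init=False)
    vmax: float = field(init=False)

    def __post_init__(self) -> None:
        if self.k not in (2, 3):
            raise ValueError(f"k must be 2 or 3, got {self.k}")
        expected = 4 ** self.k
        if len(self.values) != expected:
            raise ValueError(
                f"scale {self.name!r}: expected {expected} {self.k}-mers, "
                f"got {len(self.values)}"
            )
        for kmer, value in self.values.items():
            if len(kmer) != self.k or any(b not in _BASE_CODE for b in kmer):
                raise ValueError(f"scale {self.name!r}: bad k-mer {kmer!r}")
            if not np.isfinite(value):
                raise ValueError(f"scale {self.name!r}: non-finite value for {kmer}")
        vals = np.fromiter(self.values.values(), dtype=float)
        object.__setattr__(self, "vmin", float(vals.min()))
        object.__setattr__(self, "vmax", float(vals.max()))

    @classmethod
    def from_values(cls, name: str, values: Mapping[str, float]) -> "PropertyScale":
        ks = {len(kmer) for kmer in values}
        if len(ks) != 1:
            raise ValueError(f"scale {name!r}: mixed k-mer lengths {sorted(ks)}")
        return cls(name=name, k=ks.pop(), values=dict(values))

    @functools.cached_property
    def lookup(self) -> np.ndarray:
        """Values indexed by base-4 k-mer code (A=0, C=1, G=2, T=3)."""
        table = np.empty(4 ** self.k, dtype=float)
        for kmer, value in self.values.items():
            code = 0
            for b in kmer:
                code = code * 4 + _BASE_CODE[b]
            table[code] = value
        return table

    @property
    def mean_value(self) -> float:
        return float(self.lookup.mean())


def load_scale(path: str | Path, name: str | None = None) -> PropertyScale:
    """Read a two-column ``kmer<TAB>value`` schema file.

    The file must cover the full k-mer alphabet for a single k in {2, 3};
    missing k-mers, mixed lengths, duplicates and non-numeric values raise
    ``ValueError``.
    """
    path = Path(path)
    values: dict[str, float] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if lineno == 1 and parts[0].lower() == "kmer":
                continue
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns, got {len(parts)}")
            kmer = parts[0].upper()
            try:
                value = float(parts[1])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric value {parts[1]!r}") from exc
            if kmer in values:
                raise ValueError(f"{path}:{lineno}: duplicate k-mer {kmer!r}")
            values[kmer] = value
    if not values:
        raise ValueError(f"{path}: empty schema file")
    return PropertyScale.from_values(name or path.stem, values)


@functools.lru_cache(maxsize=1)
def _default_scales() -> tuple[PropertyScale, ...]:
    root = resources.files("promstruct") / "data" / "scales"
    scales = []
    for feat in DEFAULT_FEATURE_ORDER:
        with resources.as_file(root / f"{feat}.tsv") as p:
            scales.append(load_scale(p, name=feat))
    return tuple(scales)


def load_default_scales(names: Iterable[str] | None = None) -> list[PropertyScale]:
    """Return the bundled scales, in canonical order or the order of *names*."""
    by_name = {s.name: s for s in _default_scales()}
    if names is None:
        return list(_default_scales())
    try:
        return [by_name[n] for n in names]
    except KeyError as exc:
        raise KeyError(f"unknown scale {exc.args[0]!r}; known: {sorted(by_name)}") from exc


@dataclass(frozen=True)
class StructuralProfile:
    """Smoothed per-position structural signal for one sequence/feature."""

    feature: str
    values: np.ndarray
    positions: np.ndarray

    def __post_init__(self) -> None:
        if len(self.values) != len(self.positions):
            raise ValueError("values and positions must have equal length")


def _encode(seq: str) -> np.ndarray:
    """Sequence -> integer codes; non-ACGT bases become -1."""
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    codes = np.full(arr.shape, -1, dtype=np.int64)
    for base, code in _BASE_CODE.items():
        codes[arr == ord(base)] = code
    return codes


def _kmer_values(codes: np.ndarray, scale: PropertyScale) -> np.ndarray:
    """Map an encoded sequence (1-D) or batch (2-D) to k-mer scale values.

    k-mers containing an ambiguous base get the scale's mean value.
    """
    k = scale.k
    ambiguous = codes < 0
    safe = np.where(ambiguous, 0, codes)
    idx = safe[..., : codes.shape[-1] - k + 1].copy()
    bad = ambiguous[..., : codes.shape[-1] - k + 1].copy()
    for offset in range(1, k):
        idx = idx * 4 + safe[..., offset : codes.shape[-1] - k + 1 + offset]
        bad |= ambiguous[..., offset : codes.shape[-1] - k + 1 + offset]
    out = scale.lookup[idx]
    out[bad] = scale.mean_value
    return out


def raw_profile(seq: str, scale: PropertyScale) -> np.ndarray:
    """Replace each k-mer of *seq* by its scale value.

    Output length is ``len(seq) - k + 1``; element ``i`` is the value of
    ``seq[i:i+k]``.
    """
    if len(seq) < scale.k:
        raise ValueError(
            f"sequence of length {len(seq)} shorter than k={scale.k}"
        )
    return _kmer_values(_encode(seq), scale)


def smooth(
    raw: Sequence[float] | np.ndarray,
    window: int = 3,
    step: int = 1,
    pad: bool = True,
) -> np.ndarray:
    """Centered moving average with window 3 / step 1 defaults.

    With ``pad=True`` the terminal values are replicated ``window // 2``
    times on each end so output length equals input length (for step 1).
    With ``pad=False`` only fully covered windows are returned.
    """
    arr = np.asarray(raw, dtype=float)
    if arr.ndim != 1:
        raise ValueError("smooth expects a 1-D vector")
    if arr.size == 0:
        raise ValueError("cannot smooth an empty vector")
    if window < 1 or window % 2 == 0:
        raise ValueError(f"window must be odd and positive, got {window}")
    if step < 1:
        raise ValueError(f"step must be positive, got {step}")
    half = window // 2
    if pad:
        arr = np.concatenate([np.repeat(arr[0], half), arr, np.repeat(arr[-1], half)])
    if window > arr.size:
        raise ValueError("window larger than (padded) input")
    kernel = np.full(window, 1.0 / window)
    out = np.convolve(arr, kernel, mode="valid")
    return out[::step]


def _window_positions(window_length: int, up: int) -> np.ndarray:
    return np.arange(-up, window_length - up)


def _check_ambiguity(codes: np.ndarray, label: str = "sequence") -> None:
    frac = np.mean(codes < 0, axis=-1)
    if np.any(frac > MAX_AMBIGUOUS_FRACTION):
        raise ValueError(
            f"{label} has >{MAX_AMBIGUOUS_FRACTION:.0%} ambiguous bases"
        )


def convert_sequence(
    seq: str,
    scale: PropertyScale,
    window_length: int = WINDOW_LENGTH,
    up: int = WINDOW_UPSTREAM,
    smooth_window: int = 3,
) -> StructuralProfile:
    """Convert one promoter-window sequence into a structural profile.

    The raw k-mer vector (length ``window_length - k + 1``) is aligned to
    the position of each k-mer's first base, right-padded by replicating the
    terminal value, then smoothed — so the result always has exactly
    *window_length* entries on TSS-relative coordinates.
    """
    if len(seq) != window_length:
        raise ValueError(
            f"expected window of {window_length} nt, got {len(seq)}"
        )
    codes = _encode(seq)
    _check_ambiguity(codes)
    raw = _kmer_values(codes, scale)
    if scale.k > 1:
        raw = np.concatenate([raw, np.repeat(raw[-1], scale.k - 1)])
    values = smooth(raw, window=smooth_window)
    return StructuralProfile(
        feature=scale.name,
        values=values,
        positions=_window_positions(window_length, up),
    )


def profile_matrix(
    seqs: Sequence[str],
    scale: PropertyScale,
    window_length: int = WINDOW_LENGTH,
    smooth_window: int = 3,
) -> np.ndarray:
    """Vectorized ``convert_sequence`` over a batch of equal-length windows.

    Returns an ``(n_seqs, window_length)`` array.
    """
    if not seqs:
        raise ValueError("no sequences given")
    lengths = {len(s) for s in seqs}
    if lengths != {window_length}:
        raise ValueError(
            f"all sequences must have length {window_length}, got {sorted(lengths)}"
        )
    codes = np.stack([_encode(s) for s in seqs])
    _check_ambiguity(codes, label="one or more sequences")
    raw = _kmer_values(codes, scale)
    if scale.k > 1:
        tail = np.repeat(raw[:, -1:], scale.k - 1, axis=1)
        raw = np.concatenate([raw, tail], axis=1)
    half = smooth_window // 2
    padded = np.concatenate(
        [np.repeat(raw[:, :1], half, axis=1), raw, np.repeat(raw[:, -1:], half, axis=1)],
        axis=1,
    )
    csum = np.cumsum(padded, axis=1)
    csum = np.concatenate([np.zeros((padded.shape[0], 1)), csum], axis=1)
    return (csum[:, smooth_window:] - csum[:, :-smooth_window]) / smooth_window


def average_profile(
    seqs: Sequence[str],
    scale: PropertyScale,
    window_length: int | None = None,
    up: int = WINDOW_UPSTREAM,
) -> StructuralProfile:
    """Position-wise mean of per-sequence smoothed profiles."""
    seqs = list(seqs)
    if not seqs:
        raise ValueError("need at least one sequence")
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise ValueError(f"sequences have unequal lengths: {sorted(lengths)}")
    wl = window_length if window_length is not None else lengths.pop()
    mat = profile_matrix(seqs, scale, window_length=wl)
    return StructuralProfile(
        feature=scale.name,
        values=mat.mean(axis=0),
        positions=_window_positions(wl, up),
    )
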