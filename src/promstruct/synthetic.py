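"""Synthetic promoter/non-promoter sequence generation.

Negatives are sampled from a first-order Markov chain fitted to (or
supplied for) a background composition, preserving dinucleotide
frequencies.  Positives are the same background with short consensus
elements planted at fixed TSS-relative anchors: a TATA-like box starting
near -30 and an Inr-like element at the TSS, which is what produces the
characteristic trough/peak shapes in averaged structural profiles.
"""

from __future__ import annotations

from collections.abc import Sequence
from dataclasses import dataclass, field

import numpy as np

from .profiles import WINDOW_LENGTH, WINDOW_UPSTREAM

__all__ = [
    "Markov1Model",
    "PromoterSimConfig",
    "fit_markov1",
    "generate_background",
    "generate_promoters",
]

_BASES = np.array(list("ACGT"))
_BASE_CODE = {b: i for i, b in enumerate("ACGT")}

TATA_ANCHOR = -30  # TSS-relative start of the planted TATA-like box
INR_ANCHOR = 0     # TSS-relative start of the planted Inr-like element


@dataclass(frozen=True)
class Markov1Model:
    """First-order Markov model over ACGT.

    ``trans[x, y]`` is P(next = y | current = x); ``initial`` is the
    first-base distribution; ``counts`` keeps the raw dinucleotide counts
    the transitions were estimated from (zeros for hand-built models).
    """

    initial: np.ndarray
    trans: np.ndarray
    counts: np.ndarray = field(default_factory=lambda: np.zeros((4, 4)))

    def __post_init__(self) -> None:
        initial = np.asarray(self.initial, dtype=float)
        trans = np.asarray(self.trans, dtype=float)
        object.__setattr__(self, "initial", initial)
        object.__setattr__(self, "trans", trans)
        object.__setattr__(self, "counts", np.asarray(self.counts, dtype=float))
        if initial.shape != (4,) or trans.shape != (4, 4):
            raise ValueError("initial must be (4,), trans must be (4, 4)")
        if np.any(initial < 0) or np.any(trans < 0):
            raise ValueError("probabilities must be non-negative")
        if abs(initial.sum() - 1.0) > 1e-9:
            raise ValueError("initial distribution must sum to 1")
        if np.max(np.abs(trans.sum(axis=1) - 1.0)) > 1e-9:
            raise ValueError("transition rows must sum to 1")

    @classmethod
    def uniform(cls) -> "Markov1Model":
        return cls(initial=np.full(4, 0.25), trans=np.full((4, 4), 0.25))

    def stationary_dinucleotide_freqs(self) -> np.ndarray:
        """Expected dinucleotide frequencies under the stationary base law."""
        evals, evecs = np.linalg.eig(self.trans.T)
        i = int(np.argmin(np.abs(evals - 1.0)))
        pi = np.real(evecs[:, i])
        pi = pi / pi.sum()
        return pi[:, None] * self.trans


def _encode_seqs(seqs: Sequence[str]) -> list[np.ndarray]:
    out = []
    for s in seqs:
        codes = np.array([_BASE_CODE.get(b, -1) for b in s.upper()], dtype=int)
        out.append(codes)
    return out


def fit_markov1(seqs: Sequence[str], pseudocount: float = 1.0) -> Markov1Model:
    """Estimate a first-order Markov model from dinucleotide counts.

    A Laplace *pseudocount* (default 1) is added to every dinucleotide cell
    so generated sequences have full support; pass ``pseudocount=0`` for
    the bare maximum-likelihood estimate.  Ambiguous bases are ignored.
    """
    seqs = list(seqs)
    if not seqs:
        raise ValueError("need at least one sequence")
    if any(len(s) < 2 for s in seqs):
        raise ValueError("every sequence must have length >= 2")
    counts = np.zeros((4, 4))
    first = np.zeros(4)
    for codes in _encode_seqs(seqs):
        if codes[0] >= 0:
            first[codes[0]] += 1
        a, b = codes[:-1], codes[1:]
        ok = (a >= 0) & (b >= 0)
        np.add.at(counts, (a[ok], b[ok]), 1)
    if counts.sum() == 0:
        raise ValueError("no unambiguous dinucleotides in input")
    smoothed = counts + pseudocount
    row_sums = smoothed.sum(axis=1, keepdims=True)
    # unseen states with no pseudocount fall back to a uniform row
    trans = np.where(row_sums > 0, smoothed / np.where(row_sums > 0, row_sums, 1), 0.25)
    if first.sum() == 0:
        initial = np.full(4, 0.25)
    else:
        initial = (first + pseudocount) / (first.sum() + 4 * pseudocount)
    return Markov1Model(initial=initial, trans=trans, counts=counts)


def _as_rng(seed: int | np.random.Generator | None) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def generate_background(
    model: Markov1Model,
    n: int,
    length: int,
    seed: int | np.random.Generator | None = None,
) -> list[str]:
    """Sample *n* i.i.d. chains of *length* bases from *model*."""
    if n <= 0 or length <= 0:
        raise ValueError("n and length must be positive")
    rng = _as_rng(seed)
    states = np.empty((n, length), dtype=np.int64)
    cum_init = np.cumsum(model.initial)
    cum_trans = np.cumsum(model.trans, axis=1)
    states[:, 0] = np.searchsorted(cum_init, rng.random(n), side="right")
    for t in range(1, length):
        u = rng.random(n)
        rows = cum_trans[states[:, t - 1]]
        states[:, t] = (u[:, None] >= rows).sum(axis=1)
    np.clip(states, 0, 3, out=states)
    return ["".join(row) for row in _BASES[states]]


@dataclass(frozen=True)
class PromoterSimConfig:
    """Configuration for the planted-element promoter simulator."""

    n: int
    length: int = WINDOW_LENGTH
    up: int = WINDOW_UPSTREAM
    tata_motif: str = "TATAAA"
    inr_motif: str = "TCAGTT"
    plant_prob: float = 1.0
    background: Markov1Model = field(default_factory=Markov1Model.uniform)
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValueError("n must be positive")
        if not 0.0 <= self.plant_prob <= 1.0:
            raise ValueError("plant_prob must be in [0, 1]")
        for motif, anchor in self.element_anchors().items():
            start = anchor + self.up
            if start < 0 or start + len(motif) > self.length:
                raise ValueError(
                    f"motif {motif!r} at TSS-relative {anchor} overflows a "
                    f"{self.length}-nt window"
                )

    def element_anchors(self) -> dict[str, int]:
        """TSS-relative start coordinate of each planted element."""
        return {self.tata_motif: TATA_ANCHOR, self.inr_motif: INR_ANCHOR}


def generate_promoters(
    cfg: PromoterSimConfig,
    rng: np.random.Generator | None = None,
) -> tuple[list[str], list[dict]]:
    """Generate promoter-like windows with planted consensus elements.

    Returns the sequences plus a manifest: one dict per sequence with the
    elements actually planted and their window-index start positions.
    """
    rng = _as_rng(rng if rng is not None else cfg.seed)
    seqs = generate_background(cfg.background, cfg.n, cfg.length, seed=rng)
    manifest: list[dict] = []
    for i in range(cfg.n):
        planted: list[dict] = []
        chars = list(seqs[i])
        for motif, anchor in cfg.element_anchors().items():
            if rng.random() <= cfg.plant_prob and cfg.plant_prob > 0:
                start = anchor + cfg.up
                chars[start : start + len(motif)] = list(motif)
                planted.append(
                    {"element": motif, "tss_relative": anchor, "window_start": start}
                )
        seqs[i] = "".join(chars)
        manifest.append({"id": f"sim{i}", "planted": planted})
    return seqs, manifest


def planted_positions(
    cfg: PromoterSimConfig, manifest: Sequence[dict] | None = None
) -> np.ndarray:
    """All TSS-relative positions covered by (potentially) planted elements."""
    positions: set[int] = set()
    if manifest is None:
        for motif, anchor in cfg.element_anchors().items():
            positions.update(range(anchor, anchor + len(motif)))
    else:
        for entry in manifest:
            for p in entry["planted"]:
                positions.update(
                    range(p["tss_relative"], p["tss_relative"] + len(p["element"]))
                )
    return np.array(sorted(positions), dtype=int)
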