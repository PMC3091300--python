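"""Empirical binding-distribution model.

A :class:`BindingModel` is the probability of observing a sequenced 5'
position at a given signed offset from a protein-DNA binding event.
Typical single-TF ChIP data produce a two-shouldered shape: sonication
fragments are sequenced from either end, so forward-strand reads pile up
a few tens of bp upstream of the event and reverse-strand reads the same
distance downstream.  The model drives three steps of the caller: read
extension (its intersection with the uniform density), peak-position
refinement (log-likelihood scanning), and the read-placement distribution
of the synthetic generator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["BindingModel", "default_binding_model", "compute_extension"]

DEFAULT_HALF_WIDTH = 250


@dataclass
class BindingModel:
    """Probability mass over signed offsets ``-W .. +W`` around an event."""

    probs: np.ndarray  # length 2W+1, sums to 1

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=np.float64)
        if self.probs.ndim != 1 or self.probs.size % 2 == 0:
            raise ValueError("binding model must be a 1-d array of odd length")
        if np.any(self.probs < 0):
            raise ValueError("binding model masses must be non-negative")
        s = self.probs.sum()
        if not np.isclose(s, 1.0, atol=1e-9):
            raise ValueError("binding model masses must sum to 1")

    @property
    def half_width(self) -> int:
        return (self.probs.size - 1) // 2

    @property
    def offsets(self) -> np.ndarray:
        W = self.half_width
        return np.arange(-W, W + 1)

    def prob(self, offset: int | np.ndarray) -> np.ndarray:
        """Mass at signed offset(s); 0 outside the support."""
        W = self.half_width
        off = np.asarray(offset)
        inside = (off >= -W) & (off <= W)
        idx = np.clip(off + W, 0, 2 * W)
        return np.where(inside, self.probs[idx], 0.0)

    def log_prob(self, offset: int | np.ndarray, floor: float = 1e-6) -> np.ndarray:
        """Log mass with a floor so out-of-support reads penalize, not -inf."""
        return np.log(np.maximum(self.prob(offset), floor))

    def mirrored(self) -> "BindingModel":
        return BindingModel(self.probs[::-1].copy())

    def sample_offsets(self, n: int, rng: np.random.Generator) -> np.ndarray:
        W = self.half_width
        return rng.choice(2 * W + 1, size=n, p=self.probs) - W

    def total_variation(self, other: "BindingModel") -> float:
        if self.half_width != other.half_width:
            raise ValueError("models must share a support to compare")
        return 0.5 * float(np.abs(self.probs - other.probs).sum())


def default_binding_model(
    half_width: int = DEFAULT_HALF_WIDTH,
    shoulder: int = 35,
    decay: float = 0.95,
) -> BindingModel:
    """Symmetric fragment-shoulder model used before any refit.

    Two geometric-decay peaks at ``±shoulder`` bp emulate the two
    sequenced fragment ends flanking an event; ``decay`` is the per-bp
    geometric ratio away from each shoulder.  Any empirically estimated
    model can replace it via the caller's configuration.
    """
    offs = np.arange(-half_width, half_width + 1)
    mass = decay ** np.abs(np.abs(offs) - shoulder)
    return BindingModel(mass / mass.sum())


def compute_extension(model: BindingModel) -> tuple[int, int]:
    """Offsets where the model density crosses the uniform density.

    Reads are extended to cover the region where binding-event reads are
    more likely than a flat background over the same support: the maximal
    contiguous run of offsets around the mode with mass >= 1/(2W+1).
    Returns absolute endpoint offsets (eL, eR); an everywhere-uniform
    model yields the full support (W, W).
    """
    W = model.half_width
    u = 1.0 / (2 * W + 1)
    above = model.probs >= u
    if above.all():
        return (W, W)
    mode = int(np.argmax(model.probs))
    if not above[mode]:  # degenerate; cannot happen for a proper pmf
        return (0, 0)
    lo = mode
    while lo > 0 and above[lo - 1]:
        lo -= 1
    hi = mode
    while hi < 2 * W and above[hi + 1]:
        hi += 1
    return (max(W - lo, 0), max(hi - W, 0))
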