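"""Lempel–Ziv (LZ76) sequence complexity.

The complexity of a symbol string is the number of components in its
exhaustive production history: reading left to right, each new component is
the shortest prefix of the remaining text that cannot be reproduced by
copying from the already-parsed text (self-overlapping copies allowed).  The
final component is counted once even if the string ends before it becomes
exhaustive.  Under this convention a string of 19 distinct symbols has
complexity 19 and a homopolymer of 19 identical symbols has complexity 2.

Low complexity marks repetitive sequences, which make poor hybridization
probes: a repeat can anneal out of register, breaking the one-probe-one-target
stoichiometry required for single-molecule counting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "lz_complexity",
    "tile_complexity",
    "complexity_stats",
    "DistributionSummary",
]


def lz_complexity(sequence: str) -> int:
    """Number of LZ76 productions needed to build *sequence*.

    Parameters
    ----------
    sequence:
        Non-empty symbol string (any alphabet; case-sensitive).

    Returns
    -------
    int
        The production count, between 1 and ``len(sequence)``.
    """
    n = len(sequence)
    if n == 0:
        raise ValueError("cannot compute LZ complexity of an empty string")
    c = 1  # the first symbol is always a new component
    i = 1  # start of the current component
    while i < n:
        length = 1
        while True:
            if i + length > n:
                break
            # the candidate component is reproducible if it occurs with a
            # start position < i (copying may overlap into the component)
            if sequence.find(sequence[i : i + length], 0, i + length - 1) == -1:
                break
            length += 1
        # either an innovation terminated the component, or we ran off the
        # end (non-exhaustive final component); both count as one production
        c += 1
        i += length
    return c


def tile_complexity(sequence: str, window: int = 19) -> np.ndarray:
    """LZ76 complexity of every length-``window`` substring of *sequence*.

    Returns an integer array of length ``len(sequence) - window + 1``, one
    value per window start.  Used e.g. to profile exon sequence against the
    complexity of candidate probes.
    """
    if window < 1:
        raise ValueError("window must be positive")
    if len(sequence) < window:
        raise ValueError(
            f"sequence length {len(sequence)} is shorter than window {window}"
        )
    return np.array(
        [lz_complexity(sequence[i : i + window]) for i in range(len(sequence) - window + 1)],
        dtype=int,
    )


@dataclass
class DistributionSummary:
    """Summary of an integer-valued complexity distribution."""

    n: int
    mean: float
    sd: float
    bin_edges: np.ndarray
    probabilities: np.ndarray
    values: np.ndarray = field(repr=False)

    def fraction_at_or_above(self, threshold: float) -> float:
        """Exact count ratio of values >= threshold."""
        return float(np.mean(self.values >= threshold))


def complexity_stats(complexities, threshold: int | None = None) -> DistributionSummary:
    """Mean, spread and histogram of a set of complexity values.

    Parameters
    ----------
    complexities:
        Iterable of integers, or of objects with an ``lz_complexity``
        attribute (e.g. :class:`~fastfish.design.OligoRecord`).
    threshold:
        Unused except for convenience: the returned summary exposes
        ``fraction_at_or_above`` for any threshold.
    """
    vals = np.array(
        [getattr(c, "lz_complexity", c) for c in complexities], dtype=float
    )
    if vals.size == 0:
        raise ValueError("empty complexity set")
    lo, hi = int(vals.min()), int(vals.max())
    edges = np.arange(lo - 0.5, hi + 1.5)
    counts, _ = np.histogram(vals, bins=edges)
    return DistributionSummary(
        n=int(vals.size),
        mean=float(vals.mean()),
        sd=float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
        bin_edges=edges,
        probabilities=counts / vals.size,
        values=vals,
    )
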