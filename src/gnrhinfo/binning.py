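"""Discretization of continuous single-cell readouts.

Mutual-information estimation on continuous responses (ppERK intensity,
NFAT nuclear fraction, AUCs, ...) proceeds by binning each readout into a
fixed number of equal-width bins spanning the pooled observed range, so
that the conditional and unconditional entropies share one alphabet.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["BinningSpec", "discretize", "bin_edges"]


@dataclass(frozen=True)
class BinningSpec:
    """How to map a continuous readout onto a discrete alphabet.

    Parameters
    ----------
    n_bins:
        Number of equal-width bins (alphabet size per dimension).
    strategy:
        Only ``"equal-width"`` is supported; equal-count binning is
        deliberately not the default (see package docs).
    lo, hi:
        Optional fixed range.  When omitted the pooled observed min/max
        of the data being discretized is used, which is what makes
        H(Z) and H(Z|S) commensurable.
    """

    n_bins: int = 30
    strategy: str = "equal-width"
    lo: float | None = None
    hi: float | None = None

    def __post_init__(self) -> None:
        if self.n_bins < 1:
            raise ValueError(f"n_bins must be >= 1, got {self.n_bins}")
        if self.strategy != "equal-width":
            raise ValueError(f"unsupported binning strategy: {self.strategy!r}")
        if (self.lo is None) != (self.hi is None):
            raise ValueError("lo and hi must be given together")
        if self.lo is not None and not self.lo < self.hi:
            raise ValueError(f"fixed range needs lo < hi, got ({self.lo}, {self.hi})")


def bin_edges(values: np.ndarray, spec: BinningSpec) -> np.ndarray:
    """Strictly increasing edges of the equal-width bins for ``values``.

    Returns an empty array for a degenerate (zero-width) range, which
    downstream collapses to a single-symbol alphabet.
    """
    values = np.asarray(values, dtype=float)
    if spec.lo is not None:
        lo, hi = float(spec.lo), float(spec.hi)
    else:
        lo, hi = float(values.min()), float(values.max())
    if not (lo < hi):
        return np.empty(0)
    return np.linspace(lo, hi, spec.n_bins + 1)


def discretize(values, spec: BinningSpec = BinningSpec()) -> np.ndarray:
    """Map finite real values to bin indices in ``[0, spec.n_bins)``.

    Bins are half-open ``[e_i, e_{i+1})`` with the top bin closed, so the
    global maximum joins the last bin.  Values falling outside a fixed
    range are clipped into the terminal bins.  A zero-width range (all
    values identical) assigns every record to bin 0: a constant readout
    carries no information and must not crash a pipeline.

    Raises
    ------
    ValueError
        If ``values`` is empty or contains a non-finite entry (the
        offending positions are reported).
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot discretize an empty value array")
    bad = ~np.isfinite(values)
    if bad.any():
        where = np.flatnonzero(bad)[:10]
        raise ValueError(f"non-finite response values at record(s) {where.tolist()}")
    edges = bin_edges(values, spec)
    if edges.size == 0:
        return np.zeros(values.shape, dtype=np.intp)
    # searchsorted on interior edges gives the half-open convention; the
    # top edge is excluded so the maximum lands in the last bin.
    idx = np.searchsorted(edges[1:-1], values, side="right")
    return np.clip(idx, 0, spec.n_bins - 1).astype(np.intp)
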