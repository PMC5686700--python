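"""Mutual-information quantities between stimulus and single-cell responses.

All quantities reduce to NSB (or plug-in) entropies of discretized
responses on a shared alphabet:

    I(Z;S)      = H(Z) - H(Z|S)
    H(Z|S)      = sum_s (n_s/n) H(Z | S=s)
    I(Z1;Z2)    = H(Z1) + H(Z2) - H(Z1,Z2)
    I(Z1;Z2|S)  = sum_s (n_s/n) I(Z1;Z2 | S=s)
    I(Z2;S|Z1)  = I(Z2;S) - I(Z1;Z2) + I(Z1;Z2|S)      (chain rule)

The last line is the "additional information" carried by a second
response (e.g. a second hormone pulse) beyond a first.  Multidimensional
responses are discretized per dimension over the pooled range and mapped
onto the Cartesian-product alphabet.  Posterior standard deviations are
combined in quadrature across the constituent entropy posteriors
(covariances between them are ignored; documented approximation).
Estimates are reported unclamped and may be slightly negative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .binning import BinningSpec, discretize
from .nsb import CountTable, nsb_entropy, plugin_entropy

__all__ = [
    "StimulusResponseSample",
    "MIEstimate",
    "conditional_entropy",
    "mutual_information",
    "joint_mi",
    "trajectory_mi",
    "conditional_mi",
    "additional_information",
]


@dataclass(frozen=True)
class MIEstimate:
    """An information value in bits with its posterior standard deviation."""

    value: float
    sd: float
    n_samples: int
    method: str = "nsb"
    components: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be nonnegative")
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")


class StimulusResponseSample:
    """Per-cell records pairing a categorical stimulus level with a
    1–3 dimensional response vector.

    Parameters
    ----------
    stimulus:
        Length-n array of stimulus labels (any hashable type; numeric
        concentrations are canonically formatted and compared as strings).
    responses:
        (n, d) array of finite response values, d in {1, 2, 3}.
    cell_ids:
        Optional per-record identifiers, carried through for export.
    """

    def __init__(self, stimulus, responses, cell_ids=None):
        responses = np.atleast_2d(np.asarray(responses, dtype=float))
        if responses.shape[0] == 1 and len(stimulus) != 1:
            responses = responses.T
        if responses.ndim != 2 or not 1 <= responses.shape[1] <= 3:
            raise ValueError("responses must be (n, d) with d in 1..3")
        if not np.all(np.isfinite(responses)):
            bad = np.flatnonzero(~np.isfinite(responses).all(axis=1))[:10]
            raise ValueError(f"non-finite response at record(s) {bad.tolist()}")
        labels = np.asarray([_canon(s) for s in stimulus])
        if len(labels) != responses.shape[0]:
            raise ValueError("stimulus and responses length mismatch")
        self.levels, self.codes = np.unique(labels, return_inverse=True)
        self.responses = responses
        self.cell_ids = None if cell_ids is None else np.asarray(cell_ids)

    @property
    def n(self) -> int:
        return self.responses.shape[0]

    @property
    def dim(self) -> int:
        return self.responses.shape[1]

    @property
    def n_levels(self) -> int:
        return len(self.levels)

    def column(self, j: int) -> np.ndarray:
        return self.responses[:, j]

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, signal_col: str, response_cols: list[str],
                       cell_id_col: str | None = None) -> "StimulusResponseSample":
        ids = df[cell_id_col].to_numpy() if cell_id_col and cell_id_col in df else None
        return cls(df[signal_col].to_numpy(), df[list(response_cols)].to_numpy(), ids)

    @classmethod
    def from_csv(cls, path, signal_col: str = "stimulus",
                 response_cols=("z1",), cell_id_col: str = "cell_id"):
        df = pd.read_csv(path)
        cols = [c for c in response_cols if c in df.columns]
        if not cols:
            raise ValueError(f"no response columns {response_cols} in {path}")
        return cls.from_dataframe(df, signal_col, cols,
                                  cell_id_col if cell_id_col in df.columns else None)


def _canon(s) -> str:
    """Canonical string form of a stimulus label (0, 1e-09, 'ctrl', ...)."""
    if isinstance(s, (int, float, np.integer, np.floating)):
        f = float(s)
        return "0" if f == 0 else f"{f:.6g}"
    return str(s)


def _entropy(counts: np.ndarray, k: int, method: str, grid_size: int) -> tuple[float, float]:
    if method == "nsb":
        return nsb_entropy(CountTable(counts, alphabet_size=k), grid_size=grid_size)
    if method == "plugin":
        return plugin_entropy(counts), 0.0
    raise ValueError(f"unknown entropy method {method!r}")


def _product_symbols(sample: StimulusResponseSample, spec) -> tuple[np.ndarray, int]:
    """Discretize every response dimension on the pooled range and flatten
    onto the Cartesian-product alphabet."""
    specs = _per_dim_specs(spec, sample.dim)
    sym = np.zeros(sample.n, dtype=np.int64)
    k = 1
    for j in range(sample.dim):
        values = sample.column(j)
        if specs[j].lo is None and values.min() == values.max():
            continue  # degenerate dimension: single-symbol alphabet
        idx = discretize(values, specs[j])
        sym = sym * specs[j].n_bins + idx
        k *= specs[j].n_bins
    return sym, k


def _per_dim_specs(spec, d: int) -> list[BinningSpec]:
    if isinstance(spec, BinningSpec):
        return [spec] * d
    specs = list(spec)
    if len(specs) != d:
        raise ValueError(f"need {d} binning specs, got {len(specs)}")
    return specs


def _counts(symbols: np.ndarray, k: int) -> np.ndarray:
    return np.bincount(symbols, minlength=k)


def _check_levels(sample: StimulusResponseSample) -> None:
    if sample.n_levels < 2:
        raise ValueError("MI requires at least 2 distinct stimulus levels")


def conditional_entropy(sample: StimulusResponseSample,
                        spec: BinningSpec | list = BinningSpec(),
                        method: str = "nsb",
                        grid_size: int = 1000) -> tuple[float, float]:
    """H(Z|S) in bits with sd combined in quadrature across levels.

    Every level is binned on the pooled (whole-sample) alphabet so the
    result is commensurable with the unconditional entropy.
    """
    _check_levels(sample)
    sym, k = _product_symbols(sample, spec)
    h, var = 0.0, 0.0
    for code in range(sample.n_levels):
        mask = sample.codes == code
        w = mask.sum() / sample.n
        hs, sds = _entropy(_counts(sym[mask], k), k, method, grid_size)
        h += w * hs
        var += (w * sds) ** 2
    return h, float(np.sqrt(var))


def mutual_information(sample: StimulusResponseSample,
                       spec: BinningSpec | list = BinningSpec(),
                       method: str = "nsb",
                       grid_size: int = 1000) -> MIEstimate:
    """I(Z;S) = H(Z) − H(Z|S) for a 1-dimensional response, in bits."""
    if sample.dim != 1:
        raise ValueError("mutual_information expects a 1-D response; "
                         "use joint_mi / trajectory_mi for vectors")
    return _mi(sample, spec, method, grid_size)


def joint_mi(sample: StimulusResponseSample,
             spec: BinningSpec | list = BinningSpec(),
             method: str = "nsb",
             grid_size: int = 1000) -> MIEstimate:
    """MI between the stimulus and a two-dimensional response vector.

    Each dimension is discretized separately; the joint alphabet is the
    Cartesian product (default 30 x 30).
    """
    if sample.dim != 2:
        raise ValueError("joint_mi expects a 2-D response")
    return _mi(sample, spec, method, grid_size)


def trajectory_mi(sample: StimulusResponseSample,
                  spec: BinningSpec | list = BinningSpec(),
                  method: str = "nsb",
                  grid_size: int = 1000) -> MIEstimate:
    """MI between the stimulus and a three-time-point response trajectory.

    Note the default 30 bins/dimension give a 27000-cell alphabet that is
    very sparse at n ~ 1e3; consider fewer bins per dimension (e.g. 8).
    """
    if sample.dim != 3:
        raise ValueError("trajectory_mi expects a 3-D response (three time points)")
    return _mi(sample, spec, method, grid_size)


def _mi(sample, spec, method, grid_size) -> MIEstimate:
    _check_levels(sample)
    sym, k = _product_symbols(sample, spec)
    h_z, sd_z = _entropy(_counts(sym, k), k, method, grid_size)
    h_cond, sd_cond = _conditional_from_symbols(sample, sym, k, method, grid_size)
    return MIEstimate(
        value=h_z - h_cond,
        sd=float(np.hypot(sd_z, sd_cond)),
        n_samples=sample.n,
        method=method,
        components={"H(Z)": h_z, "H(Z|S)": h_cond, "sd_H(Z)": sd_z, "sd_H(Z|S)": sd_cond},
    )


def _conditional_from_symbols(sample, sym, k, method, grid_size):
    h, var = 0.0, 0.0
    for code in range(sample.n_levels):
        mask = sample.codes == code
        w = mask.sum() / sample.n
        hs, sds = _entropy(_counts(sym[mask], k), k, method, grid_size)
        h += w * hs
        var += (w * sds) ** 2
    return h, float(np.sqrt(var))


def _pairwise_mi(sym1, k1, sym2, k2, method, grid_size):
    """I(Z1;Z2) = H(Z1) + H(Z2) − H(Z1,Z2) from pre-discretized symbols."""
    h1, s1 = _entropy(_counts(sym1, k1), k1, method, grid_size)
    h2, s2 = _entropy(_counts(sym2, k2), k2, method, grid_size)
    joint = sym1.astype(np.int64) * k2 + sym2
    h12, s12 = _entropy(_counts(joint, k1 * k2), k1 * k2, method, grid_size)
    return h1 + h2 - h12, float(np.sqrt(s1**2 + s2**2 + s12**2)), (h1, h2, h12)


def _two_response_symbols(sample, spec):
    if sample.dim != 2:
        raise ValueError("need a 2-D response (Z1, Z2)")
    specs = _per_dim_specs(spec, 2)
    s1 = discretize(sample.column(0), specs[0])
    s2 = discretize(sample.column(1), specs[1])
    return s1, specs[0].n_bins, s2, specs[1].n_bins


def conditional_mi(sample: StimulusResponseSample,
                   spec: BinningSpec | list = BinningSpec(),
                   method: str = "nsb",
                   grid_size: int = 1000) -> MIEstimate:
    """I(Z1;Z2|S): MI between two responses conditioned on the stimulus.

    Computed as the level-weighted average of within-level I(Z1;Z2), all
    levels discretized on the shared pooled alphabets.
    """
    _check_levels(sample)
    sym1, k1, sym2, k2 = _two_response_symbols(sample, spec)
    val, var = 0.0, 0.0
    for code in range(sample.n_levels):
        mask = sample.codes == code
        if not mask.any():
            raise ValueError("stimulus level with zero records")
        w = mask.sum() / sample.n
        mi_s, sd_s, _ = _pairwise_mi(sym1[mask], k1, sym2[mask], k2, method, grid_size)
        val += w * mi_s
        var += (w * sd_s) ** 2
    return MIEstimate(val, float(np.sqrt(var)), sample.n, method,
                      components={"quantity": "I(Z1;Z2|S)"})


def additional_information(sample: StimulusResponseSample,
                           spec: BinningSpec | list = BinningSpec(),
                           method: str = "nsb",
                           grid_size: int = 1000) -> MIEstimate:
    """I(Z2;S|Z1): information a second response adds beyond the first.

    Chain-rule decomposition I(Z2;S) − I(Z1;Z2) + I(Z1;Z2|S), with each
    term estimated by NSB entropies and the sd combined in quadrature.
    Z1 is response column 0, Z2 is column 1.
    """
    _check_levels(sample)
    sym1, k1, sym2, k2 = _two_response_symbols(sample, spec)
    specs = _per_dim_specs(spec, 2)

    z2_sample = StimulusResponseSample(sample.levels[sample.codes], sample.column(1))
    i_z2_s = _mi(z2_sample, specs[1], method, grid_size)
    i_12, sd_12, _ = _pairwise_mi(sym1, k1, sym2, k2, method, grid_size)
    i_12_s = conditional_mi(sample, spec, method, grid_size)

    value = i_z2_s.value - i_12 + i_12_s.value
    sd = float(np.sqrt(i_z2_s.sd**2 + sd_12**2 + i_12_s.sd**2))
    return MIEstimate(value, sd, sample.n, method, components={
        "I(Z2;S)": i_z2_s.value, "I(Z1;Z2)": i_12, "I(Z1;Z2|S)": i_12_s.value,
        "sd_I(Z2;S)": i_z2_s.sd, "sd_I(Z1;Z2)": sd_12, "sd_I(Z1;Z2|S)": i_12_s.sd,
    })
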