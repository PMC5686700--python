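"""Pulse-protocol builders and information analyses of pulsatile sensing.

Reproduces the computational experiments on hormone-pulse sensing:

* ``during_after_analysis`` — how much a cell learns about GnRH
  concentration from its NFAT translocation response during a 15-minute
  pulse versus the 15 minutes that follow, and the additional information
  from sensing both windows;
* ``two_pulse_analysis`` — a 15-minute pulse, a 135-minute interval and a
  60-minute second pulse at the same concentration, swept over effector
  fluctuation lifetimes, asking how predictive the first-pulse response
  is of the second and how much information the second pulse adds.

Response conventions
--------------------
Windowed AUC responses are computed on the baseline-anchored trace,
NF(t) minus the cell's own pre-stimulus mean (live-cell translocation
assays reference each cell to its pre-stimulus frames); two-pulse
responses Z1/Z2 are the raw maximum nuclear fraction within each pulse
window.  Both raw and anchored variants are exposed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .binning import BinningSpec
from .effectors import PopulationRun, hybrid_simulate
from .information import (MIEstimate, StimulusResponseSample,
                          additional_information, mutual_information,
                          trajectory_mi)
from .model import CellTrajectory, ModelParameters, StimulusProtocol, build_default_parameters
from .nsb import nsb_entropy
from .binning import discretize

__all__ = [
    "PulseDesign",
    "ResponseSummary",
    "summarize",
    "window_auc",
    "pulse_max",
    "pairwise_mi",
    "single_pulse_information",
    "during_after_analysis",
    "two_pulse_analysis",
    "DEFAULT_CONCENTRATIONS",
]

DEFAULT_CONCENTRATIONS = (0.0, 1e-11, 1e-9, 1e-7)

#: minutes of pre-stimulus trace used as the per-cell baseline anchor
PRE_STIMULUS_MIN = 10.0


@dataclass(frozen=True)
class PulseDesign:
    """Two-pulse stimulus design; the second pulse repeats the first's
    concentration."""

    pulse1_min: float = 15.0
    interval_min: float = 135.0
    pulse2_min: float = 60.0
    concentrations: tuple = DEFAULT_CONCENTRATIONS

    def __post_init__(self) -> None:
        if self.pulse1_min <= 0 or self.pulse2_min <= 0:
            raise ValueError("pulse durations must be > 0")
        if self.interval_min < 0:
            raise ValueError("interval must be >= 0")

    def protocol(self, concentration: float) -> StimulusProtocol:
        t1 = self.pulse1_min
        t2 = t1 + self.interval_min
        return StimulusProtocol(((0.0, t1, concentration),
                                 (t2, t2 + self.pulse2_min, concentration)))

    @property
    def end(self) -> float:
        return self.pulse1_min + self.interval_min + self.pulse2_min

    @property
    def windows(self) -> tuple[tuple[float, float], tuple[float, float]]:
        t2 = self.pulse1_min + self.interval_min
        return (0.0, self.pulse1_min), (t2, t2 + self.pulse2_min)


@dataclass(frozen=True)
class ResponseSummary:
    """Specification of a per-cell scalar (or 3-vector) response readout.

    kind: ``snapshot(t)`` | ``auc(window)`` | ``max(window)`` |
    ``trajectory(t1,t2,t3)``.
    """

    kind: str
    times: tuple = ()
    window: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        kinds = {"snapshot", "auc", "max", "trajectory"}
        if self.kind not in kinds:
            raise ValueError(f"kind must be one of {kinds}")
        if self.kind in ("auc", "max") and self.window is None:
            raise ValueError(f"{self.kind} summary needs a window")
        if self.kind == "snapshot" and len(self.times) != 1:
            raise ValueError("snapshot needs exactly one time")
        if self.kind == "trajectory" and len(self.times) != 3:
            raise ValueError("trajectory needs exactly three times")


def summarize(trajectory: CellTrajectory, summary: ResponseSummary):
    """Evaluate a response summary on one trajectory.

    AUC is the trapezoidal integral of the nuclear fraction over the
    window (units: minutes); snapshots use the nearest grid time.
    """
    t, nf = trajectory.t, trajectory.nfat_nf
    if summary.kind in ("auc", "max"):
        a, b = summary.window
        if a < t[0] or b > t[-1]:
            raise ValueError(f"window ({a}, {b}) outside trajectory span "
                             f"({t[0]}, {t[-1]})")
        mask = (t >= a) & (t <= b)
        if summary.kind == "auc":
            return float(np.trapezoid(nf[mask], t[mask]))
        return float(nf[mask].max())
    if any(tt < t[0] or tt > t[-1] for tt in summary.times):
        raise ValueError("snapshot/trajectory times outside trajectory span")
    idx = [int(np.argmin(np.abs(t - tt))) for tt in summary.times]
    if summary.kind == "snapshot":
        return float(nf[idx[0]])
    return np.array([nf[i] for i in idx])


def window_auc(nf: np.ndarray, t: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Per-cell trapezoidal AUC of (n_cells, n_t) traces over [lo, hi]."""
    mask = (t >= lo) & (t <= hi)
    if not mask.any():
        raise ValueError(f"window ({lo}, {hi}) outside time grid")
    return np.trapezoid(nf[:, mask], t[mask], axis=1)


def pulse_max(nf: np.ndarray, t: np.ndarray, lo: float, hi: float) -> np.ndarray:
    mask = (t >= lo) & (t <= hi)
    return nf[:, mask].max(axis=1)


def _anchored(run: PopulationRun) -> np.ndarray:
    """Baseline-anchored traces: NF minus the per-cell pre-stimulus mean."""
    pre = run.t <= 0
    if not pre.any():
        raise ValueError("run has no pre-stimulus samples to anchor on")
    return run.nfat_nf - run.nfat_nf[:, pre].mean(axis=1, keepdims=True)


def _simulate_conditions(params, protocol_for, concentrations, n_cells, fl,
                         cv_r, cv_m, seed, t_out) -> dict[float, PopulationRun]:
    runs = {}
    for i, c in enumerate(concentrations):
        runs[c] = hybrid_simulate(
            params, protocol_for(c), n_cells, fl=fl, cv_r=cv_r, cv_m=cv_m,
            seed=(seed * 1009 + i) % (2**31 - 1), t_out=t_out,
        )
    return runs


def _stack(runs: dict[float, PopulationRun], values_of) -> tuple[np.ndarray, np.ndarray]:
    zs, ss = [], []
    for c, run in runs.items():
        z = values_of(run)
        zs.append(z)
        ss.append(np.full(z.shape[0], c))
    return np.concatenate(ss), np.concatenate(zs, axis=0)


def pairwise_mi(z1: np.ndarray, z2: np.ndarray,
                spec: BinningSpec = BinningSpec()) -> MIEstimate:
    """I(Z1;Z2) of two pooled continuous responses via NSB entropies on
    the 30x30 product alphabet."""
    b1 = discretize(z1, spec)
    b2 = discretize(z2, spec)
    k = spec.n_bins
    h1, s1 = nsb_entropy(np.bincount(b1, minlength=k))
    h2, s2 = nsb_entropy(np.bincount(b2, minlength=k))
    h12, s12 = nsb_entropy(np.bincount(b1.astype(np.int64) * k + b2,
                                       minlength=k * k))
    return MIEstimate(h1 + h2 - h12, float(np.sqrt(s1**2 + s2**2 + s12**2)),
                      n_samples=len(z1), components={"H1": h1, "H2": h2, "H12": h12})


def single_pulse_information(
    runs: dict[float, PopulationRun],
    snapshot_times: tuple = (15.0,),
    auc_window: tuple[float, float] = (0.0, 60.0),
    trajectory_times: tuple = (5.0, 20.0, 60.0),
    bins: BinningSpec = BinningSpec(),
    trajectory_bins: BinningSpec = BinningSpec(n_bins=8),
) -> dict[str, MIEstimate]:
    """Snapshot, AUC and trajectory MI for a single-pulse population set."""
    if len(runs) < 2:
        raise ValueError("need >= 2 concentrations")
    out: dict[str, MIEstimate] = {}
    for tt in snapshot_times:
        def snap(run, tt=tt):
            i = int(np.argmin(np.abs(run.t - tt)))
            return run.nfat_nf[:, i]
        s, z = _stack(runs, snap)
        out[f"snapshot_{tt:g}min"] = mutual_information(
            StimulusResponseSample(s, z), bins)
    s, z = _stack(runs, lambda run: window_auc(run.nfat_nf, run.t, *auc_window))
    out["auc"] = mutual_information(StimulusResponseSample(s, z), bins)
    def traj(run):
        idx = [int(np.argmin(np.abs(run.t - tt))) for tt in trajectory_times]
        return run.nfat_nf[:, idx]
    s, z = _stack(runs, traj)
    out["trajectory"] = trajectory_mi(StimulusResponseSample(s, z), trajectory_bins)
    return out


def during_after_analysis(
    fl: float,
    params: ModelParameters | None = None,
    n_cells: int = 1000,
    seed: int = 0,
    cv_r: float = 0.4,
    cv_m: float = 0.4,
    pulse_min: float = 15.0,
    concentrations: tuple = DEFAULT_CONCENTRATIONS,
    bins: BinningSpec = BinningSpec(),
    return_responses: bool = False,
):
    """Information carried by the NFAT-NF AUC during a 15-minute pulse
    versus the following 15 minutes, plus the chain-rule additional
    information from sensing both.

    Responses are AUCs of the baseline-anchored trace over [0, 15] and
    [15, 30] minutes.  Returns a dict with MIEstimates ``I_during``,
    ``I_after`` and ``additional``.
    """
    params = params or build_default_parameters()
    t_out = np.arange(-PRE_STIMULUS_MIN, 2 * pulse_min + 0.25, 0.25)
    runs = _simulate_conditions(
        params, lambda c: StimulusProtocol(((0.0, pulse_min, c),)),
        concentrations, n_cells, fl, cv_r, cv_m, seed, t_out)

    def zd(run):
        return window_auc(_anchored(run), run.t, 0.0, pulse_min)

    def za(run):
        return window_auc(_anchored(run), run.t, pulse_min, 2 * pulse_min)

    s, z_d = _stack(runs, zd)
    _, z_a = _stack(runs, za)
    i_during = mutual_information(StimulusResponseSample(s, z_d), bins)
    i_after = mutual_information(StimulusResponseSample(s, z_a), bins)
    additional = additional_information(
        StimulusResponseSample(s, np.column_stack([z_d, z_a])), bins)
    result = {"I_during": i_during, "I_after": i_after, "additional": additional,
              "fl": fl, "n_cells": n_cells, "seed": seed}
    if return_responses:
        result["responses"] = pd.DataFrame(
            {"stimulus": s, "z_during": z_d, "z_after": z_a})
    return result


def two_pulse_analysis(
    fl_grid=(10.0, 100.0, 1000.0, 10000.0),
    design: PulseDesign = PulseDesign(),
    params: ModelParameters | None = None,
    n_cells: int = 1000,
    seed: int = 0,
    cv_r: float = 0.4,
    cv_m: float = 0.4,
    bins: BinningSpec = BinningSpec(),
    return_responses: bool = False,
):
    """Two-pulse information table over a grid of fluctuation lifetimes.

    For every FL: I(Z1;S), I(Z2;S), pooled I(Z1;Z2), conditional
    I(Z1;Z2|S) and the chain-rule additional information I(Z2;S|Z1),
    where Z1/Z2 are the maximum nuclear fraction within each pulse
    window.  An AUC variant (first ``pulse1_min`` minutes of each pulse,
    baseline-anchored) is also reported.

    Returns (table: DataFrame indexed by fl, responses: DataFrame or None).
    """
    params = params or build_default_parameters()
    t_out = np.arange(-PRE_STIMULUS_MIN, design.end + 0.5, 0.5)
    (w1_lo, w1_hi), (w2_lo, w2_hi) = design.windows
    rows = []
    resp_frames = []
    for j, fl in enumerate(fl_grid):
        runs = _simulate_conditions(
            params, design.protocol, design.concentrations, n_cells, fl,
            cv_r, cv_m, (seed * 7919 + j) % (2**31 - 1), t_out)
        s, z1 = _stack(runs, lambda run: pulse_max(run.nfat_nf, run.t, w1_lo, w1_hi))
        _, z2 = _stack(runs, lambda run: pulse_max(run.nfat_nf, run.t, w2_lo, w2_hi))
        _, a1 = _stack(runs, lambda run: window_auc(_anchored(run), run.t,
                                                    w1_lo, w1_lo + design.pulse1_min))
        _, a2 = _stack(runs, lambda run: window_auc(_anchored(run), run.t,
                                                    w2_lo, w2_lo + design.pulse1_min))
        i1 = mutual_information(StimulusResponseSample(s, z1), bins)
        i2 = mutual_information(StimulusResponseSample(s, z2), bins)
        i12 = pairwise_mi(z1, z2, bins)
        pair = StimulusResponseSample(s, np.column_stack([z1, z2]))
        add_max = additional_information(pair, bins)
        pair_auc = StimulusResponseSample(s, np.column_stack([a1, a2]))
        add_auc = additional_information(pair_auc, bins)
        i1_auc = mutual_information(StimulusResponseSample(s, a1), bins)
        i2_auc = mutual_information(StimulusResponseSample(s, a2), bins)
        rows.append({
            "fl": fl,
            "I_z1_s": i1.value, "I_z1_s_sd": i1.sd,
            "I_z2_s": i2.value, "I_z2_s_sd": i2.sd,
            "I_z1_z2": i12.value, "I_z1_z2_sd": i12.sd,
            "I_z1_z2_given_s": add_max.components["I(Z1;Z2|S)"],
            "additional": add_max.value, "additional_sd": add_max.sd,
            "I_auc1_s": i1_auc.value, "I_auc2_s": i2_auc.value,
            "additional_auc": add_auc.value, "additional_auc_sd": add_auc.sd,
        })
        if return_responses:
            resp_frames.append(pd.DataFrame(
                {"fl": fl, "stimulus": s, "z1_max": z1, "z2_max": z2,
                 "z1_auc": a1, "z2_auc": a2}))
    table = pd.DataFrame(rows).set_index("fl")
    responses = pd.concat(resp_frames, ignore_index=True) if return_responses else None
    return table, responses
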