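"""Golden-angle projection schedules, Bloch sorting and protocol arithmetic.

A golden-angle radial acquisition advances the projection angle by
360/(1+sqrt(5)) ~ 111.25 degrees per index, which keeps the angles of any
run of consecutive indices nearly uniformly distributed.  *Serial* sorting
assigns golden indices chronologically; *Bloch* sorting instead assigns
them by the rank of the Bloch-predicted signal, so that neighbouring
projection angles carry neighbouring signal levels and the contrast varies
smoothly across k-space.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .bloch import SignalPrediction, simulate_timeline
from .params import SequenceParams, TissueParams

__all__ = [
    "GOLDEN_ANGLE_DEG",
    "golden_angle",
    "SortingPlan",
    "SamplingPattern",
    "bloch_sort",
    "serial_sort",
    "build_pattern",
    "sorting_deviation",
    "protocol_counts",
]

#: Golden-angle increment 360/(1+sqrt(5)) in degrees (~111.2461).
GOLDEN_ANGLE_DEG: float = 360.0 / (1.0 + np.sqrt(5.0))


def golden_angle(N) -> float | np.ndarray:
    """Projection angle of golden-angle index ``N``: (N * 360/(1+sqrt 5)) mod 360."""
    N = np.asarray(N)
    if np.any(N < 0) or not np.issubdtype(N.dtype, np.integer):
        raise ValueError("golden-angle index must be a non-negative integer")
    out = np.mod(N * GOLDEN_ANGLE_DEG, 360.0)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class SortingPlan:
    """Mapping between chronological spokes and golden-angle indices.

    ``golden_index[i]`` is the 1-based golden-angle number assigned to
    chronological spoke ``i``; ``angle[i]`` the resulting projection
    angle in degrees.
    """

    golden_index: np.ndarray
    angle: np.ndarray
    mode: str

    def __post_init__(self):
        n = len(self.golden_index)
        if sorted(self.golden_index) != list(range(1, n + 1)):
            raise ValueError("golden_index must be a bijection onto 1..n_spokes")
        expected = np.mod(np.asarray(self.golden_index) * GOLDEN_ANGLE_DEG, 360.0)
        if np.max(np.abs(expected - self.angle)) > 1e-9:
            raise ValueError("angles inconsistent with golden indices")
        if self.mode not in ("bloch", "serial"):
            raise ValueError("mode must be 'bloch' or 'serial'")

    @property
    def n_spokes(self) -> int:
        return len(self.golden_index)


@dataclass(frozen=True)
class SamplingPattern:
    """Full sampling schedule: sorting plan plus per-spoke acquisition metadata."""

    plan: SortingPlan
    prediction: SignalPrediction
    n_prep: int
    NR: int

    def __post_init__(self):
        if len(self.prediction) != self.plan.n_spokes:
            raise ValueError("prediction and plan length mismatch")

    @property
    def n_spokes(self) -> int:
        return self.plan.n_spokes

    @property
    def n_preparations(self) -> int:
        return self.n_spokes // self.NR

    @property
    def weighting_ids(self) -> np.ndarray:
        return np.unique(self.prediction.weighting_id)

    def to_table(self):
        """Columnar schedule (chronological order) for export."""
        tab = self.prediction.to_table()
        tab["golden_index"] = self.plan.golden_index
        tab["angle_deg"] = self.plan.angle
        return tab


def bloch_sort(pred: SignalPrediction) -> SortingPlan:
    """Assign golden indices by descending predicted signal.

    Rank 1 goes to the largest predicted signal; ties are broken by
    chronological index, so the plateaus of identical repeated
    preparations keep their acquisition order.  Reordering the signals
    by golden index therefore yields a non-increasing sequence.
    """
    s = np.asarray(pred.signals, dtype=float)
    if s.size == 0:
        raise ValueError("prediction is empty")
    order = np.argsort(-s, kind="stable")  # chronological tie-break
    golden = np.empty(s.size, dtype=int)
    golden[order] = np.arange(1, s.size + 1)
    return SortingPlan(
        golden_index=golden,
        angle=np.mod(golden * GOLDEN_ANGLE_DEG, 360.0),
        mode="bloch",
    )


def serial_sort(n_spokes: int) -> SortingPlan:
    """Conventional scheme: golden index follows the chronological index."""
    if n_spokes < 1:
        raise ValueError("n_spokes must be at least 1")
    golden = np.arange(1, n_spokes + 1)
    return SortingPlan(
        golden_index=golden,
        angle=np.mod(golden * GOLDEN_ANGLE_DEG, 360.0),
        mode="serial",
    )


def build_pattern(
    seq: SequenceParams,
    tissue: TissueParams | None,
    f_SL: float,
    mode: str = "bloch",
) -> SamplingPattern:
    """Build the full sampling pattern for one spin-lock amplitude.

    ``mode='bloch'`` requires tissue priors for the signal prediction;
    ``mode='serial'`` also carries the prediction (for deviation
    analysis) but ignores it when assigning angles.
    """
    if mode not in ("bloch", "serial"):
        raise ValueError("mode must be 'bloch' or 'serial'")
    if tissue is None:
        raise ValueError("tissue priors are required to predict the timeline")
    pred = simulate_timeline(seq, tissue, f_SL)
    plan = bloch_sort(pred) if mode == "bloch" else serial_sort(len(pred))
    return SamplingPattern(plan=plan, prediction=pred, n_prep=seq.n_prep, NR=seq.NR)


def sorting_deviation(plan: SortingPlan, measured: np.ndarray) -> float:
    """Mean relative deviation of golden-index-ordered signals from monotone order.

    The measured per-spoke signals are reordered by golden index; a
    perfectly sorted acquisition is then monotonically non-increasing.
    Each spoke exceeding the running minimum of its predecessors
    contributes ``(s_i - min(s_1..s_{i-1})) / s_i``; the mean over all
    spokes is returned (0 for perfect sorting).
    """
    measured = np.asarray(measured, dtype=float)
    if measured.size != plan.n_spokes:
        raise ValueError("measured signals must match the plan length")
    ordered = measured[np.argsort(plan.golden_index)]
    dev = np.zeros(ordered.size)
    running_min = np.minimum.accumulate(ordered)[:-1]
    excess = np.maximum(0.0, ordered[1:] - running_min)
    with np.errstate(divide="ignore", invalid="ignore"):
        dev[1:] = np.where(ordered[1:] > 0, excess / ordered[1:], 0.0)
    return float(dev.mean())


def protocol_counts(seq: SequenceParams, reference_preps_per_map: int = 32) -> dict:
    """Acquisition bookkeeping of the protocol.

    Returns preparation/spoke counts per map, totals across all
    spin-lock amplitudes, and the acceleration factor relative to a
    fully sampled Cartesian reference needing ``reference_preps_per_map``
    preparations per weighting (32 for a 128-matrix turbo-factor-4
    spin-echo readout, i.e. a 32:13 advantage).
    """
    n_amp = len(seq.f_SL_list)
    per_map_preps = seq.n_preparations
    return {
        "n_weightings": seq.n_weightings,
        "preparations_per_map": per_map_preps,
        "spokes_per_map": seq.n_spokes,
        "n_amplitudes": n_amp,
        "preparations_total": per_map_preps * n_amp,
        "spokes_total": seq.n_spokes * n_amp,
        "reference_preparations_per_map": reference_preps_per_map * seq.n_weightings,
        "acceleration_factor": reference_preps_per_map / seq.n_prep,
    }
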