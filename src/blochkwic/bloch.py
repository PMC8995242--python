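"""Longitudinal Bloch simulation of the spin-lock-prepared radial GRE sequence.

The sequence alternates long recovery periods with spin-lock preparations,
each followed by a short train of ``NR`` spoiled gradient-echo readouts.
Under ideal spoiling only the longitudinal magnetization ``Mz`` carries
state between pulses, so one preparation cycle reduces to three update
rules:

1. recovery over ``t_rec``:       ``Mz <- M0 + (Mz - M0) * exp(-t_rec/T1)``
2. balanced spin-lock decay:      ``Mz <- Mz * exp(-t_SL / T1rho(f_SL))``
3. each readout pulse k = 1..NR:  emit ``S_k = Mz * sin(alpha)`` then
   ``Mz <- M0 + (Mz*cos(alpha) - M0) * exp(-TR/T1)``

B0/B1 imperfections, T2rho and off-resonance effects during the lock are
neglected: the balanced preparation module is designed to suppress them.
TE/T2* decay is a constant factor absorbed into ``M0``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import SequenceParams, TissueParams

__all__ = [
    "SignalPrediction",
    "simulate_timeline",
    "steady_state_window",
    "optimal_flip_norelax",
    "optimal_flip_bloch",
]


@dataclass(frozen=True)
class SignalPrediction:
    """Bloch-predicted signal per spoke in chronological acquisition order.

    ``signals`` has length ``n_prep * W * NR`` for one spin-lock amplitude;
    ``window_id`` numbers the preparation experiments from 0, ``readout_pos``
    runs 1..NR within a window and ``weighting_id`` indexes ``t_SL_list``.
    """

    signals: np.ndarray
    window_id: np.ndarray
    readout_pos: np.ndarray
    weighting_id: np.ndarray
    f_SL: float

    def __post_init__(self):
        n = len(self.signals)
        if not (len(self.window_id) == len(self.readout_pos) == len(self.weighting_id) == n):
            raise ValueError("per-spoke arrays must share one length")

    def __len__(self) -> int:
        return len(self.signals)

    def to_table(self):
        """Columnar view of the timeline (chronological order)."""
        import pandas as pd

        return pd.DataFrame(
            {
                "chronological_index": np.arange(len(self)),
                "window_id": self.window_id,
                "readout_pos": self.readout_pos,
                "weighting_id": self.weighting_id,
                "signal": self.signals,
            }
        )


def _cycle(Mz, M0, e_rec, e_prep, sin_a, cos_a, e_tr, NR, out=None):
    """One preparation cycle; appends NR signals to ``out`` when given."""
    Mz = M0 + (Mz - M0) * e_rec
    Mz = Mz * e_prep
    for _ in range(NR):
        if out is not None:
            out.append(Mz * sin_a)
        Mz = M0 + (Mz * cos_a - M0) * e_tr
    return Mz


def simulate_timeline(
    seq: SequenceParams, tissue: TissueParams, f_SL: float
) -> SignalPrediction:
    """Simulate the chronological per-spoke signal of the full acquisition.

    The ``n_dummy`` lead-in cycles (run with the parameters of the first
    weighting block) are simulated but excluded from the output, so the
    returned timeline starts close to the block steady state.

    Parameters
    ----------
    seq, tissue :
        Protocol and tissue parameters; validated on construction.
    f_SL : float
        Spin-lock amplitude in Hz, entering through the linear
        dispersion model.

    Returns
    -------
    SignalPrediction
        Non-negative magnitude signals of the ``n_prep * W * NR`` spokes.
    """
    t1rho = tissue.t1rho(f_SL)  # raises if non-physical
    a = np.deg2rad(seq.alpha)
    sin_a, cos_a = np.sin(a), np.cos(a)
    e_rec = np.exp(-seq.t_rec / tissue.T1)
    e_tr = np.exp(-seq.TR / tissue.T1)
    order = seq.block_order

    Mz = tissue.M0
    e_first = np.exp(-seq.t_SL_list[order[0]] / t1rho)
    for _ in range(seq.n_dummy):
        Mz = _cycle(Mz, tissue.M0, e_rec, e_first, sin_a, cos_a, e_tr, seq.NR)

    signals: list = []
    window_id: list = []
    readout_pos: list = []
    weighting_id: list = []
    window = 0
    for w in order:
        e_prep = np.exp(-seq.t_SL_list[w] / t1rho)
        for _ in range(seq.n_prep):
            Mz = _cycle(Mz, tissue.M0, e_rec, e_prep, sin_a, cos_a, e_tr, seq.NR, signals)
            window_id.extend([window] * seq.NR)
            readout_pos.extend(range(1, seq.NR + 1))
            weighting_id.extend([w] * seq.NR)
            window += 1

    return SignalPrediction(
        signals=np.asarray(signals, dtype=float),
        window_id=np.asarray(window_id, dtype=int),
        readout_pos=np.asarray(readout_pos, dtype=int),
        weighting_id=np.asarray(weighting_id, dtype=int),
        f_SL=float(f_SL),
    )


def steady_state_window(
    seq: SequenceParams,
    tissue: TissueParams,
    f_SL: float,
    weighting: int,
    n_settle: int = 60,
) -> np.ndarray:
    """Steady-state readout signals of one weighting block.

    Repeats identical preparation cycles until the block steady state is
    reached (geometric convergence; ``n_settle`` cycles are far more than
    needed for realistic timings) and returns the NR signals of the final
    cycle.  Supports vectorized tissue/sequence scalars via broadcasting.
    """
    t1rho = tissue.t1rho(f_SL)
    a = np.deg2rad(seq.alpha)
    sin_a, cos_a = np.sin(a), np.cos(a)
    e_rec = np.exp(-seq.t_rec / tissue.T1)
    e_tr = np.exp(-seq.TR / tissue.T1)
    e_prep = np.exp(-seq.t_SL_list[weighting] / t1rho)

    Mz = tissue.M0
    for _ in range(n_settle):
        Mz = _cycle(Mz, tissue.M0, e_rec, e_prep, sin_a, cos_a, e_tr, seq.NR)
    out: list = []
    _cycle(Mz, tissue.M0, e_rec, e_prep, sin_a, cos_a, e_tr, seq.NR, out)
    return np.asarray(out, dtype=float)


def optimal_flip_norelax(NR: int, step: float = 0.01) -> float:
    """Flip angle maximizing the relaxation-free mean signal of an NR train.

    With perfect spoiling and no relaxation between pulses, readout k of
    a train sees longitudinal magnetization ``cos(alpha)**(k-1)``, so the
    summed signal is ``sum_k sin(alpha) * cos(alpha)**(k-1)``.  The argmax
    over alpha in (0, 90] degrees is located by deterministic grid search
    at ``step`` resolution.
    """
    if NR < 1:
        raise ValueError("NR must be at least 1")
    alphas = np.arange(step, 90.0 + step / 2, step)
    a = np.deg2rad(alphas)
    k = np.arange(NR)[:, None]
    total = (np.sin(a) * np.cos(a) ** k).sum(axis=0)
    return float(round(alphas[int(np.argmax(total))], 10))


def optimal_flip_bloch(
    seq: SequenceParams,
    tissue: TissueParams,
    f_SL: float | None = None,
    alpha_grid: np.ndarray | None = None,
) -> float:
    """Flip angle maximizing the Bloch-simulated mean readout signal.

    The figure of merit is the steady-state signal averaged over all
    spin-lock times and all NR readouts of a window — the mean signal
    level the protocol actually delivers once the repeated preparations
    have settled.  Relaxation during the readout train and incomplete
    recovery shift the optimum below the relaxation-free value.
    """
    if alpha_grid is None:
        alpha_grid = np.arange(0.01, 90.0 + 0.005, 0.01)
    alpha_grid = np.asarray(alpha_grid, dtype=float)
    if alpha_grid.size == 0:
        raise ValueError("alpha_grid must be non-empty")
    if np.any((alpha_grid <= 0) | (alpha_grid > 90)):
        raise ValueError("alpha_grid angles must lie in (0, 90] degrees")
    if f_SL is None:
        f_SL = seq.f_SL_list[0]

    t1rho = tissue.t1rho(f_SL)
    a = np.deg2rad(alpha_grid)
    sin_a, cos_a = np.sin(a), np.cos(a)
    e_rec = np.exp(-seq.t_rec / tissue.T1)
    e_tr = np.exp(-seq.TR / tissue.T1)

    mean_signal = np.zeros_like(alpha_grid)
    for t_SL in seq.t_SL_list:
        e_prep = np.exp(-t_SL / t1rho)
        Mz = np.full_like(alpha_grid, tissue.M0)
        for _ in range(60):
            Mz = _cycle(Mz, tissue.M0, e_rec, e_prep, sin_a, cos_a, e_tr, seq.NR)
        out: list = []
        _cycle(Mz, tissue.M0, e_rec, e_prep, sin_a, cos_a, e_tr, seq.NR, out)
        mean_signal += np.mean(out, axis=0)
    mean_signal /= len(seq.t_SL_list)
    return float(round(alpha_grid[int(np.argmax(mean_signal))], 10))
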