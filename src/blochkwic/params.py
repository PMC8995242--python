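"""Protocol and tissue parameter containers.

Times are in milliseconds, spin-lock amplitudes in Hz, flip angles in
degrees, geometry in millimetres.  Dispersion slopes are expressed in
ms/kHz so that fitted values match the convention used in quantitative
spin-lock relaxometry.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = ["SequenceParams", "TissueParams"]


@dataclass(frozen=True)
class SequenceParams:
    """Timing and geometry of the spin-lock-prepared radial GRE protocol.

    Parameters
    ----------
    TR : float
        Repetition time of the gradient-echo readout train, ms.
    TE : float
        Echo time, ms.  Metadata only: TE/T2* decay is treated as a
        constant factor absorbed into the equilibrium magnetization.
    t_rec : float
        Recovery time between preparation experiments, ms.
    alpha : float
        Readout flip angle, degrees.
    NR : int
        Number of radial readouts acquired after each preparation.
    t_SL_list : tuple of float
        Spin-lock durations (ms), strictly increasing; one image
        weighting per entry.
    f_SL_list : tuple of float
        Spin-lock amplitudes (Hz) of the protocol.
    n_prep : int
        Preparation experiments per (t_SL, f_SL) combination.
    n_dummy : int
        Dummy cycles executed before the first counted preparation.
    matrix : int
        Square image matrix size in pixels (must be even).
    fov : float
        Field of view, mm.
    weighting_order : tuple of int or None
        Chronological order of the weighting blocks as indices into
        ``t_SL_list``; ``None`` means ascending spin-lock time.
    """

    TR: float = 5.0
    TE: float = 2.0
    t_rec: float = 1500.0
    alpha: float = 40.0
    NR: int = 4
    t_SL_list: tuple = tuple(np.linspace(4.0, 60.0, 8))
    f_SL_list: tuple = (1500.0,)
    n_prep: int = 13
    n_dummy: int = 2
    matrix: int = 128
    fov: float = 38.4
    weighting_order: tuple | None = None

    def __post_init__(self):
        object.__setattr__(self, "t_SL_list", tuple(float(t) for t in self.t_SL_list))
        object.__setattr__(self, "f_SL_list", tuple(float(f) for f in self.f_SL_list))
        if self.TR <= 0 or self.t_rec <= 0:
            raise ValueError("TR and t_rec must be positive")
        if not (0 <= self.alpha < 180):
            raise ValueError("alpha must lie in [0, 180) degrees")
        if self.NR < 1 or self.n_prep < 1:
            raise ValueError("NR and n_prep must be at least 1")
        if self.n_dummy < 0:
            raise ValueError("n_dummy must be non-negative")
        if any(t < 0 for t in self.t_SL_list):
            raise ValueError("spin-lock times must be non-negative")
        if any(b <= a for a, b in zip(self.t_SL_list, self.t_SL_list[1:])):
            raise ValueError("t_SL_list must be strictly increasing")
        if self.matrix < 2 or self.matrix % 2:
            raise ValueError("matrix must be a positive even integer")
        if self.fov <= 0:
            raise ValueError("fov must be positive")
        if self.weighting_order is not None:
            order = tuple(int(i) for i in self.weighting_order)
            if sorted(order) != list(range(len(self.t_SL_list))):
                raise ValueError("weighting_order must permute the t_SL indices")
            object.__setattr__(self, "weighting_order", order)

    @property
    def n_weightings(self) -> int:
        return len(self.t_SL_list)

    @property
    def block_order(self) -> tuple:
        """Chronological weighting-block order (defaults to ascending t_SL)."""
        if self.weighting_order is None:
            return tuple(range(self.n_weightings))
        return self.weighting_order

    @property
    def n_preparations(self) -> int:
        """Counted preparations per spin-lock amplitude."""
        return self.n_prep * self.n_weightings

    @property
    def n_spokes(self) -> int:
        """Radial readouts per spin-lock amplitude."""
        return self.n_preparations * self.NR

    def with_(self, **kw) -> "SequenceParams":
        return replace(self, **kw)


@dataclass(frozen=True)
class TissueParams:
    """Relaxation properties of one tissue compartment.

    The rotating-frame relaxation time follows the linear dispersion
    model ``T1rho(f_SL) = T1rho0 + m1rho * f_SL`` with the slope in
    ms/kHz and ``f_SL`` in Hz.
    """

    T1: float
    T1rho0: float
    m1rho: float = 0.0
    M0: float = 1.0
    label: str = ""

    def __post_init__(self):
        if self.T1 <= 0:
            raise ValueError("T1 must be positive")
        if self.T1rho0 <= 0:
            raise ValueError("T1rho0 must be positive")
        if self.m1rho < 0:
            raise ValueError("m1rho must be non-negative")
        if self.M0 < 0:
            raise ValueError("M0 must be non-negative")

    def t1rho(self, f_SL: float) -> float:
        """Effective T1rho (ms) at spin-lock amplitude ``f_SL`` in Hz."""
        val = self.T1rho0 + self.m1rho * f_SL / 1000.0
        if val <= 0:
            raise ValueError(f"effective T1rho non-positive at f_SL={f_SL} Hz")
        return val
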