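"""PGSE encodings and acquisition protocols.

Units are fixed package-wide: times in ms, lengths in um, b-values in
ms/um^2, diffusivities in um^2/ms.  The gyromagnetic ratio only enters
when converting the wave-vector amplitude to a physical gradient
strength; all modelling works directly with q(t) in 1/um.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "PulseSequence",
    "AcquisitionProtocol",
    "make_pgse",
    "exvivo_protocol",
    "GAMMA_PROTON",
]

#: proton gyromagnetic ratio in rad / (ms * mT)
GAMMA_PROTON = 0.2675221874

_REL_TOL = 1e-9


@dataclass(frozen=True)
class PulseSequence:
    """One pulsed-gradient spin-echo encoding with ideal rectangular pulses.

    The dephasing wave vector q(t) rises linearly over [0, delta], stays
    flat at q0 over [delta, Delta] and returns to zero over
    [Delta, Delta + delta], so the encoding is balanced: q(Delta+delta)=0.
    The amplitude q0 satisfies b = q0^2 (Delta - delta/3).
    """

    b: float  # diffusion weighting, ms/um^2
    Delta: float  # pulse separation, ms
    delta: float  # pulse width, ms

    def __post_init__(self) -> None:
        if self.delta <= 0 or self.Delta <= 0:
            raise ValueError("pulse timings must be positive")
        if self.delta > self.Delta:
            raise ValueError("delta must not exceed Delta")
        if self.b < 0:
            raise ValueError("b must be nonnegative")

    @property
    def duration(self) -> float:
        """Total encoding time Delta + delta in ms."""
        return self.Delta + self.delta

    @property
    def q0(self) -> float:
        """Plateau amplitude of q(t) in 1/um."""
        return float(np.sqrt(self.b / (self.Delta - self.delta / 3.0)))

    @property
    def gradient_mT_per_m(self) -> float:
        """Physical gradient amplitude g = q0/(gamma*delta), in mT/m."""
        # q0 [1/um] = gamma [rad/(ms mT)] * g [mT/um] * delta [ms]
        return self.q0 / (GAMMA_PROTON * self.delta) * 1e6

    def q(self, t):
        """Piecewise-linear q(t) in 1/um, zero outside [0, Delta+delta]."""
        t = np.asarray(t, dtype=float)
        q0, d, D = self.q0, self.delta, self.Delta
        up = q0 * t / d
        down = q0 * (D + d - t) / d
        out = np.where(t < d, up, np.where(t <= D, q0, down))
        return np.where((t < 0) | (t > D + d), 0.0, out)

    def q2(self, t):
        """q(t)^2, evaluated analytically (piecewise polynomial)."""
        q = self.q(t)
        return q * q

    def key(self) -> tuple[float, float, float]:
        return (self.b, self.Delta, self.delta)


def make_pgse(b: float, Delta: float, delta: float) -> PulseSequence:
    """Construct a PGSE encoding from (b, Delta, delta).

    Raises ValueError for non-positive timings, delta > Delta, or b < 0.
    """
    return PulseSequence(b=float(b), Delta=float(Delta), delta=float(delta))


@dataclass(frozen=True)
class AcquisitionProtocol:
    """An ordered collection of PGSE encodings with unique (b, Delta, delta)."""

    sequences: tuple[PulseSequence, ...]
    directions_per_shell: int | None = None

    def __post_init__(self) -> None:
        keys = [s.key() for s in self.sequences]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (b, Delta, delta) triples in protocol")
        # deterministic ordering: by (Delta, delta, b)
        ordered = tuple(
            sorted(self.sequences, key=lambda s: (s.Delta, s.delta, s.b))
        )
        object.__setattr__(self, "sequences", ordered)

    def __len__(self) -> int:
        return len(self.sequences)

    def __iter__(self):
        return iter(self.sequences)

    @property
    def b(self) -> np.ndarray:
        return np.array([s.b for s in self.sequences])

    @property
    def Delta(self) -> np.ndarray:
        return np.array([s.Delta for s in self.sequences])

    @property
    def delta(self) -> np.ndarray:
        return np.array([s.delta for s in self.sequences])

    def timings(self) -> list[tuple[float, float]]:
        """Unique (Delta, delta) pairs, in protocol order."""
        seen: list[tuple[float, float]] = []
        for s in self.sequences:
            t = (s.Delta, s.delta)
            if t not in seen:
                seen.append(t)
        return seen

    def subset(self, Delta: float | None = None, delta: float | None = None,
               b_min: float | None = None, b_max: float | None = None
               ) -> "AcquisitionProtocol":
        keep = []
        for s in self.sequences:
            if Delta is not None and not np.isclose(s.Delta, Delta):
                continue
            if delta is not None and not np.isclose(s.delta, delta):
                continue
            if b_min is not None and s.b < b_min:
                continue
            if b_max is not None and s.b > b_max:
                continue
            keep.append(s)
        return AcquisitionProtocol(tuple(keep), self.directions_per_shell)


def _invsqrtb_grid(start: float, stop: float, step: float) -> np.ndarray:
    """Grid linear in b^(-1/2) from printed endpoints and step, inclusive."""
    n = int(round((start - stop) / step)) + 1
    return np.linspace(start, stop, n)


def exvivo_protocol(include_b01: bool = True) -> AcquisitionProtocol:
    """The 16.4 T ex vivo rat-brain protocol: delta = 4.5 ms, three
    pulse separations, low-b shells plus dense sampling linear in b^(-1/2).

    Low b-values are 0.1, 0.5, 1, 2, 3, 4, 5 ms/um^2 for every Delta.
    High b-values are generated from grids in b^(-1/2) (um/ms^(1/2)):
    0.4 to 0.15 in steps of 0.025 for Delta = 7.5 ms (11 values),
    0.4 to 0.125 for Delta = 11 ms (12 values), and for Delta = 16 ms
    0.4 to 0.3 in steps of 0.025 then 0.3 to 0.1 with the spacing halved
    (21 values in total, reaching b = 100 ms/um^2).

    Whether the lowest shell b = 0.1 ms/um^2 belongs to every Delta is
    ambiguous for the high-b analysis; it is included for all Delta by
    default and can be dropped with ``include_b01=False``.
    """
    delta = 4.5
    low_b = [0.1, 0.5, 1.0, 2.0, 3.0, 4.0, 5.0]
    if not include_b01:
        low_b = low_b[1:]

    grids = {
        7.5: _invsqrtb_grid(0.4, 0.15, 0.025),
        11.0: _invsqrtb_grid(0.4, 0.125, 0.025),
        16.0: np.concatenate(
            [_invsqrtb_grid(0.4, 0.3, 0.025)[:-1],
             _invsqrtb_grid(0.3, 0.1, 0.0125)]
        ),
    }
    seqs: list[PulseSequence] = []
    for Delta, grid in grids.items():
        for b in low_b:
            seqs.append(make_pgse(b, Delta, delta))
        for x in grid:
            seqs.append(make_pgse(1.0 / (x * x), Delta, delta))
    return AcquisitionProtocol(tuple(seqs))
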