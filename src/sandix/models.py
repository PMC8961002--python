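"""Full powder-averaged gray-matter signal models and signal analyses.

Assembles SANDI (no exchange), SMEX (stick-extracellular exchange),
SANDIX (SMEX plus a soma sphere) and eSANDIX (SANDIX plus a
non-exchanging, "impermeable" stick sub-population sharing the neurite
diffusivity) over an acquisition protocol.  Also provides the apparent
power-law exponent, the exchange-vs-structure time-dependence
classification, and the powder kurtosis (DKI) summary fit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .compartments import (gaussian_signal, sphere_diffusivity_gpa,
                           stick_powder_signal)
from .karger import (PowderQuadrature, powder_quadrature,
                     stick_exchange_powder_bgrid)
from .protocol import AcquisitionProtocol

__all__ = [
    "MODEL_IDS",
    "GmModelParams",
    "PowderSignalTable",
    "model_signal",
    "powerlaw_exponent",
    "time_dependence_sign",
    "dki_powder_fit",
]

MODEL_IDS = ("SANDI", "SMEX", "SANDIX", "eSANDIX")

#: compartments present per model: (soma, exchange, impermeable stick)
_MODEL_FEATURES = {
    "SANDI": dict(soma=True, exchange=False, imp_stick=False),
    "SMEX": dict(soma=False, exchange=True, imp_stick=False),
    "SANDIX": dict(soma=True, exchange=True, imp_stick=False),
    "eSANDIX": dict(soma=True, exchange=True, imp_stick=True),
}


@dataclass(frozen=True)
class GmModelParams:
    """Union of compartment parameters for the four gray-matter models.

    Signal fractions (of total S0): fe extracellular, fn neurite
    (exchanging), fn_imp impermeable neurite, fs soma, fim immobile
    offset.  Fields irrelevant to ``model_id`` must be zero/None.
    Permeable and impermeable sticks share the diffusivity Dn.
    """

    model_id: str
    fe: float
    fn: float
    De: float  # um^2/ms
    Dn: float  # um^2/ms
    fs: float = 0.0
    fn_imp: float = 0.0
    fim: float = 0.0
    tau_n: float | None = None  # neurite residence time, ms
    Rs: float | None = None  # soma radius, um
    D0: float = 2.0  # intrasoma free diffusivity, um^2/ms

    def __post_init__(self) -> None:
        if self.model_id not in MODEL_IDS:
            raise ValueError(f"unknown model_id {self.model_id!r}")
        feat = _MODEL_FEATURES[self.model_id]
        fr = (self.fe, self.fn, self.fn_imp, self.fs, self.fim)
        if any(f < 0 for f in fr):
            raise ValueError("fractions must be nonnegative")
        if abs(sum(fr) - 1.0) > 1e-9:
            raise ValueError("fractions must sum to 1")
        if not feat["soma"] and (self.fs != 0 or self.Rs is not None):
            raise ValueError(f"{self.model_id} has no soma compartment")
        if feat["soma"] and self.fs > 0 and self.Rs is None:
            raise ValueError("soma compartment requires Rs")
        if not feat["exchange"] and self.tau_n is not None:
            raise ValueError(f"{self.model_id} has no exchange")
        if not feat["imp_stick"] and self.fn_imp != 0:
            raise ValueError(f"{self.model_id} has no impermeable sticks")
        for D in (self.De, self.Dn, self.D0):
            if not 0.0 <= D <= 3.5:
                raise ValueError("diffusivities must lie in [0, 3.5] um^2/ms")
        if self.Rs is not None and not 0.0 < self.Rs <= 20.0:
            raise ValueError("Rs must lie in (0, 20] um")

    @property
    def rn(self) -> float:
        """Neurite escape rate 1/tau_n (0 without exchange)."""
        if self.tau_n is None or np.isinf(self.tau_n):
            return 0.0
        return 1.0 / self.tau_n


@dataclass
class PowderSignalTable:
    """Signal vs (b, Delta, delta) with optional noise level.

    Wraps a DataFrame with columns b, Delta, delta, S and optionally
    sigma; keys (b, Delta, delta) are unique.  ``provenance`` tags the
    origin: measured | synthetic | model.
    """

    frame: pd.DataFrame
    provenance: str = "model"

    def __post_init__(self) -> None:
        required = {"b", "Delta", "delta", "S"}
        if not required.issubset(self.frame.columns):
            raise ValueError(f"table must have columns {sorted(required)}")
        keys = self.frame[["b", "Delta", "delta"]].round(12)
        if keys.duplicated().any():
            raise ValueError("duplicate (b, Delta, delta) keys")
        if self.provenance not in ("measured", "synthetic", "model"):
            raise ValueError("provenance must be measured|synthetic|model")
        sig = self.frame.get("sigma")
        smax = 1.0 + (5.0 * sig.max() if sig is not None else 0.0)
        if (self.frame["S"] < 0).any() or (self.frame["S"] > smax + 1e-12).any():
            raise ValueError("signals outside [0, 1 + 5 sigma]")

    def __len__(self) -> int:
        return len(self.frame)

    def subset(self, Delta: float | None = None, b_min: float | None = None,
               b_max: float | None = None) -> "PowderSignalTable":
        df = self.frame
        if Delta is not None:
            df = df[np.isclose(df["Delta"], Delta)]
        if b_min is not None:
            df = df[df["b"] >= b_min]
        if b_max is not None:
            df = df[df["b"] <= b_max]
        return PowderSignalTable(df.reset_index(drop=True), self.provenance)

    def to_csv(self, path, sep: str = ",") -> None:
        self.frame.to_csv(path, sep=sep, index=False, float_format="%.12g")

    @classmethod
    def read_csv(cls, path, provenance: str = "measured") -> "PowderSignalTable":
        from .io import read_signal_table
        return read_signal_table(path, provenance=provenance)


def model_signal(protocol: AcquisitionProtocol, params: GmModelParams,
                 quad: PowderQuadrature | None = None, n_ramp: int = 32
                 ) -> PowderSignalTable:
    """Evaluate a model's powder-averaged signal over a protocol.

    SANDI:   fe e^(-b De) + fn stick(b Dn) + fs e^(-b Ds(Delta,delta,Rs)) + fim
    SMEX:    (fe+fn) * pair_powder + fim  (Karger stick-extracellular block)
    SANDIX:  SMEX + fs e^(-b Ds)
    eSANDIX: SANDIX + fn_imp stick(b Dn)

    The soma diffusivity uses the finite-pulse GPA at all b-values.  The
    exchange block is evaluated with the fast segment-exponential engine,
    vectorized per (Delta, delta) group.
    """
    if quad is None:
        quad = powder_quadrature()
    feat = _MODEL_FEATURES[params.model_id]
    frames = []
    for (Delta, delta) in protocol.timings():
        sub = protocol.subset(Delta=Delta, delta=delta)
        b = sub.b
        S = np.full(len(b), params.fim)
        if feat["exchange"]:
            f_pair = params.fe + params.fn
            if f_pair > 0:
                fn_rel = params.fn / f_pair
                S = S + f_pair * stick_exchange_powder_bgrid(
                    b, Delta, delta, params.Dn, params.De, fn_rel,
                    params.rn, quad, n_ramp)
        else:
            S = S + params.fe * np.asarray(gaussian_signal(b, params.De))
            S = S + params.fn * np.asarray(stick_powder_signal(b, params.Dn))
        if feat["imp_stick"] and params.fn_imp > 0:
            S = S + params.fn_imp * np.asarray(
                stick_powder_signal(b, params.Dn))
        if feat["soma"] and params.fs > 0:
            Ds = sphere_diffusivity_gpa(Delta, delta, params.Rs, params.D0)
            S = S + params.fs * np.exp(-b * Ds)
        frames.append(pd.DataFrame(
            {"b": b, "Delta": Delta, "delta": delta, "S": S}))
    frame = pd.concat(frames, ignore_index=True)
    return PowderSignalTable(frame, provenance="model")


def powerlaw_exponent(table: PowderSignalTable | pd.DataFrame,
                      b_min: float = 10.0, b_max: float = 100.0) -> float:
    """Apparent power-law exponent: absolute slope of the OLS line through
    (ln b, ln S) for b in [b_min, b_max] at a single (Delta, delta).

    Requires at least 4 points in range.
    """
    df = table.frame if isinstance(table, PowderSignalTable) else table
    if df[["Delta", "delta"]].round(9).drop_duplicates().shape[0] > 1:
        raise ValueError("exponent is defined for a single (Delta, delta)")
    sel = df[(df["b"] >= b_min) & (df["b"] <= b_max)]
    if len(sel) < 4:
        raise ValueError("need at least 4 points with b in range")
    x = np.log(sel["b"].to_numpy())
    y = np.log(sel["S"].to_numpy())
    slope = np.polyfit(x, y, 1)[0]
    return float(abs(slope))


def time_dependence_sign(table: PowderSignalTable, b_min: float = 0.0,
                         dead_band: float = 0.005) -> str:
    """Classify the signal's diffusion-time dependence at fixed b.

    For every b value shared by at least two Delta, the signal across
    increasing Delta is labelled decreasing (exchange-dominated),
    increasing (structure/restriction-dominated) or flat within a
    relative dead-band.  Returns "decreasing", "increasing" or "mixed".
    Exact b matching across Delta is required (protocol design, not
    interpolation).
    """
    df = table.frame
    df = df[df["b"] >= b_min]
    votes = []
    for b, grp in df.groupby(df["b"].round(9)):
        if grp["Delta"].nunique() < 2:
            continue
        g = grp.sort_values("Delta")
        S = g["S"].to_numpy()
        rel = np.diff(S) / S[:-1]
        if np.all(rel < 0) and np.any(rel < -dead_band):
            votes.append("decreasing")
        elif np.all(rel > 0) and np.any(rel > dead_band):
            votes.append("increasing")
        elif np.all(np.abs(rel) <= dead_band):
            votes.append("flat")
        else:
            votes.append("mixed")
    if not votes:
        raise ValueError("need at least 2 diffusion times at a shared b")
    kinds = set(votes)
    if kinds <= {"decreasing", "flat"} and "decreasing" in kinds:
        return "decreasing"
    if kinds <= {"increasing", "flat"} and "increasing" in kinds:
        return "increasing"
    if kinds == {"flat"}:
        return "mixed"
    return "mixed"


def dki_powder_fit(table: PowderSignalTable | pd.DataFrame,
                   b_max: float = 3.0) -> tuple[float, float]:
    """Powder kurtosis summary fit over the low-b regime.

    Least squares of ln S = -b D + (1/6) b^2 D^2 K on the subset
    b <= b_max (at least 3 distinct b required); returns (D, K).
    """
    df = table.frame if isinstance(table, PowderSignalTable) else table
    sel = df[df["b"] <= b_max]
    if sel["b"].nunique() < 3:
        raise ValueError("need at least 3 distinct b <= b_max")
    b = sel["b"].to_numpy()
    y = np.log(sel["S"].to_numpy())
    A = np.column_stack([-b, b**2])
    (c1, c2), *_ = np.linalg.lstsq(A, y, rcond=None)
    D = float(c1)
    K = float(6.0 * c2 / (c1 * c1)) if c1 != 0 else 0.0
    return D, K
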