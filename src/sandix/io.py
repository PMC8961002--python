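"""Delimited-text and JSON I/O for signal tables, protocols and parameters.

All writers round-trip at 12 significant digits; CSV vs TSV is detected
from the file content (or forced via ``sep``).
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .models import GmModelParams, PowderSignalTable
from .protocol import AcquisitionProtocol, make_pgse

__all__ = [
    "read_signal_table",
    "write_signal_table",
    "read_protocol",
    "write_protocol",
    "read_params",
    "write_params",
]


def _detect_sep(path) -> str:
    head = Path(path).read_text().splitlines()[0]
    return "\t" if "\t" in head else ","


def read_signal_table(path, provenance: str = "measured",
                      sep: str | None = None) -> PowderSignalTable:
    sep = sep or _detect_sep(path)
    df = pd.read_csv(path, sep=sep)
    return PowderSignalTable(df, provenance=provenance)


def write_signal_table(table: PowderSignalTable, path,
                       sep: str | None = None) -> None:
    sep = sep or ("\t" if str(path).endswith(".tsv") else ",")
    table.frame.to_csv(path, sep=sep, index=False, float_format="%.12g")


def read_protocol(path, sep: str | None = None) -> AcquisitionProtocol:
    sep = sep or _detect_sep(path)
    df = pd.read_csv(path, sep=sep)
    seqs = tuple(make_pgse(r.b, r.Delta, r.delta) for r in df.itertuples())
    return AcquisitionProtocol(seqs)


def write_protocol(protocol: AcquisitionProtocol, path,
                   sep: str | None = None) -> None:
    sep = sep or ("\t" if str(path).endswith(".tsv") else ",")
    df = pd.DataFrame({"b": protocol.b, "Delta": protocol.Delta,
                       "delta": protocol.delta})
    df.to_csv(path, sep=sep, index=False, float_format="%.12g")


def write_params(params: GmModelParams, path) -> None:
    d = {k: getattr(params, k) for k in
         ("model_id", "fe", "fn", "fn_imp", "fs", "fim", "De", "Dn",
          "tau_n", "Rs", "D0")}
    Path(path).write_text(json.dumps(d, indent=2) + "\n")


def read_params(path) -> GmModelParams:
    d = json.loads(Path(path).read_text())
    return GmModelParams(**d)
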