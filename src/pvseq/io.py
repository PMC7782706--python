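"""Readers and writers for expression matrices, metadata, sweeps, and config.

Formats
-------
* Expression: TSV/CSV with genes as rows and a header of cell ids, or Matrix
  Market coordinate format plus sidecar ``<stem>.genes.txt`` /
  ``<stem>.cells.txt`` label files (one symbol/id per line).
* Metadata: TSV/CSV with at least ``cell_id`` and ``age_days`` columns.
* Sweeps: one CSV per cell (column 0 = time in ms, one column per sweep) plus
  a JSON sidecar describing the protocol.
* Config: a single YAML (or JSON, which YAML subsumes) file with per-stage
  blocks.
"""
from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import io as spio
from scipy import sparse

from .data import CellTable, ExpressionMatrix, ValidationError

logger = logging.getLogger(__name__)

_SEPARATORS = {"tsv": "\t", "csv": ","}


def _sidecar_paths(path: Path) -> tuple[Path, Path]:
    stem = path.with_suffix("")
    return Path(f"{stem}.genes.txt"), Path(f"{stem}.cells.txt")


def read_expression(path: str | Path, format: str = "tsv") -> ExpressionMatrix:
    """Read a gene x cell TPM matrix.

    Duplicate gene symbols are summed, mirroring the collapse of Ensembl gene
    IDs that share a symbol.  Negative or non-finite values raise
    :class:`ValidationError`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format in _SEPARATORS:
        try:
            df = pd.read_csv(path, sep=_SEPARATORS[format], index_col=0)
        except (pd.errors.ParserError, ValueError) as exc:
            raise ValidationError(f"malformed {format} file {path}: {exc}") from exc
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
    elif format == "mtx_triplet":
        genes_path, cells_path = _sidecar_paths(path)
        for p in (genes_path, cells_path):
            if not p.exists():
                raise FileNotFoundError(f"mtx_triplet sidecar missing: {p}")
        mat = spio.mmread(path)
        genes = genes_path.read_text().split()
        cells = cells_path.read_text().split()
        dense = np.asarray(mat.todense() if sparse.issparse(mat) else mat, dtype=float)
        if dense.shape != (len(genes), len(cells)):
            raise ValidationError(
                f"matrix shape {dense.shape} does not match sidecar labels "
                f"({len(genes)} genes, {len(cells)} cells)"
            )
        df = pd.DataFrame(dense, index=genes, columns=cells)
    else:
        raise ValueError(f"unknown expression format {format!r}")
    return ExpressionMatrix(df, collapse_duplicates=True)


def write_expression(expr: ExpressionMatrix, path: str | Path, format: str = "tsv") -> None:
    path = Path(path)
    if format in _SEPARATORS:
        expr.df.to_csv(path, sep=_SEPARATORS[format])
    elif format == "mtx_triplet":
        genes_path, cells_path = _sidecar_paths(path)
        spio.mmwrite(str(path), sparse.coo_matrix(expr.df.to_numpy()))
        genes_path.write_text("\n".join(expr.genes) + "\n")
        cells_path.write_text("\n".join(expr.cells) + "\n")
    else:
        raise ValueError(f"unknown expression format {format!r}")


def read_metadata(path: str | Path) -> CellTable:
    """Read a per-cell metadata table (TSV or CSV, sniffed by extension)."""
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, dtype={"cell_id": str})
    return CellTable(df)


def write_metadata(meta: CellTable, path: str | Path) -> None:
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    meta.df.to_csv(path, sep=sep, index=False)


def read_sweeps(csv_path: str | Path, json_path: str | Path | None = None):
    """Read a per-cell sweep CSV + JSON protocol sidecar into a SweepSet.

    The CSV holds time (ms) in column 0 and one sweep per remaining column;
    the sidecar lists ``sampling_rate_hz`` and a ``protocol`` entry per sweep
    with ``type`` ("vc" or "cc"), ``amplitude`` (mV for vc, pA for cc),
    ``onset_ms`` and ``offset_ms``.
    """
    from .ephys import CurrentClampStep, SweepSet, VoltageClampStep

    csv_path = Path(csv_path)
    if json_path is None:
        json_path = csv_path.with_suffix(".json")
    sidecar = json.loads(Path(json_path).read_text())
    table = pd.read_csv(csv_path)
    time_full = table.iloc[:, 0].to_numpy(dtype=float)
    traces = []
    times = []
    for i in range(table.shape[1] - 1):
        col = table.iloc[:, i + 1].to_numpy(dtype=float)
        valid = ~np.isnan(col)  # shorter sweeps are NaN-padded on disk
        traces.append(col[valid])
        times.append(time_full[valid])
    protocol = sidecar["protocol"]
    if len(protocol) != len(traces):
        raise ValidationError(
            f"protocol lists {len(protocol)} sweeps but CSV has {len(traces)}"
        )
    vc_step = None
    cc_steps = []
    for entry, trace, time_ms in zip(protocol, traces, times):
        if entry["type"] == "vc":
            vc_step = VoltageClampStep(
                delta_mv=float(entry["amplitude"]),
                onset_ms=float(entry["onset_ms"]),
                offset_ms=float(entry["offset_ms"]),
                time_ms=time_ms,
                current_pa=trace,
            )
        elif entry["type"] == "cc":
            cc_steps.append(
                CurrentClampStep(
                    i_inj_pa=float(entry["amplitude"]),
                    onset_ms=float(entry["onset_ms"]),
                    offset_ms=float(entry["offset_ms"]),
                    time_ms=time_ms,
                    voltage_mv=trace,
                )
            )
        else:
            raise ValidationError(f"unknown sweep type {entry['type']!r}")
    return SweepSet(
        sampling_rate_hz=float(sidecar["sampling_rate_hz"]),
        vc_step=vc_step,
        cc_steps=cc_steps,
    )


def write_sweeps(sweeps, csv_path: str | Path, json_path: str | Path | None = None) -> None:
    csv_path = Path(csv_path)
    if json_path is None:
        json_path = csv_path.with_suffix(".json")
    columns = {"time_ms": None}
    protocol = []
    traces = []
    if sweeps.vc_step is not None:
        protocol.append(
            {
                "type": "vc",
                "amplitude": sweeps.vc_step.delta_mv,
                "onset_ms": sweeps.vc_step.onset_ms,
                "offset_ms": sweeps.vc_step.offset_ms,
            }
        )
        traces.append(("vc_0", sweeps.vc_step.time_ms, sweeps.vc_step.current_pa))
    for i, step in enumerate(sweeps.cc_steps):
        protocol.append(
            {
                "type": "cc",
                "amplitude": step.i_inj_pa,
                "onset_ms": step.onset_ms,
                "offset_ms": step.offset_ms,
            }
        )
        traces.append((f"cc_{i}", step.time_ms, step.voltage_mv))
    # pad traces to common length with NaN so one CSV can hold all sweeps
    n = max(len(t[1]) for t in traces)
    time = next(t[1] for t in traces if len(t[1]) == n)
    data = {"time_ms": time}
    for name, t, y in traces:
        col = np.full(n, np.nan)
        col[: len(y)] = y
        data[name] = col
    pd.DataFrame(data).to_csv(csv_path, index=False)
    Path(json_path).write_text(
        json.dumps({"sampling_rate_hz": sweeps.sampling_rate_hz, "protocol": protocol}, indent=1)
    )


def load_config(path: str | Path) -> dict:
    """Load a YAML/JSON config file with per-stage blocks."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValidationError("config file must contain a mapping of stage blocks")
    return cfg
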