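"""Plain-text and TIFF input/output.

Formats:

* expression matrix — TSV, genes as rows, columns named ``condition:replicate``;
* cell tables / flow event tables / truth tables — CSV with header;
* gene positions — 4-column BED-like TSV (chrom, start, end, gene_id) or a
  full GenePosition table; chromosome lengths — 2-column TSV;
* region annotations — JSON (0-based pixel coordinates, half-open boxes);
* image stacks — multi-page TIFF, 16-bit, z pages in order (in-memory stacks
  are float64; quantisation happens only here);
* provenance — JSON with parameters, seed and package version, written next
  to every generated dataset.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataError, ParameterError
from .imaging import RegionAnnotation


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------

def write_expression_matrix(matrix: pd.DataFrame, path) -> None:
    flat = matrix.copy()
    flat.columns = [f"{c}:{r}" for c, r in matrix.columns]
    flat.to_csv(path, sep="\t", index_label="gene_id")


def read_expression_matrix(path) -> pd.DataFrame:
    flat = pd.read_csv(path, sep="\t", index_col="gene_id")
    try:
        pairs = [tuple(c.split(":", 1)) for c in flat.columns]
        if any(len(p) != 2 for p in pairs):
            raise ValueError
    except ValueError:
        raise DataError("expression matrix columns must be 'condition:replicate'")
    flat.columns = pd.MultiIndex.from_tuples(pairs, names=["condition", "replicate"])
    return flat


# ---------------------------------------------------------------------------
# tabular data
# ---------------------------------------------------------------------------

def write_cell_table(cells: pd.DataFrame, path) -> None:
    cells.to_csv(path, index=False)


def read_cell_table(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_flow_events(events: pd.DataFrame, path) -> None:
    events.to_csv(path, index=False)


def read_flow_events(path) -> pd.DataFrame:
    events = pd.read_csv(path)
    missing = {"fsc", "ssc", "fl1"} - set(events.columns)
    if missing:
        raise DataError(f"flow event table missing columns: {sorted(missing)}")
    events.attrs["gated"] = False
    return events


def read_gene_positions(path) -> pd.DataFrame:
    """BED-like TSV: either headerless 4 columns or a full GenePosition table."""
    probe = pd.read_csv(path, sep="\t", nrows=1, header=None)
    first = str(probe.iloc[0, 0])
    if first in ("chromosome", "chrom", "gene_id"):
        return pd.read_csv(path, sep="\t")
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chromosome", "start", "end", "gene_id"])
    return df


def read_chrom_lengths(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", header=None, names=["chromosome", "length"],
                     comment="#")
    if df["chromosome"].iloc[0] == "chromosome":  # tolerate a header line
        df = df.iloc[1:]
    return pd.Series(df["length"].astype(int).to_numpy(),
                     index=df["chromosome"].to_numpy())


# ---------------------------------------------------------------------------
# annotations and image stacks
# ---------------------------------------------------------------------------

def write_annotations(annotations, path) -> None:
    payload = [a.as_dict() for a in annotations]
    Path(path).write_text(json.dumps(payload, indent=1))


def read_annotations(path) -> list:
    payload = json.loads(Path(path).read_text())
    return [RegionAnnotation.from_dict(d) for d in payload]


def write_stack_tiff(stack: np.ndarray, path, max_value: float | None = None) -> None:
    """Write a float stack as 16-bit multi-page TIFF (z pages in order).

    Values are linearly scaled so ``max_value`` (default: the stack maximum)
    maps to 65535; negative values clip to 0.
    """
    import tifffile

    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3:
        raise ParameterError("stack must be (n_z, H, W)")
    top = float(stack.max()) if max_value is None else float(max_value)
    if top <= 0:
        raise ParameterError("stack has no positive values to scale")
    scaled = np.clip(stack / top, 0.0, 1.0) * 65535.0
    tifffile.imwrite(path, scaled.round().astype(np.uint16),
                     photometric="minisblack",
                     metadata={"tagen_scale": top})


def read_stack_tiff(path) -> np.ndarray:
    import tifffile

    return tifffile.imread(path)


# ---------------------------------------------------------------------------
# provenance
# ---------------------------------------------------------------------------

def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def write_provenance(out_dir, parameters: dict, seed: int) -> Path:
    """Record parameters + seed + package version next to generated outputs."""
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    payload = {"package": "tagen", "version": __version__,
               "seed": int(seed), "parameters": _jsonable(parameters)}
    path = out_dir / "provenance.json"
    path.write_text(json.dumps(payload, indent=1, sort_keys=True))
    return path
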