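"""Reading and writing landmark coordinate tables.

Three dialects are supported:

* ``csv`` — wide CSV, one row per specimen with columns
  ``specimen_id, group, sex, x1, y1, z1, ..., xK, yK, zK`` (1-based landmark
  numbering in headers); an empty cell marks a missing coordinate.
* ``tps`` — the classic morphometrics TPS landmark file (``LM3=`` blocks with
  ``ID=`` lines); missing points are coded as ``9999 9999 9999`` per the
  common convention.  Group/sex travel in the ID field as
  ``specimen_id|group|sex`` (plain IDs get group/sex ``unknown``-compatible
  defaults and fail validation unless a roster is supplied).
* ``xlsx`` — a spreadsheet laid out like the wide CSV (configurable sheet).
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .dataset import Dataset, SpecimenRecord, ValidationError
from .scheme import LandmarkScheme, default_scheme

log = logging.getLogger(__name__)

_META_COLS = ["specimen_id", "group", "sex"]
TPS_MISSING = 9999.0


class FormatError(ValueError):
    """File layout does not match the declared dialect."""


def _coord_columns(k: int) -> list[str]:
    return [f"{ax}{i + 1}" for i in range(k) for ax in ("x", "y", "z")]


def dataset_to_frame(dataset: Dataset, precision: Optional[int] = None) -> pd.DataFrame:
    rows = []
    for r in dataset:
        flat = r.coords.reshape(-1)
        if precision is not None:
            flat = np.round(flat, precision)
        rows.append([r.specimen_id, r.group, r.sex, *flat])
    cols = _META_COLS + _coord_columns(len(dataset.scheme))
    return pd.DataFrame(rows, columns=cols)


def write_dataset(dataset: Dataset, path, format: str = "csv",
                  precision: int = 9) -> None:
    """Write a dataset; round-trips through :func:`read_dataset`."""
    path = Path(path)
    if format == "csv":
        dataset_to_frame(dataset).to_csv(
            path, index=False, float_format=f"%.{precision}f", na_rep="")
    elif format == "xlsx":
        dataset_to_frame(dataset, precision).to_excel(path, index=False)
    elif format == "tps":
        with open(path, "w") as fh:
            for r in dataset:
                fh.write(f"LM3={len(dataset.scheme)}\n")
                for row in r.coords:
                    if np.isnan(row).any():
                        fh.write(f"{TPS_MISSING:.1f} {TPS_MISSING:.1f} {TPS_MISSING:.1f}\n")
                    else:
                        fh.write(" ".join(f"{v:.{precision}f}" for v in row) + "\n")
                fh.write(f"ID={r.specimen_id}|{r.group}|{r.sex}\n")
    else:
        raise ValueError(f"unknown format {format!r}")


def _frame_to_dataset(df: pd.DataFrame, scheme: LandmarkScheme,
                      source: str) -> Dataset:
    for c in _META_COLS:
        if c not in df.columns:
            raise FormatError(f"{source}: missing column {c!r}")
    k = len(scheme)
    want = _coord_columns(k)
    missing_cols = [c for c in want if c not in df.columns]
    if missing_cols:
        raise FormatError(
            f"{source}: expected {3 * k} coordinate columns, "
            f"missing {missing_cols[:4]}{'...' if len(missing_cols) > 4 else ''}")
    records = []
    for _, row in df.iterrows():
        sid = str(row["specimen_id"])
        coords = pd.to_numeric(row[want], errors="coerce").to_numpy(float).reshape(k, 3)
        try:
            records.append(SpecimenRecord(sid, str(row["group"]), str(row["sex"]), coords))
        except ValidationError as e:
            raise ValidationError(f"{source}: {e}") from e
    ds = Dataset(scheme, records)
    n_missing = [int(r.missing_mask.sum()) for r in ds]
    log.info("read %d specimens from %s; missing points per specimen: %s",
             len(ds), source, n_missing)
    return ds


def read_dataset(path, format: str = "csv",
                 scheme: Optional[LandmarkScheme] = None,
                 sheet: int | str = 0) -> Dataset:
    """Read a landmark table into a validated :class:`Dataset`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    scheme = scheme or default_scheme()
    if format == "csv":
        df = pd.read_csv(path, dtype={c: str for c in _META_COLS})
        return _frame_to_dataset(df, scheme, str(path))
    if format == "xlsx":
        df = pd.read_excel(path, sheet_name=sheet)
        return _frame_to_dataset(df, scheme, str(path))
    if format == "tps":
        return _read_tps(path, scheme)
    raise ValueError(f"unknown format {format!r}")


def _read_tps(path: Path, scheme: LandmarkScheme) -> Dataset:
    records = []
    coords: list[list[float]] = []
    n_expected = None
    sid = None

    def flush(line_no):
        nonlocal coords, n_expected, sid
        if n_expected is None:
            return
        if len(coords) != n_expected:
            raise FormatError(
                f"{path}:{line_no}: specimen {sid or '?'} has {len(coords)} "
                f"points, header said {n_expected}")
        arr = np.array(coords, float)
        arr[np.all(arr == TPS_MISSING, axis=1)] = np.nan
        parts = (sid or f"spec{len(records) + 1}").split("|")
        spec_id = parts[0]
        group = parts[1] if len(parts) > 1 else "unknown"
        sex = parts[2] if len(parts) > 2 else "unknown"
        records.append(SpecimenRecord(spec_id, group, sex, arr))
        coords, n_expected, sid = [], None, None

    with open(path) as fh:
        for ln, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line:
                continue
            upper = line.upper()
            if upper.startswith("LM3=") or upper.startswith("LM="):
                flush(ln)
                n_expected = int(line.split("=", 1)[1])
            elif upper.startswith("ID="):
                sid = line.split("=", 1)[1].strip()
            elif "=" in line and not line[0].isdigit() and not line[0] in "-+.":
                continue  # IMAGE=, SCALE=, ... ignored
            else:
                vals = line.split()
                if len(vals) != 3:
                    raise FormatError(f"{path}:{ln}: expected 3 coordinates, got {len(vals)}")
                coords.append([float(v) for v in vals])
        flush(None)
    return Dataset(scheme, records)


def load_deposited_dataset(search_dir="data") -> Dataset:
    """Load the published cranial coordinate table, if the user has placed it
    in ``data/`` as ``deposited_coordinates.csv`` (wide-CSV dialect) or
    ``deposited_coordinates.xlsx``.

    The 70-specimen table (26 fossil + 44 extant crania) is distributed as
    supplementary material of the source study and is not redistributed
    with this package; analyses that reproduce its printed values require
    it, everything else runs on synthetic data.
    """
    search_dir = Path(search_dir)
    for name, fmt in (("deposited_coordinates.csv", "csv"),
                      ("deposited_coordinates.xlsx", "xlsx")):
        p = search_dir / name
        if p.exists():
            return read_dataset(p, format=fmt)
    raise FileNotFoundError(
        f"deposited coordinate table not found under {search_dir}/ "
        "(expected deposited_coordinates.csv or .xlsx); download the "
        "supplementary landmark table of the source study and convert it "
        "to the wide-CSV dialect")


def sex_ratio(dataset: Dataset, count_uncertain_as_sexed: bool = True) -> float:
    """Percentage of female specimens: 100 x n(F [+ F?]) / n total."""
    if len(dataset) == 0:
        raise ValidationError("sex ratio undefined on an empty dataset")
    female = {"F", "F?"} if count_uncertain_as_sexed else {"F"}
    n_f = sum(r.sex in female for r in dataset)
    return 100.0 * n_f / len(dataset)
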