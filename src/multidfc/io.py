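"""File readers and writers: TSV time series, TSV atlas, HDF5 dFC arrays.

Time-series files are time-by-ROI delimited text (rows = TRs); the ROI
order is defined by the atlas file, never by the data header -- a header,
when present, must match the atlas order exactly or reading fails.  The
dFC array container is a single HDF5 file holding the 5-way value array
and its label axes, plus the YAML run configuration (including seed) that
produced it.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .config import RunConfig
from .containers import AtlasTable, DfcArray, ParcellatedTimeSeries
from .errors import ContainerError, FormatError, ParseError

_ATLAS_COLUMNS = ("roi_id", "rsn_label", "hemisphere")


def read_atlas(path) -> AtlasTable:
    """Read a 3-column atlas table (roi_id, rsn_label, hemisphere)."""
    try:
        df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    except Exception as err:  # noqa: BLE001 - surface as format error
        raise FormatError(f"cannot parse atlas {path}: {err}") from err
    missing = [c for c in _ATLAS_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"atlas {path} lacks column(s) {missing}")
    df = df.fillna("None")
    return AtlasTable(
        df["roi_id"].to_numpy(), df["rsn_label"].to_numpy(), df["hemisphere"].to_numpy()
    )


def write_atlas(atlas: AtlasTable, path) -> None:
    pd.DataFrame(
        {
            "roi_id": atlas.roi_ids,
            "rsn_label": atlas.rsn_labels,
            "hemisphere": atlas.hemispheres,
        }
    ).to_csv(path, sep="\t", index=False)


def atlas_from_timeseries(ts: ParcellatedTimeSeries) -> AtlasTable:
    return AtlasTable(ts.roi_labels, ts.rsn_labels, ts.hemispheres)


def read_timeseries(
    path,
    atlas: AtlasTable,
    tr_seconds: float = 0.72,
    subject_id: str | None = None,
) -> ParcellatedTimeSeries:
    """Read a T x R delimited time-series matrix; columns follow the atlas.

    A header row (matching the atlas ROI ids) is optional.  A column-count
    mismatch against the atlas is a :class:`FormatError`; a non-numeric
    body cell is a :class:`ParseError` naming the offending row/column.
    """
    path = Path(path)
    text = path.read_text()
    first = text.splitlines()[0] if text else ""
    sep = "\t" if "\t" in first else ","
    tokens = [t.strip() for t in first.split(sep)]

    def _numeric(tok: str) -> bool:
        try:
            float(tok)
            return True
        except ValueError:
            return False

    has_header = bool(tokens) and not all(_numeric(t) for t in tokens)
    if has_header:
        if tokens != list(atlas.roi_ids):
            raise FormatError(
                f"{path}: header does not match the atlas ROI order; "
                "reordering is never done silently"
            )
    df = pd.read_csv(
        _io.StringIO(text), sep=sep, header=0 if has_header else None, dtype=str
    )
    if df.shape[1] != atlas.n_rois:
        raise FormatError(
            f"{path}: {df.shape[1]} columns but atlas defines {atlas.n_rois} ROIs"
        )
    raw = df.to_numpy()
    try:
        values = raw.astype(float)
    except ValueError:
        for (r, c), cell in np.ndenumerate(raw):
            if not _numeric(str(cell)):
                raise ParseError(
                    f"{path}: non-numeric cell at row {r}, column {c}: {cell!r}"
                ) from None
        raise
    if subject_id is None:
        subject_id = path.stem
    return ParcellatedTimeSeries(
        subject_id, tr_seconds, values,
        atlas.roi_ids, atlas.rsn_labels, atlas.hemispheres,
    )


def write_timeseries(ts: ParcellatedTimeSeries, path, header: bool = True) -> None:
    """Write a time-by-ROI TSV (full float precision, lossless roundtrip)."""
    df = pd.DataFrame(ts.values, columns=ts.roi_labels)
    df.to_csv(path, sep="\t", index=False, header=header, float_format="%.17g")


# ---------------------------------------------------------------------------
# HDF5 dFC array container

_DATASETS = ("values", "subject_ids", "method_ids", "time_stamps",
             "roi_labels", "rsn_labels")


def write_dfc_array(arr: DfcArray, path, config: RunConfig | None = None) -> None:
    """Write the 5-way dFC array with its label axes to one HDF5 file."""
    with h5py.File(path, "w") as fh:
        fh.create_dataset("values", data=arr.values)
        fh.create_dataset("time_stamps", data=arr.time_stamps)
        for name in ("subject_ids", "method_ids", "roi_labels", "rsn_labels"):
            data = np.asarray(getattr(arr, name), dtype=object)
            fh.create_dataset(name, data=data, dtype=h5py.string_dtype())
        if config is not None:
            fh.attrs["config_yaml"] = config.to_yaml()
            fh.attrs["seed"] = config.seed


def read_dfc_array(path) -> tuple[DfcArray, RunConfig | None]:
    """Read a dFC array container; raises :class:`ContainerError` on a
    corrupted file or missing dataset (never returns silent NaNs)."""
    try:
        fh = h5py.File(path, "r")
    except OSError as err:
        raise ContainerError(f"cannot open dFC container {path}: {err}") from err
    with fh:
        missing = [name for name in _DATASETS if name not in fh]
        if missing:
            raise ContainerError(f"{path}: missing dataset(s) {missing}")
        arr = DfcArray(
            fh["values"][()],
            fh["subject_ids"].asstr()[()],
            fh["method_ids"].asstr()[()],
            fh["time_stamps"][()],
            fh["roi_labels"].asstr()[()],
            fh["rsn_labels"].asstr()[()],
        )
        config = None
        if "config_yaml" in fh.attrs:
            config = RunConfig.from_yaml(str(fh.attrs["config_yaml"]))
    return arr, config
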