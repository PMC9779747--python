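"""Delimited-text I/O and YAML run configuration.

File dialects (tab-separated by default, comma accepted on read):

* localization/track tables: header ``frame, track_id, x_nm, y_nm``
  (``track_id`` empty for unlinked localizations; lengths in nm);
* correlograms: header ``lag_s, g2``.

Internally everything is SI; conversion to/from nanometers happens
here and only here.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import yaml

from .dls import CorrelationFunction
from .physics import MediumConditions
from .simulate import AcquisitionSpec, DlsAcquisitionSpec, PopulationMode
from .tracking import Track, TrackSet

__all__ = [
    "write_tracks",
    "read_localizations",
    "read_tracks",
    "write_correlogram",
    "read_correlogram",
    "load_config",
    "load_liposome_reference",
]


def _read_delimited(path) -> pd.DataFrame:
    with open(path) as fh:
        header = fh.readline()
    sep = "\t" if "\t" in header else ","
    return pd.read_csv(path, sep=sep)


def write_tracks(ts: TrackSet, path) -> Path:
    """Write a TrackSet as a ``frame, track_id, x_nm, y_nm`` TSV."""
    df = ts.to_dataframe()
    out = pd.DataFrame(
        {
            "frame": df["frame"],
            "track_id": df["track_id"],
            "x_nm": df["x"] * 1e9,
            "y_nm": df["y"] * 1e9,
        }
    )
    path = Path(path)
    out.to_csv(path, sep="\t", index=False)
    return path


def read_localizations(path) -> pd.DataFrame:
    """Read a localization table; returns columns frame, x, y (meters), track_id.

    ``track_id`` is NaN where the file left it empty (unlinked points).
    """
    df = _read_delimited(path)
    required = {"frame", "x_nm", "y_nm"}
    if not required <= set(df.columns):
        raise ValueError(f"localization file needs columns {sorted(required)}")
    out = pd.DataFrame(
        {
            "frame": df["frame"].astype(np.int64),
            "x": df["x_nm"] * 1e-9,
            "y": df["y_nm"] * 1e-9,
        }
    )
    out["track_id"] = df["track_id"] if "track_id" in df.columns else np.nan
    return out


def read_tracks(path, acquisition: Optional[AcquisitionSpec] = None) -> TrackSet:
    """Read a pre-linked track table into a TrackSet (rows without id are dropped)."""
    df = read_localizations(path)
    df = df.dropna(subset=["track_id"])
    tracks = []
    for tid, grp in df.groupby("track_id"):
        grp = grp.sort_values("frame")
        if len(grp) < 2:
            continue
        tracks.append(
            Track(
                track_id=int(tid),
                frames=grp["frame"].to_numpy(),
                positions=grp[["x", "y"]].to_numpy(),
            )
        )
    return TrackSet(tracks=tracks, acquisition=acquisition, provenance=str(path))


def write_correlogram(cf: CorrelationFunction, path) -> Path:
    """Write a correlogram as a ``lag_s, g2`` TSV."""
    path = Path(path)
    pd.DataFrame({"lag_s": cf.lags, "g2": cf.g2}).to_csv(path, sep="\t", index=False)
    return path


def read_correlogram(path, beta: Optional[float] = None) -> CorrelationFunction:
    df = _read_delimited(path)
    if not {"lag_s", "g2"} <= set(df.columns):
        raise ValueError("correlogram file needs columns lag_s, g2")
    return CorrelationFunction(lags=df["lag_s"].to_numpy(), g2=df["g2"].to_numpy(), beta=beta)


def load_config(path) -> dict:
    """Load a YAML run configuration.

    Recognized top-level keys: ``seed`` (int), ``medium``,
    ``acquisition``, ``dls`` and ``modes`` (list).  The ``dls`` section
    may give the lag grid as ``lag_min``/``lag_max``/``n_lags``
    (log-spaced).  Missing sections fall back to package defaults.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}

    def _num(v):
        # YAML 1.1 reads "2.0e10" (no exponent sign) as a string; coerce
        if isinstance(v, str):
            return float(v)
        return v

    medium = MediumConditions(**{k: float(v) for k, v in (raw.get("medium") or {}).items()})
    acq_kwargs = {k: _num(v) for k, v in (raw.get("acquisition") or {}).items()}
    if "n_frames" in acq_kwargs:
        acq_kwargs["n_frames"] = int(acq_kwargs["n_frames"])
    if "field_extent" in acq_kwargs and acq_kwargs["field_extent"] is not None:
        acq_kwargs["field_extent"] = tuple(float(v) for v in acq_kwargs["field_extent"])
    acq = AcquisitionSpec(**acq_kwargs)
    dls_kwargs = {k: _num(v) for k, v in (raw.get("dls") or {}).items()}
    if {"lag_min", "lag_max"} <= set(dls_kwargs):
        n_lags = int(dls_kwargs.pop("n_lags", 120))
        lag_min = float(dls_kwargs.pop("lag_min"))
        lag_max = float(dls_kwargs.pop("lag_max"))
        dls_kwargs["lag_grid"] = np.logspace(np.log10(lag_min), np.log10(lag_max), n_lags)
    dls = DlsAcquisitionSpec(**dls_kwargs)
    modes = [
        PopulationMode(**{k: (v if k == "shape" else _num(v)) for k, v in m.items()})
        for m in (raw.get("modes") or [])
    ]
    return {
        "seed": int(raw.get("seed", 0)),
        "medium": medium,
        "acquisition": acq,
        "dls": dls,
        "modes": modes,
    }


def load_liposome_reference() -> pd.DataFrame:
    """Published liposome summary measurements shipped with the package.

    Per sample (LA, LB, LC) and dilution (100x, 1000x): dilution-corrected
    nanotracking number density and mean Rh, DLS main-peak Rh, and UV-vis
    absorbance at 280 nm.  Used by the comparison-stage examples.
    """
    with resources.files("scpsizer.data").joinpath("liposome_reference.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")
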