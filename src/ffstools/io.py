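"""File formats: photon traces (TSV and raw binary), correlation curves,
FRAP series, SEC standards, flat key-value configs and reports.

All text formats carry headers with units; every writer/reader pair
round-trips bit-exactly.
"""

from __future__ import annotations

import struct
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ParseError, ValidationError
from .fcs import CorrelationCurve
from .frap import FRAPSeries
from .simulate import PhotonTrace

__all__ = [
    "write_trace",
    "read_trace",
    "write_curve",
    "read_curve",
    "write_frap",
    "read_frap",
    "read_standards",
    "write_report",
    "read_config",
]

_BINARY_MAGIC = b"FFSTRACE"
_BINARY_HEADER = struct.Struct("<8sIIdQ")  # magic, version, reserved, bin_width, n_bins


def write_trace(path, trace: PhotonTrace, format: str = "tsv") -> None:
    """Write a photon trace as TSV (default) or the raw binary variant.

    TSV: a header line ``# bin_width_s=<float>`` then tab-separated columns
    ``bin_index  counts_g  counts_r``.  Binary: a 64-byte header (magic
    ``FFSTRACE``, version, bin width as little-endian float64, bin count as
    uint64, zero padding) followed by interleaved little-endian uint32
    (counts_g, counts_r) pairs.
    """
    path = Path(path)
    if format == "tsv":
        with open(path, "w") as fh:
            fh.write(f"# bin_width_s={trace.bin_width!r}\n")
            fh.write("bin_index\tcounts_g\tcounts_r\n")
            df = pd.DataFrame(
                {
                    "bin_index": np.arange(len(trace)),
                    "counts_g": trace.counts_g,
                    "counts_r": trace.counts_r,
                }
            )
            df.to_csv(fh, sep="\t", header=False, index=False)
    elif format == "binary":
        header = _BINARY_HEADER.pack(_BINARY_MAGIC, 1, 0, trace.bin_width, len(trace))
        header = header.ljust(64, b"\0")
        inter = np.empty(2 * len(trace), dtype="<u4")
        inter[0::2] = trace.counts_g
        inter[1::2] = trace.counts_r
        with open(path, "wb") as fh:
            fh.write(header)
            fh.write(inter.tobytes())
    else:
        raise ValidationError("format must be 'tsv' or 'binary'")


def read_trace(path, format: str | None = None) -> PhotonTrace:
    """Read a photon trace; the format is sniffed from the magic bytes unless
    given.  Raises :class:`ParseError` naming the offending line or offset."""
    path = Path(path)
    if format is None:
        with open(path, "rb") as fh:
            format = "binary" if fh.read(8) == _BINARY_MAGIC else "tsv"

    if format == "binary":
        raw = path.read_bytes()
        if len(raw) < 64:
            raise ParseError(f"{path}: truncated binary header (offset 0)")
        magic, version, _, bin_width, n_bins = _BINARY_HEADER.unpack(raw[: _BINARY_HEADER.size])
        if magic != _BINARY_MAGIC:
            raise ParseError(f"{path}: bad magic at offset 0")
        if version != 1:
            raise ParseError(f"{path}: unsupported version {version}")
        body = np.frombuffer(raw, dtype="<u4", offset=64)
        if body.size != 2 * n_bins:
            raise ParseError(
                f"{path}: expected {2 * n_bins} uint32 values after offset 64, got {body.size}"
            )
        return PhotonTrace(bin_width, body[0::2].astype(np.int64), body[1::2].astype(np.int64))

    with open(path) as fh:
        first = fh.readline()
    if not first.startswith("# bin_width_s="):
        raise ParseError(f"{path}:1: missing '# bin_width_s=' header")
    try:
        bin_width = float(first.split("=", 1)[1])
    except ValueError as exc:
        raise ParseError(f"{path}:1: unreadable bin width: {exc}") from exc
    try:
        df = pd.read_csv(path, sep="\t", skiprows=1)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ParseError(f"{path}: {exc}") from exc
    for col in ("bin_index", "counts_g", "counts_r"):
        if col not in df.columns:
            raise ParseError(f"{path}:2: missing column {col!r}")
    if (df["counts_g"] < 0).any() or (df["counts_r"] < 0).any():
        bad = int(np.nonzero((df["counts_g"] < 0) | (df["counts_r"] < 0))[0][0]) + 3
        raise ParseError(f"{path}:{bad}: negative count")
    if not (df["bin_index"].to_numpy() == np.arange(len(df))).all():
        raise ParseError(f"{path}: bin_index is not contiguous from 0")
    return PhotonTrace(bin_width, df["counts_g"].to_numpy(), df["counts_r"].to_numpy())


def write_curve(path, curve: CorrelationCurve) -> None:
    """Correlation curve as CSV: lag_s, G, se, kind."""
    pd.DataFrame(
        {"lag_s": curve.lags, "G": curve.G, "se": curve.se, "kind": curve.kind}
    ).to_csv(path, index=False, float_format="%.12g")


def read_curve(path) -> CorrelationCurve:
    df = pd.read_csv(path)
    for col in ("lag_s", "G", "se", "kind"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing column {col!r}")
    return CorrelationCurve(
        lags=df["lag_s"].to_numpy(),
        G=df["G"].to_numpy(),
        se=df["se"].to_numpy(),
        kind=str(df["kind"].iloc[0]),
    )


def write_frap(path, series: FRAPSeries) -> None:
    """FRAP series as CSV: time_s, bleached, unbleached, is_prebleach."""
    pd.DataFrame(
        {
            "time_s": series.time,
            "bleached": series.bleached,
            "unbleached": series.unbleached,
            "is_prebleach": (series.time < 0).astype(int),
        }
    ).to_csv(path, index=False, float_format="%.12g")


def read_frap(path, normalized: bool = False) -> FRAPSeries:
    df = pd.read_csv(path)
    for col in ("time_s", "bleached", "unbleached"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing column {col!r}")
    return FRAPSeries(
        time=df["time_s"].to_numpy(),
        bleached=df["bleached"].to_numpy(),
        unbleached=df["unbleached"].to_numpy(),
        normalized=normalized,
    )


def read_standards(path) -> pd.DataFrame:
    """SEC standards CSV with columns name, mw_kda, ev_ml."""
    df = pd.read_csv(path)
    for col in ("name", "mw_kda", "ev_ml"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing column {col!r}")
    return df


def write_report(path, values: dict) -> None:
    """Flat ``key = value`` text report (repr-stable float formatting)."""
    with open(path, "w") as fh:
        for key, val in values.items():
            if isinstance(val, float):
                fh.write(f"{key} = {val:.10g}\n")
            else:
                fh.write(f"{key} = {val}\n")


def read_config(path) -> dict:
    """Flat key-value config: ``key = value`` lines, ``#`` comments.

    Values parse as int, then float, then comma-separated lists of numbers,
    falling back to strings.
    """
    out = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ParseError(f"{path}:{lineno}: expected 'key = value'")
            key, _, val = line.partition("=")
            out[key.strip()] = _parse_value(val.strip())
    return out


def _parse_value(text: str):
    if "," in text:
        return [_parse_value(t.strip()) for t in text.split(",") if t.strip()]
    for cast in (int, float):
        try:
            return cast(text)
        except ValueError:
            continue
    if text.lower() in ("true", "false"):
        return text.lower() == "true"
    return text
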