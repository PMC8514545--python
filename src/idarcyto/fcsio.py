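"""Minimal FCS 3.1 reader/writer plus cohort metadata CSV adapters.

Events are stored as list-mode 32-bit little-endian floats with linear
($PnE 0,0) scaling — sufficient for round-tripping the synthetic samples
this package produces and for ingesting comparable exports.  Channel
short names ($PnN) are mapped onto panel markers through an explicit
``channel_map`` when instrument names differ.
"""

from __future__ import annotations

import struct
from pathlib import Path

import numpy as np
import pandas as pd

from .panel import ALL_CHANNELS

_DELIM = "/"


def write_fcs(path, events: pd.DataFrame) -> None:
    """Write one event table as an FCS 3.1 file (float32, list mode)."""
    channels = list(events.columns)
    data = events.to_numpy(dtype="<f4")
    n_tot, n_par = data.shape
    databytes = data.tobytes()

    def build_text(begin_data: int, end_data: int) -> bytes:
        kw = {
            "$BEGINANALYSIS": "0", "$ENDANALYSIS": "0",
            "$BEGINSTEXT": "0", "$ENDSTEXT": "0",
            "$BEGINDATA": f"{begin_data:010d}", "$ENDDATA": f"{end_data:010d}",
            "$BYTEORD": "1,2,3,4", "$DATATYPE": "F", "$MODE": "L",
            "$NEXTDATA": "0", "$TOT": str(n_tot), "$PAR": str(n_par),
        }
        for i, ch in enumerate(channels, start=1):
            kw[f"$P{i}N"] = ch
            kw[f"$P{i}B"] = "32"
            kw[f"$P{i}E"] = "0,0"
            kw[f"$P{i}R"] = "262144"
        body = _DELIM + _DELIM.join(f"{k}{_DELIM}{v}" for k, v in kw.items()) + _DELIM
        return body.encode("ascii")

    text_start = 64
    # two passes: offsets have fixed width, so the text length is stable
    text = build_text(0, 0)
    data_start = text_start + len(text)
    data_end = data_start + len(databytes) - 1
    text = build_text(data_start, data_end)
    text_end = text_start + len(text) - 1

    header = b"FCS3.1    " + (
        f"{text_start:8d}{text_end:8d}{data_start:8d}{data_end:8d}"
        f"{0:8d}{0:8d}"
    ).encode("ascii")
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(b" " * (text_start - len(header)))
        fh.write(text)
        fh.write(databytes)


def read_fcs(path, channel_map: dict[str, str] | None = None,
             require_panel: bool = True) -> tuple[pd.DataFrame, dict]:
    """Read an FCS 3.0/3.1 file into an event table plus keyword metadata.

    ``channel_map`` renames $PnN short names to panel markers.  With
    ``require_panel`` every panel channel must be present after mapping;
    a missing channel raises a ``ValueError`` naming it.  Unknown
    channels are preserved in the returned table but ignored downstream.
    """
    raw = Path(path).read_bytes()
    if not raw[:6] in (b"FCS3.0", b"FCS3.1"):
        raise ValueError(f"{path}: not an FCS 3.0/3.1 file")
    try:
        text_start = int(raw[10:18])
        text_end = int(raw[18:26])
    except ValueError as err:
        raise ValueError(f"{path}: unparseable FCS header") from err
    text = raw[text_start:text_end + 1].decode("ascii", errors="replace")
    delim = text[0]
    parts = text.strip(delim).split(delim)
    kw = dict(zip(parts[::2], parts[1::2]))

    n_par = int(kw["$PAR"])
    n_tot = int(kw["$TOT"])
    if n_tot == 0:
        raise ValueError(f"{path}: file contains no events; unusable sample")
    if kw.get("$DATATYPE") != "F":
        raise ValueError(f"{path}: only $DATATYPE F is supported")
    endian = "<" if kw.get("$BYTEORD", "1,2,3,4").startswith("1") else ">"
    data_start = int(kw.get("$BEGINDATA") or raw[26:34])
    n_vals = n_par * n_tot
    vals = np.frombuffer(raw, dtype=f"{endian}f4", count=n_vals, offset=data_start)
    data = vals.reshape(n_tot, n_par).astype(float)

    names = [kw.get(f"$P{i}N", f"P{i}") for i in range(1, n_par + 1)]
    if channel_map:
        names = [channel_map.get(n, n) for n in names]
    events = pd.DataFrame(data, columns=names)
    if require_panel:
        for ch in ALL_CHANNELS:
            if ch not in events.columns:
                raise ValueError(f"{path}: required panel channel {ch} is missing")
    return events, kw


# ---------------------------------------------------------------------------
# Cohort directory layout: one FCS per sample + metadata.csv
# ---------------------------------------------------------------------------

METADATA_COLUMNS = ["subject_id", "condition", "time_h", "wbc_per_ul", "label", "fcs_file", "seed"]


def write_cohort_dir(samples, outdir, seed: int | None = None) -> Path:
    """Write every sample as FCS plus a cohort metadata CSV; returns outdir."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, s in enumerate(samples):
        fname = f"sample_{i:04d}_{s.subject_id}.fcs"
        write_fcs(outdir / fname, s.events)
        rows.append({
            "subject_id": s.subject_id, "condition": s.condition,
            "time_h": s.sampling_time, "wbc_per_ul": s.wbc,
            "label": s.label, "fcs_file": fname, "seed": seed,
        })
    pd.DataFrame(rows, columns=METADATA_COLUMNS).to_csv(outdir / "metadata.csv", index=False)
    return outdir


def read_cohort_dir(indir, channel_map: dict[str, str] | None = None):
    """Yield `(metadata_row, events)` pairs from a cohort directory."""
    indir = Path(indir)
    meta = pd.read_csv(indir / "metadata.csv")
    for _, row in meta.iterrows():
        events, _ = read_fcs(indir / row["fcs_file"], channel_map=channel_map)
        yield row, events
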