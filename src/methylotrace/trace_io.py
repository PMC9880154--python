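"""Sanger chromatogram IO and base calling.

A chromatogram is the four-channel (A, C, G, T) fluorescence intensity
record of a capillary sequencing run, plus the scan index of each called
base's peak. Two on-disk dialects are supported:

* the standard binary ABIF (``.ab1``) container written by Applied
  Biosystems instruments, read through Biopython's ``abi`` parser; a
  minimal ABIF writer is included so traces can be round-tripped and
  synthetic fixtures materialised in the instrument format;
* a plain-text TSV dialect (columns ``scan_index, A, C, G, T, is_peak``)
  that is lossless and diff-able.

Base calling here is deliberately simple and re-derivable: at each peak
the primary call is the strongest channel and the secondary call is the
second-strongest channel when it reaches a fraction of the primary
amplitude. For pooled bisulfite PCR product the downstream methylation
estimator consumes the raw per-base channel amplitudes, not the letters.
"""

from __future__ import annotations

import io
import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

CHANNEL_ORDER = "ACGT"
#: default secondary-call threshold: fraction of the primary amplitude a
#: second channel must reach to be reported as a mixed (secondary) base
SECONDARY_THRESHOLD = 0.33


class TraceFormatError(ValueError):
    """Raised when a trace file is malformed or truncated."""


@dataclass
class Chromatogram:
    """Four-channel trace with peak locations for the called bases.

    channels is an (n_scans, 4) float array in A, C, G, T column order;
    peak_locations are strictly increasing scan indices, one per base.
    """

    channels: np.ndarray
    peak_locations: np.ndarray
    sample_id: str = ""
    source_format: str = "memory"

    def __post_init__(self) -> None:
        self.channels = np.asarray(self.channels, dtype=float)
        self.peak_locations = np.asarray(self.peak_locations, dtype=int)
        if self.channels.ndim != 2 or self.channels.shape[1] != 4:
            raise TraceFormatError("channels must be an (n_scans, 4) array")
        if np.any(self.channels < 0):
            raise TraceFormatError("channel intensities must be non-negative")
        if self.peak_locations.size:
            if np.any(np.diff(self.peak_locations) <= 0):
                raise TraceFormatError("peak locations must be strictly increasing")
            if self.peak_locations[0] < 0 or self.peak_locations[-1] >= len(self.channels):
                raise TraceFormatError("peak location outside the scanned range")

    @property
    def n_scans(self) -> int:
        return self.channels.shape[0]

    @property
    def n_bases(self) -> int:
        return self.peak_locations.size


@dataclass
class BaseCalls:
    """Primary/secondary calls plus per-base channel amplitudes.

    per_base_intensity is (n_bases, 4) in A, C, G, T order, sampled at
    each peak location. ``flagged`` marks positions where every channel
    was zero (called N).
    """

    primary: str
    secondary: str
    per_base_intensity: np.ndarray
    flagged: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=bool))

    def __len__(self) -> int:
        return len(self.primary)


# ---------------------------------------------------------------------------
# ABIF (.ab1)

_ABIF_MAGIC = b"ABIF"
# instrument filter-wheel order used when writing; readers must consult FWO_1
_FWO = "GATC"


def read_ab1(path: str | Path, sample_id: str | None = None) -> Chromatogram:
    """Read the processed channels and peak locations of an AB1 file.

    Channels come from the standard processed-data tags DATA9–DATA12 in
    the dye order given by FWO_1; peak locations from PLOC2 (or PLOC1).
    """
    path = Path(path)
    with open(path, "rb") as fh:
        if fh.read(4) != _ABIF_MAGIC:
            raise TraceFormatError(f"{path}: not an ABIF file (bad magic)")
    try:
        record = SeqIO.read(str(path), "abi")
    except Exception as exc:  # biopython raises bare ValueError/struct.error
        raise TraceFormatError(f"{path}: unreadable ABIF container: {exc}") from exc
    raw = record.annotations["abif_raw"]
    fwo = raw.get("FWO_1")
    if fwo is None:
        raise TraceFormatError(f"{path}: missing FWO_1 tag")
    fwo = fwo.decode() if isinstance(fwo, bytes) else str(fwo)
    data = {}
    for i, base in enumerate(fwo):
        tag = f"DATA{9 + i}"
        if tag not in raw:
            raise TraceFormatError(f"{path}: missing processed-channel tag {tag}")
        data[base] = np.asarray(raw[tag], dtype=float)
    lengths = {len(v) for v in data.values()}
    if len(lengths) != 1:
        raise TraceFormatError(f"{path}: channel lengths differ: {sorted(lengths)}")
    ploc = raw.get("PLOC2", raw.get("PLOC1"))
    if ploc is None:
        raise TraceFormatError(f"{path}: missing peak-location tag PLOC2/PLOC1")
    channels = np.column_stack([data[b] for b in CHANNEL_ORDER])
    return Chromatogram(
        channels=channels,
        peak_locations=np.asarray(ploc, dtype=int),
        sample_id=sample_id or path.stem,
        source_format="ab1",
    )


def _abif_entry(name: bytes, number: int, etype: int, esize: int,
                nelem: int, data: bytes, offset: int) -> tuple[bytes, bytes]:
    size = len(data)
    if size <= 4:  # small payloads are inlined in the offset field
        inlined = struct.unpack(">i", data.ljust(4, b"\0"))[0]
        return struct.pack(">4sihhiiii", name, number, etype, esize, nelem, size, inlined, 0), b""
    return struct.pack(">4sihhiiii", name, number, etype, esize, nelem, size, offset, 0), data


def write_ab1(chromatogram: Chromatogram, path: str | Path,
              primary: str | None = None) -> None:
    """Write a minimal ABIF container with processed channels + peaks.

    Emits DATA9–12 (dye order GATC), FWO_1, PLOC2, PBAS2 and SMPL1 —
    the subset consumed by :func:`read_ab1` and by standard viewers.
    """
    ch = np.rint(chromatogram.channels).astype(int)
    if ch.size and ch.max() > 32767:
        ch = np.clip(ch, 0, 32767)  # ABIF processed data are int16
    if primary is None:
        primary = call_bases(chromatogram).primary
    tags: list[tuple[bytes, int, int, int, int, bytes]] = []
    for i, base in enumerate(_FWO):
        col = ch[:, CHANNEL_ORDER.index(base)]
        tags.append((b"DATA", 9 + i, 4, 2, len(col), col.astype(">i2").tobytes()))
    tags.append((b"FWO_", 1, 2, 1, 4, _FWO.encode()))
    tags.append((b"PLOC", 2, 4, 2, chromatogram.n_bases,
                 chromatogram.peak_locations.astype(">i2").tobytes()))
    tags.append((b"PBAS", 2, 2, 1, len(primary), primary.encode()))
    sid = chromatogram.sample_id or "trace"
    tags.append((b"SMPL", 1, 18, 1, len(sid) + 1, bytes([len(sid)]) + sid.encode()))

    body = io.BytesIO()
    body.write(b"\0" * 128)  # header block
    entries = []
    for name, number, etype, esize, nelem, payload in tags:
        entry, blob = _abif_entry(name, number, etype, esize, nelem, payload, body.tell())
        entries.append(entry)
        body.write(blob)
    dir_offset = body.tell()
    for entry in entries:
        body.write(entry)
    tdir = struct.pack(">4sihhiiii", b"tdir", 1, 1023, 28, len(entries),
                       28 * len(entries), dir_offset, 0)
    header = (_ABIF_MAGIC + struct.pack(">h", 101) + tdir).ljust(128, b"\0")
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(body.getvalue()[128:])


# ---------------------------------------------------------------------------
# plain-text TSV dialect

_TSV_COLUMNS = ["scan_index", "A", "C", "G", "T", "is_peak"]


def read_trace_tsv(path: str | Path, sample_id: str | None = None) -> Chromatogram:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t")
    except pd.errors.EmptyDataError as exc:
        raise TraceFormatError(f"{path}: empty trace file") from exc
    if list(df.columns) != _TSV_COLUMNS:
        raise TraceFormatError(f"{path}: expected columns {_TSV_COLUMNS}, got {list(df.columns)}")
    if df.empty:
        raise TraceFormatError(f"{path}: no data rows")
    for col in _TSV_COLUMNS:
        if not pd.api.types.is_numeric_dtype(df[col]):
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
            line = int(bad[0]) + 2 if len(bad) else "?"
            raise TraceFormatError(f"{path}: non-numeric value in column {col!r} at line {line}")
    scan = df["scan_index"].to_numpy()
    if np.any(np.diff(scan) <= 0):
        line = int(np.argmax(np.diff(scan) <= 0)) + 3
        raise TraceFormatError(f"{path}: scan_index not strictly increasing at line {line}")
    inten = df[["A", "C", "G", "T"]].to_numpy(dtype=float)
    if np.any(inten < 0):
        row = int(np.argwhere(inten < 0)[0, 0]) + 2
        raise TraceFormatError(f"{path}: negative intensity at line {row}")
    peaks = np.flatnonzero(df["is_peak"].to_numpy() != 0)
    return Chromatogram(channels=inten, peak_locations=peaks,
                        sample_id=sample_id or path.stem, source_format="tsv")


def write_trace_tsv(chromatogram: Chromatogram, path: str | Path) -> None:
    is_peak = np.zeros(chromatogram.n_scans, dtype=int)
    is_peak[chromatogram.peak_locations] = 1
    df = pd.DataFrame({
        "scan_index": np.arange(chromatogram.n_scans),
        "A": chromatogram.channels[:, 0],
        "C": chromatogram.channels[:, 1],
        "G": chromatogram.channels[:, 2],
        "T": chromatogram.channels[:, 3],
        "is_peak": is_peak,
    })
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# base calling


def call_bases(chromatogram: Chromatogram,
               secondary_threshold: float = SECONDARY_THRESHOLD) -> BaseCalls:
    """Call primary/secondary bases at each peak from channel amplitudes.

    Primary = strongest channel; secondary = second-strongest channel if
    its amplitude is at least ``secondary_threshold`` times the primary,
    else the primary base again. Ties break by fixed channel order
    A < C < G < T. All-zero peaks are called N and flagged.
    """
    if not 0 < secondary_threshold <= 1:
        raise ValueError("secondary_threshold must be in (0, 1]")
    amps = chromatogram.channels[chromatogram.peak_locations]
    n = amps.shape[0]
    primary = np.empty(n, dtype="U1")
    secondary = np.empty(n, dtype="U1")
    flagged = np.zeros(n, dtype=bool)
    for i in range(n):
        a = amps[i]
        if not a.any():
            primary[i] = secondary[i] = "N"
            flagged[i] = True
            continue
        order = np.argsort(-a, kind="stable")  # stable keeps A<C<G<T on ties
        primary[i] = CHANNEL_ORDER[order[0]]
        second = order[1]
        if a[second] >= secondary_threshold * a[order[0]]:
            secondary[i] = CHANNEL_ORDER[second]
        else:
            secondary[i] = primary[i]
    return BaseCalls(primary="".join(primary), secondary="".join(secondary),
                     per_base_intensity=amps, flagged=flagged)
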