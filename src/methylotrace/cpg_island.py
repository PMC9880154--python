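"""Sliding-window CpG island detection.

Implements the classical compositional criteria for CpG islands: a
region qualifies when its GC content is at least 50% and its
observed/expected CpG ratio,

    obs/exp = (N_CpG * L) / (N_C * N_G),

is at least 0.6. A 100 bp window slides along the sequence in 1 bp
steps; a maximal run of consecutive passing window starts defines a
candidate spanning from the first start to the last start + window − 1,
and candidates whose spans overlap (runs separated by fewer than
``window`` failing starts) are merged so reported calls are disjoint.
Candidates at least ``minlen`` long are reported. Regions of 100–199 bp
that meet the composition thresholds but fall short of the conventional
200 bp island minimum are classified as CpG *islets*.

A CpG is counted in a window only when both of its bases lie inside the
window. Windows lacking C or G entirely get obs/exp = 0 (they fail the
threshold anyway).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass
class IslandCall:
    """A detected CpG island/islet (1-based inclusive coordinates)."""

    start: int
    end: int
    mean_gc: float       # percent, averaged over the run's windows
    mean_obs_exp: float  # averaged over the run's windows
    n_cpg: int           # CpGs fully inside the span
    klass: str           # "island" (>=200 bp) or "islet" (100..199 bp)

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def window_stats(seq: str, start: int, window: int) -> tuple[float, float]:
    """GC percent and observed/expected CpG of one window.

    ``start`` is 1-based; the window covers start..start+window-1
    inclusive. obs/exp is defined as 0 when the window has no C or no G.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if start < 1 or start + window - 1 > len(seq):
        raise ValueError(f"window [{start}, {start + window - 1}] outside sequence "
                         f"of length {len(seq)}")
    w = seq[start - 1:start + window - 1]
    n_c = w.count("C")
    n_g = w.count("G")
    n_cpg = w.count("CG")
    gc = 100.0 * (n_c + n_g) / window
    oe = (n_cpg * window) / (n_c * n_g) if n_c and n_g else 0.0
    return gc, oe


def _all_window_stats(seq: str, window: int) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised window_stats for every start position (cumulative sums)."""
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    is_c = (arr == ord("C")).astype(int)
    is_g = (arr == ord("G")).astype(int)
    is_cg = np.zeros(len(seq), dtype=int)
    if len(seq) > 1:
        is_cg[:-1] = (arr[:-1] == ord("C")) & (arr[1:] == ord("G"))
    cum_c = np.concatenate([[0], np.cumsum(is_c)])
    cum_g = np.concatenate([[0], np.cumsum(is_g)])
    cum_cg = np.concatenate([[0], np.cumsum(is_cg)])
    n = len(seq) - window + 1
    starts = np.arange(n)
    n_c = cum_c[starts + window] - cum_c[starts]
    n_g = cum_g[starts + window] - cum_g[starts]
    # a CG whose C sits at the last window position straddles the edge
    n_cpg = cum_cg[starts + window - 1] - cum_cg[starts]
    gc = 100.0 * (n_c + n_g) / window
    with np.errstate(divide="ignore", invalid="ignore"):
        oe = np.where((n_c > 0) & (n_g > 0), n_cpg * window / (n_c * n_g), 0.0)
    return gc, oe


def find_cpg_islands(seq: str, window: int = 100, minlen: int = 200,
                     min_oe: float = 0.6, min_gc: float = 50.0) -> list[IslandCall]:
    """Scan ``seq`` for CpG islands/islets.

    Returns non-overlapping calls sorted by start; mean_gc/mean_obs_exp
    are averaged over the passing windows of each run.
    """
    if window > len(seq):
        raise ValueError("window longer than the sequence")
    gc, oe = _all_window_stats(seq, window)
    passing = (gc >= min_gc) & (oe >= min_oe)
    # maximal runs of consecutive passing starts
    runs: list[tuple[int, int]] = []
    i = 0
    n = passing.size
    while i < n:
        if not passing[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and passing[j + 1]:
            j += 1
        runs.append((i, j))
        i = j + 1
    # runs closer than one window length produce overlapping spans;
    # merge them so reported calls are disjoint
    merged: list[list[tuple[int, int]]] = []
    for run in runs:
        if merged and run[0] <= merged[-1][-1][1] + window - 1:
            merged[-1].append(run)
        else:
            merged.append([run])
    calls: list[IslandCall] = []
    for group in merged:
        start = group[0][0] + 1            # 1-based
        end = group[-1][1] + window        # last start + window - 1
        if end - start + 1 < minlen:
            continue
        idx = np.concatenate([np.arange(a, b + 1) for a, b in group])
        span = seq[start - 1:end]
        calls.append(IslandCall(
            start=start, end=end,
            mean_gc=float(gc[idx].mean()),
            mean_obs_exp=float(oe[idx].mean()),
            n_cpg=span.count("CG"),
            klass="island" if end - start + 1 >= 200 else "islet",
        ))
    return calls


def calls_to_frame(calls: list[IslandCall]) -> pd.DataFrame:
    """BED-like table: 0-based half-open plus 1-based inclusive columns."""
    return pd.DataFrame({
        "start0": [c.start - 1 for c in calls],
        "end0": [c.end for c in calls],
        "start_1based": [c.start for c in calls],
        "end_1based": [c.end for c in calls],
        "length": [c.length for c in calls],
        "mean_gc_percent": [round(c.mean_gc, 3) for c in calls],
        "mean_obs_exp": [round(c.mean_obs_exp, 4) for c in calls],
        "n_cpg": [c.n_cpg for c in calls],
        "class": [c.klass for c in calls],
    })


def write_report(calls: list[IslandCall], path: str | Path) -> None:
    lines = [f"{len(calls)} CpG island/islet call(s)"]
    for c in calls:
        lines.append(f"  {c.klass:6s} {c.start}-{c.end} ({c.length} bp), "
                     f"GC {c.mean_gc:.1f}%, obs/exp {c.mean_obs_exp:.2f}, "
                     f"{c.n_cpg} CpGs")
    Path(path).write_text("\n".join(lines) + "\n")
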