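"""Shared test helpers (imported by test modules, not a fixture file)."""

import numpy as np
import pandas as pd


def make_profile_frame(means_by_stage_region, animals=3, sd=0.0, seed=0,
                       sites_per_region=3):
    """Tidy profile frame with known region means (percent scale)."""
    rng = np.random.default_rng(seed)
    rows = []
    stages = sorted({s for s, _ in means_by_stage_region})
    regions = sorted({r for _, r in means_by_stage_region})
    for stage in stages:
        for a in range(1, animals + 1):
            sample = f"{stage}_a{a}"
            for region in regions:
                mean = means_by_stage_region[(stage, region)]
                for k in range(sites_per_region):
                    val = mean + (rng.normal(0, sd) if sd else 0.0)
                    rows.append((sample, stage, f"CpG_r{region}_{k}", region,
                                 float(np.clip(val, 0, 100)), "ok", 50.0, 50.0))
    return pd.DataFrame(rows, columns=["sample", "stage", "cpg_id", "region_id",
                                       "percent", "flag", "i_c", "i_t"])


def overlap_align_score(a: str, b: str, match=2, mismatch=-1, open_=-5, ext=-1):
    """Independent affine-gap DP (Gotoh) with free end gaps; returns score."""
    n, m = len(a), len(b)
    neg = float("-inf")
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[neg] * (m + 1) for _ in range(n + 1)]  # gap in a (consumes b)
    F = [[neg] * (m + 1) for _ in range(n + 1)]  # gap in b (consumes a)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] + open_, E[i][j - 1] + ext)
            F[i][j] = max(H[i - 1][j] + open_, F[i - 1][j] + ext)
            s = match if a[i - 1] == b[j - 1] else mismatch
            H[i][j] = max(H[i - 1][j - 1] + s, E[i][j], F[i][j])
    best = H[n][m]
    for i in range(n + 1):
        best = max(best, H[i][m])
    for j in range(m + 1):
        best = max(best, H[n][j])
    return best


def direct_window_stats(window_seq: str):
    """Independent direct-count oracle for GC% and observed/expected CpG."""
    L = len(window_seq)
    n_c = sum(1 for b in window_seq if b == "C")
    n_g = sum(1 for b in window_seq if b == "G")
    n_cpg = sum(1 for i in range(L - 1) if window_seq[i] == "C"
                and window_seq[i + 1] == "G")
    gc = 100.0 * (n_c + n_g) / L
    oe = (n_cpg * L) / (n_c * n_g) if n_c > 0 and n_g > 0 else 0.0
    return gc, oe


def oracle_mss(counts, site: str, pseudocount=0.8) -> float:
    """Independent reimplementation of the information-weighted match score."""
    import math
    freqs = (counts + pseudocount / 4) / (counts.sum(axis=1, keepdims=True)
                                          + pseudocount)
    info = [sum(f * math.log(4 * f) for f in row if f > 0) for row in freqs]
    cur = sum(info[i] * freqs[i, "ACGT".index(b)] for i, b in enumerate(site))
    lo = sum(info[i] * freqs[i].min() for i in range(len(info)))
    hi = sum(info[i] * freqs[i].max() for i in range(len(info)))
    return 1.0 if hi == lo else (cur - lo) / (hi - lo)
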