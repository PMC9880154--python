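"""PWM scanning with a MATCH-style matrix similarity score.

Position frequency matrices (JASPAR text format) are converted to
frequencies with a total pseudocount of 0.8 split by a uniform
background, and each column gets an information weight

    I(i) = sum_b f(i, b) * ln(4 * f(i, b)),

so conserved columns dominate the score. A candidate site scores

    MSS = (current - min) / (max - min),

where current = sum_i I(i) * f(i, site_i) and min/max are the extreme
achievable information-weighted sums — the classic matrix similarity
score in [0, 1]. A scan with deficit ``d`` accepts sites with
MSS >= 1 - d (the conventional default deficit is 0.15, i.e. a 0.85
score cut-off). Scanning is positive-strand by default, matching
promoter analyses that only consider sites on the sense strand; minus-
strand scanning scores the reverse complement of each window.

Hits are summarised per *factor* (multiple matrix versions and multiple
sites collapse to one factor), cross-referenced against an annotation
table of regulator activity (activator / repressor / both) and
expression (nTPM), and filtered to expressed repressors — the
candidates able to silence the locus when its islet is methylated.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import motifs as bio_motifs

BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


class MotifFormatError(ValueError):
    pass


@dataclass
class PWMModel:
    """A PFM with information weights and score extremes precomputed."""

    matrix_id: str
    factor_name: str
    freqs: np.ndarray         # (length, 4) frequencies, rows sum to 1
    info_weights: np.ndarray  # (length,)
    score_min: float
    score_max: float

    def __len__(self) -> int:
        return self.freqs.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.freqs.argmax(axis=1))


@dataclass
class TFBSHit:
    factor_name: str
    matrix_id: str
    start: int   # 1-based on the scanned sequence
    strand: str  # "+" or "-"
    mss: float
    site: str


def build_pwm(matrix_id: str, factor_name: str, counts: np.ndarray,
              pseudocount: float = 0.8,
              background: tuple[float, float, float, float] = (0.25,) * 4) -> PWMModel:
    """Normalise a count matrix and precompute weights and extremes."""
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2 or counts.shape[1] != 4:
        raise MotifFormatError("counts must be (length, 4)")
    if np.any(counts < 0):
        raise MotifFormatError("negative counts")
    bg = np.asarray(background, dtype=float)
    freqs = (counts + pseudocount * bg) / (counts.sum(axis=1, keepdims=True)
                                           + pseudocount)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(freqs > 0, freqs * np.log(4.0 * freqs), 0.0)
    info = terms.sum(axis=1)
    info = np.clip(info, 0.0, None)  # guard tiny negative rounding
    score_min = float((info * freqs.min(axis=1)).sum())
    score_max = float((info * freqs.max(axis=1)).sum())
    return PWMModel(matrix_id=matrix_id, factor_name=factor_name, freqs=freqs,
                    info_weights=info, score_min=score_min, score_max=score_max)


def read_jaspar(path: str | Path | io.TextIOBase,
                pseudocount: float = 0.8) -> list[PWMModel]:
    """Read a JASPAR-format PFM file into scored PWM models."""
    if isinstance(path, (str, Path)):
        handle = open(path)
        close = True
    else:
        handle, close = path, False
    try:
        try:
            parsed = list(bio_motifs.parse(handle, "jaspar"))
        except Exception as exc:
            raise MotifFormatError(f"malformed JASPAR file: {exc}") from exc
    finally:
        if close:
            handle.close()
    models = []
    for motif in parsed:
        counts = np.column_stack([np.asarray(motif.counts[b], dtype=float)
                                  for b in BASES])
        if counts.shape[0] == 0:
            raise MotifFormatError(f"{motif.matrix_id}: empty matrix")
        models.append(build_pwm(motif.matrix_id or motif.name,
                                motif.name or motif.matrix_id,
                                counts, pseudocount=pseudocount))
    if not models:
        raise MotifFormatError("no matrices found")
    return models


def matrix_similarity_score(pwm: PWMModel, site: str) -> float | None:
    """MSS of one site in [0, 1]; None for sites with N/invalid bases."""
    if len(site) != len(pwm):
        raise ValueError(f"site length {len(site)} != matrix length {len(pwm)}")
    idx = np.empty(len(site), dtype=int)
    for i, b in enumerate(site.upper()):
        j = BASES.find(b)
        if j < 0:
            return None  # ambiguous base: site is skipped
        idx[i] = j
    current = float((pwm.info_weights * pwm.freqs[np.arange(len(site)), idx]).sum())
    if pwm.score_max == pwm.score_min:
        return 1.0  # uninformative matrix: every site is maximal
    return (current - pwm.score_min) / (pwm.score_max - pwm.score_min)


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def scan_sequence(pwms: list[PWMModel], seq: str, deficit: float = 0.15,
                  strands: frozenset[str] | set[str] = frozenset("+")) -> list[TFBSHit]:
    """Score every window x matrix x strand; keep MSS >= 1 - deficit.

    Minus-strand windows are scored on their reverse complement; the
    reported start is always the window's 1-based start on the input
    sequence. Hits are sorted by (start, factor, strand).
    """
    if not 0.0 <= deficit <= 1.0:
        raise ValueError("deficit must be in [0, 1]")
    bad = set(strands) - {"+", "-"}
    if bad:
        raise ValueError(f"unknown strands: {sorted(bad)}")
    if pwms and len(seq) < min(len(p) for p in pwms):
        raise ValueError("sequence shorter than every matrix")
    threshold = 1.0 - deficit
    seq = seq.upper()
    hits = []
    for pwm in pwms:
        L = len(pwm)
        if L > len(seq):
            continue
        for start in range(len(seq) - L + 1):
            window = seq[start:start + L]
            for strand in sorted(strands):
                candidate = window if strand == "+" else reverse_complement(window)
                mss = matrix_similarity_score(pwm, candidate)
                if mss is not None and mss >= threshold:
                    hits.append(TFBSHit(factor_name=pwm.factor_name,
                                        matrix_id=pwm.matrix_id,
                                        start=start + 1, strand=strand,
                                        mss=mss, site=window))
    hits.sort(key=lambda h: (h.start, h.factor_name, h.strand))
    return hits


def hits_to_frame(hits: list[TFBSHit]) -> pd.DataFrame:
    return pd.DataFrame({
        "factor": [h.factor_name for h in hits],
        "matrix_id": [h.matrix_id for h in hits],
        "start_1based": [h.start for h in hits],
        "strand": [h.strand for h in hits],
        "mss": [round(h.mss, 6) for h in hits],
        "site": [h.site for h in hits],
    })


# ---------------------------------------------------------------------------
# regulator classification

ACTIVITIES = ("activator", "repressor", "both")


@dataclass
class RegulatorSummary:
    n_factors: int
    counts_by_activity: dict[str, int]
    expressed_repressors: pd.DataFrame  # factor, activity, ntpm
    unannotated: list[str]


def read_annotation_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"factor", "activity", "ntpm"}
    if not required.issubset(df.columns):
        raise MotifFormatError(f"annotation table needs columns {sorted(required)}")
    if (df["ntpm"] < 0).any():
        raise MotifFormatError("nTPM values must be >= 0")
    return df


def classify_regulators(hits: list[TFBSHit], annotation: pd.DataFrame,
                        min_ntpm: float = 1.0) -> RegulatorSummary:
    """Distinct-factor tally by activity plus expressed-repressor focus list.

    Factors with activity ``repressor`` or ``both`` and nTPM >=
    ``min_ntpm`` form the focus list (candidate silencers of the
    scanned promoter region); hit factors missing from the annotation
    are reported as unannotated.
    """
    factors = sorted({h.factor_name for h in hits})
    ann = annotation.set_index("factor")
    counts = {a: 0 for a in ACTIVITIES}
    unannotated = []
    focus_rows = []
    for f in factors:
        if f not in ann.index:
            unannotated.append(f)
            continue
        activity = str(ann.loc[f, "activity"])
        ntpm = float(ann.loc[f, "ntpm"])
        if activity not in counts:
            raise MotifFormatError(f"unknown activity {activity!r} for {f}")
        counts[activity] += 1
        if activity in ("repressor", "both") and ntpm >= min_ntpm:
            focus_rows.append((f, activity, ntpm))
    focus = pd.DataFrame(focus_rows, columns=["factor", "activity", "ntpm"])
    return RegulatorSummary(n_factors=len(factors) - len(unannotated),
                            counts_by_activity=counts,
                            expressed_repressors=focus,
                            unannotated=unannotated)
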