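"""Per-CpG methylation from direct bisulfite Sanger traces.

In direct (non-clonal) bisulfite sequencing, the PCR product pools many
molecules, so the chromatogram shows a mixed C/T peak at each CpG: the
methylated fraction of molecules retained C while the unmethylated
fraction reads T. The estimator implemented here is the bounded
peak-intensity ratio

    methylation% = 100 * I_C / (I_C + I_T)

at every cytosine of the reference that sits in CpG context, after
aligning the called read to the in-silico bisulfite-converted reference
(every C -> T). Sites with too little combined C+T signal, or not
covered by the alignment, are flagged ``insufficient`` and carry no
percentage — mirroring how low-coverage CpGs are dropped from analysis.

A conversion QC uses the *non*-CpG cytosines, which should be fully
converted: their mean T/(C+T) estimates the bisulfite conversion rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import Align

from .trace_io import BaseCalls

PROFILE_COLUMNS = ["cpg_id", "region_id", "percent", "flag", "i_c", "i_t"]

#: coverage flag values
FLAG_OK = "ok"
FLAG_INSUFFICIENT = "insufficient"


class AlignmentFailure(RuntimeError):
    """Read could not be aligned to the converted reference."""


class InputError(ValueError):
    pass


@dataclass
class CpGSite:
    """One catalogued CpG: the 1-based position of its C."""

    cpg_id: str
    abs_pos: int
    tss_rel: int
    region_id: int | None = None
    islet_member: bool = False


@dataclass
class ReferenceContext:
    """Reference promoter, its converted form, TSS anchor and CpG catalog."""

    reference: str
    tss_abs_pos: int
    cpg_sites: list[CpGSite]
    converted: str = field(init=False)

    def __post_init__(self) -> None:
        self.converted = convert_reference(self.reference)
        for site in self.cpg_sites:
            if self.reference[site.abs_pos - 1:site.abs_pos + 1] != "CG":
                raise InputError(f"{site.cpg_id}: position {site.abs_pos} is not "
                                 "the C of a CG in the reference")
        positions = [s.abs_pos for s in self.cpg_sites]
        if positions != sorted(positions):
            raise InputError("CpG catalog must be ordered 5'->3'")

    @classmethod
    def from_catalog(cls, reference: str, tss_abs_pos: int,
                     catalog: pd.DataFrame) -> "ReferenceContext":
        sites = [CpGSite(cpg_id=row.cpg_id, abs_pos=int(row.abs_pos),
                         tss_rel=int(row.tss_rel),
                         region_id=int(row.region_id) if "region_id" in catalog.columns
                         and not pd.isna(row.region_id) else None)
                 for row in catalog.itertuples()]
        return cls(reference=reference, tss_abs_pos=tss_abs_pos, cpg_sites=sites)

    @property
    def catalog_positions(self) -> np.ndarray:
        return np.array([s.abs_pos for s in self.cpg_sites])


@dataclass
class MethylationProfile:
    """Per-sample methylation percentages at the catalogued CpGs."""

    sample_id: str
    stage: str
    sites: pd.DataFrame  # PROFILE_COLUMNS

    def __post_init__(self) -> None:
        missing_pct = self.sites["percent"].isna()
        ok = self.sites["flag"] == FLAG_OK
        if (ok & missing_pct).any() or (~ok & ~missing_pct).any():
            raise InputError("percent must be present exactly when flag == 'ok'")
        valid = self.sites.loc[~missing_pct, "percent"]
        if ((valid < 0) | (valid > 100)).any():
            raise InputError("methylation percent outside [0, 100]")


def convert_reference(reference: str) -> str:
    """In-silico bisulfite conversion of the reference: every C -> T."""
    allowed = set("ACGTN")
    bad = set(reference) - allowed
    if bad:
        raise InputError(f"invalid characters in reference: {sorted(bad)}")
    return reference.replace("C", "T")


# ---------------------------------------------------------------------------
# alignment

@dataclass
class CoordinateMap:
    """Monotone read-index -> reference-index map (both 0-based)."""

    read_to_ref: dict[int, int]
    identity: float
    score: float

    @property
    def ref_to_read(self) -> dict[int, int]:
        return {r: q for q, r in self.read_to_ref.items()}


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2
    aligner.mismatch_score = -1
    aligner.open_gap_score = -5
    aligner.extend_gap_score = -1
    # free end gaps: the read may cover only part of the reference
    # (the study's two PCR amplicons) and vice versa
    aligner.open_end_insertion_score = 0
    aligner.extend_end_insertion_score = 0
    aligner.open_end_deletion_score = 0
    aligner.extend_end_deletion_score = 0
    return aligner


_ALIGNER = _make_aligner()


def align_read(primary: str, reference_ctx: ReferenceContext,
               min_identity: float = 0.8, min_length: int = 50) -> CoordinateMap:
    """Globally align the primary read to the converted reference.

    Affine-gap global alignment (match +2 / mismatch −1 / open −5 /
    extend −1, end gaps free). Identity is computed over aligned
    columns; below ``min_identity`` the sample fails with
    :class:`AlignmentFailure`.
    """
    if len(primary) < min_length:
        raise InputError(f"read shorter than {min_length} bases")
    read = primary.upper()
    converted = reference_ctx.converted
    alignment = _ALIGNER.align(read, converted)[0]
    read_blocks, ref_blocks = alignment.aligned
    mapping: dict[int, int] = {}
    matches = 0
    aligned_cols = 0
    for (q0, q1), (r0, r1) in zip(read_blocks, ref_blocks):
        for off in range(q1 - q0):
            q, r = q0 + off, r0 + off
            mapping[q] = r
            aligned_cols += 1
            if read[q] == converted[r]:
                matches += 1
            # a methylated CpG keeps its C against the converted T:
            # count it as a match so heavy methylation is not penalised
            elif read[q] == "C" and reference_ctx.reference[r] == "C":
                matches += 1
    identity = matches / aligned_cols if aligned_cols else 0.0
    if identity < min_identity:
        raise AlignmentFailure(
            f"alignment identity {identity:.3f} below {min_identity}")
    return CoordinateMap(read_to_ref=mapping, identity=identity,
                         score=float(alignment.score))


# ---------------------------------------------------------------------------
# methylation calling

def default_min_total_intensity(calls: BaseCalls) -> float:
    """10% of the read's median per-base total (all-channel) amplitude."""
    totals = calls.per_base_intensity.sum(axis=1)
    return 0.1 * float(np.median(totals)) if totals.size else 0.0


def call_methylation(calls: BaseCalls, coord_map: CoordinateMap,
                     reference_ctx: ReferenceContext,
                     min_total_intensity: float | None = None,
                     sample_id: str = "", stage: str = "") -> MethylationProfile:
    """C/(C+T) peak-intensity methylation at every catalogued CpG.

    Sites not covered by the alignment, or whose combined C+T amplitude
    falls below ``min_total_intensity`` (default: 10% of the read's
    median per-base total amplitude), are flagged insufficient.
    """
    if not coord_map.read_to_ref:
        raise InputError("empty coordinate map")
    covered = set(coord_map.read_to_ref.values())
    if not covered & {s.abs_pos - 1 for s in reference_ctx.cpg_sites}:
        raise InputError("coordinate map covers no catalogued CpG site")
    if min_total_intensity is None:
        min_total_intensity = default_min_total_intensity(calls)
    ref_to_read = coord_map.ref_to_read
    rows = []
    for site in reference_ctx.cpg_sites:
        ref_idx = site.abs_pos - 1
        read_idx = ref_to_read.get(ref_idx)
        if read_idx is None:
            rows.append((site.cpg_id, site.region_id, np.nan, FLAG_INSUFFICIENT,
                         np.nan, np.nan))
            continue
        i_c = float(calls.per_base_intensity[read_idx, 1])
        i_t = float(calls.per_base_intensity[read_idx, 3])
        if i_c + i_t < min_total_intensity or i_c + i_t == 0:
            rows.append((site.cpg_id, site.region_id, np.nan, FLAG_INSUFFICIENT,
                         i_c, i_t))
        else:
            rows.append((site.cpg_id, site.region_id, 100.0 * i_c / (i_c + i_t),
                         FLAG_OK, i_c, i_t))
    sites = pd.DataFrame(rows, columns=PROFILE_COLUMNS)
    return MethylationProfile(sample_id=sample_id, stage=stage, sites=sites)


# ---------------------------------------------------------------------------
# conversion QC

@dataclass
class ConversionQC:
    n_sites: int
    rate: float | None
    status: str  # "pass" | "warn" | "not-evaluable"


def conversion_qc(calls: BaseCalls, coord_map: CoordinateMap,
                  reference_ctx: ReferenceContext,
                  warn_below: float = 0.95, min_sites: int = 5) -> ConversionQC:
    """Estimate bisulfite conversion from non-CpG reference cytosines.

    Fully converted libraries read T at these positions, so the mean
    T/(C+T) should approach 1; a rate below ``warn_below`` warns of
    incomplete conversion (which inflates apparent methylation).
    """
    catalog = {s.abs_pos - 1 for s in reference_ctx.cpg_sites}
    ref_to_read = coord_map.ref_to_read
    ratios = []
    for ref_idx, base in enumerate(reference_ctx.reference):
        if base != "C" or ref_idx in catalog:
            continue
        read_idx = ref_to_read.get(ref_idx)
        if read_idx is None:
            continue
        i_c = calls.per_base_intensity[read_idx, 1]
        i_t = calls.per_base_intensity[read_idx, 3]
        if i_c + i_t > 0:
            ratios.append(i_t / (i_c + i_t))
    if len(ratios) < min_sites:
        return ConversionQC(n_sites=len(ratios), rate=None, status="not-evaluable")
    rate = float(np.mean(ratios))
    return ConversionQC(n_sites=len(ratios), rate=rate,
                        status="pass" if rate >= warn_below else "warn")


# ---------------------------------------------------------------------------
# amplicon merging

def merge_amplicons(profiles: list[MethylationProfile]) -> MethylationProfile:
    """Merge per-amplicon profiles of one sample into one profile.

    A site covered by a single amplicon is taken as-is; a site covered
    by several averages the ok percents (an ok value beats an
    insufficient one; all-insufficient stays insufficient).
    """
    if not profiles:
        raise InputError("no profiles to merge")
    sample_ids = {p.sample_id for p in profiles}
    if len(sample_ids) != 1:
        raise InputError(f"profiles from different samples: {sorted(sample_ids)}")
    stages = {p.stage for p in profiles}
    if len(stages) != 1:
        raise InputError(f"conflicting stage labels: {sorted(stages)}")
    combined = pd.concat([p.sites for p in profiles], ignore_index=True)
    rows = []
    for cpg_id, grp in combined.groupby("cpg_id", sort=False):
        ok = grp[grp["flag"] == FLAG_OK]
        region = grp["region_id"].iloc[0]
        if len(ok):
            rows.append((cpg_id, region, float(ok["percent"].mean()), FLAG_OK,
                         float(ok["i_c"].mean()), float(ok["i_t"].mean())))
        else:
            rows.append((cpg_id, region, np.nan, FLAG_INSUFFICIENT,
                         np.nan, np.nan))
    sites = pd.DataFrame(rows, columns=PROFILE_COLUMNS)
    # keep catalog order of first occurrence
    return MethylationProfile(sample_id=profiles[0].sample_id,
                              stage=profiles[0].stage, sites=sites)


# ---------------------------------------------------------------------------
# tidy IO

def profiles_to_frame(profiles: list[MethylationProfile]) -> pd.DataFrame:
    frames = []
    for p in profiles:
        df = p.sites.copy()
        df.insert(0, "stage", p.stage)
        df.insert(0, "sample", p.sample_id)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def write_profiles_tsv(profiles: list[MethylationProfile], path) -> None:
    profiles_to_frame(profiles).to_csv(path, sep="\t", index=False, float_format="%.4f")


def read_profiles_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
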