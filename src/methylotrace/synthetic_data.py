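"""Synthetic promoter cohorts with known methylation ground truth.

This module emulates a direct bisulfite Sanger study of a ~1 kb mouse
promoter across three postnatal stages (PND14 / PND35 / PND56, i.e.
pre-pubertal, pubertal and post-pubertal): it generates

* a promoter sequence with a planted high-CpG "islet" (a short CpG
  island, GC ≥ 50% and observed/expected CpG ≥ 0.6 but under 200 bp) on
  a CpG-poor background, together with the catalogue of all CpG sites;
* per-animal true methylation fractions around stage × region means;
* pools of bisulfite-converted molecules (methylated CpG cytosines are
  protected and stay C, unmethylated cytosines deaminate to T with the
  kit's conversion efficiency);
* four-channel chromatograms whose C/T peak mixture at each CpG encodes
  the pooled methylation fraction; and
* qPCR Ct tables for a target and a housekeeping reference gene whose
  ΔΔCt recovers a chosen relative-expression profile.

Every generator is a pure function of its parameters and seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .trace_io import CHANNEL_ORDER, Chromatogram

STAGES = ("PND14", "PND35", "PND56")

#: default stage × region true mean methylation fractions. Region 2
#: (which contains the islet) carries the planted pubertal effect:
#: +5 pp at PND35 and +6 pp at PND56 on a 42% pre-pubertal base; the
#: other regions sit flat in the 48–69% band.
DEFAULT_REGION_MEANS: dict[tuple[str, int], float] = {}
for _stage, _r2 in zip(STAGES, (0.42, 0.47, 0.48)):
    DEFAULT_REGION_MEANS[(_stage, 1)] = 0.65
    DEFAULT_REGION_MEANS[(_stage, 2)] = _r2
    DEFAULT_REGION_MEANS[(_stage, 3)] = 0.48
    DEFAULT_REGION_MEANS[(_stage, 4)] = 0.67
    DEFAULT_REGION_MEANS[(_stage, 5)] = 0.69

#: ~70% expression drop at puberty, sustained post-puberty
DEFAULT_EXPRESSION_FOLD = {"PND14": 1.0, "PND35": 0.3, "PND56": 0.3}


class ParameterError(ValueError):
    """Raised for infeasible or contradictory generator parameters."""


@dataclass
class CohortDesign:
    """Study design: stages, cohort size and ground-truth effect sizes."""

    stages: tuple[str, ...] = STAGES
    animals_per_stage: int = 3
    region_means: dict[tuple[str, int], float] = field(
        default_factory=lambda: dict(DEFAULT_REGION_MEANS))
    animal_sd: float = 0.05
    expression_fold: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_EXPRESSION_FOLD))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.animals_per_stage < 1:
            raise ParameterError("animals_per_stage must be >= 1")
        for key, m in self.region_means.items():
            if not 0.0 <= m <= 1.0:
                raise ParameterError(f"region mean {key} = {m} outside [0, 1]")
        calibrator = self.stages[0]
        if not math.isclose(self.expression_fold.get(calibrator, 1.0), 1.0):
            raise ParameterError(
                f"expression_fold of calibrator stage {calibrator} must be 1.0")
        if self.animal_sd < 0:
            raise ParameterError("animal_sd must be >= 0")

    @property
    def sample_ids(self) -> list[tuple[str, str]]:
        """[(stage, sample_id), ...] in stage-major order."""
        return [(s, f"{s}_a{i + 1}")
                for s in self.stages for i in range(self.animals_per_stage)]


@dataclass
class MoleculePool:
    """A pool of bisulfite-converted molecules from one genomic sample.

    The pool is stored as a dense (n_molecules, L) base-code matrix;
    ``variants`` deduplicates it into (sequence, count) pairs on demand.
    """

    matrix: np.ndarray  # uint8 codes indexing into CHANNEL_ORDER
    source_reference: str
    true_methylation: dict[int, float]  # 1-based C position -> fraction
    conversion_rate: float

    @property
    def n_molecules(self) -> int:
        return self.matrix.shape[0]

    @property
    def variants(self) -> list[tuple[str, int]]:
        rows, counts = np.unique(self.matrix, axis=0, return_counts=True)
        out = []
        for row, cnt in zip(rows, counts):
            out.append(("".join(CHANNEL_ORDER[c] for c in row), int(cnt)))
        return out

    def base_frequencies(self) -> np.ndarray:
        """(L, 4) per-position base frequencies in A, C, G, T order."""
        n, L = self.matrix.shape
        freq = np.empty((L, 4))
        for b in range(4):
            freq[:, b] = (self.matrix == b).sum(axis=0)
        return freq / n


_CODE = {b: i for i, b in enumerate(CHANNEL_ORDER)}


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype=np.uint8).copy().view(np.uint8)


def _seq_to_codes(seq: str) -> np.ndarray:
    lut = np.zeros(128, dtype=np.uint8)
    for b, i in _CODE.items():
        lut[ord(b)] = i
    return lut[_encode(seq)]


def _codes_to_seq(codes: np.ndarray) -> str:
    return "".join(CHANNEL_ORDER[c] for c in codes)


# ---------------------------------------------------------------------------
# coordinates

def tss_relative(abs_pos: int, tss_abs_pos: int) -> int:
    """1-based absolute position -> TSS-relative coordinate (no zero).

    +1 is the first transcribed base (= tss_abs_pos); -1 is immediately
    upstream of it.
    """
    return abs_pos - tss_abs_pos + 1 if abs_pos >= tss_abs_pos else abs_pos - tss_abs_pos


def tss_absolute(rel_pos: int, tss_abs_pos: int) -> int:
    if rel_pos == 0:
        raise ParameterError("TSS-relative coordinates have no position 0")
    return tss_abs_pos + rel_pos - 1 if rel_pos > 0 else tss_abs_pos + rel_pos


# ---------------------------------------------------------------------------
# promoter sequence with a planted CpG islet

def make_promoter_sequence(total_len: int = 1080,
                           islet_span: tuple[int, int] = (-200, -81),
                           islet_gc: float = 0.55,
                           islet_oe: float = 0.75,
                           background_cpg_per_100bp: float = 2.6,
                           seed: int = 0,
                           tss_abs_pos: int = 842,
                           planted_site: str | None = "GTAGGCA") -> tuple[str, pd.DataFrame]:
    """Generate a promoter with a planted CpG islet; return (seq, catalog).

    The background is CpG-free by construction and AT-rich (~30% GC, as
    in the real locus's primer-friendly promoter context), with isolated
    CG dinucleotides planted at ``background_cpg_per_100bp``; the islet
    span (TSS-relative, inclusive) is filled to hit ``islet_gc`` GC
    content and at least ``islet_oe`` observed/expected CpG (the
    defaults realise 7 islet CpGs in ~120 bp). ``planted_site``, if
    given, embeds that exact subsequence in the islet as ground truth
    for binding-site scans (it must not contain CG). The catalog lists
    every CG in the final sequence (1-based position of the C), numbered
    CpG1.. in 5'->3' order.

    The construction is verified and, under an unlucky draw, rebuilt
    deterministically: the returned sequence always contains exactly one
    composition-passing islet overlapping ``islet_span`` (found at
    minlen=100, absent at minlen=200) and every 100 bp window inside the
    span passes both thresholds.
    """
    if islet_gc < 0.5:
        raise ParameterError("islet_gc must be >= 0.5 to satisfy the island criteria")
    if not 0.6 <= islet_oe:
        raise ParameterError("islet_oe must be >= 0.6 to satisfy the island criteria")
    if islet_gc > 0.95:
        raise ParameterError("islet_gc > 0.95 leaves no room for a valid islet")
    a0, a1 = (tss_absolute(islet_span[0], tss_abs_pos),
              tss_absolute(islet_span[1], tss_abs_pos))
    if not (1 <= a0 < a1 <= total_len):
        raise ParameterError(f"islet span {islet_span} outside the sequence")
    islet_len = a1 - a0 + 1
    if total_len < islet_len:
        raise ParameterError("total_len shorter than the islet span")

    n_gc = round(islet_gc * islet_len)
    n_c = n_gc // 2
    n_g = n_gc - n_c
    n_cpg = math.ceil(islet_oe * n_c * n_g / islet_len)
    if n_cpg > min(n_c, n_g) or 2 * n_cpg > islet_len:
        raise ParameterError(
            f"islet_oe={islet_oe} infeasible at islet_gc={islet_gc}: "
            f"needs {n_cpg} CpGs in {islet_len} bp")
    if planted_site:
        if "CG" in planted_site or set(planted_site) - set("ACGT"):
            raise ParameterError("planted_site must be CG-free DNA")
        site_c = planted_site.count("C")
        site_g = planted_site.count("G")
        if (site_c > n_c - n_cpg or site_g > n_g - n_cpg
                or len(planted_site) > islet_len - 2 * n_cpg):
            raise ParameterError("planted_site does not fit the islet composition")

    rng = np.random.default_rng(seed)
    from .cpg_island import find_cpg_islands, window_stats  # no cycle at import time

    for _attempt in range(50):
        seq = _build_sequence(rng, total_len, a0, a1, islet_len,
                              n_c, n_g, n_cpg, background_cpg_per_100bp,
                              planted_site)
        if (_islet_windows_pass(seq, a0, a1, window_stats)
                and _planted_islet_recovered(seq, a0, a1, find_cpg_islands)):
            break
    else:  # pragma: no cover - defaults converge within a few attempts
        raise ParameterError("could not realise an islet meeting both thresholds")

    positions = [i + 1 for i in range(total_len - 1) if seq[i:i + 2] == "CG"]
    catalog = pd.DataFrame({
        "cpg_id": [f"CpG{k + 1}" for k in range(len(positions))],
        "abs_pos": positions,
        "tss_rel": [tss_relative(p, tss_abs_pos) for p in positions],
    })
    return seq, catalog


def _build_sequence(rng, total_len, a0, a1, islet_len, n_c, n_g, n_cpg,
                    background_cpg_per_100bp, planted_site=None) -> str:
    # CpG-free AT-rich background
    probs = np.array([0.35, 0.15, 0.15, 0.35])  # A C G T
    bases = np.array(list("ACGT"))
    seq = list(rng.choice(bases, size=total_len, p=probs))
    for i in range(1, total_len):
        if seq[i - 1] == "C" and seq[i] == "G":
            seq[i] = rng.choice(["A", "T"])

    # islet: CG blocks + (optional planted TFBS site) + leftover
    # C/G/A/T tokens, shuffled
    rest_c = n_c - n_cpg
    rest_g = n_g - n_cpg
    tokens = ["CG"] * n_cpg + ["C"] * rest_c + ["G"] * rest_g
    if planted_site:
        rest_c -= planted_site.count("C")
        rest_g -= planted_site.count("G")
        tokens = (["CG"] * n_cpg + [planted_site]
                  + ["C"] * rest_c + ["G"] * rest_g)
    n_filled = sum(len(t) for t in tokens)
    tokens += list(rng.choice(["A", "T"], size=islet_len - n_filled))
    islet = None
    for _ in range(100):
        islet = _assemble_islet(tokens, rng)
        if islet is not None:
            break
    else:  # pragma: no cover
        raise ParameterError("could not assemble islet without stray CpGs")
    seq[a0 - 1:a1] = list(islet)
    # repair accidental CpGs straddling the islet boundary
    if a0 >= 2 and seq[a0 - 2] == "C" and islet[0] == "G":
        seq[a0 - 2] = "T"
    if a1 < total_len and islet[-1] == "C" and seq[a1] == "G":
        seq[a1] = "A"

    # isolated background CpGs outside the islet
    n_bg = round(background_cpg_per_100bp * (total_len - islet_len) / 100)
    candidates = [p for p in range(total_len - 1)
                  if p + 2 < a0 - 1 or p > a1]  # 0-based, clear of the islet
    rng.shuffle(candidates)
    placed: list[int] = []
    for p in candidates:
        if len(placed) >= n_bg:
            break
        if all(abs(p - q) >= 3 for q in placed):
            seq[p], seq[p + 1] = "C", "G"
            placed.append(p)
    return "".join(seq)


def _assemble_islet(tokens: list[str], rng) -> str | None:
    """Shuffle islet tokens without creating accidental C->G adjacencies.

    Tokens are "CG" blocks, single C/G/A/T fills and at most one planted
    site; only a token ending in C followed by one starting with G would
    mint an uncatalogued CpG, so such collisions are repaired by swapping
    the G-starting token with a later A/T fill. Returns None (caller
    reshuffles) if a collision cannot be repaired.
    """
    rng.shuffle(tokens)
    i = 0
    while i < len(tokens) - 1:
        if tokens[i][-1] == "C" and tokens[i + 1][0] == "G":
            for j in range(i + 2, len(tokens)):
                if tokens[j] in ("A", "T") and tokens[j - 1][-1] != "C":
                    tokens[i + 1], tokens[j] = tokens[j], tokens[i + 1]
                    break
            else:
                return None
        else:
            i += 1
    return "".join(tokens)


def _planted_islet_recovered(seq, a0, a1, find_cpg_islands) -> bool:
    """Exactly one sub-200 bp islet call overlapping the planted span."""
    if find_cpg_islands(seq, window=100, minlen=200):
        return False
    calls = find_cpg_islands(seq, window=100, minlen=100)
    overlapping = [c for c in calls if c.start <= a1 and c.end >= a0]
    return len(overlapping) == 1 and len(calls) == len(overlapping)


def _islet_windows_pass(seq, a0, a1, window_stats, min_gc=50.0, min_oe=0.6) -> bool:
    islet_len = a1 - a0 + 1
    w = min(100, islet_len)
    for start in range(a0, a1 - w + 2):
        gc, oe = window_stats(seq, start, w)
        if gc < min_gc or oe < min_oe:
            return False
    return True


# ---------------------------------------------------------------------------
# per-animal methylomes

def simulate_methylome(catalog: pd.DataFrame, design: CohortDesign,
                       region_map: dict[str, int], seed: int) -> pd.DataFrame:
    """Draw per-animal, per-CpG true methylation fractions.

    Each fraction is an independent Gaussian draw around the animal's
    stage × region mean with sd ``design.animal_sd``, truncated to
    [0, 1]. Returns a tidy frame (stage, sample, cpg_id, region_id,
    true_fraction).
    """
    missing = [c for c in catalog["cpg_id"] if c not in region_map]
    if missing:
        raise ParameterError(f"CpGs without a region assignment: {missing[:5]}")
    for cpg_id in catalog["cpg_id"]:
        for stage in design.stages:
            if (stage, region_map[cpg_id]) not in design.region_means:
                raise ParameterError(
                    f"no region mean for stage={stage}, region={region_map[cpg_id]}")
    rng = np.random.default_rng(seed)
    rows = []
    for stage, sample in design.sample_ids:
        for cpg_id in catalog["cpg_id"]:
            region = region_map[cpg_id]
            mean = design.region_means[(stage, region)]
            frac = float(np.clip(rng.normal(mean, design.animal_sd), 0.0, 1.0)) \
                if design.animal_sd > 0 else mean
            rows.append((stage, sample, cpg_id, region, frac))
    return pd.DataFrame(rows, columns=["stage", "sample", "cpg_id",
                                       "region_id", "true_fraction"])


# ---------------------------------------------------------------------------
# bisulfite conversion of a molecule pool

def bisulfite_convert_pool(reference: str, methylation_map: dict[int, float],
                           n_molecules: int, conversion_rate: float = 0.99,
                           seed: int = 0) -> MoleculePool:
    """Simulate sodium-bisulfite conversion of ``n_molecules`` copies.

    At each CpG cytosine (1-based positions keying ``methylation_map``)
    a molecule is methylated with that site's fraction; methylated Cs
    are protected, unmethylated Cs deaminate to T with probability
    ``conversion_rate``. Every other C converts with the same rate.
    G/A/T are untouched; length is conserved (no indels).
    """
    if n_molecules < 1:
        raise ParameterError("n_molecules must be >= 1")
    if not 0.0 <= conversion_rate <= 1.0:
        raise ParameterError("conversion_rate must be in [0, 1]")
    codes = _seq_to_codes(reference)
    L = codes.size
    c_idx = np.flatnonzero(codes == _CODE["C"])
    for pos in methylation_map:
        if not (1 <= pos <= L) or reference[pos - 1] != "C":
            raise ParameterError(f"methylation_map position {pos} is not a C")
    cpg_idx = np.array(sorted(p - 1 for p in methylation_map), dtype=int)
    noncpg_idx = np.setdiff1d(c_idx, cpg_idx)

    rng = np.random.default_rng(seed)
    mat = np.tile(codes, (n_molecules, 1))
    t_code = _CODE["T"]
    if cpg_idx.size:
        fracs = np.array([methylation_map[p + 1] for p in cpg_idx])
        methylated = rng.random((n_molecules, cpg_idx.size)) < fracs
        converts = rng.random((n_molecules, cpg_idx.size)) < conversion_rate
        to_t = (~methylated) & converts
        sub = mat[:, cpg_idx]
        sub[to_t] = t_code
        mat[:, cpg_idx] = sub
    if noncpg_idx.size:
        converts = rng.random((n_molecules, noncpg_idx.size)) < conversion_rate
        sub = mat[:, noncpg_idx]
        sub[converts] = t_code
        mat[:, noncpg_idx] = sub
    return MoleculePool(matrix=mat, source_reference=reference,
                        true_methylation=dict(methylation_map),
                        conversion_rate=conversion_rate)


# ---------------------------------------------------------------------------
# chromatogram rendering

def render_trace(pool: MoleculePool, peak_spacing: int = 12,
                 peak_sd: float = 2.0, noise_sd: float = 5.0,
                 seed: int = 0, sample_id: str = "synthetic",
                 amplitude: float = 1000.0) -> Chromatogram:
    """Render the pooled molecules as a four-channel chromatogram.

    One Gaussian peak per base position, centred at ``i * peak_spacing +
    peak_spacing // 2``; each channel's amplitude is proportional to the
    frequency of that base among the pooled molecules, so channel
    amplitudes sum to ``amplitude`` at every position before noise.
    Additive Gaussian noise is clipped at zero.
    """
    if peak_spacing <= 0:
        raise ParameterError("peak_spacing must be positive")
    if pool.n_molecules == 0:
        raise ParameterError("empty molecule pool")
    freqs = pool.base_frequencies()  # (L, 4)
    L = freqs.shape[0]
    n_scans = L * peak_spacing
    centers = np.arange(L) * peak_spacing + peak_spacing // 2
    half = max(1, int(math.ceil(4 * peak_sd)))
    offsets = np.arange(-half, half + 1)
    kernel = np.exp(-0.5 * (offsets / peak_sd) ** 2)
    channels = np.zeros((n_scans, 4))
    for i in range(L):
        lo = centers[i] - half
        sl = slice(max(lo, 0), min(centers[i] + half + 1, n_scans))
        ker = kernel[(sl.start - lo):(sl.start - lo) + (sl.stop - sl.start)]
        channels[sl] += amplitude * np.outer(ker, freqs[i])
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        channels = np.clip(channels + rng.normal(0, noise_sd, channels.shape), 0, None)
    return Chromatogram(channels=channels, peak_locations=centers,
                        sample_id=sample_id, source_format="memory")


# ---------------------------------------------------------------------------
# qPCR Ct tables

def simulate_qpcr(design: CohortDesign, replicates: int = 3,
                  ct_noise_sd: float = 0.15, seed: int = 0,
                  target_gene: str = "Mkrn3", reference_gene: str = "Actb",
                  base_ct_reference: float = 20.0,
                  calibrator_dct: float = 5.0) -> pd.DataFrame:
    """Simulate a Ct table (sample, stage, gene, replicate, ct).

    ΔCt (target − reference) per sample equals the calibrator ΔCt minus
    log2 of the stage's relative expression, plus replicate noise; a
    shared per-sample loading shift exercises the housekeeping
    normalisation.
    """
    if replicates < 1:
        raise ParameterError("replicates must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    for stage, sample in design.sample_ids:
        fold = design.expression_fold[stage]
        if fold <= 0:
            raise ParameterError(f"expression_fold for {stage} must be > 0")
        loading = rng.normal(0, 0.3)  # RNA input varies per sample
        ct_ref = base_ct_reference + loading
        ct_tgt = ct_ref + calibrator_dct - math.log2(fold)
        for gene, ct in ((reference_gene, ct_ref), (target_gene, ct_tgt)):
            for rep in range(1, replicates + 1):
                noisy = ct + (rng.normal(0, ct_noise_sd) if ct_noise_sd > 0 else 0.0)
                rows.append((sample, stage, gene, rep, noisy))
    return pd.DataFrame(rows, columns=["sample", "stage", "gene", "replicate", "ct"])


# ---------------------------------------------------------------------------
# default synthetic region partition and file writers

#: contiguous TSS-relative partition mirroring the study's five-region
#: grouping (region 2 contains the islet, region 4 the 5'UTR, region 5
#: the start of the CDS); covers every possible CpG position.
DEFAULT_REGION_SPANS = {
    1: (-841, -260),
    2: (-259, -60),
    3: (-59, -1),
    4: (1, 100),
    5: (101, 239),
}


def assign_regions(catalog: pd.DataFrame,
                   region_spans: dict[int, tuple[int, int]] | None = None) -> pd.DataFrame:
    """Attach region_id (and islet membership) to a CpG catalog by span."""
    spans = region_spans or DEFAULT_REGION_SPANS
    out = catalog.copy()

    def _region(rel: int) -> int:
        for rid, (lo, hi) in spans.items():
            if lo <= rel <= hi:
                return rid
        raise ParameterError(f"TSS-relative position {rel} outside every region span")

    out["region_id"] = [_region(r) for r in out["tss_rel"]]
    return out


def write_fasta(seq: str, path: str | Path, name: str = "promoter") -> None:
    with open(path, "w") as fh:
        fh.write(f">{name}\n")
        for i in range(0, len(seq), 70):
            fh.write(seq[i:i + 70] + "\n")


def write_catalog_tsv(catalog: pd.DataFrame, path: str | Path) -> None:
    cols = {"cpg_id": "cpg_id", "abs_pos": "abs_pos_1based",
            "tss_rel": "tss_rel_pos", "region_id": "region_id"}
    out = catalog.rename(columns=cols)
    out[[c for c in cols.values() if c in out.columns]].to_csv(path, sep="\t", index=False)


def read_catalog_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    return df.rename(columns={"abs_pos_1based": "abs_pos", "tss_rel_pos": "tss_rel"})


# Small synthetic PFM set + regulator annotations so a simulated run can
# exercise the TFBS scan end to end; consensus sites of the first two
# motifs occur by chance or by planting, and activities are invented.
SYNTHETIC_MOTIFS = """\
>SYN0001.1 SynEts1
A [  2  1 90  3  1  2 40 ]
C [  3  2  3  2  1 90 20 ]
G [ 90  2  4 90 95  4 20 ]
T [  5 95  3  5  3  4 20 ]
>SYN0002.1 SynZf2
A [  1 85  2  2 80  3 ]
C [ 90  5  3 90  5  3 ]
G [  4  5 90  4  5  4 ]
T [  5  5  5  4 10 90 ]
>SYN0003.1 SynRep3
A [ 70  5  5 10 ]
C [ 10  5 80 10 ]
G [ 10 85  5 10 ]
T [ 10  5 10 70 ]
"""

SYNTHETIC_ANNOTATION = pd.DataFrame({
    "factor": ["SynEts1", "SynZf2", "SynRep3"],
    "activity": ["activator", "both", "repressor"],
    "ntpm": [12.5, 3.1, 26.7],
})


def write_synthetic_motifs(path: str | Path) -> None:
    Path(path).write_text(SYNTHETIC_MOTIFS)


def write_synthetic_annotation(path: str | Path) -> None:
    SYNTHETIC_ANNOTATION.to_csv(path, sep="\t", index=False)
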