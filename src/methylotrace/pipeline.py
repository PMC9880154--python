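"""End-to-end orchestration: simulate -> call -> islands -> scan -> stats.

A run is described by a single :class:`RunConfig` (YAML-serialisable);
every stage output lands in one run directory, stamped with the config
hash and seed so a run can be replayed bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from . import cpg_island, methylation, stats_expression, synthetic_data, tfbs, trace_io

log = logging.getLogger("methylotrace")


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    mode: str = "simulate"            # "simulate" or "replicate"
    seed: int = 0
    # --- paths (replicate mode; simulate mode fills them in) ---
    reference_fasta: str | None = None
    catalog_tsv: str | None = None
    traces_dir: str | None = None
    motifs_jaspar: str | None = None
    annotation_tsv: str | None = None
    ct_tsv: str | None = None
    # --- simulate parameters ---
    total_len: int = 1080
    tss_abs_pos: int = 842
    islet_span: tuple[int, int] = (-200, -81)
    islet_gc: float = 0.55
    islet_oe: float = 0.75
    background_cpg_per_100bp: float = 2.6
    animals_per_stage: int = 3
    animal_sd: float = 0.05
    n_molecules: int = 2000
    conversion_rate: float = 0.99
    peak_spacing: int = 12
    peak_sd: float = 2.0
    noise_sd: float = 5.0
    amplicons: int = 2
    ct_noise_sd: float = 0.15
    qpcr_replicates: int = 3
    # --- analysis parameters ---
    island_window: int = 100
    island_minlen: int = 100
    island_min_oe: float = 0.6
    island_min_gc: float = 50.0
    tfbs_deficit: float = 0.15
    tfbs_strands: str = "+"
    min_ntpm: float = 1.0
    anova_mode: str = "mixed"
    scan_tfbs: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        if isinstance(cfg.islet_span, list):
            cfg.islet_span = tuple(cfg.islet_span)
        return cfg

    def validate(self) -> None:
        if self.mode not in ("simulate", "replicate"):
            raise ConfigError(f"unknown mode {self.mode!r}")
        if self.mode == "replicate":
            required = {"reference_fasta": self.reference_fasta,
                        "catalog_tsv": self.catalog_tsv,
                        "traces_dir": self.traces_dir}
            for name, value in required.items():
                if value is None:
                    raise ConfigError(f"replicate mode requires {name}")
        if self.scan_tfbs and self.mode == "replicate" and self.motifs_jaspar is None:
            raise ConfigError("TFBS scan enabled but motifs_jaspar not set")
        for name, value in (("reference_fasta", self.reference_fasta),
                            ("catalog_tsv", self.catalog_tsv),
                            ("traces_dir", self.traces_dir),
                            ("motifs_jaspar", self.motifs_jaspar),
                            ("annotation_tsv", self.annotation_tsv),
                            ("ct_tsv", self.ct_tsv)):
            if value is not None and not Path(value).exists():
                raise ConfigError(f"{name} path does not exist: {value}")
        if not 0 <= self.tfbs_deficit <= 1:
            raise ConfigError("tfbs_deficit must be in [0, 1]")
        if self.amplicons not in (1, 2):
            raise ConfigError("amplicons must be 1 or 2")

    def config_hash(self) -> str:
        canon = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _child_seed(seed: int, k: int) -> int:
    return (seed * 1009 + k) % (2 ** 31)


def _read_fasta(path: str | Path) -> str:
    lines = Path(path).read_text().splitlines()
    return "".join(l.strip() for l in lines if l and not l.startswith(">")).upper()


# ---------------------------------------------------------------------------
# stages

def simulate_stage(config: RunConfig, outdir: Path) -> dict:
    """Generate reference, catalog, traces, qPCR table and truth files."""
    seed = config.seed
    seq, catalog = synthetic_data.make_promoter_sequence(
        total_len=config.total_len, islet_span=config.islet_span,
        islet_gc=config.islet_gc, islet_oe=config.islet_oe,
        background_cpg_per_100bp=config.background_cpg_per_100bp,
        seed=_child_seed(seed, 1), tss_abs_pos=config.tss_abs_pos)
    catalog = synthetic_data.assign_regions(catalog)
    design = synthetic_data.CohortDesign(animals_per_stage=config.animals_per_stage,
                                         animal_sd=config.animal_sd, seed=seed)
    region_map = dict(zip(catalog["cpg_id"], catalog["region_id"]))
    truth = synthetic_data.simulate_methylome(catalog, design, region_map,
                                              seed=_child_seed(seed, 2))

    traces_dir = outdir / "traces"
    traces_dir.mkdir(parents=True, exist_ok=True)
    bounds = [(0, config.total_len)]
    if config.amplicons == 2:
        mid = config.total_len // 2
        bounds = [(0, min(mid + 100, config.total_len)),
                  (max(mid - 100, 0), config.total_len)]
    for i, (stage, sample) in enumerate(design.sample_ids):
        sample_truth = truth[truth["sample"] == sample]
        meth_map = {int(p): float(f) for p, f in zip(
            catalog["abs_pos"],
            sample_truth.set_index("cpg_id").loc[catalog["cpg_id"], "true_fraction"])}
        pool = synthetic_data.bisulfite_convert_pool(
            seq, meth_map, n_molecules=config.n_molecules,
            conversion_rate=config.conversion_rate, seed=_child_seed(seed, 10 + i))
        for a, (lo, hi) in enumerate(bounds, start=1):
            sub = synthetic_data.MoleculePool(
                matrix=pool.matrix[:, lo:hi], source_reference=seq[lo:hi],
                true_methylation=pool.true_methylation,
                conversion_rate=pool.conversion_rate)
            chrom = synthetic_data.render_trace(
                sub, peak_spacing=config.peak_spacing, peak_sd=config.peak_sd,
                noise_sd=config.noise_sd, seed=_child_seed(seed, 100 + 10 * i + a),
                sample_id=f"{sample}__amp{a}")
            trace_io.write_trace_tsv(chrom, traces_dir / f"{sample}__amp{a}.tsv")

    ct = synthetic_data.simulate_qpcr(design, replicates=config.qpcr_replicates,
                                      ct_noise_sd=config.ct_noise_sd,
                                      seed=_child_seed(seed, 3))
    synthetic_data.write_fasta(seq, outdir / "reference.fa")
    synthetic_data.write_catalog_tsv(catalog, outdir / "cpg_catalog.tsv")
    truth.to_csv(outdir / "truth_methylome.tsv", sep="\t", index=False)
    ct.to_csv(outdir / "qpcr_ct.tsv", sep="\t", index=False)
    synthetic_data.write_synthetic_motifs(outdir / "motifs.jaspar")
    synthetic_data.write_synthetic_annotation(outdir / "annotation.tsv")
    log.info("simulate: %d CpGs, %d samples, %d trace file(s)",
             len(catalog), len(design.sample_ids),
             len(list(traces_dir.glob("*.tsv"))))
    return {"reference": seq, "catalog": catalog, "design": design,
            "traces_dir": traces_dir, "ct": ct,
            "motifs": outdir / "motifs.jaspar",
            "annotation": outdir / "annotation.tsv"}


def call_stage(reference: str, tss_abs_pos: int, catalog: pd.DataFrame,
               traces_dir: Path, outdir: Path,
               stage_of: dict[str, str] | None = None) -> list[methylation.MethylationProfile]:
    """Base-call, align and quantify every trace; merge per sample."""
    ctx = methylation.ReferenceContext.from_catalog(reference, tss_abs_pos, catalog)
    by_sample: dict[str, list[methylation.MethylationProfile]] = {}
    qc_rows = []
    for path in sorted(traces_dir.glob("*.tsv")):
        chrom = trace_io.read_trace_tsv(path)
        sample = chrom.sample_id.split("__")[0]
        stage = (stage_of or {}).get(sample, sample.split("_")[0])
        calls = trace_io.call_bases(chrom)
        try:
            cmap = methylation.align_read(calls.primary, ctx)
        except methylation.AlignmentFailure as exc:
            log.warning("%s: %s (trace skipped)", path.name, exc)
            qc_rows.append((chrom.sample_id, None, None, "alignment-failed"))
            continue
        profile = methylation.call_methylation(calls, cmap, ctx,
                                               sample_id=sample, stage=stage)
        qc = methylation.conversion_qc(calls, cmap, ctx)
        qc_rows.append((chrom.sample_id, qc.n_sites, qc.rate, qc.status))
        by_sample.setdefault(sample, []).append(profile)
    profiles = [methylation.merge_amplicons(plist) for plist in by_sample.values()]
    methylation.write_profiles_tsv(profiles, outdir / "profiles.tsv")
    pd.DataFrame(qc_rows, columns=["trace", "n_noncpg_c", "conversion_rate",
                                   "status"]).to_csv(outdir / "qc.tsv",
                                                     sep="\t", index=False)
    log.info("call: %d sample profile(s) from %d trace(s)", len(profiles),
             len(qc_rows))
    return profiles


def islands_stage(reference: str, config: RunConfig, outdir: Path) -> list:
    calls = cpg_island.find_cpg_islands(reference, window=config.island_window,
                                        minlen=config.island_minlen,
                                        min_oe=config.island_min_oe,
                                        min_gc=config.island_min_gc)
    cpg_island.calls_to_frame(calls).to_csv(outdir / "islands.tsv",
                                            sep="\t", index=False)
    cpg_island.write_report(calls, outdir / "islands_report.txt")
    log.info("islands: %d call(s) at minlen=%d", len(calls), config.island_minlen)
    return calls


def tfbs_stage(reference: str, island_calls: list, config: RunConfig,
               motifs_path: Path, annotation_path: Path | None,
               outdir: Path) -> dict:
    if island_calls:
        span = (island_calls[0].start, island_calls[0].end)
    else:  # no islet found: scan the whole sequence
        span = (1, len(reference))
    islet_seq = reference[span[0] - 1:span[1]]
    pwms = tfbs.read_jaspar(motifs_path)
    strands = set(config.tfbs_strands.replace("plus", "+").replace("minus", "-"))
    hits = tfbs.scan_sequence(pwms, islet_seq, deficit=config.tfbs_deficit,
                              strands=strands)
    tfbs.hits_to_frame(hits).to_csv(outdir / "tfbs_hits.tsv", sep="\t", index=False)
    summary = None
    if annotation_path is not None:
        annotation = tfbs.read_annotation_tsv(annotation_path)
        summary = tfbs.classify_regulators(hits, annotation, min_ntpm=config.min_ntpm)
        with open(outdir / "regulators.json", "w") as fh:
            json.dump({"scanned_span_1based": list(span),
                       "n_factors": summary.n_factors,
                       "counts_by_activity": summary.counts_by_activity,
                       "expressed_repressors":
                           summary.expressed_repressors.to_dict("records"),
                       "unannotated": summary.unannotated}, fh, indent=2)
    log.info("scan-tfbs: %d hit(s) over span %s", len(hits), span)
    return {"hits": hits, "summary": summary, "span": span}


def stats_stage(profiles: list[methylation.MethylationProfile],
                ct_table: pd.DataFrame | None, config: RunConfig,
                outdir: Path) -> dict:
    frame = methylation.profiles_to_frame(profiles)
    sitewise = stats_expression.sitewise_tests(frame)
    sitewise.to_csv(outdir / "sitewise_tests.tsv", sep="\t", index=False)
    regions = stats_expression.region_anova(frame, mode=config.anova_mode)
    region_json = [{"region_id": r.region_id, "omnibus_p": r.omnibus_p,
                    "omnibus_f": r.omnibus_f, "n_sites": r.n_sites,
                    "note": r.note,
                    "pairwise": r.pairwise.to_dict("records")} for r in regions]
    expression = corr = None
    if ct_table is not None:
        expression = stats_expression.ddct_expression(ct_table)
        expression.per_sample.to_csv(outdir / "expression.tsv", sep="\t",
                                     index=False)
        corr = stats_expression.region_expression_correlation(frame, expression)
        corr.to_csv(outdir / "region_expression_correlation.tsv", sep="\t",
                    index=False)
    with open(outdir / "stats.json", "w") as fh:
        json.dump({
            "region_anova": region_json,
            "anova_mode": config.anova_mode,
            "expression": None if expression is None else {
                "anova_p": expression.anova_p,
                "per_stage": expression.per_stage.to_dict("records"),
                "tukey": expression.tukey.to_dict("records"),
            },
            "correlation": None if corr is None else corr.to_dict("records"),
        }, fh, indent=2)
    log.info("stats: %d region(s), sitewise rows=%d", len(regions), len(sitewise))
    return {"sitewise": sitewise, "regions": regions,
            "expression": expression, "correlation": corr}


# ---------------------------------------------------------------------------

def run_all(config: RunConfig, outdir: str | Path) -> dict:
    """Execute the full pipeline into ``outdir``; return stage results."""
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    results: dict = {}
    stage_name = "init"
    try:
        with open(outdir / "run.json", "w") as fh:
            json.dump({"version": __version__, "seed": config.seed,
                       "config_hash": config.config_hash(),
                       "config": asdict(config)}, fh, indent=2, default=str)
        if config.mode == "simulate":
            stage_name = "simulate"
            sim = simulate_stage(config, outdir)
            reference, catalog = sim["reference"], sim["catalog"]
            traces_dir, ct = sim["traces_dir"], sim["ct"]
            motifs_path, annotation_path = sim["motifs"], sim["annotation"]
            tss = config.tss_abs_pos
        else:
            stage_name = "load"
            reference = _read_fasta(config.reference_fasta)
            catalog = synthetic_data.read_catalog_tsv(config.catalog_tsv)
            traces_dir = Path(config.traces_dir)
            ct = (pd.read_csv(config.ct_tsv, sep="\t")
                  if config.ct_tsv else None)
            motifs_path = Path(config.motifs_jaspar) if config.motifs_jaspar else None
            annotation_path = (Path(config.annotation_tsv)
                               if config.annotation_tsv else None)
            tss = config.tss_abs_pos
        stage_name = "call"
        profiles = call_stage(reference, tss, catalog, traces_dir, outdir)
        results["profiles"] = profiles
        stage_name = "islands"
        island_calls = islands_stage(reference, config, outdir)
        results["islands"] = island_calls
        if config.scan_tfbs and motifs_path is not None:
            stage_name = "scan-tfbs"
            results["tfbs"] = tfbs_stage(reference, island_calls, config,
                                         motifs_path, annotation_path, outdir)
        stage_name = "stats"
        results["stats"] = stats_stage(profiles, ct, config, outdir)
    except Exception as exc:
        log.error("stage %r failed: %s", stage_name, exc)
        raise RuntimeError(f"pipeline stage {stage_name!r} failed: {exc}") from exc
    finally:
        log.removeHandler(handler)
        handler.close()
    return results
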