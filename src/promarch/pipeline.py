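"""Orchestration: simulate -> write standard formats -> analyze -> report.

``run_simulate`` materializes a seeded synthetic study (genome, transcript
models, CAGE track, MNase fragments, depletion counts, ground truth) as
plain-text standard formats; ``run_analyze`` reads those formats back —
never the in-memory truth — and runs the full analysis battery: TSS
correction, PWM classification, initiation metrics, +1 nucleosome calls,
CAGE x MNase cross-correlation, spike-normalized depletion calls, and motif
enrichment of the down-regulated set. Every output table carries the config
hash in a header comment, and a manifest of SHA-256 checksums makes
bit-level reproducibility checkable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import chromatin, classify, depletion, genomic_io, initiation
from . import synthetic, tss_correction
from .pwm import DEFAULT_THRESHOLDS, default_pwms, default_windows

log = logging.getLogger("promarch")

HOUSEKEEPING_CLASSES = ("TCT", "DRE", "Ohler1/6")
DEVELOPMENTAL_CLASSES = ("TATA", "DPE", "INR")


@dataclass
class PipelineConfig:
    """Simulation settings plus every analysis constant, JSON-serializable."""

    sim: synthetic.SimConfig = field(default_factory=synthetic.SimConfig)
    # TSS correction
    w_small: int = 250
    w_large: int = 500
    # classification
    thresholds: dict = field(default_factory=lambda: dict(DEFAULT_THRESHOLDS))
    tpm_min: float = 5.0
    k: int = 9
    kmeans_restarts: int = 10
    # initiation metrics
    profile_flank: int = 120
    activated_rel: float = 0.2
    width_floor: float = 1.0
    # chromatin
    nuc_search: tuple[int, int] = (1, 200)
    fragment_length_range: tuple[int, int] = (100, 200)
    lags: tuple[int, int] = (-50, 200)
    min_fragments: int = 10
    # depletion calls
    fold_threshold: float = 1.5
    alpha: float = 0.05
    min_norm_total: float = 10.0

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        raw = json.loads(text)
        sim_raw = raw.pop("sim", {})
        classes = tuple(
            synthetic.ClassSpec(
                name=c["name"],
                motifs=tuple((m, o) for m, o in c["motifs"]),
                mode=c["mode"], focused_width=c["focused_width"],
                dispersed_width=c["dispersed_width"],
                nuc_offset=c["nuc_offset"], nuc_sd=c["nuc_sd"])
            for c in sim_raw.pop("classes", [])
        ) or synthetic.default_class_specs()
        known = {c.name for c in synthetic.default_class_specs()}
        for c in classes:
            if c.name not in known:
                raise ValueError(f"unknown promoter class {c.name!r}")
        scen_raw = sim_raw.pop("scenario", {})
        scenario = synthetic.DepletionScenario(
            target_classes=tuple(scen_raw.get("target_classes", ())),
            fold_change=scen_raw.get("fold_change", 1.0),
            global_factor=scen_raw.get("global_factor", 1.0),
            affected_fraction=scen_raw.get("affected_fraction", 0.0))
        for key in ("annotation_jitter", "fragment_length_bounds"):
            if key in sim_raw:
                sim_raw[key] = tuple(sim_raw[key])
        sim = synthetic.SimConfig(classes=classes, scenario=scenario, **sim_raw)
        for key in ("nuc_search", "fragment_length_range", "lags"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(sim=sim, **raw)

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_manifest(outdir: Path, paths: list[Path]) -> Path:
    manifest = {p.name: _sha256(p) for p in sorted(paths)}
    mpath = outdir / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return mpath


def _write_table(df: pd.DataFrame, path: Path, config: PipelineConfig,
                 index_label: str | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(f"# promarch config_hash={config.config_hash}\n")
        df.to_csv(fh, sep="\t", index_label=index_label)


# ---------------------------------------------------------------------------
# simulate


def run_simulate(config: PipelineConfig, outdir) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sim = config.sim
    known = {spec.name for spec in sim.classes}
    unknown = set(sim.scenario.target_classes) - known
    if unknown:
        raise ValueError(f"scenario targets unknown classes: {sorted(unknown)}")
    log.info("simulating landscape: %d promoters/class, seed %d",
             sim.n_per_class, sim.seed)
    genome, transcripts, truth = synthetic.simulate_promoter_landscape(sim)
    cage = synthetic.simulate_cage(truth, sim)
    frags = synthetic.simulate_mnase(truth, sim)
    cm, count_truth = synthetic.simulate_depletion_counts(sim, truth)

    paths: dict[str, Path] = {}
    paths["genome"] = outdir / "genome.fa"
    genomic_io.write_fasta(genome, paths["genome"])
    paths["transcripts"] = outdir / "transcripts.bed"
    genomic_io.write_transcripts_bed12(transcripts, paths["transcripts"])
    plus, minus = genomic_io.write_stranded_track(cage, outdir / "cage")
    paths["cage_plus"], paths["cage_minus"] = plus, minus
    paths["fragments"] = outdir / "mnase_fragments.bed"
    genomic_io.write_fragments_bed(frags, paths["fragments"])
    paths["counts"] = outdir / "counts.tsv"
    paths["samples"] = outdir / "samples.tsv"
    cm.write_tsv(paths["counts"], paths["samples"])
    paths["truth_promoters"] = outdir / "truth_promoters.tsv"
    truth.promoters.to_csv(paths["truth_promoters"], sep="\t", index=False)
    paths["truth_genes"] = outdir / "truth_genes.tsv"
    count_truth.genes.to_csv(paths["truth_genes"], sep="\t")
    paths["truth_samples"] = outdir / "truth_samples.tsv"
    count_truth.samples.to_csv(paths["truth_samples"], sep="\t")
    paths["config"] = outdir / "config.json"
    paths["config"].write_text(config.to_json() + "\n")
    paths["manifest"] = _write_manifest(outdir, list(paths.values()))
    return paths


# ---------------------------------------------------------------------------
# analyze


def run_analyze(config: PipelineConfig, indir, outdir) -> dict[str, Path]:
    indir, outdir = Path(indir), Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome = genomic_io.parse_fasta(indir / "genome.fa")
    transcripts = genomic_io.load_transcripts(indir / "transcripts.bed")
    cage = genomic_io.read_stranded_track(indir / "cage")
    frags = genomic_io.read_fragments_bed(indir / "mnase_fragments.bed")
    cm = depletion.CountMatrix.read_tsv(indir / "counts.tsv", indir / "samples.tsv")
    paths: dict[str, Path] = {}

    # 1. TSS correction and per-TSS deduplication
    results = tss_correction.correct_tss(
        transcripts, cage, w_small=config.w_small, w_large=config.w_large)
    corrected = tss_correction.apply_corrections(transcripts, results)
    promoters = tss_correction.collapse_by_tss(corrected)
    res_df = pd.DataFrame([dataclasses.asdict(r) for r in results])
    paths["tss_correction"] = outdir / "tss_correction.tsv"
    _write_table(res_df.set_index("transcript_id"), paths["tss_correction"], config)
    paths["corrected_transcripts"] = outdir / "corrected_transcripts.bed"
    genomic_io.write_transcripts_bed12(promoters, paths["corrected_transcripts"])

    # 2. PWM classification at corrected TSSs
    anchors = [classify.PromoterAnchor(t.gene_id, t.contig, t.tss, t.strand)
               for t in promoters]
    pwms, windows = default_pwms(), default_windows()
    scores = classify.score_promoters(genome, anchors, pwms, windows)
    percent = scores["percent"]
    flags = classify.apply_thresholds(percent, config.thresholds)
    labels = classify.assign_class(flags)
    tpm = classify.cage_tpm(cage, anchors)
    cls_df = percent.add_suffix("_pct")
    cls_df = cls_df.join(flags.add_suffix("_flag")).join(tpm)
    cls_df["active"] = tpm >= config.tpm_min
    cls_df["class_label"] = labels
    paths["classification"] = outdir / "classification.tsv"
    _write_table(cls_df, paths["classification"], config, index_label="gene_id")

    k = min(config.k, len(percent))
    clusters, centers = classify.kmeans_overview(
        percent, k=k, seed=config.sim.seed, restarts=config.kmeans_restarts)
    paths["kmeans"] = outdir / "kmeans_clusters.tsv"
    _write_table(clusters.to_frame(), paths["kmeans"], config, index_label="gene_id")

    # 3. initiation metrics at corrected TSSs
    metrics_rows, dom_abs = [], {}
    for a in anchors:
        prof = initiation.extract_profile(
            cage, a.promoter_id, a.contig, a.tss, a.strand,
            config.profile_flank, config.profile_flank)
        if not prof.active:
            continue
        m = initiation.profile_metrics(prof, config.activated_rel,
                                       config.width_floor)
        metrics_rows.append(dataclasses.asdict(m))
        dom_abs[a.promoter_id] = (
            a.tss + m.dominant_offset if a.strand == "+"
            else a.tss - m.dominant_offset)
    if metrics_rows:
        metrics_df = pd.DataFrame(metrics_rows).set_index("promoter_id")
    else:
        metrics_df = pd.DataFrame()
    paths["initiation_metrics"] = outdir / "initiation_metrics.tsv"
    _write_table(metrics_df, paths["initiation_metrics"], config,
                 index_label="gene_id")

    # 4. +1 nucleosome calls from dominant TSSs
    centers_track = chromatin.fragment_center_track(
        frags, config.fragment_length_range)
    calls = []
    for a in anchors:
        if a.promoter_id not in dom_abs:
            continue
        call = chromatin.plus1_center(
            centers_track, a.promoter_id, a.contig, dom_abs[a.promoter_id],
            a.strand, config.nuc_search, config.fragment_length_range)
        if call is not None:
            calls.append(dataclasses.asdict(call))
    calls_df = (pd.DataFrame(calls).set_index("promoter_id")
                if calls else pd.DataFrame())
    paths["nucleosome_calls"] = outdir / "nucleosome_calls.tsv"
    _write_table(calls_df, paths["nucleosome_calls"], config,
                 index_label="gene_id")

    # 5. CAGE x MNase cross-correlation per promoter group
    xcorr_frames = []
    for group, members in (("housekeeping", HOUSEKEEPING_CLASSES),
                           ("developmental", DEVELOPMENTAL_CLASSES)):
        proms = [(a.promoter_id, a.contig, dom_abs[a.promoter_id], a.strand)
                 for a in anchors
                 if a.promoter_id in dom_abs and labels[a.promoter_id] in members]
        if not proms:
            continue
        curve = chromatin.cage_mnase_crosscorrelation(
            cage, centers_track, proms, config.lags, config.lags,
            config.min_fragments)
        xcorr_frames.append(pd.DataFrame({
            "group": group, "lag": curve.lags, "mean_r": curve.mean_r,
            "sd_r": curve.sd_r, "n": curve.n}))
    paths["crosscorrelation"] = outdir / "crosscorrelation.tsv"
    _write_table(pd.concat(xcorr_frames, ignore_index=True)
                 if xcorr_frames else pd.DataFrame(),
                 paths["crosscorrelation"], config, index_label="row")

    # 6. spike-normalized depletion calls
    factors = depletion.spike_size_factors(
        cm.samples["spike_reads"], cm.samples["reference_reads"])
    de = depletion.call_downregulated(
        cm, factors, config.fold_threshold, config.alpha, config.min_norm_total)
    paths["size_factors"] = outdir / "size_factors.tsv"
    _write_table(factors.to_frame(), paths["size_factors"], config,
                 index_label="sample")
    paths["differential"] = outdir / "differential.tsv"
    _write_table(de, paths["differential"], config, index_label="gene_id")

    # 7. motif enrichment of the down-regulated set among labeled promoters
    expressed = set(flags.index) & set(de.index[de["testable"]])
    down = set(de.index[de["down"]]) & expressed
    if down and expressed:
        enr = depletion.fisher_motif_enrichment(down, expressed, flags)
        enr_df = pd.DataFrame([dataclasses.asdict(e) for e in enr]).set_index("motif")
    else:
        enr_df = pd.DataFrame(
            columns=["a", "b", "c", "d", "odds_ratio", "log2_odds_ratio", "p"])
        enr_df.index.name = "motif"
    paths["enrichment"] = outdir / "enrichment.tsv"
    _write_table(enr_df, paths["enrichment"], config)

    log_path = outdir / "run.log"
    log_path.write_text(
        f"config_hash={config.config_hash}\n"
        f"promoters={len(anchors)} with_signal={len(dom_abs)} "
        f"nucleosome_calls={len(calls)}\n"
        f"genes={len(de)} testable={int(de['testable'].sum())} "
        f"down={int(de['down'].sum())}\n")
    paths["log"] = log_path
    paths["manifest"] = _write_manifest(outdir, list(paths.values()))
    return paths
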