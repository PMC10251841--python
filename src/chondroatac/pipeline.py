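"""End-to-end orchestration of the synthetic ATAC/RNA integration analysis.

``run_pipeline`` executes the stages in order — fragment QC, peak
calling per replicate, replicate consensus, feature annotation,
over-representation analysis, GWAS-SNP permutation enrichment,
motif/footprint analysis and RNA-seq cross-checks — writing every
intermediate to the output directory and emitting a machine-readable
JSON report.  The report contains only seed-determined quantities, so
an identical config and seed reproduces it byte for byte; timings and
progress go to the logger instead.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import annotate as ann
from . import expression as expr
from . import footprint as fp
from . import gwas
from . import intervals as iv
from . import signal_peaks as sp
from . import simulate as sim

__all__ = ["RunConfig", "run_pipeline", "REPORT_SCHEMA_VERSION"]

logger = logging.getLogger(__name__)

REPORT_SCHEMA_VERSION = 1

_REQUIRED_STAGES = (
    "qc",
    "peak_calling",
    "consensus",
    "annotation",
    "ora",
    "gwas_enrichment",
    "motif_footprint",
    "expression",
)


@dataclass
class RunConfig:
    """All tunables of the end-to-end run, with the study defaults."""

    sim: sim.SimulationConfig = field(default_factory=sim.SimulationConfig)
    outdir: str = "chondroatac_run"
    consensus_min_replicates: int = 2
    consensus_threshold: float = 0.5
    promoter_flank: int = 3000
    downstream_flank: int = 3000
    peak_shift: int = -100
    peak_extsize: int = 200
    peak_q_threshold: float = 0.05
    n_perm: int = 10000
    footprint_window: int = 100
    tpm_threshold: float = 2.0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        sim_data = data.pop("sim", {})
        if "fragment_mixture" in sim_data:
            sim_data["fragment_mixture"] = tuple(sim_data["fragment_mixture"])
        return cls(sim=sim.SimulationConfig(**sim_data), **data)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def run_pipeline(config: RunConfig) -> dict:
    """Run the synthetic end-to-end analysis; returns the report dict.

    Every stage writes its intermediates under ``config.outdir`` and
    appends a block to the report.  Any stage failure aborts with a
    RuntimeError naming the stage; files written so far are retained.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "seed": config.sim.seed,
        "stages": {},
    }
    files: dict[str, str] = {}
    state: dict = {}

    stages = [
        ("simulate", _stage_simulate),
        ("qc", _stage_qc),
        ("peak_calling", _stage_peak_calling),
        ("consensus", _stage_consensus),
        ("annotation", _stage_annotation),
        ("ora", _stage_ora),
        ("gwas_enrichment", _stage_gwas),
        ("motif_footprint", _stage_motif_footprint),
        ("expression", _stage_expression),
    ]
    for name, fn in stages:
        t0 = time.perf_counter()
        try:
            block = fn(config, state, outdir, files)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        logger.info("stage %s finished in %.2f s", name, time.perf_counter() - t0)
        if name != "simulate":
            report["stages"][name] = _jsonable(block)

    report["files"] = {k: files[k] for k in sorted(files)}
    report_path = outdir / "report.json"
    _validate_report(report)
    report_path.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    return report


def _validate_report(report: dict) -> None:
    if report.get("schema_version") != REPORT_SCHEMA_VERSION:
        raise ValueError("report schema version mismatch")
    missing = [s for s in _REQUIRED_STAGES if s not in report.get("stages", {})]
    if missing:
        raise ValueError(f"report missing stage blocks: {missing}")


def _register(files: dict, key: str, path: Path) -> None:
    files[key] = _sha256(path)


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _stage_simulate(config: RunConfig, state: dict, outdir: Path, files: dict):
    genome = sim.make_genome(config.sim)
    state["genome"] = genome
    replicate_sets, true_peaks = sim.simulate_replicate_peaks(genome, config.sim)
    state["true_peaks"] = true_peaks
    state["fragments"] = []
    state["cuts"] = []
    for rep in range(config.sim.n_replicates):
        rng = np.random.default_rng([config.sim.seed, 30 + rep])
        frags, cuts = sim.simulate_fragments(genome, true_peaks, config.sim, rng=rng)
        state["fragments"].append(frags)
        state["cuts"].append(cuts)
        path = outdir / f"fragments_rep{rep + 1}.bed"
        sim.write_fragments_bed(frags, path)
        _register(files, path.name, path)
    gene_path = outdir / "genes.tsv"
    ann.write_gene_table(list(genome.genes), gene_path)
    _register(files, gene_path.name, gene_path)
    true_path = outdir / "true_peaks.bed"
    iv.write_bed(true_peaks, true_path)
    _register(files, true_path.name, true_path)
    return {}


def _stage_qc(config: RunConfig, state: dict, outdir: Path, files: dict):
    genome = state["genome"]
    pooled = pd.concat(state["fragments"], ignore_index=True)
    lengths = (pooled["end"] - pooled["start"]).to_numpy()
    # nucleosome-ladder period is a property of nucleosome-spanning
    # fragments; the sub-100 bp nucleosome-free mode is excluded
    periodicity = sp.fragment_periodicity(lengths[lengths >= 100])
    pooled_cuts = pd.concat(state["cuts"], ignore_index=True)
    tss = sp.tss_enrichment(pooled_cuts, genome.genes)
    block = {
        "n_fragments": int(len(pooled)),
        "fragment_classes": sp.fragment_length_summary(lengths),
        "periodicity_bp": periodicity.period,
        "periodic": periodicity.periodic,
        "tss_enrichment": tss,
    }
    state["pooled_cuts"] = pooled_cuts
    return block


def _stage_peak_calling(config: RunConfig, state: dict, outdir: Path, files: dict):
    genome = state["genome"]
    state["called"] = []
    per_rep = []
    for rep, cuts in enumerate(state["cuts"]):
        peaks = sp.call_peaks(
            cuts,
            genome.chrom_lengths,
            shift=config.peak_shift,
            extsize=config.peak_extsize,
            q_threshold=config.peak_q_threshold,
        )
        state["called"].append([p.interval for p in peaks])
        path = outdir / f"peaks_rep{rep + 1}.narrowPeak"
        sp.write_narrowpeak(peaks, path)
        _register(files, path.name, path)
        per_rep.append({"replicate": rep + 1, "n_peaks": len(peaks)})
    # coverage track for the pooled replicates (bedGraph text export)
    pooled = state["pooled_cuts"]
    tracks = sp.pileup_tracks(
        pooled, genome.chrom_lengths, shift=config.peak_shift, extsize=config.peak_extsize
    )
    bg_path = outdir / "coverage.bedGraph"
    sp.export_bedgraph(tracks, bg_path, track_name="pooled_pileup")
    _register(files, bg_path.name, bg_path)
    return {"replicates": per_rep}


def _stage_consensus(config: RunConfig, state: dict, outdir: Path, files: dict):
    genome = state["genome"]
    consensus = iv.consensus_peaks(
        state["called"],
        min_replicates=config.consensus_min_replicates,
        threshold=config.consensus_threshold,
    )
    state["consensus"] = [c.interval for c in consensus]
    path = outdir / "consensus_peaks.bed"
    iv.write_bed([c.interval for c in consensus], path)
    _register(files, path.name, path)
    mean_len = (
        float(np.mean([c.interval.length for c in consensus])) if consensus else 0.0
    )
    frac = iv.genome_fraction(state["consensus"], genome.chrom_lengths)
    # recovery vs ground truth: true peaks overlapped by >=1 consensus peak
    true_peaks = state["true_peaks"]
    recovered = sum(
        1
        for t in true_peaks
        if any(iv.overlap_bp(t, c) > 0 for c in state["consensus"])
    )
    return {
        "n_consensus_peaks": len(consensus),
        "mean_peak_length_bp": mean_len,
        "genome_fraction_pct": 100.0 * frac,
        "true_peak_recall": recovered / len(true_peaks) if true_peaks else 0.0,
    }


def _stage_annotation(config: RunConfig, state: dict, outdir: Path, files: dict):
    genome = state["genome"]
    tracks = ann.feature_tracks(
        genome.genes,
        promoter_flank=config.promoter_flank,
        downstream_flank=config.downstream_flank,
        chrom_lengths=genome.chrom_lengths,
    )
    annotations = ann.annotate_peaks(state["consensus"], tracks, genome.genes)
    state["annotations"] = annotations
    path = outdir / "peak_annotations.tsv"
    ann.write_annotations(annotations, path)
    _register(files, path.name, path)
    summary = ann.annotation_summary(annotations) if annotations else {}
    return {"category_pct": summary, "n_annotated": len(annotations)}


def _stage_ora(config: RunConfig, state: dict, outdir: Path, files: dict):
    genome = state["genome"]
    term_map = sim.simulate_term_map(genome, config.sim)
    universe = [g.gene_id for g in genome.genes]
    # genes with promoter-proximal open chromatin, the set the nearest-gene
    # annotation is built for
    gene_set = sorted(
        {
            a.nearest_gene
            for a in state["annotations"]
            if a.nearest_gene is not None and a.category == "promoter"
        }
    )
    results = ann.ora_test(gene_set, term_map, universe)
    path = outdir / "ora_results.tsv"
    with open(path, "w") as fh:
        fh.write("term_id\tk\tn\tK\tN\tp_value\tadjusted_p\tsignificant\n")
        for r in results:
            fh.write(
                f"{r.term_id}\t{r.k}\t{r.n}\t{r.K}\t{r.N}\t{r.p_value:.6g}"
                f"\t{r.adjusted_p:.6g}\t{r.significant}\n"
            )
    _register(files, path.name, path)
    return {
        "n_genes_tested": len(gene_set),
        "n_terms": len(results),
        "n_significant": sum(r.significant for r in results),
        "top_terms": [
            {"term_id": r.term_id, "p_value": r.p_value, "adjusted_p": r.adjusted_p}
            for r in results[:5]
        ],
    }


def _stage_gwas(config: RunConfig, state: dict, outdir: Path, files: dict):
    genome = state["genome"]
    background, candidates = sim.simulate_snps(genome, state["consensus"], config.sim)
    panel = pd.concat([background, candidates], ignore_index=True)
    result = gwas.permutation_enrichment(
        candidates,
        panel,
        state["consensus"],
        n_perm=config.n_perm,
        seed=config.sim.seed,
    )
    for name, df in (("snps_background.tsv", background), ("snps_candidates.tsv", candidates)):
        path = outdir / name
        gwas.write_snp_table(df, path)
        _register(files, name, path)
    path = outdir / "gwas_enrichment.json"
    path.write_text(json.dumps(_jsonable(result.to_dict()), indent=2, sort_keys=True) + "\n")
    _register(files, path.name, path)
    return result.to_dict()


def _stage_motif_footprint(config: RunConfig, state: dict, outdir: Path, files: dict):
    genome = state["genome"]
    pwms = sim.demo_pwms()
    active_pwm, inactive_pwm = pwms[0], pwms[1]

    targets, backgrounds, _ = sim.simulate_motif_sequences(
        state["consensus"], active_pwm, config.sim
    )
    enrich = fp.motif_enrichment(targets, backgrounds, pwms)
    path = outdir / "motif_enrichment.tsv"
    enrich.to_csv(path, sep="\t", index=False)
    _register(files, path.name, path)

    # footprints: the CCAAT-like TF is simulated bound, the AP-1-like unbound
    calls: dict[str, str] = {}
    profiles = {}
    for pwm, bound_fraction in ((active_pwm, config.sim.bound_motif_fraction), (inactive_pwm, 0.0)):
        cfg = dataclasses.replace(config.sim, bound_motif_fraction=bound_fraction)
        sites, bound, cuts = sim.simulate_footprint_sites(
            genome, state["consensus"], pwm, cfg, window=config.footprint_window
        )
        index = sp.cut_site_index(cuts)
        profile = fp.aggregate_footprint(
            index, sites, window=config.footprint_window, tf_name=pwm.name
        )
        calls[pwm.name] = fp.classify_active(profile)
        profiles[pwm.name] = profile
        ppath = outdir / f"footprint_{pwm.name}.tsv"
        with open(ppath, "w") as fh:
            fh.write("offset\tcount\n")
            for off, count in zip(
                range(-profile.window, profile.window + 1), profile.counts
            ):
                fh.write(f"{off}\t{int(count)}\n")
        _register(files, ppath.name, ppath)
    state["tf_calls"] = calls
    return {
        "motif_enrichment": [
            {
                "motif": row.motif,
                "target_hits": int(row.target_hits),
                "background_hits": int(row.background_hits),
                "p_value": float(row.p_value),
                "q_value": float(row.q_value),
            }
            for row in enrich.itertuples(index=False)
        ],
        "footprints": {
            name: {
                "depth_score": profiles[name].depth_score,
                "n_sites": profiles[name].n_sites,
                "call": calls[name],
            }
            for name in sorted(profiles)
        },
    }


def _stage_expression(config: RunConfig, state: dict, outdir: Path, files: dict):
    genome = state["genome"]
    counts, lengths, expressed_truth = sim.simulate_counts(genome, config.sim)
    path = outdir / "counts.tsv"
    expr.write_counts_tsv(counts, lengths, path)
    _register(files, path.name, path)

    tpm = expr.compute_tpm(counts, lengths)
    tpm_path = outdir / "tpm.tsv"
    tpm.round(4).to_csv(tpm_path, sep="\t", index_label="gene_id")
    _register(files, tpm_path.name, tpm_path)

    expressed = expr.expressed_genes(tpm, threshold=config.tpm_threshold)
    corr = expr.replicate_correlation(tpm)
    off_diag = corr.to_numpy()[np.triu_indices(corr.shape[0], k=1)]

    # expression cross-check of the footprint calls: map the bound demo TF to
    # an expressed gene and the unbound one to a silent gene
    truth = expressed_truth
    expressed_gene = truth.index[truth][0] if truth.any() else truth.index[0]
    silent_gene = truth.index[~truth][0] if (~truth).any() else truth.index[0]
    tf_gene_map = {"NFY_CCAAT": expressed_gene, "FOS_AP1": silent_gene}
    crosscheck = fp.crosscheck_expression(
        state.get("tf_calls", {}), tpm, tf_gene_map, tpm_threshold=config.tpm_threshold
    )
    cc_path = outdir / "tf_expression_crosscheck.tsv"
    crosscheck.to_csv(cc_path, sep="\t", index=False)
    _register(files, cc_path.name, cc_path)

    return {
        "n_genes": int(counts.shape[0]),
        "n_expressed": len(expressed),
        "true_expressed": int(expressed_truth.sum()),
        "mean_replicate_correlation": float(np.mean(off_diag)),
        "tf_crosscheck": [
            {
                "tf": row.tf,
                "call": row.footprint_call,
                "gene": row.gene,
                "mean_tpm": None if pd.isna(row.mean_tpm) else float(row.mean_tpm),
                "status": row.status,
            }
            for row in crosscheck.itertuples(index=False)
        ],
    }
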