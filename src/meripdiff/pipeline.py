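"""End-to-end analysis: simulate (or load) coverage, call peaks, build
the union peak reference per contrast, score enrichment, call DMPs,
intersect the three contrasts' gene sets into demethylase targets, and
produce metagene and k-mer motif summaries.

Every stage is deterministic for a fixed seed; when an output directory
is given, all tables are written alongside a manifest recording every
parameter that affects the results.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .differential import (
    Contrast,
    UnionPeak,
    build_union_reference,
    call_dmps,
    enrichment_matrix,
    group_common_peaks,
)
from .io import write_annotation, write_bedgraph, write_fasta, write_peaks_bed
from .motif import kmer_enrichment, summit_window
from .peaks import Peak, PeakCallerParams, call_peaks, select_top_peaks
from .simulate import (
    CoverageTrack,
    SimulationConfig,
    TranscriptModel,
    generate_transcriptome,
    simulate_counts,
)
from .targets import (
    TargetGene,
    assign_peaks_to_genes,
    intersect_targets,
    metagene_profile,
)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "recovery_stats"]


@dataclass(frozen=True)
class PipelineConfig:
    """All stage parameters for a full synthetic-data run."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    peak_params: PeakCallerParams = field(default_factory=PeakCallerParams)
    min_score: float = 6.0
    min_abs_log2fc: float = 1.0
    score_mode: str = "max"
    metagene_bins: tuple[int, int, int] = (20, 50, 30)
    stop_window: int = 50
    top_n_motif_peaks: int = 3000
    motif_window: int = 100
    motif_k: int = 5
    motif_shuffles: int = 20

    def contrasts(self) -> list[Contrast]:
        sim = self.simulation
        perturbed = [g for g in sim.groups if g != sim.control_group]
        return [Contrast(case=g, control=sim.control_group) for g in perturbed]

    def validate(self) -> None:
        sim = self.simulation
        for c in self.contrasts():
            for g in (c.case, c.control):
                if g not in sim.groups:
                    raise ValueError(f"contrast group {g!r} not in simulation groups")
        for g in (*sim.hyper_groups, *sim.hypo_groups):
            if g not in sim.groups:
                raise ValueError(f"effect group {g!r} not in simulation groups")


@dataclass
class PipelineResult:
    models: list[TranscriptModel]
    truth: pd.DataFrame
    peaks: dict[str, list[Peak]]
    references: dict[str, list[UnionPeak]]
    matrices: dict[str, pd.DataFrame]
    dmp_tables: dict[str, pd.DataFrame]
    hyper_genes: dict[str, set[str]]
    hypo_genes: dict[str, set[str]]
    targets: list[TargetGene]
    metagene: "np.ndarray"
    metagene_bins: tuple[int, int, int]
    motif_table: pd.DataFrame
    manifest: dict

    @property
    def target_gene_ids(self) -> set[str]:
        return {t.gene_id for t in self.targets}


def _contrast_label(c: Contrast) -> str:
    return f"{c.case}_vs_{c.control}"


def _dmp_gene_sets(
    dmp_table: pd.DataFrame,
    reference: list[UnionPeak],
    models: list[TranscriptModel],
) -> tuple[set[str], set[str], dict[str, tuple[str, ...]], dict[str, tuple[str, ...]]]:
    by_key = {p.key: p for p in reference}
    passing = dmp_table[dmp_table.passed_filters]
    hyper: dict[str, list[str]] = {}
    hypo: dict[str, list[str]] = {}
    if len(passing):
        assigns = assign_peaks_to_genes(
            [by_key[k] for k in passing.index], models
        )
        for (key, row), asg in zip(passing.iterrows(), assigns):
            bucket = hyper if row.status == "hyper" else hypo
            bucket.setdefault(asg.gene_id, []).append(key)
    return (
        set(hyper),
        set(hypo),
        {g: tuple(v) for g, v in hyper.items()},
        {g: tuple(v) for g, v in hypo.items()},
    )


def run_pipeline(config: PipelineConfig, outdir: str | None = None) -> PipelineResult:
    """Run every stage on synthetic data with a known truth table."""
    config.validate()
    sim = config.simulation

    models, truth = generate_transcriptome(sim)
    tracks = simulate_counts(models, truth, sim)
    by_sample: dict[str, list[CoverageTrack]] = {}
    for t in tracks:
        by_sample.setdefault(t.sample_id, []).append(t)

    peaks: dict[str, list[Peak]] = {
        sample: [
            p
            for track in sample_tracks
            for p in call_peaks(track, config.peak_params)
        ]
        for sample, sample_tracks in by_sample.items()
    }

    group_samples: dict[str, list[str]] = {}
    for s in sim.sample_ids:
        group_samples.setdefault(sim.group_of(s), []).append(s)
    common_by_group = {
        g: group_common_peaks([peaks[s] for s in samples])
        for g, samples in group_samples.items()
    }

    sample_groups = {s: sim.group_of(s) for s in sim.sample_ids}
    references, matrices, dmp_tables = {}, {}, {}
    hyper_genes: dict[str, set[str]] = {}
    hypo_genes: dict[str, set[str]] = {}
    hyper_support: dict[str, dict[str, tuple[str, ...]]] = {}
    hypo_support: dict[str, dict[str, tuple[str, ...]]] = {}
    for contrast in config.contrasts():
        label = _contrast_label(contrast)
        reference = build_union_reference(
            {g: common_by_group[g] for g in (contrast.case, contrast.control)}
        )
        contrast_samples = [
            t
            for t in tracks
            if sim.group_of(t.sample_id) in (contrast.case, contrast.control)
        ]
        matrix = enrichment_matrix(reference, contrast_samples)
        table = call_dmps(
            matrix,
            sample_groups,
            contrast,
            min_score=config.min_score,
            min_abs_log2fc=config.min_abs_log2fc,
            score_mode=config.score_mode,
        )
        hyper, hypo, hsup, losup = _dmp_gene_sets(table, reference, models)
        references[label] = reference
        matrices[label] = matrix
        dmp_tables[label] = table
        hyper_genes[label] = hyper
        hypo_genes[label] = hypo
        hyper_support[label] = hsup
        hypo_support[label] = losup

    hyper_labels = [
        _contrast_label(Contrast(g, sim.control_group)) for g in sim.hyper_groups
    ]
    hypo_labels = [
        _contrast_label(Contrast(g, sim.control_group)) for g in sim.hypo_groups
    ]
    gene_sets = [hyper_genes[l] for l in hyper_labels] + [
        hypo_genes[l] for l in hypo_labels
    ]
    support = {l: hyper_support[l] for l in hyper_labels}
    support.update({l: hypo_support[l] for l in hypo_labels})
    if len(gene_sets) == 3:
        targets = intersect_targets(*gene_sets, support=support)
    else:  # generalized: intersection of all required sets
        genes = set.intersection(*gene_sets) if gene_sets else set()
        targets = [
            TargetGene(g, {c: tuple(d.get(g, ())) for c, d in support.items()})
            for g in sorted(genes)
        ]

    # metagene and motif summaries over the control group's peaks
    ctl_peaks = [
        p for s in group_samples[sim.control_group] for p in peaks[s]
    ]
    profile = metagene_profile(ctl_peaks, models, bins=config.metagene_bins)

    top = select_top_peaks(ctl_peaks, config.top_n_motif_peaks)
    seq_by_tx = {m.transcript_id: m.sequence for m in models}
    windows = [
        summit_window(seq_by_tx[p.transcript_id], p.summit, config.motif_window)
        for p in top
    ]
    motif_table = kmer_enrichment(
        windows,
        k=config.motif_k,
        n_shuffles=config.motif_shuffles,
        seed=sim.seed,
    )

    manifest = {
        "package": "meripdiff",
        "version": __version__,
        "seed": sim.seed,
        "simulation": asdict(sim),
        "peak_params": asdict(config.peak_params),
        "dmp": {
            "min_score": config.min_score,
            "min_abs_log2fc": config.min_abs_log2fc,
            "score_mode": config.score_mode,
        },
        "metagene_bins": list(config.metagene_bins),
        "stop_window": config.stop_window,
        "motif": {
            "top_n_peaks": config.top_n_motif_peaks,
            "window": config.motif_window,
            "k": config.motif_k,
            "n_shuffles": config.motif_shuffles,
        },
        "contrasts": [_contrast_label(c) for c in config.contrasts()],
        "n_targets_found": len(targets),
    }

    result = PipelineResult(
        models=models,
        truth=truth,
        peaks=peaks,
        references=references,
        matrices=matrices,
        dmp_tables=dmp_tables,
        hyper_genes=hyper_genes,
        hypo_genes=hypo_genes,
        targets=targets,
        metagene=profile.density,
        metagene_bins=profile.bins,
        motif_table=motif_table,
        manifest=manifest,
    )
    if outdir is not None:
        _write_bundle(result, tracks, outdir)
    return result


def _write_bundle(result: PipelineResult, tracks: list[CoverageTrack], outdir: str) -> None:
    import os

    os.makedirs(outdir, exist_ok=True)
    write_fasta(os.path.join(outdir, "transcripts.fa"), result.models)
    write_annotation(os.path.join(outdir, "annotation.tsv"), result.models)
    result.truth.to_csv(os.path.join(outdir, "truth.tsv"), sep="\t", index=False)

    by_sample: dict[str, dict[str, np.ndarray]] = {}
    for t in tracks:
        by_sample.setdefault(t.sample_id, {})
        by_sample[t.sample_id][t.transcript_id] = t
    for sample, d in by_sample.items():
        write_bedgraph(
            os.path.join(outdir, f"{sample}.ip.bedgraph"),
            {tx: tr.ip_counts for tx, tr in d.items()},
        )
        write_bedgraph(
            os.path.join(outdir, f"{sample}.input.bedgraph"),
            {tx: tr.input_counts for tx, tr in d.items()},
        )

    for sample, plist in result.peaks.items():
        write_peaks_bed(
            os.path.join(outdir, f"{sample}.peaks.bed"),
            plist,
            os.path.join(outdir, f"{sample}.summits.tsv"),
        )

    for label in result.references:
        with open(os.path.join(outdir, f"union_{label}.bed"), "w") as fh:
            for p in result.references[label]:
                fh.write(f"{p.transcript_id}\t{p.start}\t{p.end}\t{p.key}\t0\t+\n")
        result.matrices[label].to_csv(
            os.path.join(outdir, f"enrichment_{label}.tsv"), sep="\t"
        )
        result.dmp_tables[label].to_csv(
            os.path.join(outdir, f"dmp_{label}.tsv"), sep="\t"
        )

    pd.DataFrame(
        [(t.gene_id, json.dumps(t.support)) for t in result.targets],
        columns=["gene_id", "support"],
    ).to_csv(os.path.join(outdir, "targets.tsv"), sep="\t", index=False)

    summary = {
        **{f"n_hyper_{l}": len(s) for l, s in result.hyper_genes.items()},
        **{f"n_hypo_{l}": len(s) for l, s in result.hypo_genes.items()},
        "n_triple_intersection": len(result.targets),
    }
    with open(os.path.join(outdir, "intersection_summary.json"), "w") as fh:
        json.dump(summary, fh, indent=2)

    pd.DataFrame(
        {"bin": np.arange(len(result.metagene)), "density": result.metagene}
    ).to_csv(os.path.join(outdir, "metagene.tsv"), sep="\t", index=False)
    result.motif_table.to_csv(os.path.join(outdir, "motif.tsv"), sep="\t", index=False)

    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(result.manifest, fh, indent=2, default=str)


def recovery_stats(result: PipelineResult) -> dict[str, float]:
    """Sensitivity and precision of the recovered target set against the
    generator's planted truth."""
    planted = set(result.truth.loc[result.truth.is_target, "gene_id"]) if len(
        result.truth
    ) else set()
    found = result.target_gene_ids
    tp = len(found & planted)
    sensitivity = tp / len(planted) if planted else float("nan")
    precision = tp / len(found) if found else float("nan")
    return {
        "n_planted": len(planted),
        "n_found": len(found),
        "true_positives": tp,
        "sensitivity": sensitivity,
        "precision": precision,
    }
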