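"""End-to-end pipeline orchestration with config, logging and reports.

``run_pipeline`` executes: (simulate?) -> demultiplex -> quality trim ->
length filter -> map -> pileup -> genuine-SNC calling -> codon merge ->
per-AMP summaries -> read clustering -> peptide enumeration -> cross-sample
statistics, and emits TSV reports plus a JSON manifest with read counts at
every gate and the resolved configuration for provenance.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import diversity_stats as dstats
from . import snc_analysis as snc
from .demo import demo_panel
from .mapping_pileup import Scoring, align_read, build_pileup, coverage_stats
from .preprocess import Read, demultiplex, length_filter, mott_trim, read_fastq
from .reference_model import ReferencePanel, load_panel
from .synthetic_reads import (
    ErrorModel454,
    build_haplotype_pool,
    merge_pools,
    simulate_study,
)

log = logging.getLogger("ampdiv")


@dataclass
class SimulateConfig:
    """Synthetic-input settings for a pipeline run.

    The planted variant structure mirrors the study design: per amplicon a
    set of population-wide (common) variant sites shared by every sample,
    plus a smaller, per-sample exclusive set — so cross-sample partitions
    and per-AMP variability statistics have realistic structure.
    """

    n_reads_per_pool: int = 400
    common_sites: int = 3
    common_freqs: tuple[float, ...] = (0.05, 0.10, 0.20)
    exclusive_sites_range: tuple[int, int] = (1, 3)   # per sample, inclusive
    exclusive_freq_range: tuple[float, float] = (0.06, 0.18)
    noiseless: bool = False
    samples: Optional[tuple[str, ...]] = None       # default: all panel samples
    amplicons: Optional[tuple[str, ...]] = None     # default: all amplicons

    def __post_init__(self):
        if len(self.common_freqs) != self.common_sites:
            raise ValueError("common_freqs length must equal common_sites")


@dataclass
class RunConfig:
    """Pipeline configuration; thresholds default to the study settings."""

    panel_dir: Optional[str] = None          # None -> bundled demo panel
    input_fastq: Optional[tuple[str, ...]] = None
    simulate: Optional[SimulateConfig] = None
    min_depth: int = 30
    min_freq: float = 0.03
    qual_min: int = 20
    neighborhood_min: int = 15
    neighborhood_radius: int = 5
    trim_limit: float = 0.05
    min_len: int = 100
    cluster_min_cov: int = 3
    min_identity: float = 0.8
    max_mismatch: int = 0
    max_freq: Optional[float] = None
    seed: int = 0
    outdir: Optional[str] = None
    make_plots: bool = False

    def __post_init__(self):
        if not (self.min_depth >= 1 and 0 < self.min_freq < 1
                and 0 < self.trim_limit < 1 and self.min_len >= 0
                and self.qual_min >= 0 and self.neighborhood_min >= 0
                and self.neighborhood_radius >= 0 and self.cluster_min_cov >= 1):
            raise ValueError("threshold out of valid range")

    def resolved(self) -> dict:
        d = dataclasses.asdict(self)
        return json.loads(json.dumps(d, default=list))


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")


@dataclass
class PipelineResult:
    panel: ReferencePanel
    manifest: dict
    snc_frame: pd.DataFrame
    summary_frame: pd.DataFrame
    diversity_frame: pd.DataFrame
    common_exclusive_frame: pd.DataFrame
    grouping_frame: pd.DataFrame
    map_frame: pd.DataFrame
    coverage_frame: pd.DataFrame
    sidecar: Optional[pd.DataFrame] = None
    truth_pools: Optional[dict] = None
    summaries: dict = field(default_factory=dict)
    sncs_by_sample_amp: dict = field(default_factory=dict)


def _simulate_inputs(panel: ReferencePanel, sim: SimulateConfig, seed: int):
    rng = np.random.default_rng(seed)
    samples = sim.samples or tuple(panel.samples)
    amplicons = sim.amplicons or tuple(sorted(panel.amplicons))
    lo_n, hi_n = sim.exclusive_sites_range
    lo_f, hi_f = sim.exclusive_freq_range
    pools = {}
    for aid in amplicons:
        amp = panel.amplicons[aid]
        common = build_haplotype_pool(
            amp, sim.common_sites, list(sim.common_freqs),
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        taken = [t.position for t in common.true_sncs]
        for sample in samples:
            n_excl = int(rng.integers(lo_n, hi_n + 1))
            freqs = [float(f) for f in rng.uniform(lo_f, hi_f, size=n_excl)]
            exclusive = build_haplotype_pool(
                amp, n_excl, freqs,
                seed=int(rng.integers(0, 2**31 - 1)),
                sample_id=sample,
                exclude_positions=taken,
            )
            pools[(sample, aid)] = merge_pools(common, exclusive, amp.sequence)
    model = ErrorModel454.noiseless() if sim.noiseless else ErrorModel454()
    reads, sidecar = simulate_study(panel, pools, sim.n_reads_per_pool,
                                    model=model,
                                    seed=int(rng.integers(0, 2**31 - 1)))
    return reads, sidecar, pools


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Run the whole pipeline; returns all report tables and the manifest.

    Output files (if ``config.outdir`` is set) are only written once every
    stage has succeeded, so a failing run leaves no partial reports.
    """
    manifest: dict = {"config": config.resolved(), "gates": {}}

    stage = "panel"
    try:
        panel = load_panel(config.panel_dir) if config.panel_dir else demo_panel()

        stage = "input"
        sidecar = None
        pools = None  # truth pools when simulating
        if config.simulate is not None:
            reads, sidecar, pools = _simulate_inputs(panel, config.simulate,
                                                     config.seed)
        elif config.input_fastq:
            reads = []
            for path in config.input_fastq:
                reads.extend(read_fastq(path))
        else:
            raise ValueError("config needs input_fastq or simulate")
        manifest["gates"]["input_reads"] = len(reads)

        stage = "demultiplex"
        demux = demultiplex(reads, panel, max_mismatch=config.max_mismatch)
        manifest["gates"]["assigned"] = len(demux.assigned)
        manifest["gates"]["unassigned"] = len(demux.unassigned)

        stage = "trim"
        trimmed = [mott_trim(r, config.trim_limit) for r in demux.assigned]
        kept, discarded = length_filter(trimmed, config.min_len)
        manifest["gates"]["kept"] = len(kept)
        manifest["gates"]["discarded_short"] = len(discarded)
        log.info("demux: %d assigned, %d unassigned; trim+filter: %d kept, "
                 "%d discarded", len(demux.assigned), len(demux.unassigned),
                 len(kept), len(discarded))

        stage = "map"
        by_pool: dict[tuple[str, str], list[Read]] = {}
        for r in kept:
            by_pool.setdefault((r.assigned_sample, r.assigned_amplicon), []).append(r)
        scoring = Scoring()
        alignments = {}
        coverage_rows = []
        n_aligned = 0
        n_nonspecific = 0
        for (sample, aid), pool_reads in sorted(by_pool.items()):
            amp = panel.amplicons[aid]
            alns = []
            for r in pool_reads:
                a = align_read(r, amp, scoring, min_identity=config.min_identity)
                if a is None:
                    n_nonspecific += 1
                else:
                    alns.append(a)
            alignments[(sample, aid)] = alns
            n_aligned += len(alns)
            cov = coverage_stats(alns, amp)
            coverage_rows.append({
                "sample_id": sample, "amplicon_id": aid, "amp_id": amp.amp_id,
                "n_reads": len(alns),
                "average_coverage": round(cov.average_coverage, 2),
            })
        manifest["gates"]["aligned"] = n_aligned
        manifest["gates"]["nonspecific"] = n_nonspecific
        coverage_frame = pd.DataFrame(coverage_rows)

        stage = "call"
        sncs_by_sample_amp: dict[tuple[str, str], list] = {}
        changes_by_sample_amp: dict[tuple[str, str], list] = {}
        for (sample, aid), alns in sorted(alignments.items()):
            amp = panel.amplicons[aid]
            pileup = build_pileup(
                alns, amp, qual_min=config.qual_min,
                neighborhood_min=config.neighborhood_min,
                neighborhood_radius=config.neighborhood_radius,
            )
            called = snc.call_sncs(pileup, amp, min_depth=config.min_depth,
                                   min_freq=config.min_freq,
                                   max_freq=config.max_freq)
            merged = snc.merge_and_classify(called, amp)
            key = (sample, amp.amp_id)
            sncs_by_sample_amp.setdefault(key, []).append(called)
            changes_by_sample_amp.setdefault(key, []).append(merged)

        stage = "summarize"
        covered = panel.covered_codons_per_amp()
        summaries = {}
        snc_frames = []
        for (sample, amp_id), snc_lists in sorted(sncs_by_sample_amp.items()):
            pooled_sncs = snc.pool_sncs(snc_lists)
            pooled_changes = snc.pool_changes(changes_by_sample_amp[(sample, amp_id)])
            summaries[(sample, amp_id)] = snc.summarize(
                pooled_changes, pooled_sncs, amp_id, sample, covered[amp_id],
            )
            snc_frames.append(snc.sncs_to_frame(pooled_sncs, sample))
        snc_frame = (pd.concat(snc_frames, ignore_index=True) if snc_frames
                     else snc.sncs_to_frame([], ""))
        summary_frame = snc.summaries_to_frame(
            [summaries[k] for k in sorted(summaries)])

        stage = "cluster"
        clusters_by_key: dict[tuple[str, str], list] = {}
        peptides_by_key: dict[tuple[str, str], list] = {}
        for (sample, aid), pool_reads in sorted(by_pool.items()):
            amp = panel.amplicons[aid]
            clusters = dstats.cluster_reads(pool_reads, amp, sample)
            peptides = dstats.enumerate_peptides(
                clusters, amp, min_cov=config.cluster_min_cov,
                min_identity=config.min_identity)
            ckey = (amp.amp_id, sample)
            clusters_by_key.setdefault(ckey, []).extend(clusters)
            peptides_by_key.setdefault(ckey, []).extend(peptides)
        for ckey, peps in peptides_by_key.items():
            seen = {}
            for p in peps:
                seen.setdefault(p.peptide, p)
            peptides_by_key[ckey] = list(seen.values())
        diversity_frame = dstats.clusters_to_frame(clusters_by_key, peptides_by_key)

        stage = "statistics"
        snc_sets = {}
        for (sample, amp_id), snc_lists in sncs_by_sample_amp.items():
            keys = {s.key() for s in snc.pool_sncs(snc_lists)}
            snc_sets.setdefault(sample, set()).update(keys)
        if len(snc_sets) >= 2:
            ce = dstats.common_exclusive(snc_sets)
            ce_rows = [{"category": "common", "sample_id": "", "count": len(ce.common)}]
            for s in sorted(ce.exclusive):
                ce_rows.append({"category": "exclusive", "sample_id": s,
                                "count": len(ce.exclusive[s])})
            ce_rows.append({"category": "shared_partial", "sample_id": "",
                            "count": len(ce.shared_partial)})
            for s in sorted(ce.percent_common):
                ce_rows.append({"category": "percent_common", "sample_id": s,
                                "count": round(ce.percent_common[s], 1)})
            common_exclusive_frame = pd.DataFrame(ce_rows)
        else:
            common_exclusive_frame = pd.DataFrame(
                columns=["category", "sample_id", "count"])

        freq_rows = [{"amp_id": amp_id, "sample_id": sample,
                      "frequency": s.frequency}
                     for (sample, amp_id), s in summaries.items()]
        freq_table = pd.DataFrame(freq_rows)
        grouping_rows = []
        if len(snc_sets) >= 2 and freq_table["amp_id"].nunique() >= 2:
            grouping = dstats.anova_tukey(freq_table)
            manifest["anova"] = {
                "F": None if np.isnan(grouping.anova_F) else grouping.anova_F,
                "p": None if np.isnan(grouping.anova_p) else grouping.anova_p,
                "rejected": grouping.rejected,
                "undefined": grouping.undefined,
            }
            for gi, group in enumerate(grouping.groups or [], start=1):
                for amp_id in group:
                    grouping_rows.append({
                        "group": gi, "amp_id": amp_id,
                        "mean_frequency": round(grouping.means[amp_id], 4),
                    })
        grouping_frame = pd.DataFrame(grouping_rows,
                                      columns=["group", "amp_id", "mean_frequency"])

        map_frames = []
        for amp_id in panel.amp_ids:
            changes_by_sample = {}
            for (sample, a_id), change_lists in changes_by_sample_amp.items():
                if a_id == amp_id:
                    changes_by_sample[sample] = snc.pool_changes(change_lists)
            if changes_by_sample:
                bounds = panel.by_amp(amp_id)[0].region_bounds
                map_frames.append(snc.snc_maps(changes_by_sample, amp_id, bounds))
        map_frame = (pd.concat(map_frames, ignore_index=True) if map_frames
                     else snc.snc_maps({}, ""))

        # conservation checks recorded in the manifest
        g = manifest["gates"]
        manifest["conservation"] = {
            "input_equals_assigned_plus_unassigned":
                g["input_reads"] == g["assigned"] + g["unassigned"],
            "assigned_equals_kept_plus_discarded":
                g["assigned"] == g["kept"] + g["discarded_short"],
            "kept_equals_aligned_plus_nonspecific":
                g["kept"] == g["aligned"] + g["nonspecific"],
        }
    except Exception as exc:  # noqa: BLE001 - stage reporting
        raise PipelineError(stage, exc) from exc

    result = PipelineResult(
        panel=panel, manifest=manifest, snc_frame=snc_frame,
        summary_frame=summary_frame, diversity_frame=diversity_frame,
        common_exclusive_frame=common_exclusive_frame,
        grouping_frame=grouping_frame, map_frame=map_frame,
        coverage_frame=coverage_frame, sidecar=sidecar, truth_pools=pools,
        summaries=summaries, sncs_by_sample_amp=sncs_by_sample_amp,
    )
    if config.outdir:
        _write_outputs(result, config)
    return result


def _write_outputs(result: PipelineResult, config: RunConfig) -> None:
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    result.snc_frame.to_csv(out / "sncs.tsv", sep="\t", index=False)
    result.summary_frame.to_csv(out / "summary.tsv", sep="\t", index=False)
    result.diversity_frame.to_csv(out / "diversity.tsv", sep="\t", index=False,
                                  float_format="%.2f")
    result.common_exclusive_frame.to_csv(out / "common_exclusive.tsv", sep="\t",
                                         index=False)
    result.grouping_frame.to_csv(out / "grouping.tsv", sep="\t", index=False)
    result.map_frame.to_csv(out / "snc_map.tsv", sep="\t", index=False)
    result.coverage_frame.to_csv(out / "coverage.tsv", sep="\t", index=False)
    (out / "manifest.json").write_text(
        json.dumps(result.manifest, indent=2, sort_keys=True) + "\n")
    if config.make_plots:
        from .snc_analysis import plot_snc_map
        for amp_id in result.panel.amp_ids:
            sub = result.map_frame[result.map_frame["amp_id"] == amp_id]
            if len(sub):
                plot_snc_map(sub, result.panel.by_amp(amp_id)[0],
                             out / f"snc_map_{amp_id}.png")
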