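"""End-to-end orchestration: panel -> simulate -> QC -> classify -> call -> stats.

``run_validation`` executes the whole validation experiment in memory and
is what the acceptance checks and the analysis drivers use;  ``run_all``
additionally writes every stage's tables plus a machine-readable manifest
to an output directory.  Execution is single-threaded and fully
deterministic: per-sample simulation seeds are spawned from one master
seed, so reruns with the same config are byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .align import Scoring
from .calling import CallThresholds, ContaminationCall, call_batch, calls_table
from .classify import (
    CompositionProfile, CoverageStats, KmerIndex, align_reads, composition,
    composition_table, compute_coverage, coverage_table,
)
from .panel import (
    ReferencePanel, UNIVERSAL_16S, amplicon_table, insilico_pcr, meat_panel,
    write_fasta, write_taxonomy,
)
from .qc import QCParams, apply_qc
from .simulate import (
    MixtureDesign, QualityProfile, build_paper_designs, simulate_sample, write_fastq,
)
from .stats import describe_deviations, percentage_deviation, prop_test, contingency_test


class PipelineError(RuntimeError):
    def __init__(self, stage: str, sample: str | None, cause: Exception):
        self.stage, self.sample = stage, sample
        where = f"stage {stage!r}" + (f", sample {sample!r}" if sample else "")
        super().__init__(f"pipeline failed at {where}: {cause}")


@dataclass
class PipelineConfig:
    """Study-mimic defaults: 9 pure controls in duplicate plus 13 mixtures
    in triplicate, error-free reads, 10,000 pairs per sample."""

    n_pairs: int = 10_000
    error_rate: float = 0.0
    panel_seed: int = 101
    sim_seed: int = 7
    genome_length: int = 2000
    designs: list[MixtureDesign] | None = None  # None -> build_paper_designs()
    quality: QualityProfile = field(default_factory=QualityProfile)
    qc: QCParams = field(default_factory=QCParams)
    scoring: Scoring = field(default_factory=Scoring)
    min_score_frac: float = 0.6
    mode: str = "seeded"
    thresholds: CallThresholds = field(default_factory=CallThresholds)
    bootstrap_reps: int = 10_000
    stats_seed: int = 0
    write_fastq: bool = False

    def to_dict(self) -> dict:
        d = {
            "n_pairs": self.n_pairs, "error_rate": self.error_rate,
            "panel_seed": self.panel_seed, "sim_seed": self.sim_seed,
            "genome_length": self.genome_length,
            "n_designs": len(self.designs) if self.designs is not None else None,
            "quality": vars(self.quality).copy(),
            "qc": {k: list(v) if isinstance(v, tuple) else v for k, v in vars(self.qc).items()},
            "scoring": vars(self.scoring).copy(),
            "min_score_frac": self.min_score_frac, "mode": self.mode,
            "thresholds": vars(self.thresholds).copy(),
            "bootstrap_reps": self.bootstrap_reps, "stats_seed": self.stats_seed,
        }
        return d


@dataclass
class SampleResult:
    design: MixtureDesign
    profile: CompositionProfile
    coverage: list[CoverageStats]
    pairs_before: int
    pairs_after: int
    assigned: int
    unassigned: int


@dataclass
class ValidationRun:
    panel: ReferencePanel
    samples: list[SampleResult]
    calls: list[ContaminationCall]
    category_counts: pd.DataFrame
    deviation_stats: pd.DataFrame
    group_stats: pd.DataFrame


def _design_category(design: MixtureDesign) -> str:
    if len(design.components) == 1:
        return "pure"
    props = sorted(p for _, p in design.components)
    return "mix_9to1" if props[0] < 0.25 else "mix_1to1"


def run_validation(config: PipelineConfig = PipelineConfig()) -> ValidationRun:
    """Run the full validation experiment in memory."""
    stage, sample = "panel", None
    try:
        panel = meat_panel(seed=config.panel_seed, genome_length=config.genome_length)
        amplicons = insilico_pcr(panel, UNIVERSAL_16S)
        index = KmerIndex(panel)
        designs = config.designs if config.designs is not None else build_paper_designs()
        seeds = np.random.SeedSequence(config.sim_seed).generate_state(
            max(len(designs), 1)
        ) % (2**31)

        results: list[SampleResult] = []
        for design, seed in zip(designs, seeds):
            sample = design.sample_id
            stage = "simulate"
            reads = simulate_sample(
                panel, amplicons, design, config.n_pairs,
                error_rate=config.error_rate, quality_profile=config.quality,
                seed=int(seed),
            )
            stage = "qc"
            filtered, report = apply_qc(reads, config.qc)
            stage = "classify"
            clf = align_reads(
                filtered, panel, scoring=config.scoring,
                min_score_frac=config.min_score_frac, mode=config.mode, index=index,
            )
            coverage = compute_coverage(clf.hits, panel)
            profile = composition(
                coverage, panel.genus_map, design.sample_id, clf.unassigned_pairs
            )
            results.append(
                SampleResult(
                    design, profile, coverage,
                    pairs_before=report.pairs_before, pairs_after=report.pairs_after,
                    assigned=clf.assigned_pairs, unassigned=clf.unassigned_pairs,
                )
            )
        sample = None
        stage = "call"
        declared = {
            d.sample_id: d.declared_genus
            for d in designs if d.declared_genus is not None
        }
        categories = {d.sample_id: _design_category(d) for d in designs}
        calls, counts = call_batch(
            [r.profile for r in results], config.thresholds, declared, categories
        )
        stage = "stats"
        dev_stats = _deviation_stats(results)
        group_stats = _group_stats(counts, config)
        return ValidationRun(panel, results, calls, counts, dev_stats, group_stats)
    except Exception as exc:  # noqa: BLE001 - annotate failure location
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(stage, sample, exc) from exc


def _deviation_stats(results: list[SampleResult]) -> pd.DataFrame:
    groups: dict[str, list[float]] = {"pure": [], "mixed": []}
    for r in results:
        expected_map = r.design.expected_genus_pct
        genera = sorted(expected_map)
        expected = [expected_map[g] for g in genera]
        observed = [r.profile.entries.get(g, 0.0) for g in genera]
        devs = percentage_deviation(expected, observed)
        key = "pure" if len(r.design.components) == 1 else "mixed"
        groups[key].extend(devs.tolist())
    rows = []
    for group, devs in groups.items():
        if not devs:
            continue
        s = describe_deviations(devs)
        rows.append(
            {
                "group": group, "n": s.n, "min": s.min, "max": s.max,
                "median": s.median, "mean_abs": s.mean_abs,
                "sd": s.sd, "variance": s.variance,
            }
        )
    return pd.DataFrame(rows)


def _group_stats(counts: pd.DataFrame, config: PipelineConfig) -> pd.DataFrame:
    """Per-category proportion tests plus a pure-vs-mixed contingency row."""
    rows = []
    mixed_k = mixed_n = 0
    for rec in counts.itertuples():
        k, n = int(rec.contaminated), int(rec.total)
        if rec.category.startswith("mix"):
            mixed_k, mixed_n = mixed_k + k, mixed_n + n
        res = prop_test(k, n)
        rows.append(
            {
                "category": rec.category, "k": k, "n": n,
                "chi2": res.chi2, "df": res.df, "p_value": res.p_value,
                "cramers_v": np.nan,
            }
        )
    pure = counts[counts.category == "pure"]
    if len(pure) and mixed_n:
        pk, pn = int(pure.contaminated.iloc[0]), int(pure.total.iloc[0])
        res = prop_test(mixed_k, mixed_n)
        rows.append(
            {
                "category": "mixed_all", "k": mixed_k, "n": mixed_n,
                "chi2": res.chi2, "df": res.df, "p_value": res.p_value,
                "cramers_v": np.nan,
            }
        )
        table = [[pk, pn - pk], [mixed_k, mixed_n - mixed_k]]
        if min(pn, mixed_n) > 0:
            cont = contingency_test(
                table, bootstrap_reps=config.bootstrap_reps, seed=config.stats_seed
            )
            rows.append(
                {
                    "category": "pure_vs_mixed", "k": pk + mixed_k, "n": pn + mixed_n,
                    "chi2": cont.chi2, "df": cont.df, "p_value": cont.p_value,
                    "cramers_v": cont.cramers_v,
                }
            )
    return pd.DataFrame(rows)


def run_all(config: PipelineConfig = PipelineConfig(), outdir: str | Path = "results/run") -> dict:
    """Run the validation experiment and write all stage outputs + manifest."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    try:
        run = run_validation(config)
    except PipelineError as exc:
        (out / "manifest.failed.json").write_text(
            json.dumps(
                {"failed_stage": exc.stage, "failed_sample": exc.sample,
                 "error": str(exc), "config": config.to_dict()},
                indent=2, sort_keys=True,
            )
        )
        raise

    write_fasta(run.panel, out / "panel.fasta")
    write_taxonomy(run.panel, out / "taxonomy.tsv")
    amplicon_table(insilico_pcr(run.panel)).to_csv(out / "amplicons.tsv", sep="\t", index=False)

    composition_table([r.profile for r in run.samples]).to_csv(
        out / "compositions.tsv", sep="\t", index=False
    )
    cov_frames = []
    for r in run.samples:
        df = coverage_table(r.coverage)
        df.insert(0, "sample_id", r.design.sample_id)
        cov_frames.append(df)
    cov_all = (
        pd.concat(cov_frames, ignore_index=True)
        if cov_frames
        else pd.DataFrame(
            columns=["sample_id", "accession", "length", "total_aligned_bases",
                     "avg_fold", "pct_covered"]
        )
    )
    cov_all.to_csv(out / "covstats.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {
                "sample_id": r.design.sample_id, "pairs_before": r.pairs_before,
                "pairs_after": r.pairs_after,
                "fraction_retained": r.pairs_after / r.pairs_before if r.pairs_before else 1.0,
                "assigned": r.assigned, "unassigned": r.unassigned,
            }
            for r in run.samples
        ]
    ).to_csv(out / "qc_summary.tsv", sep="\t", index=False)
    calls_table(run.calls).to_csv(out / "calls.tsv", sep="\t", index=False)
    run.category_counts.to_csv(out / "category_counts.tsv", sep="\t", index=False)
    run.deviation_stats.to_csv(out / "deviation_stats.tsv", sep="\t", index=False)
    run.group_stats.to_csv(out / "group_stats.tsv", sep="\t", index=False)

    if config.write_fastq:
        fq = out / "fastq"
        fq.mkdir(exist_ok=True)
        amplicons = insilico_pcr(run.panel, UNIVERSAL_16S)
        seeds = np.random.SeedSequence(config.sim_seed).generate_state(
            max(len(run.samples), 1)
        ) % (2**31)
        for r, seed in zip(run.samples, seeds):
            reads = simulate_sample(
                run.panel, amplicons, r.design, config.n_pairs,
                error_rate=config.error_rate, quality_profile=config.quality,
                seed=int(seed),
            )
            write_fastq(
                reads,
                fq / f"{r.design.sample_id}_R1.fastq",
                fq / f"{r.design.sample_id}_R2.fastq",
            )

    manifest = {
        "config": config.to_dict(),
        "n_samples": len(run.samples),
        "outputs": sorted(p.name for p in out.iterdir() if p.is_file()),
        "samples": [
            {
                "sample_id": r.design.sample_id,
                "pairs": r.pairs_before,
                "pairs_after_qc": r.pairs_after,
                "assigned": r.assigned,
                "unassigned": r.unassigned,
                "top_genus": (r.profile.top or (None, 0.0))[0],
                "top_pct": (r.profile.top or (None, 0.0))[1],
            }
            for r in run.samples
        ],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
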