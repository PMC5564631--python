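"""End-to-end orchestration: configuration, staged execution, reporting.

A run is described by a :class:`RunConfig` (sample table + stage
parameters), executes target stats, M-bias/bowing and methylation calling
per sample; trim sweep, deamination test, concordance and discordance
histogram per matched pair; and consensus + sensitivity against replicate
gold standards when replicates are declared.  Everything lands in one
machine-validated JSON report plus per-stage TSV/BED artifacts; all paths
inside the report are relative to the output directory and no timestamps
are recorded, so a rerun on identical inputs is byte-identical.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
from pydantic import BaseModel, Field, field_validator

from . import simdata
from .bsio import read_bed, read_fasta, read_sam, read_vcf_ct_candidates, write_bed, write_sam
from .methcall import CallParams, FilterStats, MethProfile, aggregate_observations, collect_observations
from .biasqc import bias_curve_from_observations, bowing_score, trim_sweep
from .artifactqc import deamination_counts, deamination_test, target_stats
from .concord import (
    build_consensus,
    discordance_histogram,
    intersect_profiles,
    sensitivity_by_coverage,
)

__all__ = ["RunConfig", "SampleSpec", "PairSpec", "Report", "run_all", "make_demo"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and cause."""


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

class SampleSpec(BaseModel):
    label: str
    preservation: str  # FFPE | FF
    sam: str

    @field_validator("preservation")
    @classmethod
    def _check_ptype(cls, v: str) -> str:
        if v not in ("FFPE", "FF"):
            raise ValueError("preservation must be 'FFPE' or 'FF'")
        return v


class PairSpec(BaseModel):
    name: str
    ffpe: str
    ff: str


class CallParamsModel(BaseModel):
    min_mapq: int = 30
    min_baseq: int = 20
    trim5: int = 5
    trim3: int = 5
    clip_overlap: bool = True
    exclude_duplicates: bool = True
    exclude_secondary: bool = True

    def to_params(self) -> CallParams:
        return CallParams(**self.model_dump())


class RunConfig(BaseModel):
    reference: str
    targets: str
    samples: list[SampleSpec]
    pairs: list[PairSpec] = Field(default_factory=list)
    replicates: tuple[str, str] | None = None  # gold-standard replicate labels
    candidates: str | None = None  # C>T candidate VCF
    params: CallParamsModel = Field(default_factory=CallParamsModel)
    trims: list[int] = Field(default_factory=lambda: list(range(5, 91, 5)))
    consensus_min_cov: int = 10
    sensitivity_max_cov: int = 30
    bowing_k_head: int = 30
    bowing_plateau: tuple[int, int] = (60, 100)

    @field_validator("samples")
    @classmethod
    def _unique_labels(cls, v: list[SampleSpec]) -> list[SampleSpec]:
        labels = [s.label for s in v]
        if len(set(labels)) != len(labels):
            raise ValueError("sample labels must be unique")
        return v

    def check_paths(self, base: Path) -> None:
        missing = [
            str(p) for p in
            [base / self.reference, base / self.targets]
            + [base / s.sam for s in self.samples]
            + ([base / self.candidates] if self.candidates else [])
            if not p.exists()
        ]
        if missing:
            raise PipelineError(f"config references missing paths: {missing}")
        labels = {s.label for s in self.samples}
        for pair in self.pairs:
            for l in (pair.ffpe, pair.ff):
                if l not in labels:
                    raise PipelineError(f"pair {pair.name} references unknown sample {l!r}")
        if self.replicates is not None:
            for l in self.replicates:
                if l not in labels:
                    raise PipelineError(f"replicates reference unknown sample {l!r}")


# ---------------------------------------------------------------------------
# report schema
# ---------------------------------------------------------------------------

class BowingReport(BaseModel):
    head: float
    plateau: float
    score: float
    bowed: bool


class SampleReport(BaseModel):
    label: str
    preservation: str
    total_reads: int
    filtered_reads: int
    on_target_reads: int
    on_target_rate: float
    n_offtarget_regions: int
    offtarget_bp: int
    n_calls: int
    bowing: BowingReport
    profile_file: str
    bias_curve_file: str
    offtarget_bed: str


class ConcordanceReport(BaseModel):
    n_a: int
    n_b: int
    n_intersect: int
    n_concordant: int
    concordant_fraction: float
    overlap_fraction_a: float
    overlap_fraction_b: float


class SweepReport(BaseModel):
    rho: float
    p: float
    min_concordant_fraction: float
    max_concordant_fraction: float
    table_file: str


class DeaminationReport(BaseModel):
    count_a: tuple[int, int]  # (A, G) in the FFPE sample
    count_b: tuple[int, int]  # (A, G) in the FF sample
    p: float
    degenerate: bool
    snv_fraction_ffpe: float
    snv_fraction_ff: float
    direction: str | None


class PairReport(BaseModel):
    ffpe: str
    ff: str
    concordance: ConcordanceReport
    sweep: SweepReport
    deamination: DeaminationReport | None
    histogram_file: str


class SensitivityReport(BaseModel):
    plateau: float
    sensitivity_at_10x: float
    table_file: str


class GoldReport(BaseModel):
    replicates: tuple[str, str]
    n_sites: int
    n_off: int
    sensitivity: dict[str, SensitivityReport]


class Report(BaseModel):
    config: RunConfig
    samples: dict[str, SampleReport]
    pairs: dict[str, PairReport]
    gold: GoldReport | None


# ---------------------------------------------------------------------------
# execution
# ---------------------------------------------------------------------------

def _stage(name: str):
    """Abort with the stage name and cause on failure."""
    class _Ctx:
        def __enter__(self):
            logger.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
            logger.info("stage %s: done", name)
            return False
    return _Ctx()


def _write_df(df, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def run_all(config: RunConfig, outdir: str | Path, base: str | Path = ".") -> Report:
    """Execute every declared stage; write artifacts + report under outdir."""
    base = Path(base)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.check_paths(base)
    params = config.params.to_params()

    with _stage("load-inputs"):
        reference = read_fasta(base / config.reference)
        targets = read_bed(base / config.targets)
        candidates = (
            read_vcf_ct_candidates(base / config.candidates) if config.candidates else None
        )

    sample_reports: dict[str, SampleReport] = {}
    profiles: dict[str, MethProfile] = {}
    observations: dict[str, list] = {}
    reads_by_label: dict[str, list] = {}
    for spec in config.samples:
        with _stage(f"sample:{spec.label}"):
            reads = list(read_sam(base / spec.sam))
            reads_by_label[spec.label] = reads
            tstats = target_stats(reads, targets, label=spec.label)
            stats = FilterStats()
            obs = collect_observations(reads, reference, targets, params, stats=stats)
            stats.log(spec.label)
            observations[spec.label] = obs
            curve = bias_curve_from_observations(obs, params)
            score = bowing_score(
                curve, k_head=config.bowing_k_head, plateau_window=config.bowing_plateau
            )
            profile = aggregate_observations(obs, params)
            profile.label = spec.label
            profiles[spec.label] = profile

            profile_file = f"{spec.label}.profile.tsv"
            curve_file = f"{spec.label}.bias.tsv"
            offbed = f"{spec.label}.offtarget.bed"
            profile.write_tsv(outdir / profile_file)
            _write_df(curve.to_dataframe(), outdir / curve_file)
            write_bed(outdir / offbed, tstats.off_target_regions)
            sample_reports[spec.label] = SampleReport(
                label=spec.label,
                preservation=spec.preservation,
                total_reads=tstats.total_reads,
                filtered_reads=tstats.filtered_reads,
                on_target_reads=tstats.on_target_reads,
                on_target_rate=tstats.on_target_rate,
                n_offtarget_regions=len(tstats.off_target_regions),
                offtarget_bp=tstats.off_target_bp,
                n_calls=len(profile),
                bowing=BowingReport(
                    head=score.head, plateau=score.plateau,
                    score=score.score, bowed=score.bowed,
                ),
                profile_file=profile_file,
                bias_curve_file=curve_file,
                offtarget_bed=offbed,
            )

    pair_reports: dict[str, PairReport] = {}
    for pair in config.pairs:
        with _stage(f"pair:{pair.name}"):
            sweep = trim_sweep(
                observations[pair.ffpe], observations[pair.ff],
                reference, targets, params, trims=config.trims,
            )
            sweep_file = f"{pair.name}.trimsweep.tsv"
            _write_df(sweep.table, outdir / sweep_file)
            summary, paired = intersect_profiles(profiles[pair.ffpe], profiles[pair.ff])
            hist = discordance_histogram(paired)
            hist_file = f"{pair.name}.discordance.tsv"
            _write_df(hist, outdir / hist_file)
            deam_report = None
            if candidates is not None:
                ca = deamination_counts(
                    reads_by_label[pair.ffpe], candidates, reference, label=pair.ffpe
                )
                cb = deamination_counts(
                    reads_by_label[pair.ff], candidates, reference, label=pair.ff
                )
                res = deamination_test(ca, cb)
                deam_report = DeaminationReport(
                    count_a=res.table[0], count_b=res.table[1],
                    p=res.p, degenerate=res.degenerate,
                    snv_fraction_ffpe=res.snv_fraction_a,
                    snv_fraction_ff=res.snv_fraction_b,
                    direction=res.direction,
                )
            pair_reports[pair.name] = PairReport(
                ffpe=pair.ffpe,
                ff=pair.ff,
                concordance=ConcordanceReport(
                    n_a=summary.n_a, n_b=summary.n_b,
                    n_intersect=summary.n_intersect,
                    n_concordant=summary.n_concordant,
                    concordant_fraction=summary.concordant_fraction,
                    overlap_fraction_a=summary.overlap_fraction_a,
                    overlap_fraction_b=summary.overlap_fraction_b,
                ),
                sweep=SweepReport(
                    rho=sweep.rho, p=sweep.p,
                    min_concordant_fraction=float(sweep.table["concordant_fraction"].min()),
                    max_concordant_fraction=float(sweep.table["concordant_fraction"].max()),
                    table_file=sweep_file,
                ),
                deamination=deam_report,
                histogram_file=hist_file,
            )

    gold_report = None
    if config.replicates is not None:
        with _stage("gold"):
            r1, r2 = config.replicates
            consensus = build_consensus(
                profiles[r1], profiles[r2], min_cov=config.consensus_min_cov
            )
            sens: dict[str, SensitivityReport] = {}
            for spec in config.samples:
                if spec.label in config.replicates:
                    continue
                curve = sensitivity_by_coverage(
                    consensus, profiles[spec.label], max_cov=config.sensitivity_max_cov
                )
                sfile = f"{spec.label}.sensitivity.tsv"
                _write_df(curve.table, outdir / sfile)
                sens[spec.label] = SensitivityReport(
                    plateau=curve.plateau,
                    sensitivity_at_10x=curve.sensitivity_at(10),
                    table_file=sfile,
                )
            gold_report = GoldReport(
                replicates=(r1, r2),
                n_sites=len(consensus),
                n_off=consensus.n_off,
                sensitivity=sens,
            )

    report = Report(
        config=config, samples=sample_reports, pairs=pair_reports, gold=gold_report
    )
    with open(outdir / "report.json", "w") as fh:
        json.dump(report.model_dump(mode="json"), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report


# ---------------------------------------------------------------------------
# demo
# ---------------------------------------------------------------------------

#: simulation scale of the worked demo: three matched FFPE/FF tumor pairs
#: plus a duplicated cell-line-style sample, CpG-dense 16 kb of targets at
#: 30x — small enough for minutes on one CPU, large enough for every stage
#: to produce stable numbers
DEMO_CONFIG = simdata.SimConfig(
    reference_length=80_000,
    n_targets=8,
    target_size=2_000,
    cpg_period=10,
    mean_coverage=30.0,
    p_on_target=0.8,
    n_deamination_sites=30,
    deamination_prob=0.3,
    n_snv_sites=10,
    snv_allele_fraction=1.0,
    candidate_min_spacing=400,
)

DEMO_TRUTH_SHARE = 0.6  # fraction of CpG dyads each tumor shares with the cell line


def make_demo(seed: int, outdir: str | Path) -> Report:
    """Simulate the full comparison design and run the whole pipeline.

    Three tumor pairs (S1..S3, each an FFPE + FF split of one simulated
    tumor; FFPE carries bowing) and two cell-line replicates (shared truth,
    independent reads, no bowing) are generated, then every declared stage
    runs against the replicate-consensus gold standard.  Deterministic for a
    fixed seed.
    """
    outdir = Path(outdir)
    datadir = outdir / "data"
    datadir.mkdir(parents=True, exist_ok=True)
    cfg = simdata.with_overrides(DEMO_CONFIG, seed=int(seed))
    ss = np.random.SeedSequence(int(seed))
    streams = iter(ss.spawn(32))

    reference, targets = simdata.simulate_reference(cfg, np.random.default_rng(next(streams)))
    cell_truth = simdata.simulate_truth(reference, targets, cfg, np.random.default_rng(next(streams)))
    deam, snv = simdata.simulate_variant_sites(reference, targets, cfg, np.random.default_rng(next(streams)))
    refs = {c: len(s) for c, s in reference.items()}

    from .bsio import write_fasta, write_vcf_sites

    write_fasta(datadir / "reference.fa", reference)
    write_bed(datadir / "targets.bed", targets)
    write_vcf_sites(datadir / "ct_candidates.vcf", sorted(deam + snv), refs)

    samples: list[SampleSpec] = []
    pairs: list[PairSpec] = []
    for i in (1, 2, 3):
        tumor_truth = simdata.derive_related_truth(
            cell_truth, DEMO_TRUTH_SHARE, cfg, np.random.default_rng(next(streams))
        )
        for ptype in ("FFPE", "FF"):
            label = f"S{i}_{ptype}"
            reads = simdata.simulate_reads(
                reference, targets, tumor_truth, cfg, label, ptype,
                rng=np.random.default_rng(next(streams)),
                deamination_sites=deam, snv_sites=snv,
            )
            write_sam(datadir / f"{label}.sam", reads, refs)
            samples.append(SampleSpec(label=label, preservation=ptype, sam=f"data/{label}.sam"))
        pairs.append(PairSpec(name=f"S{i}", ffpe=f"S{i}_FFPE", ff=f"S{i}_FF"))
    for rep in (1, 2):
        label = f"CL_N{rep}"
        reads = simdata.simulate_reads(
            reference, targets, cell_truth, cfg, label, "FF",
            rng=np.random.default_rng(next(streams)),
            deamination_sites=deam, snv_sites=snv,
        )
        write_sam(datadir / f"{label}.sam", reads, refs)
        samples.append(SampleSpec(label=label, preservation="FF", sam=f"data/{label}.sam"))

    config = RunConfig(
        reference="data/reference.fa",
        targets="data/targets.bed",
        candidates="data/ct_candidates.vcf",
        samples=samples,
        pairs=pairs,
        replicates=("CL_N1", "CL_N2"),
    )
    with open(outdir / "run_config.json", "w") as fh:
        json.dump(config.model_dump(mode="json"), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return run_all(config, outdir, base=outdir)
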