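"""End-to-end orchestration of the analysis stages with a summary report.

Stage order: events -> PSI -> differential test -> variant masking ->
intron features -> first-intron analysis; the phosphoproteomics branch is
independent.  Masked events are excluded from the significant set reported
in the summary (they are removed from the final output) but their PSI and
test results remain inspectable in the full table alongside the removal
log.
"""

from __future__ import annotations

import json
import logging
import math
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from pyfaidx import Fasta

from . import __version__
from .annotation import enumerate_introns, parse_annotation
from .events import EVENT_TYPES, extract_all_events
from .features import intron_features
from .firstintron import first_intron_enrichment, partition_ir, retention_comparison
from .io import write_event_table, write_removal_log
from .mask import filter_events, read_variants
from .phospho import read_protein_fasta, read_psm_table, results_to_frame, site_tests, aggregate_sites
from .psi import delta_psi_test, read_quantifications, records_to_frame
from .pwm import train_pwms_from_annotation

log = logging.getLogger("splicescreen")


@dataclass
class RunConfig:
    """Paths and thresholds for one pipeline run."""

    gtf: str
    quant_dir: str
    design: str
    out_dir: str
    genome: str | None = None
    vcf: str | None = None
    psm: str | None = None
    proteins: str | None = None
    event_types: tuple[str, ...] = EVENT_TYPES
    dpsi_threshold: float = 0.1
    alpha: float = 0.01
    expression_floor: float = 1.0
    expression_bins: int = 10
    z_cutoff: float = 1.96
    pass_only: bool = False
    seed: int = 0

    def validate(self) -> None:
        for name in ("dpsi_threshold", "alpha", "expression_floor", "z_cutoff"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("gtf", "quant_dir", "design", "genome", "vcf", "psm", "proteins"):
            path = getattr(self, name)
            if path is not None and not Path(path).exists():
                raise FileNotFoundError(f"configured {name} input does not exist: {path}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "event_types" in raw:
            raw["event_types"] = tuple(raw["event_types"])
        return cls(**raw)


@dataclass
class SummaryReport:
    per_type: dict[str, dict]          # type -> {tested, significant, more_included, less_included}
    masked_events: int
    first_intron: dict | None
    phospho: dict | None
    metadata: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"per_type": self.per_type, "masked_events": self.masked_events,
                 "first_intron": self.first_intron, "phospho": self.phospho,
                 "metadata": self.metadata},
                fh, indent=2, default=str,
            )
        log.info("summary written to %s", path)


def run_pipeline(config: RunConfig) -> SummaryReport:
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()

    def stage(name):
        log.info("[%6.1fs] stage %s", time.time() - t0, name)

    stage("events")
    transcripts = parse_annotation(config.gtf)
    introns = enumerate_introns(transcripts)
    types = list(config.event_types)
    if "EX" in types and not any(t.cds for t in transcripts):
        log.warning("no CDS annotation; skipping exitron (EX) extraction")
        types.remove("EX")
    events = extract_all_events(transcripts, introns, types)
    write_event_table(events, out / "events.tsv",
                      header_comment=_meta_line(config))
    log.info("%d transcripts, %d introns, %d events", len(transcripts),
             len(introns), len(events))

    stage("psi/diffsplice")
    quant = read_quantifications(config.quant_dir, config.design)
    records = delta_psi_test(
        events, quant, expression_bins=config.expression_bins,
        seed=config.seed, dpsi_threshold=config.dpsi_threshold,
        alpha=config.alpha, expression_floor=config.expression_floor,
    )
    psi_frame = records_to_frame(records)

    masked_ids: set[str] = set()
    if config.vcf:
        stage("mask")
        variants = read_variants(config.vcf, pass_only=config.pass_only)
        kept, removed = filter_events(events, variants)
        masked_ids = {r.event_id for r in removed}
        write_removal_log(removed, out / "removed_events.tsv")
        write_event_table(kept, out / "events.masked.tsv")
        log.info("%d events removed by variant masking", len(masked_ids))

    psi_frame["masked"] = psi_frame["event_id"].isin(masked_ids)
    psi_frame.to_csv(out / "diffsplice.tsv", sep="\t", index=False, float_format="%.6g")

    by_id = {e.event_id: e for e in events}
    per_type: dict[str, dict] = {}
    for etype in types:
        sub = [r for r in records
               if by_id[r.event_id].type == etype and r.event_id not in masked_ids]
        tested = [r for r in sub if not math.isnan(r.p_value)]
        sig = [r for r in tested if r.significant]
        per_type[etype] = {
            "tested": len(tested),
            "significant": len(sig),
            "more_included": sum(r.direction == "more_included" for r in sig),
            "less_included": sum(r.direction == "less_included" for r in sig),
        }

    first_block = None
    if config.genome:
        stage("features")
        genome = Fasta(config.genome)
        pwm5, pwm3 = train_pwms_from_annotation(introns, genome)
        pwm5.to_tsv(out / "pwm_five_prime.tsv")
        pwm3.to_tsv(out / "pwm_three_prime.tsv")
        intron_features(introns, genome, pwm5, pwm3).to_csv(
            out / "intron_features.tsv", sep="\t", index=False, float_format="%.6g")

    sig_ir = [by_id[r.event_id] for r in records
              if r.significant and r.event_id not in masked_ids
              and by_id[r.event_id].type == "IR"]
    all_ir = [e for e in events if e.type == "IR"]
    if sig_ir and all_ir:
        stage("firstintron")
        partition = partition_ir(sig_ir, all_ir)
        enr = first_intron_enrichment(partition)
        first_block = {
            "observed_first": enr.observed_first,
            "observed_remaining": enr.observed_remaining,
            "expected_first_fraction": enr.expected_first_fraction,
            "chi_square": enr.chi_square,
            "p_value": enr.p_value,
        }
        if len(partition.first) >= 2 and len(partition.remaining) >= 2:
            cmp_ = retention_comparison(partition, records)
            first_block["retention_wilcoxon_p"] = cmp_.p_value

    phospho_block = None
    if config.psm:
        stage("phospho")
        proteins = read_protein_fasta(config.proteins) if config.proteins else None
        psms = read_psm_table(config.psm, proteins)
        stats = aggregate_sites(psms)
        results = site_tests(psms, z_cutoff=config.z_cutoff)
        results_to_frame(results, stats).to_csv(
            out / "phosphosites.tsv", sep="\t", index=False, float_format="%.6g")
        tested = [r for r in results if not math.isnan(r.p_value)]
        sig = [r for r in tested if r.p_value < 0.05]
        phospho_block = {
            "sites": len(results),
            "tested": len(tested),
            "significant_p05": len(sig),
            "gain": sum(r.direction == "gain" for r in sig),
            "loss": sum(r.direction == "loss" for r in sig),
        }

    report = SummaryReport(
        per_type=per_type, masked_events=len(masked_ids),
        first_intron=first_block, phospho=phospho_block,
        metadata={"version": __version__, "seed": config.seed,
                  "dpsi_threshold": config.dpsi_threshold, "alpha": config.alpha,
                  "expression_floor": config.expression_floor},
    )
    report.to_json(out / "summary.json")
    for etype, block in per_type.items():
        assert block["significant"] <= block["tested"]
    stage("done")
    return report


def _meta_line(config: RunConfig) -> str:
    return (f"splicescreen {__version__} seed={config.seed} "
            f"dpsi>={config.dpsi_threshold} p<{config.alpha}")
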