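"""End-to-end orchestration: simulate -> QC -> GWAS -> homozygosity mapping
-> variant cascade -> consequence annotation -> segregation.

``run_all`` reproduces the complete mapping workflow on a synthetic bundle
and writes, per stage: the marker-QC audit, the Manhattan-ready association
table, the critical-interval BED and report, the cascade step counts, the
consequence table for the surviving candidates, and the cohort segregation
report — every output stamped with the configuration hash and seed, and
byte-identical across reruns of the same configuration.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from contextlib import contextmanager
from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

from . import association, autozygosity, marker_qc, prioritization, segregation
from .consequence import annotate, read_coding_variants_tsv
from .errors import ConfigurationError, RecessmapError
from .iomodel import (read_genotypes, read_panel_vcf, read_transcripts_fasta,
                      read_variants, write_interval_bed)
from .simulate import SimConfig, simulate_validation_cohort, write_bundle

__all__ = ["PipelineConfig", "PipelineError", "run_all"]

log = logging.getLogger("recessmap")


class PipelineError(RecessmapError):
    """A pipeline stage failed; carries the stage name and an error code."""

    def __init__(self, stage, code, message):
        super().__init__(f"[{stage}] {code}: {message}")
        self.stage, self.code = stage, code


@dataclass
class PipelineConfig:
    """Everything `run_all` needs; defaults are the study's printed thresholds."""

    seed: Optional[int] = None
    sim: SimConfig = field(default_factory=SimConfig)
    call_rate_min: float = 0.90
    maf_min: float = 0.05
    hwe_alpha: float = 1e-5
    n_perm: int = 10_000
    min_markers: int = 25
    make_plot: bool = False

    def validate(self) -> None:
        if self.n_perm > 0 and self.seed is None:
            raise ConfigurationError("a seed is mandatory when permutations are requested")
        if not (0 <= self.call_rate_min <= 1 and 0 <= self.maf_min <= 0.5
                and 0 < self.hwe_alpha < 1):
            raise ConfigurationError("QC thresholds outside documented ranges")
        self.sim.validate()

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = SimConfig(**raw.pop("sim", {}))
        cfg = cls(sim=sim, **raw)
        return cfg

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if d["sim"]["ibd_segment"] is not None:
            d["sim"]["ibd_segment"] = list(d["sim"]["ibd_segment"])
        return d

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.as_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@contextmanager
def _stage(name):
    log.info("stage %s: start", name)
    try:
        yield
    except RecessmapError as exc:
        raise PipelineError(name, type(exc).__name__, str(exc)) from exc
    except Exception as exc:   # noqa: BLE001 - annotate unexpected failures too
        raise PipelineError(name, "unexpected_error", str(exc)) from exc
    log.info("stage %s: done", name)


def _write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def run_all(config: PipelineConfig, out_dir) -> dict:
    """Run the whole pipeline into ``out_dir``; returns the summary dict."""
    config.validate()
    os.makedirs(out_dir, exist_ok=True)
    stamp = {"config_hash": config.config_hash, "seed": config.seed}
    summary = dict(stamp)

    with _stage("simulate"):
        config.sim.seed = config.seed if config.seed is not None else config.sim.seed
        paths = write_bundle(config.sim, os.path.join(out_dir, "inputs"))
        with open(paths["truth"]) as fh:
            truth_doc = json.load(fh)

    with _stage("load"):
        ds = read_genotypes(paths["ped"], paths["map"])
        variants = read_variants(paths["proband_vcf"])
        panel = read_panel_vcf(paths["panel_vcf"])
        transcripts = read_transcripts_fasta(paths["transcripts"])
        coding_variants = read_coding_variants_tsv(paths["coding_variants"])

    with _stage("qc"):
        log.info("thresholds: call_rate>=%.2f maf>=%.3f hwe_p>=%.1e",
                 config.call_rate_min, config.maf_min, config.hwe_alpha)
        ds_qc, audit = marker_qc.qc_filter(ds, config.call_rate_min,
                                           config.maf_min, config.hwe_alpha)
        _write_tsv(pd.DataFrame([{
            "marker": r.marker_id, "call_rate": round(r.call_rate, 6),
            "maf": round(r.maf, 6), "hwe_p_controls": r.hwe_p_controls,
            "excluded": r.excluded,
            "reasons": ",".join(sorted(r.exclusion_reasons)) or "-",
        } for r in audit]), os.path.join(out_dir, "qc_audit.tsv"))
        summary["qc"] = {"input_markers": ds.n_markers,
                         "retained_markers": ds_qc.n_markers,
                         "excluded_markers": ds.n_markers - ds_qc.n_markers}

    with _stage("gwas"):
        results = association.run_gwas(ds_qc)
        lam = association.genomic_inflation([r.chi2 for r in results])
        if config.n_perm > 0:
            p_corr = association.max_t_permutation(ds_qc, config.n_perm, config.seed)
            association.attach_corrected(results, p_corr)
        table = association.manhattan_table(ds_qc, results)
        _write_tsv(table, os.path.join(out_dir, "gwas.tsv"))
        if config.make_plot:
            association.plot_manhattan(table, os.path.join(out_dir, "manhattan.png"))
        best = table.loc[table["p_raw"].idxmin()]
        summary["gwas"] = {
            "lambda": round(lam, 4),
            "best_marker": str(best["marker"]),
            "best_position_bp": int(best["position_bp"]),
            "best_p_raw": float(best["p_raw"]),
            "best_p_corrected": (float(best["p_corrected"]) if config.n_perm > 0 else None),
            "n_perm": config.n_perm,
        }

    with _stage("autozygosity"):
        runs = autozygosity.find_shared_runs(ds_qc, min_markers=config.min_markers)
        if not runs:
            raise ConfigurationError(
                f"no shared-homozygosity run of >= {config.min_markers} markers")
        longest = max(runs, key=lambda r: r.n_markers)
        interval = autozygosity.delineate_interval(longest, ds_qc)
        write_interval_bed(interval, os.path.join(out_dir, "interval.bed"))
        with open(os.path.join(out_dir, "intervals.tsv"), "w") as fh:
            fh.write(autozygosity.interval_report(
                [autozygosity.delineate_interval(r, ds_qc) for r in runs]))
        summary["interval"] = {"chromosome": interval.chromosome,
                               "start_bp": interval.start_bp,
                               "end_bp": interval.end_bp,
                               "length_mb": interval.length_mb,
                               "n_core_markers": interval.n_core_markers}

    with _stage("prioritize"):
        consequences = {vid: annotate(transcripts[cv.transcript_id], cv)
                        for vid, cv in coding_variants.items()}
        report = prioritization.run_cascade(variants, interval, panel, consequences)
        _write_tsv(pd.DataFrame(report.steps, columns=["filtering_step", "n_variants"]),
                   os.path.join(out_dir, "cascade.tsv"))
        summary["cascade"] = {"steps": report.as_dict(),
                              "survivors": report.surviving_variants}

    with _stage("annotate"):
        rows = []
        for vid in report.surviving_variants:
            call = consequences[vid]
            chrom, pos, alleles = vid.split(":")
            ref, alt = alleles.split(">")
            gene = transcripts[coding_variants[vid].transcript_id].gene_symbol
            rows.append({"chromosome": chrom, "position_bp": int(pos), "ref": ref,
                         "alt": alt, "gene": gene, "cdna": call.hgvs_c,
                         "protein": call.hgvs_p, "effect": call.effect})
        _write_tsv(pd.DataFrame(rows, columns=["chromosome", "position_bp", "ref", "alt",
                                               "gene", "cdna", "protein", "effect"]),
                   os.path.join(out_dir, "consequences.tsv"))

    with _stage("segregate"):
        cohort = simulate_validation_cohort(config.sim, _truth_from_doc(truth_doc))
        rows = []
        for vid, gt in sorted(cohort.tables.items()):
            ok, violations = segregation.recessive_concordance(gt)
            cf = segregation.carrier_frequency(gt, "breed_controls")
            rows.append({"variant": vid, "concordant": ok, "violations": violations,
                         "breed_control_carrier_freq": segregation.format_percent(cf)})
        ids = sorted(cohort.dosages)
        r2 = segregation.genotype_r2(cohort.dosages[ids[0]], cohort.dosages[ids[1]])
        _write_tsv(pd.DataFrame(rows), os.path.join(out_dir, "segregation.tsv"))
        summary["segregation"] = {"candidates": rows, "candidate_r2": round(r2, 6)}

    with open(os.path.join(out_dir, "summary.json"), "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary


def _truth_from_doc(doc):
    """Rehydrate the GroundTruth the segregation stage needs from truth.json."""
    import numpy as np

    from .simulate import GroundTruth
    return GroundTruth(planted_interval=tuple(doc["planted_interval"]),
                       segment_marker_indices=np.array([], dtype=int),
                       carrier_status=doc["carrier_status"],
                       causal_variant_id=doc["causal_variant_id"],
                       passenger_variant_id=doc["passenger_variant_id"])
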