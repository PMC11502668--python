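"""End-to-end scenario orchestration and configuration.

Two reproduction scenarios wire the simulator through every analysis stage:

* ``oligo_control`` — fully modified and fully unmodified synthetic-oligo
  runs over both reporter motifs; reports per-motif U→C mismatch, tag-only,
  and union (modified-read) percentages plus mean base accuracy and the
  −5..+5 context profiles.
* ``oreo_vs_nes`` — three biological conditions (membrane-organelle-targeted
  "OREO", cytoplasmic "NES", and non-targeting control) assayed by all three
  readouts: direct-RNA classification with control subtraction and
  mCherry/eGFP fold change, BID-seq deletion scoring with del_score fold
  change, and flow-cytometry selectivity normalized to the NES condition.

Ground-truth modification fractions for oreo_vs_nes encode the target effect
sizes (mCherry/eGFP fold changes of 2.9 for NES and 25.1 for OREO by direct
RNA, 3.4 and 15.7 by BID-seq, 4× selectivity shift by flow), given the
oligo-calibrated per-motif detection rates.

All defaults match the analysis parameters used throughout: probability
threshold 0.95, pileup max_depth 10,000 (accuracy) / 100,000 (modification
calling), min_base_quality 13, quadrant quantile 0.999.
"""

from __future__ import annotations

import json
import math
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pysam
import yaml

from . import __version__
from .bidseq import bidseq_fold_change, count_deletions, site_from_table
from .errors import ConfigError, UndefinedResultError
from .flowstats import (
    DEFAULT_IRFP_THRESHOLD,
    DEFAULT_QUADRANT_QUANTILE,
    DEFAULT_VIABILITY_CUT,
    gate_events,
    selectivity,
)
from .pileup import (
    DEFAULT_MAX_DEPTH_ACCURACY,
    DEFAULT_MIN_BASE_QUALITY,
    build_pileup,
    context_profile,
    mean_base_accuracy,
)
from .pseucall import (
    DEFAULT_MAX_DEPTH_MODCALL,
    DEFAULT_THRESHOLD,
    classify_site_in_bam,
    run_pseucall,
    summarize_site,
)
from .simdata import (
    DEFAULT_FLOW_CHANNELS,
    DEFAULT_P_MISMATCH_GIVEN_MOD,
    DEFAULT_P_MISMATCH_GIVEN_UNMOD,
    DEFAULT_TAG_TAIL_MOD,
    DEFAULT_TAG_TAIL_UNMOD,
    DrsSimConfig,
    FlowSimConfig,
    make_reference,
    simulate_bidseq_reads,
    simulate_drs_reads,
    simulate_flow_events,
)

SCENARIOS = ("oligo_control", "oreo_vs_nes")

# Default reporter target motifs: synthetic 11-mers with the premature-stop
# uridine centered in a UAG context. Real experiments supply their own
# construct-specific motifs to make_reference.
SYNTHETIC_EGFP_MOTIF = "GACCTTAGCAA"
SYNTHETIC_MCHERRY_MOTIF = "CGGCATAGAAC"


def derive_seed(seed: int, label: str) -> int:
    """Stable sub-seed (< 2^31) for one named stage of a scenario."""
    ss = np.random.SeedSequence([int(seed), zlib.crc32(label.encode())])
    return int(ss.generate_state(1)[0] >> 1)


def union_detection_rate(ref_name: str, modified: bool) -> float:
    """Expected fraction of reads called modified (mismatch ∪ high-conf tag)."""
    p_mm = (DEFAULT_P_MISMATCH_GIVEN_MOD if modified else DEFAULT_P_MISMATCH_GIVEN_UNMOD)[ref_name]
    tail = (DEFAULT_TAG_TAIL_MOD if modified else DEFAULT_TAG_TAIL_UNMOD)[ref_name]
    return p_mm + (1.0 - p_mm) * tail


def drs_scenario_fracs(fold_change: float, mcherry_frac: float) -> dict[str, float]:
    """Per-reporter true modification fractions yielding a given corrected
    mCherry/eGFP fold change in expectation under the default emission model."""
    d_mch = union_detection_rate("mCherry", True) - union_detection_rate("mCherry", False)
    d_egfp = union_detection_rate("eGFP", True) - union_detection_rate("eGFP", False)
    return {
        "mCherry": mcherry_frac,
        "eGFP": mcherry_frac * d_mch / (d_egfp * fold_change),
    }


@dataclass
class PipelineConfig:
    """Every tunable parameter of the pipeline, with analysis defaults."""

    threshold: float = DEFAULT_THRESHOLD
    max_depth_accuracy: int = DEFAULT_MAX_DEPTH_ACCURACY
    max_depth_modcall: int = DEFAULT_MAX_DEPTH_MODCALL
    min_base_quality: int = DEFAULT_MIN_BASE_QUALITY
    quadrant_quantile: float = DEFAULT_QUADRANT_QUANTILE
    viability_cut: float = DEFAULT_VIABILITY_CUT
    irfp_threshold: float = DEFAULT_IRFP_THRESHOLD
    egfp_motif: str = SYNTHETIC_EGFP_MOTIF
    mcherry_motif: str = SYNTHETIC_MCHERRY_MOTIF
    flank_len: int = 50
    context_window: int = 5
    oligo_n_reads: int = 5000
    drs_n_reads: int = 100000
    bidseq_n_reads: int = 100000
    flow_n_events: int = 50000
    # effect sizes encoded by the oreo_vs_nes scenario
    nes_drs_fold: float = 2.9
    oreo_drs_fold: float = 25.1
    nes_mcherry_frac: float = 0.30
    oreo_mcherry_frac: float = 0.60
    bidseq_p_del_given_mod: float = 0.9
    bidseq_p_del_given_unmod: float = 0.0
    nes_bidseq_fracs: dict = field(default_factory=lambda: {"mCherry": 0.34, "eGFP": 0.10})
    oreo_bidseq_fracs: dict = field(default_factory=lambda: {"mCherry": 0.314, "eGFP": 0.02})
    flow_mcherry_shift: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.threshold < 1.0:
            raise ConfigError(f"threshold must be in (0, 1), got {self.threshold}")
        for name in ("quadrant_quantile", "viability_cut"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ConfigError(f"{name} must be in (0, 1), got {v}")
        for name in ("max_depth_accuracy", "max_depth_modcall"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0")
        if self.min_base_quality < 0:
            raise ConfigError("min_base_quality must be >= 0")
        for name in ("oligo_n_reads", "drs_n_reads", "bidseq_n_reads", "flow_n_events"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)
        return path


def _write_manifest(out_dir: Path, cfg: PipelineConfig, scenario: str, seed: int) -> None:
    manifest = {
        "scenario": scenario,
        "seed": seed,
        "parameters": asdict(cfg),
        "versions": {
            "oreo": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "pysam": pysam.__version__,
        },
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")


def _write_json(path: Path, obj) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


# ---------------------------------------------------------------------------
# scenarios
# ---------------------------------------------------------------------------


def _run_oligo_control(cfg: PipelineConfig, out_dir: Path, seed: int) -> dict:
    ref = make_reference(
        cfg.egfp_motif,
        cfg.mcherry_motif,
        flank_len=cfg.flank_len,
        seed=derive_seed(seed, "reference"),
        context_window=cfg.context_window,
    )
    summary: dict = {"samples": {}}
    rows = []
    for sample, frac in (("fully_modified", 1.0), ("unmodified", 0.0)):
        sim = simulate_drs_reads(
            ref,
            DrsSimConfig(
                n_reads=cfg.oligo_n_reads,
                frac_modified=frac,
                seed=derive_seed(seed, f"oligo:{sample}"),
            ),
            out_dir / "sim",
            prefix=f"oligo_{sample}",
        )
        acc_pileup = build_pileup(
            sim.bam_path, ref, max_depth=cfg.max_depth_accuracy, min_base_quality=cfg.min_base_quality
        )
        accuracy = mean_base_accuracy(acc_pileup)
        acc_pileup.to_tsv(out_dir / f"pileup_{sample}.tsv")
        sample_summary = {"mean_base_accuracy_pct": accuracy, "sites": {}}
        for site in ref.target_sites:
            cls = classify_site_in_bam(
                sim.bam_path, site, threshold=cfg.threshold, max_depth=cfg.max_depth_modcall
            )
            s = summarize_site(cls, sample_label=sample)
            ctx = context_profile(acc_pileup, site, window=cfg.context_window)
            ctx.to_csv(out_dir / f"context_{sample}_{site.ref_name}.tsv", sep="\t", index=False)
            rows.append(
                {
                    "sample": sample,
                    "ref_name": site.ref_name,
                    "position": site.position,
                    "display_position": site.display_position,
                    "n_reads": s.n_reads_covering,
                    "pct_u_to_c": s.pct_u_to_c,
                    "pct_high_conf_only": s.pct_high_conf_only,
                    "pct_modified": s.pct_modified_raw,
                    "mean_base_accuracy_pct": accuracy,
                }
            )
            sample_summary["sites"][site.ref_name] = {
                "n_reads": s.n_reads_covering,
                "pct_u_to_c": s.pct_u_to_c,
                "pct_high_conf_only": s.pct_high_conf_only,
                "pct_modified": s.pct_modified_raw,
            }
        summary["samples"][sample] = sample_summary
    report = pd.DataFrame(rows)
    report.to_csv(out_dir / "report.tsv", sep="\t", index=False)
    _write_json(out_dir / "summary.json", summary)
    return summary


def _flow_config(kind: str, cfg: PipelineConfig, seed: int) -> FlowSimConfig:
    """Flow-simulation conditions for one transfection condition.

    ``reporter_only``: no enzyme, so no stop-codon readthrough — both reporter
    channels stay at autofluorescence background. ``nes``: transfected cells
    express both reporters. ``oreo``: like nes with the mCherry channel of
    transfected cells shifted ``flow_mcherry_shift``-fold (selective
    readthrough of the recruited reporter).
    """
    channels = {pop: dict(chs) for pop, chs in DEFAULT_FLOW_CHANNELS.items()}
    bg = channels["untransfected"]["gfp"]
    if kind == "reporter_only":
        for pop in ("transfected_low", "transfected_high"):
            channels[pop]["gfp"] = bg
            channels[pop]["mcherry"] = bg
    elif kind == "oreo":
        for pop in ("transfected_low", "transfected_high"):
            mu, sigma = channels[pop]["mcherry"]
            channels[pop]["mcherry"] = (mu + math.log(cfg.flow_mcherry_shift), sigma)
    elif kind != "nes":
        raise ConfigError(f"unknown flow condition {kind!r}")
    return FlowSimConfig(
        n_events=cfg.flow_n_events,
        channels=channels,
        seed=derive_seed(seed, f"flow:{kind}"),
    )


def _run_oreo_vs_nes(cfg: PipelineConfig, out_dir: Path, seed: int) -> dict:
    ref = make_reference(
        cfg.egfp_motif,
        cfg.mcherry_motif,
        flank_len=cfg.flank_len,
        seed=derive_seed(seed, "reference"),
        context_window=cfg.context_window,
    )
    mch_site = next(s for s in ref.target_sites if s.ref_name == "mCherry")
    egfp_site = next(s for s in ref.target_sites if s.ref_name == "eGFP")
    summary: dict = {}

    # --- direct RNA readout -------------------------------------------------
    drs_fracs = {
        "control": {"mCherry": 0.0, "eGFP": 0.0},
        "nes": drs_scenario_fracs(cfg.nes_drs_fold, cfg.nes_mcherry_frac),
        "oreo": drs_scenario_fracs(cfg.oreo_drs_fold, cfg.oreo_mcherry_frac),
    }
    sims = {}
    for label, fracs in drs_fracs.items():
        # frac_modified is scalar in DrsSimConfig; simulate per reference set
        # with a per-reference mapping by splitting into two single-ref runs
        sims[label] = {
            name: simulate_drs_reads(
                _single_ref(ref, name),
                DrsSimConfig(
                    n_reads=cfg.drs_n_reads,
                    frac_modified=fracs[name],
                    seed=derive_seed(seed, f"drs:{label}:{name}"),
                ),
                out_dir / "sim",
                prefix=f"drs_{label}_{name}",
            )
            for name in ref.names
        }
    drs_summary = {}
    reports = []
    for label in ("nes", "oreo"):
        per_site = {}
        for name, site in (("mCherry", mch_site), ("eGFP", egfp_site)):
            rep = run_pseucall(
                sims[label][name].bam_path,
                sims["control"][name].bam_path,
                _single_ref(ref, name),
                threshold=cfg.threshold,
                max_depth=cfg.max_depth_modcall,
                sample_label=label,
                fold_change_pair=None,
            )
            rep = rep[rep["sample"] == label]
            reports.append(rep)
            per_site[name] = float(rep["pct_modified_corrected"].iloc[0])
        drs_summary[label] = {
            "pct_modified_corrected": per_site,
            # None when the off-target corrected percent is 0 (undefined ratio)
            "fold_change_mcherry_over_egfp": (
                per_site["mCherry"] / per_site["eGFP"] if per_site["eGFP"] > 0 else None
            ),
            "true_fracs": drs_fracs[label],
        }
    pd.concat(reports, ignore_index=True).to_csv(out_dir / "drs_report.tsv", sep="\t", index=False)
    summary["drs"] = drs_summary

    # --- BID-seq readout ----------------------------------------------------
    bid_fracs = {"nes": dict(cfg.nes_bidseq_fracs), "oreo": dict(cfg.oreo_bidseq_fracs)}
    bid_summary = {}
    bid_tables = []
    for label, fracs in bid_fracs.items():
        sim = simulate_bidseq_reads(
            ref,
            n_reads=cfg.bidseq_n_reads,
            frac_modified=fracs,
            p_del_given_mod=cfg.bidseq_p_del_given_mod,
            p_del_given_unmod=cfg.bidseq_p_del_given_unmod,
            seed=derive_seed(seed, f"bidseq:{label}"),
            out_dir=out_dir / "sim",
            prefix=f"bidseq_{label}",
        )
        table = count_deletions(sim.bam_path, ref)
        table.insert(0, "sample", label)
        bid_tables.append(table)
        tgt = site_from_table(table, mch_site.ref_name, mch_site.position)
        off = site_from_table(table, egfp_site.ref_name, egfp_site.position)
        try:
            bid_fc = bidseq_fold_change(tgt, off)
        except UndefinedResultError:
            bid_fc = None
        bid_summary[label] = {
            "del_score": {"mCherry": tgt.del_score, "eGFP": off.del_score},
            "fold_change_mcherry_over_egfp": bid_fc,
            "true_fracs": fracs,
        }
    pd.concat(bid_tables, ignore_index=True).to_csv(
        out_dir / "bidseq_report.tsv", sep="\t", index=False
    )
    summary["bidseq"] = bid_summary

    # --- flow cytometry readout ----------------------------------------------
    reporter_only = simulate_flow_events(
        _flow_config("reporter_only", cfg, seed), out_dir / "flow_reporter_only.csv"
    )
    flow_summary = {}
    gated = {}
    for label in ("nes", "oreo"):
        events = simulate_flow_events(_flow_config(label, cfg, seed), out_dir / f"flow_{label}.csv")
        gated[label], thresholds = gate_events(
            events,
            reporter_only,
            viability_cut=cfg.viability_cut,
            quadrant_quantile=cfg.quadrant_quantile,
        )
    ctrl_gated, _ = gate_events(
        reporter_only,
        reporter_only,
        viability_cut=cfg.viability_cut,
        quadrant_quantile=cfg.quadrant_quantile,
    )
    ctrl_live = ctrl_gated[ctrl_gated["live"]]
    sel = selectivity(gated["oreo"], gated["nes"])
    flow_summary = {
        "selectivity_ratio_oreo": sel.ratio,
        "selectivity_ratio_nes": sel.reference_ratio,
        "normalized_fold_change_oreo_vs_nes": sel.normalized_fold_change,
        "reporter_only_q4_pct": 100.0 * float((ctrl_live["quadrant"] == "Q4").mean()),
        "thresholds": asdict(thresholds),
        "n_live": {label: int(g["live"].sum()) for label, g in gated.items()},
    }
    summary["flow"] = flow_summary

    _write_json(out_dir / "summary.json", summary)
    return summary


def _single_ref(ref, name: str):
    from .simdata import ReferenceSet

    return ReferenceSet(
        records=[(name, ref.sequence(name))],
        target_sites=ref.sites_for(name),
        context_window=ref.context_window,
    )


def run_scenario(
    name: str, cfg: PipelineConfig | None = None, out_dir: str | Path = "oreo_scenario", seed: int | None = None
) -> dict:
    """Run a named reproduction scenario; returns its summary dictionary.

    Writes all simulated inputs, stage reports, a ``summary.json``, and a run
    manifest (versions, seed, full parameter set) under ``out_dir``.
    Deterministic per seed.
    """
    if name not in SCENARIOS:
        raise ConfigError(f"unknown scenario {name!r}; choose from {SCENARIOS}")
    cfg = cfg or PipelineConfig()
    seed = cfg.seed if seed is None else int(seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    _write_manifest(out_dir, cfg, name, seed)
    if name == "oligo_control":
        return _run_oligo_control(cfg, out_dir, seed)
    return _run_oreo_vs_nes(cfg, out_dir, seed)
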