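"""End-to-end orchestration of the synthetic study analysis.

``run_full_analysis`` generates a two-condition synthetic suite, then
exercises every analysis stage in order — duplicate capping, two-pass
event calling per condition, channel-swap FDR, exclusivity
classification, mappability-aware background sampling, coincidence
rates, motif threshold calibration and scanning, prior-state ranking
curves, and the SVM occupancy classifier — writing machine-readable
artifacts plus a single ``summary.json`` that is byte-identical across
reruns with the same configuration.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as bio
from .differential import (
    SiteSet,
    call_exclusive,
    coincidence_rate,
    random_background_sites,
    saturation_threshold,
)
from .events import DetectionConfig, call_events, estimate_fdr_by_swap
from .motifs import (
    HREConfig,
    bundled_halfsite_pwm,
    calibrate_threshold,
    dimer_weights,
    scan_pwm,
)
from .predict import (
    Ranking,
    additional_at_tp,
    average_conservation,
    combine_rankings,
    extract_features,
    rank_by_collection,
    rank_normalize,
    tp_additional_curve,
    train_occupancy_classifier,
)
from .reads import cap_duplicates
from .synth import SyntheticSpec, simulate_experiment_suite

logger = logging.getLogger("bindshift")

__all__ = ["PipelineConfig", "PipelineStageError", "run_full_analysis"]


@dataclass
class PipelineConfig:
    """Everything the orchestrator needs, with defaults matching the
    analysis conventions (50/25 bins, candidate p 1e-9, corrected p
    0.001, 5/10-kbp local background, 200-bp exclusivity window, 500-bp
    feature window, 20-bp conservation window, 26-mer/80% mappability,
    1e-7 duplicate cap, half-site threshold 5.0)."""

    outdir: str = "bindshift_out"
    seed: int = 0
    # synthetic suite
    genome_length: int = 50_000
    n_chroms: int = 1
    background_rate: float = 0.05
    n_shared: int = 6
    n_a_only: int = 3
    n_b_only: int = 3
    event_strength: float = 200.0
    duplicate_rate: float = 0.05
    n_aux_tracks: int = 3
    informativeness: float = 0.9
    n_decoy_motifs: int = 30
    # analysis parameters
    detection: DetectionConfig = field(default_factory=DetectionConfig)
    exclusivity_window: int = 200
    feature_window: int = 500
    conservation_window: int = 20
    n_background_sites: int = 200
    mappability_window: int = 500
    min_mappable_fraction: float = 0.8
    cap_p_threshold: float = 1e-7
    half_site_threshold: float = 5.0
    calibration_seqs: int = 20_000
    calibration_len: int = 100
    svm_repeats: int = 20
    svm_holdout: int = 5

    def spec(self) -> SyntheticSpec:
        return SyntheticSpec(
            genome_length=self.genome_length,
            n_chroms=self.n_chroms,
            background_rate=self.background_rate,
            n_shared=self.n_shared,
            n_a_only=self.n_a_only,
            n_b_only=self.n_b_only,
            event_strength=self.event_strength,
            duplicate_rate=self.duplicate_rate,
            n_aux_tracks=self.n_aux_tracks,
            informativeness=self.informativeness,
            seed=self.seed,
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        det = raw.pop("detection", None)
        cfg = cls(**raw)
        if det:
            if "local_windows" in det:
                det["local_windows"] = tuple(det["local_windows"])
            cfg.detection = DetectionConfig(**det)
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    def config_hash(self) -> str:
        data = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(data.encode()).hexdigest()[:12]


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def _round_floats(obj, ndigits: int = 6):
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    return obj


def run_full_analysis(config: PipelineConfig) -> dict:
    """Run every stage on a freshly generated synthetic suite.

    Writes all artifacts under ``config.outdir`` and returns the
    summary dictionary (also written as ``summary.json``).  Any stage
    failure raises :class:`PipelineStageError` naming the stage;
    artifacts written before the failure remain on disk.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "parameters": _round_floats(dataclasses.asdict(config)),
    }
    stage = "generate"
    try:
        logger.info("stage %s", stage)
        pwm = bundled_halfsite_pwm()
        suite = simulate_experiment_suite(
            config.spec(),
            halfsite_pwm=pwm,
            motif_configs=[(HREConfig("DR", 2), 0.5), (HREConfig("DR", 5), 0.5)],
            n_decoy_motifs=config.n_decoy_motifs,
        )
        bio.write_fasta(out / "genome.fa", suite.genome)
        bio.write_ground_truth(out / "truth.json", suite.truth)
        bio.write_bedgraph(out / "mappability.bedgraph", suite.mappability)
        bio.write_bedgraph(out / "conservation.bedgraph", suite.conservation)
        summary["suite"] = {
            "n_events": len(suite.truth.events),
            "n_motifs": len(suite.truth.motifs),
            "reads": {k: ds.total for k, ds in sorted(suite.datasets.items())},
        }

        stage = "cap_duplicates"
        logger.info("stage %s", stage)
        capped = {}
        caps = {}
        mappable = suite.datasets["signal_A"].genome_length
        for name, ds in suite.datasets.items():
            capped[name], caps[name] = cap_duplicates(ds, mappable, config.cap_p_threshold)
        summary["duplicate_cap"] = {
            name: {"cap": caps[name].cap, "kept": capped[name].total, "input": ds.total}
            for name, ds in sorted(suite.datasets.items())
        }

        stage = "call_events"
        logger.info("stage %s", stage)
        events_a, fit_a, _ = call_events(capped["signal_A"], capped["control"], config.detection)
        events_b, fit_b, _ = call_events(capped["signal_B"], capped["control"], config.detection)
        bio.write_events(out / "events_A.bed", events_a, {"seed": config.seed, "config": summary["config_hash"]})
        bio.write_events(out / "events_B.bed", events_b, {"seed": config.seed, "config": summary["config_hash"]})
        summary["events"] = {
            "A": {"n": len(events_a), "sigma": round(fit_a.sigma, 6), "sigma_mode": fit_a.mode},
            "B": {"n": len(events_b), "sigma": round(fit_b.sigma, 6), "sigma_mode": fit_b.mode},
        }

        stage = "swap_fdr"
        logger.info("stage %s", stage)
        fdr = estimate_fdr_by_swap(capped["signal_A"], capped["control"], config.detection)
        summary["swap_fdr"] = _round_floats(fdr)

        stage = "exclusivity"
        logger.info("stage %s", stage)
        excl = call_exclusive(
            capped["signal_A"], capped["signal_B"], capped["control"],
            config.detection, window=config.exclusivity_window,
        )
        bio.write_exclusivity_tsv(out / "exclusivity.tsv", excl)
        summary["exclusivity"] = {
            "constitutive": len(excl.constitutive),
            "A_exclusive": len(excl.a_exclusive),
            "B_exclusive": len(excl.b_exclusive),
            "ambiguous": len(excl.ambiguous),
        }

        stage = "background_sites"
        logger.info("stage %s", stage)
        all_sites = SiteSet("called", excl.constitutive.sites + excl.a_exclusive.sites
                            + excl.b_exclusive.sites + excl.ambiguous.sites)
        background = random_background_sites(
            config.n_background_sites,
            capped["signal_A"].chrom_lengths,
            suite.mappability,
            exclude=all_sites,
            seed=config.seed + 1,
            mappability_window=config.mappability_window,
            min_mappable_fraction=config.min_mappable_fraction,
        )
        bio.write_sites_bed(out / "background_sites.bed", background)

        stage = "coincidence"
        logger.info("stage %s", stage)
        truth_sites = SiteSet("truth", [(c, p) for c, p, _, _ in suite.truth.events])
        sites_a = SiteSet.from_events("A", events_a)
        summary["coincidence"] = {
            "A_vs_truth": round(coincidence_rate(sites_a, truth_sites), 6) if len(sites_a) else None,
            "background_vs_truth": round(coincidence_rate(background, truth_sites), 6),
        }
        summary["saturation_threshold_A"] = saturation_threshold(capped["signal_A"])

        stage = "motifs"
        logger.info("stage %s", stage)
        from .synth import fit_markov_model

        markov = fit_markov_model(suite.genome, order=3)
        summary["motif_thresholds"] = {}
        matches = []
        for spacer in (2, 5):
            w = dimer_weights(pwm, HREConfig("DR", spacer))
            thresholds = calibrate_threshold(
                w, markov,
                n_seqs=config.calibration_seqs,
                seq_len=config.calibration_len,
                seed=config.seed + 2,
                motif=f"DR{spacer}",
            )
            summary["motif_thresholds"][f"DR{spacer}"] = {
                f"{t.target_rate:g}": round(t.threshold, 4) for t in thresholds
            }
            matches.extend(scan_pwm(suite.genome, w, thresholds[0].threshold, f"DR{spacer}"))
        summary["motif_matches"] = len(matches)

        stage = "prediction"
        logger.info("stage %s", stage)
        positions = sorted({(m.chrom, m.start) for m in matches})
        truth_positions = {
            (c, s) for c, s, _, _ in suite.truth.motifs[: len(suite.truth.events)]
        }
        pred = None
        if positions:
            aux_names = [k for k in capped if k.startswith("aux_")]
            feats = extract_features(
                positions,
                {k: capped[k] for k in aux_names},
                window=config.feature_window,
                collections={"TF": aux_names},
            )
            motif_scores = {}
            for m in matches:
                key = (m.chrom, m.start)
                motif_scores[key] = max(motif_scores.get(key, -np.inf), m.score)
            motif_rank = Ranking(
                positions, rank_normalize(np.array([motif_scores[p] for p in positions]))
            )
            tf_rank = rank_by_collection(feats, "TF")
            combined = combine_rankings(motif_rank, tf_rank)
            truth_in = truth_positions & set(positions)
            cons = average_conservation(positions, suite.conservation, config.conservation_window)
            pred = {
                "n_candidate_positions": len(positions),
                "n_true_positions": len(truth_in),
                "mean_conservation_true": round(
                    float(np.mean([c for p, c in zip(positions, cons) if p in truth_in])), 6
                ) if truth_in else None,
            }
            if truth_in:
                target = max(int(0.8 * len(truth_in)), 1)
                curve_m = tp_additional_curve(motif_rank, truth_in)
                curve_c = tp_additional_curve(combined, truth_in)
                pred["additional_at_80tp_motif"] = additional_at_tp(curve_m, target)
                pred["additional_at_80tp_combined"] = additional_at_tp(curve_c, target)
                with open(out / "curves.tsv", "w") as fh:
                    fh.write("cutoff\ttp_motif\tadd_motif\ttp_combined\tadd_combined\n")
                    for pm, pc in zip(curve_m, curve_c):
                        fh.write(f"{pm.cutoff}\t{pm.true_positives}\t{pm.additional}\t"
                                 f"{pc.true_positives}\t{pc.additional}\n")
        summary["prediction"] = pred

        stage = "svm"
        logger.info("stage %s", stage)
        svm = None
        if pred and pred["n_true_positions"] >= 2 * config.svm_holdout:
            bound = sorted(truth_in)
            unbound = sorted(set(positions) - truth_in)
            if len(unbound) >= 2 * config.svm_holdout:
                res = train_occupancy_classifier(
                    feats, bound, unbound,
                    n_pos=len(bound), n_neg=len(unbound),
                    holdout=(config.svm_holdout, config.svm_holdout),
                    repeats=config.svm_repeats,
                    seed=config.seed + 3,
                )
                svm = {
                    "mean_auc": round(res.mean_auc, 6),
                    "sd_auc": round(res.sd_auc, 6),
                    "repeats": res.repeats,
                }
                with open(out / "classifier.json", "w") as fh:
                    json.dump(svm, fh, sort_keys=True, indent=1)
        summary["svm"] = svm
    except Exception as exc:  # noqa: BLE001 - annotate with the failing stage
        raise PipelineStageError(stage, exc) from exc

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, sort_keys=True, indent=1)
        fh.write("\n")
    return summary
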