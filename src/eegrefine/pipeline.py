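"""End-to-end two-stage refine-filtering runs.

Stage 1 trains the multi-branch network on raw epochs fold by fold.  Inside
each fold, a class-stratified tenth of the *training* trials is attributed
with signed Grad-CAM, the useful/useless intervals are tallied into good/bad
peak-frequency counts, and the top-20-bad-minus-top-100-good rule yields that
fold's filtering frequencies — held-out trials never influence the selection
unless the explicitly leaky variant is requested.  Stage 2 notch-filters the
fold's raw train and test epochs at those frequencies and trains a fresh,
identically specified network.  Reports, filter sets and a paired t-test
comparing the stages are written under an output directory with a manifest,
so finished stages can be resumed byte-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np

from .evaluate import (
    FoldResult,
    StageReport,
    TTestResult,
    cohen_kappa,
    fold_seed,
    make_folds,
    paired_ttest,
    run_fold,
)
from .freqselect import FilterSet, SelectionConfig, select_filter_frequencies, tally
from .gradcam import attribute_set, sample_for_attribution
from .io import EpochSet, N_CLASSES, crop_set, load_epochset, read_recording
from .network import NetworkParams, default_spec
from .notch import apply_notches, merge_close
from .synth import SimConfig, simulate

logger = logging.getLogger(__name__)

__all__ = ["FilterConfig", "ResumeError", "RunConfig", "resume", "run_two_stage"]


class ResumeError(RuntimeError):
    """Manifest missing, corrupt, or inconsistent with the requested config."""


@dataclass
class FilterConfig:
    family: str = "iir-notch"
    q: float = 30.0
    min_gap: float = 1.0


@dataclass
class RunConfig:
    """Everything one reproducible two-stage run needs."""

    sim: SimConfig | None = None
    data_path: str | None = None
    data_format: str | None = None
    crop_seconds: float = 1.25
    network: NetworkParams | None = None
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    filter: FilterConfig = field(default_factory=FilterConfig)
    n_folds: int = 10
    seed: int = 0
    leaky: bool = False
    stages: int = 2  # iterate_n; 1 = stage 1 only
    gradcam_threshold: float = 0.35
    gradcam_min_run: int = 64
    gradcam_target: str = "true"
    #: keyword overrides applied when the network spec is built from the data
    #: shape at run time (epochs, batch_size, learning_rate, dense_nodes, ...)
    network_overrides: dict | None = None
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if self.stages < 1:
            raise ValueError("stages must be >= 1")
        if self.sim is None and self.data_path is None:
            self.sim = SimConfig(seed=self.seed)

    def config_digest(self) -> str:
        payload = {
            "sim": None if self.sim is None else {
                "n_trials_per_class": self.sim.n_trials_per_class,
                "fs": self.sim.fs,
                "duration": self.sim.duration,
                "class_bands": {str(k): [v[0], v[1], list(v[2])]
                                for k, v in self.sim.class_bands.items()},
                "interference": [[f, a, s if s == "all" else list(s)]
                                 for f, a, s in self.sim.interference],
                "noise_exponent": self.sim.noise_exponent,
                "noise_scale": self.sim.noise_scale,
                "seed": self.sim.seed,
            },
            "data_path": self.data_path,
            "crop_seconds": self.crop_seconds,
            "network": (json.loads(self.network.to_json()) if self.network is not None
                        else self.network_overrides),
            "selection": {"k_bad": self.selection.k_bad, "m_good": self.selection.m_good,
                          "sample_fraction": self.selection.sample_fraction,
                          "band": list(self.selection.band)},
            "filter": dataclasses.asdict(self.filter),
            "n_folds": self.n_folds,
            "seed": self.seed,
            "leaky": self.leaky,
            "stages": self.stages,
            "gradcam": [self.gradcam_threshold, self.gradcam_min_run, self.gradcam_target],
        }
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()


def _load_data(cfg: RunConfig) -> EpochSet:
    if cfg.data_path is not None:
        if os.path.isdir(cfg.data_path):
            eset = load_epochset(cfg.data_path)
        else:
            eset = read_recording(cfg.data_path, cfg.data_format)
    else:
        eset = simulate(cfg.sim)
    return crop_set(eset, cfg.crop_seconds)


def _select_for_fold(
    model, train_set: EpochSet, cfg: RunConfig, seed: int
) -> FilterSet:
    """Grad-CAM a stratified tenth of the training trials, tally, select, merge."""
    sample = sample_for_attribution(train_set, cfg.selection.sample_fraction, seed)
    intervals = attribute_set(
        model, sample,
        threshold=cfg.gradcam_threshold,
        min_run=cfg.gradcam_min_run,
        target=cfg.gradcam_target,
    )
    good, bad = tally(intervals, sample, cfg.selection)
    fset = select_filter_frequencies(bad, good, cfg.selection, seed=seed)
    return merge_close(fset, cfg.filter.min_gap)


def _report_from_folds(results, subject_id, stage, filter_freqs) -> StageReport:
    accs = np.array([fr.accuracy for fr in results])
    kappas = np.array([fr.kappa for fr in results])
    pooled = np.sum([fr.confusion for fr in results], axis=0)
    return StageReport(
        subject_id=subject_id,
        stage=stage,
        fold_results=list(results),
        mean_accuracy=float(accs.mean()),
        std_accuracy=float(accs.std(ddof=1)) if len(accs) > 1 else 0.0,
        mean_kappa=float(kappas.mean()),
        pooled_kappa=cohen_kappa(pooled),
        filter_frequencies=sorted(filter_freqs),
    )


def _write_json(path: str, payload) -> None:
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)


def _report_to_disk(report: StageReport, path: str) -> None:
    _write_json(path, report.to_dict())


def _report_from_disk(path: str) -> StageReport:
    with open(path) as fh:
        d = json.load(fh)
    d["fold_results"] = [
        FoldResult(fold=fr["fold"], accuracy=fr["accuracy"], kappa=fr["kappa"],
                   confusion=np.array(fr["confusion"]), seed=fr.get("seed", 0))
        for fr in d["fold_results"]
    ]
    return StageReport(**d)


def run_two_stage(
    cfg: RunConfig, *, allow_resume: bool = False
) -> tuple[StageReport, StageReport | None, TTestResult | None]:
    """Run the (up to ``cfg.stages``-stage) refine-filtering pipeline.

    Returns (stage-1 report, last-stage report or None, paired t-test of last
    stage vs stage 1 fold accuracies or None).  With ``stages=1`` only the raw
    training runs and no frequencies are selected.
    """
    out = cfg.output_dir
    digest = cfg.config_digest()
    manifest_path = os.path.join(out, "manifest.json") if out else None
    manifest = {"config_digest": digest, "completed_stages": [], "reports": {}}
    if out:
        os.makedirs(out, exist_ok=True)
        if os.path.exists(manifest_path):
            try:
                with open(manifest_path) as fh:
                    prev = json.load(fh)
            except (OSError, json.JSONDecodeError) as exc:
                raise ResumeError(f"corrupt manifest: {exc}") from exc
            if allow_resume:
                if prev.get("config_digest") != digest:
                    raise ResumeError("manifest config digest does not match")
                manifest = prev

    eset = _load_data(cfg)
    if len(eset) < cfg.n_folds:
        raise ValueError("too few trials for the requested fold count")
    folds = make_folds(eset, cfg.n_folds, cfg.seed)
    if cfg.network is None:
        m = eset.montage
        cfg.network = default_spec(
            (m.grid_height, m.grid_width, eset[0].n_samples),
            seed=cfg.seed, **(cfg.network_overrides or {}),
        )
    spec = cfg.network
    assert spec.input_shape == (
        eset.montage.grid_height, eset.montage.grid_width, eset[0].n_samples
    ), "network input shape must match montage grid and crop length"

    indices = folds.fold_indices(eset)
    # evolving per-fold raw data (stage > 2 iterates on already-filtered data)
    fold_data = []
    for f, test_ix in enumerate(indices):
        train_ix = np.concatenate([ix for g, ix in enumerate(indices) if g != f])
        fold_data.append((eset.subset(train_ix), eset.subset(test_ix)))

    reports: list[StageReport] = []
    fold_fsets: list[list[FilterSet]] = []  # per stage, per fold
    leaky_fset: FilterSet | None = None

    for stage in range(1, cfg.stages + 1):
        report_path = os.path.join(out, f"stage{stage}_report.json") if out else None
        fsets_path = os.path.join(out, f"stage{stage}_filtersets.json") if out else None
        if stage > 1:
            prev_fsets = fold_fsets[stage - 2]
            new_data = []
            for f, (tr, te) in enumerate(fold_data):
                fset = leaky_fset if cfg.leaky else prev_fsets[f]
                new_data.append((
                    apply_notches(tr, fset, cfg.filter.q,
                                  family=cfg.filter.family, stage=stage),
                    apply_notches(te, fset, cfg.filter.q,
                                  family=cfg.filter.family, stage=stage),
                ))
            fold_data = new_data

        resumed = (
            allow_resume
            and stage in manifest["completed_stages"]
            and report_path and os.path.exists(report_path)
        )
        if resumed:
            logger.info("stage %d: resuming from %s", stage, report_path)
            report = _report_from_disk(report_path)
            reports.append(report)
            if stage < cfg.stages and fsets_path and os.path.exists(fsets_path):
                with open(fsets_path) as fh:
                    fold_fsets.append(
                        [FilterSet.from_json(json.dumps(d)) for d in json.load(fh)]
                    )
            elif stage < cfg.stages:
                raise ResumeError(f"stage {stage} marked complete but filter sets missing")
            continue

        results = []
        stage_fsets: list[FilterSet] = []
        for f, (tr, te) in enumerate(fold_data):
            # identical network spec AND seed across stages: the two stages
            # differ only in their training data
            seed_f = fold_seed(cfg.seed, f)
            try:
                fr, model = run_fold(tr, te, spec, seed_f, f)
            except Exception as exc:
                raise RuntimeError(f"stage {stage} fold {f} failed: {exc}") from exc
            results.append(fr)
            if stage < cfg.stages and not cfg.leaky:
                stage_fsets.append(_select_for_fold(model, tr, cfg, seed_f))
            logger.info("stage %d fold %d: acc %.3f kappa %.3f",
                        stage, f, fr.accuracy, fr.kappa)
        if stage < cfg.stages and cfg.leaky:
            # explicit faithfulness mode: one selection over all trials
            _, model_all = run_fold(eset, eset, spec, fold_seed(cfg.seed, 999), -1)
            leaky_fset = _select_for_fold(model_all, eset, cfg, cfg.seed)
            stage_fsets = [leaky_fset] * len(fold_data)
        fold_fsets.append(stage_fsets)

        freq_union = sorted({f for fs in (fold_fsets[stage - 2] if stage > 1 else [])
                             for f in fs}) if stage > 1 else []
        report = _report_from_folds(results, eset[0].subject_id, stage, freq_union)
        reports.append(report)
        if out:
            _report_to_disk(report, report_path)
            if stage < cfg.stages:
                _write_json(fsets_path, [json.loads(fs.to_json()) for fs in stage_fsets])
            manifest["completed_stages"] = sorted(set(manifest["completed_stages"]) | {stage})
            manifest["reports"][str(stage)] = os.path.basename(report_path)
            _write_json(manifest_path, manifest)

    stage1 = reports[0]
    if cfg.stages == 1:
        return stage1, None, None
    last = reports[-1]
    comparison = paired_ttest(last.fold_accuracies, stage1.fold_accuracies)
    if out:
        _write_json(os.path.join(out, "comparison.json"), dataclasses.asdict(comparison))
    return stage1, last, comparison


def resume(output_dir: str, cfg: RunConfig):
    """Re-run a directory's configured pipeline, skipping completed stages."""
    manifest_path = os.path.join(output_dir, "manifest.json")
    if not os.path.exists(manifest_path):
        raise ResumeError(f"no manifest in {output_dir}")
    cfg = dataclasses.replace(cfg, output_dir=output_dir)
    return run_two_stage(cfg, allow_resume=True)
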