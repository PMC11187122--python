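"""End-to-end experiment orchestration.

``run_experiment`` drives the full study on synthetic patients: simulate
source corpus and target patients -> preprocess -> DCAE pretraining on
the source corpus -> per-patient standard and transfer fits (n_repeats
each) -> per-window prediction on the test segments -> firing-power
alarms -> SS / FPR/h / surrogate validation -> paired comparison of the
two approaches.  Every stage is seeded from ``ExperimentConfig.seed``
and all artefacts (per-patient JSON reports, comparison CSV, loss
curves, the DCAE weight bundle) carry the config hash.

The experiment "scale" — recording lengths, network widths, epoch
counts — lives entirely in the config; the scientific structure (three
leading seizures >= 4.5 h apart, 40-min preictal, 10-s windows at
256 Hz) is fixed by the task definition.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .alarms import PredictionSeries, firing_power, trigger_alarms
from .annotate import (
    HorizonConfig,
    SeizureAnnotation,
    chronological_split,
    label_windows,
    select_leading_seizures,
)
from .evaluate import (
    PatientReport,
    SurrogateConfig,
    compare_approaches,
    evaluate_patient,
    interictal_hours,
)
from .models import DCAEConfig, PredictorConfig, encoder_bundle
from .preprocess import (
    Recording,
    compute_norm_stats,
    filter_eeg,
    reject_artifacts,
    resample,
    segment,
    standardize,
    NormStats,
    TARGET_FS,
)
from .synthetic import SimSpec, generate_recording
from .train import (
    TrainProtocol,
    dcae_protocol,
    predictor_protocol,
    train_dcae,
    train_predictor_repeats,
)

__all__ = ["ExperimentConfig", "run_experiment", "preprocess_recording", "predict_series"]


@dataclass
class ExperimentConfig:
    """Everything needed to rerun one experiment."""

    out_dir: str = "results"
    seed: int = 0
    n_patients: int = 2
    #: source-corpus recordings for DCAE pretraining (no seizures needed)
    source_duration: float = 1800.0
    n_source_recordings: int = 2
    #: per-patient simulation
    patient_duration: float = 15.5 * 3600.0
    seizure_onsets: tuple[float, ...] = (5.0 * 3600.0, 10.0 * 3600.0, 15.0 * 3600.0)
    signature_strength: float = 2.0
    artifact_rate: float = 2.0
    #: architecture / training scale
    dcae: DCAEConfig = field(default_factory=DCAEConfig)
    bilstm_units: int = 64
    dcae_epochs: int = 2000
    dcae_patience: int = 200
    dcae_batch: int = 2048
    predictor_epochs: int = 500
    predictor_patience: int = 50
    n_repeats: int = 5
    max_interictal_per_seizure: int | None = None
    #: task timing and validation
    horizon: HorizonConfig = field(default_factory=HorizonConfig)
    surrogate: SurrogateConfig = field(default_factory=SurrogateConfig)
    fp_threshold: float = 0.5
    modes: tuple[str, ...] = ("standard", "transfer")
    make_plots: bool = True

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:12]

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        if "dcae" in d and isinstance(d["dcae"], dict):
            for key in ("enc_filters", "strides", "dec_filters", "upsample_factors"):
                if key in d["dcae"]:
                    d["dcae"][key] = tuple(d["dcae"][key])
            d["dcae"] = DCAEConfig(**d["dcae"])
        if "horizon" in d and isinstance(d["horizon"], dict):
            d["horizon"] = HorizonConfig(**d["horizon"])
        if "surrogate" in d and isinstance(d["surrogate"], dict):
            d["surrogate"] = SurrogateConfig(**d["surrogate"])
        for key in ("seizure_onsets", "modes"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path: str | Path) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def preprocess_recording(rec: Recording, amp_thresh: float = 300.0) -> Recording:
    """Standard conditioning: resample to 256 Hz, band-pass 0.5-100 Hz +
    50 Hz notch, amplitude-based artifact masking."""
    rec = resample(rec, TARGET_FS)
    rec = filter_eeg(rec, copy=False)
    return reject_artifacts(rec, amp_thresh=amp_thresh)


def predict_series(model, ws, stats: NormStats, lo: float, hi: float) -> PredictionSeries:
    """Classifier outputs for the valid windows of one test segment."""
    sel = (ws.start_times >= lo) & (ws.start_times + ws.window_seconds <= hi)
    idx = np.flatnonzero(sel)
    valid = ws.valid[idx]
    times = ws.start_times[idx]
    o = np.zeros(len(idx))
    vidx = idx[valid]
    if len(vidx):
        X = (ws.windows[vidx] - stats.mean.astype(np.float32)[None, :, None]) / stats.sd.astype(
            np.float32
        )[None, :, None]
        o[valid] = model.predict_proba(X)[:, 1]
    return PredictionSeries(times=times, o=o, valid=valid)


def _simulate_source_windows(cfg: ExperimentConfig, rng: np.random.Generator):
    """Source-corpus windows pooled over several seizure-free recordings."""
    all_windows = []
    for i in range(cfg.n_source_recordings):
        spec = SimSpec(
            duration=cfg.source_duration,
            n_channels=cfg.dcae.n_channels,
            artifact_rate=cfg.artifact_rate,
            seed=int(rng.integers(2**31)),
        )
        ds = generate_recording(spec)
        rec = preprocess_recording(ds.recording)
        ws = segment(rec)
        all_windows.append(ws.windows[ws.valid])
    X = np.concatenate(all_windows, axis=0).astype(np.float32)
    from .preprocess import WindowSet

    pooled = WindowSet(
        windows=X,
        start_times=np.arange(len(X)) * 10.0,
        valid=np.ones(len(X), dtype=bool),
    )
    stats = compute_norm_stats(pooled, source="source_corpus")
    return standardize(pooled, stats).windows, stats


def _patient_spec(cfg: ExperimentConfig, patient_seed: int) -> SimSpec:
    return SimSpec(
        duration=cfg.patient_duration,
        n_channels=cfg.dcae.n_channels,
        seizure_onsets=cfg.seizure_onsets,
        preictal_len=cfg.horizon.preictal_s,
        signature_strength=cfg.signature_strength,
        artifact_rate=cfg.artifact_rate,
        seed=patient_seed,
    )


def run_patient(
    cfg: ExperimentConfig,
    patient_seed: int,
    source_stats: NormStats,
    dcae_bundle,
    rec: Recording | None = None,
    ann: SeizureAnnotation | None = None,
) -> dict[str, PatientReport]:
    """Fit and evaluate both approaches for one patient; returns one
    report per mode."""
    if rec is None:
        ds = generate_recording(_patient_spec(cfg, patient_seed))
        rec, ann = preprocess_recording(ds.recording), ds.annotations
    leading = select_leading_seizures(ann, cfg.horizon)
    ws = segment(rec)
    lw = label_windows(ws, leading, cfg.horizon)
    plan = chronological_split(
        leading,
        lw,
        cfg.horizon,
        seed=patient_seed,
        max_interictal_per_seizure=cfg.max_interictal_per_seizure,
    )

    patient_stats_src = ws.windows[plan.train_idx]
    from .preprocess import WindowSet

    train_ws = WindowSet(
        windows=patient_stats_src,
        start_times=ws.start_times[plan.train_idx],
        valid=np.ones(len(plan.train_idx), dtype=bool),
    )
    patient_stats = compute_norm_stats(train_ws, source=f"patient{patient_seed}_train")

    test_onsets = leading.onsets[plan.test_seizures]
    reports: dict[str, PatientReport] = {}
    for mode in cfg.modes:
        stats = source_stats if mode == "transfer" else patient_stats
        mu = stats.mean.astype(np.float32)[None, :, None]
        sd = stats.sd.astype(np.float32)[None, :, None]
        Xtr = (ws.windows[plan.train_idx] - mu) / sd
        Xva = (ws.windows[plan.val_idx] - mu) / sd
        proto = predictor_protocol(
            mode,
            max_epochs=cfg.predictor_epochs,
            patience=cfg.predictor_patience,
            n_repeats=cfg.n_repeats,
            seed=patient_seed,
        )
        pcfg = PredictorConfig(encoder=cfg.dcae, bilstm_units=cfg.bilstm_units)
        fits = train_predictor_repeats(
            Xtr,
            plan.train_labels,
            Xva,
            plan.val_labels,
            proto,
            pcfg=pcfg,
            dcae_bundle=dcae_bundle if mode == "transfer" else None,
        )
        alarm_sets = []
        inter_h = None
        for model, _fit in fits:
            rep_alarms = []
            for (lo, hi) in plan.test_segments:
                ps = predict_series(model, ws, stats, lo, hi)
                fps = firing_power(ps, cfg.horizon)
                rep_alarms.extend(trigger_alarms(fps, cfg.fp_threshold, cfg.horizon))
            alarm_sets.append(rep_alarms)
            if inter_h is None:
                seg_mask = np.zeros(len(ws), dtype=bool)
                for (lo, hi) in plan.test_segments:
                    seg_mask |= (ws.start_times >= lo) & (
                        ws.start_times + ws.window_seconds <= hi
                    )
                inter_h = interictal_hours(
                    ws.start_times[seg_mask],
                    ws.valid[seg_mask],
                    test_onsets,
                    cfg.horizon,
                )
        scfg = dataclasses.replace(cfg.surrogate, seed=patient_seed + 17)
        reports[mode] = evaluate_patient(
            patient_id=leading.patient_id,
            mode=mode,
            alarm_sets=alarm_sets,
            onsets=test_onsets,
            test_segments=plan.test_segments,
            interictal_h=inter_h,
            cfg=cfg.horizon,
            scfg=scfg,
        )
        reports[mode].fits = fits  # loss curves for plotting
    return reports


def run_experiment(cfg: ExperimentConfig) -> dict:
    """Run the full study and write all report files under ``cfg.out_dir``.

    Returns a summary dict (also written as ``summary.json``).
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = cfg.config_hash()
    rng = np.random.default_rng(cfg.seed)
    t_start = time.time()
    cfg.to_yaml(out / "config.yaml")

    stage = "dcae_pretraining"
    try:
        X_source, source_stats = _simulate_source_windows(cfg, rng)
        proto = dcae_protocol(
            max_epochs=cfg.dcae_epochs,
            patience=cfg.dcae_patience,
            batch_size=cfg.dcae_batch,
            seed=cfg.seed,
        )
        dcae, dcae_fit = train_dcae(X_source, proto, cfg.dcae)
        bundle = encoder_bundle(
            dcae, provenance={"source": "synthetic_corpus", "config_hash": chash}
        )
        bundle.save(out / "dcae_encoder.ictw")
        np.savetxt(
            out / "dcae_loss.csv",
            np.column_stack([dcae_fit.train_loss, dcae_fit.val_loss]),
            delimiter=",",
            header="train_mse,val_mse",
            comments="",
        )

        stage = "patients"
        patient_rows = []
        all_reports: dict[str, list[PatientReport]] = {m: [] for m in cfg.modes}
        for p in range(cfg.n_patients):
            patient_seed = int(rng.integers(2**31))
            reports = run_patient(cfg, patient_seed, source_stats, bundle)
            for mode, rep in reports.items():
                all_reports[mode].append(rep)
                row = rep.to_dict()
                row["config_hash"] = chash
                patient_rows.append(row)
                with open(out / f"patient{p}_{mode}.json", "w") as fh:
                    json.dump(row, fh, indent=2)
            if cfg.make_plots:
                _plot_losses(reports, out / f"patient{p}_losses.png")

        stage = "comparison"
        summary = _summarise(cfg, all_reports, chash)
        summary["runtime_s"] = time.time() - t_start
        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2)
        pd.DataFrame(summary["table"]).to_csv(out / "comparison.csv", index=False)
        return summary
    except Exception as exc:  # pragma: no cover - error path
        raise RuntimeError(f"experiment failed during stage '{stage}': {exc}") from exc


def desk_scale_config(seed: int = 0, **overrides) -> ExperimentConfig:
    """The reduced-scale experiment used for desk runs and smoke checks.

    Task structure is untouched (19 channels at 256 Hz, three leading
    seizures 4.5-5 h apart, SOP 30 / SPH 10 min, 10-s windows); network
    width, epoch counts and the interictal subsample are shrunk so a full
    run fits on one CPU in minutes.
    """
    base = dict(
        seed=seed,
        n_patients=1,
        source_duration=600.0,
        n_source_recordings=2,
        patient_duration=14.0 * 3600.0,
        seizure_onsets=(4.6 * 3600.0, 9.2 * 3600.0, 13.8 * 3600.0),
        signature_strength=2.0,
        artifact_rate=2.0,
        dcae=DCAEConfig(enc_filters=(8, 8, 16, 16, 32, 32), dec_filters=(16, 8)),
        bilstm_units=24,
        dcae_epochs=6,
        dcae_patience=5,
        dcae_batch=32,
        predictor_epochs=500,
        predictor_patience=499,
        n_repeats=2,
        max_interictal_per_seizure=200,
        make_plots=False,
    )
    base.update(overrides)
    return ExperimentConfig(**base)


def transfer_smoke_run(
    seed: int, n_seeds: int = 3, cfg: ExperimentConfig | None = None
) -> list[dict]:
    """Transfer-mode pipeline on one synthetic patient: one pretrained
    DCAE (as in the study design, the source-corpus autoencoder is
    trained once), then ``n_seeds`` independent patient-specific fits.

    Returns one dict per fit seed with the held-out-seizure SS and FPR/h.
    The patient carries a strength-2 alpha-band preictal signature, so a
    working pipeline should raise a correctly timed alarm for the test
    seizure in most seeds.
    """
    cfg = cfg or desk_scale_config(seed, modes=("transfer",))
    rng = np.random.default_rng(seed)
    ds = generate_recording(_patient_spec(cfg, int(rng.integers(2**31))))
    rec, ann = ds.recording, ds.annotations
    rec = preprocess_recording(rec)
    X_source, source_stats = _simulate_source_windows(cfg, rng)
    proto = dcae_protocol(
        max_epochs=cfg.dcae_epochs,
        patience=cfg.dcae_patience,
        batch_size=cfg.dcae_batch,
        seed=int(rng.integers(2**31)),
    )
    dcae, _ = train_dcae(X_source, proto, cfg.dcae)
    bundle = encoder_bundle(dcae, provenance={"source": "synthetic_corpus"})
    results = []
    for s in range(n_seeds):
        run_seed = int(rng.integers(2**31))
        run_cfg = dataclasses.replace(cfg, seed=run_seed, modes=("transfer",))
        reports = run_patient(run_cfg, run_seed, source_stats, bundle, rec=rec, ann=ann)
        rep = reports["transfer"]
        results.append(
            {"seed": run_seed, "ss": rep.mean_ss, "fpr_h": rep.mean_fpr_h,
             "above_chance": rep.above_chance}
        )
    return results


def _summarise(cfg, all_reports: dict[str, list[PatientReport]], chash: str) -> dict:
    table = []
    for mode, reps in all_reports.items():
        ss = np.array([r.mean_ss for r in reps])
        fpr = np.array([r.mean_fpr_h for r in reps])
        table.append(
            {
                "approach": mode,
                "mean_ss": float(ss.mean()),
                "sd_ss": float(ss.std(ddof=1)) if len(ss) > 1 else 0.0,
                "mean_fpr_h": float(fpr.mean()),
                "sd_fpr_h": float(fpr.std(ddof=1)) if len(fpr) > 1 else 0.0,
                "n_above_chance": int(sum(r.above_chance for r in reps)),
                "n_patients": len(reps),
                "config_hash": chash,
            }
        )
    summary = {"config_hash": chash, "table": table, "wilcoxon": {}}
    if set(cfg.modes) >= {"standard", "transfer"}:
        std = all_reports["standard"]
        tra = all_reports["transfer"]
        if len(std) >= 5:
            summary["wilcoxon"]["ss_transfer_gt_standard"] = compare_approaches(
                np.array([r.mean_ss for r in tra]),
                np.array([r.mean_ss for r in std]),
                alternative="greater",
            )
            summary["wilcoxon"]["fpr_transfer_lt_standard"] = compare_approaches(
                np.array([r.mean_fpr_h for r in tra]),
                np.array([r.mean_fpr_h for r in std]),
                alternative="less",
            )
        else:
            warnings.warn(
                "fewer than 5 patients: Wilcoxon comparison skipped", stacklevel=2
            )
    return summary


def _plot_losses(reports: dict[str, PatientReport], path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    colors = {"standard": "k", "transfer": "tab:blue"}
    for mode, rep in reports.items():
        fits = getattr(rep, "fits", None)
        if not fits:
            continue
        _, fit = fits[0]
        ax.plot(fit.train_loss, color=colors.get(mode, "gray"), label=f"{mode} train")
        ax.plot(
            fit.val_loss, color=colors.get(mode, "gray"), linestyle="--", label=f"{mode} val"
        )
    ax.set_xlabel("epoch")
    ax.set_ylabel("cross-entropy")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
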