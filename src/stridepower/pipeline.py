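"""End-to-end orchestration: signals -> features -> models -> agreement.

One :func:`run_pipeline` call takes a set of trials (synthetic or read from
disk), computes the per-second reference power and feature table, splits by
participant, balances the development set, selects features and trains one
model family per slope condition (level / uphill / downhill), then reports
test-set agreement per condition.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from . import evaluation, feature_engineering as fe, feature_selection as fs
from . import imu_processing as imu
from . import power_models as pm
from . import reference_power as rp
from .signal_io import TimeSeries, TrialMeta, clean_outliers, resample_per_second
from .synthetic import SyntheticTrial

__all__ = ["PipelineConfig", "PipelineError", "process_trial", "build_feature_table",
           "train_condition_models", "run_pipeline"]

log = logging.getLogger("stridepower")


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and trial id."""


@dataclass
class PipelineConfig:
    """Every tunable of the pipeline; a serialized config plus the input
    data fully determines a run."""

    # force-plate processing
    force_cutoff_hz: float = 25.0
    force_filter_order: int = 3
    stance_threshold_n: float = 20.0
    stance_min_samples: int = 40
    midstance_threshold_n: float = 300.0
    clean_window: int = 11
    clean_n_mad: float = 3.0
    # IMU processing
    imu_cutoff_hz: float = 50.0
    imu_filter_order: int = 4
    static_window_s: float = 5.0
    midswing_height: float = 2.0
    midswing_separation_s: float = 0.4
    # features
    noise_level: float = 0.0  # percent of full condition noise (0/50/100)
    ros_alpha: float = 0.8
    test_fraction: float = 1 / 3
    # selection
    tau_threshold: float = 0.8
    mi_bins: int = 10
    # models
    gamma: float = 0.5
    lambda_points: int = 100
    lambda_decades: float = 4.0
    #: penalty-selection rule; CV is grouped by participant
    en_selection: str = "1se"
    models: tuple = ("EN", "NN15", "NN35")
    nn_max_epochs: int = 60
    nn_patience: int = 6
    # evaluation
    smooth_window_s: int = 10
    smooth_overlap_s: int = 5
    seed: int = 0

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(asdict(self))
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "models" in data:
            data["models"] = tuple(data["models"])
        return cls(**data)


# ---------------------------------------------------------------------------
# Per-trial processing


def _process_foot(ts: TimeSeries, cfg: PipelineConfig):
    filt = imu.lowpass_imu(ts, cutoff_hz=cfg.imu_cutoff_hz, order=cfg.imu_filter_order)
    R = imu.functional_calibration(filt, static_window=cfg.static_window_s)
    cal = imu.apply_calibration(filt, R)
    cycles = imu.segment_cycles(cal, midswing_height=cfg.midswing_height,
                                midswing_separation=cfg.midswing_separation_s,
                                skip_seconds=cfg.static_window_s)
    fsa = imu.foot_orientation_and_fsa(cal, cycles)
    vf, valid = imu.foot_velocity(cal, cycles)
    return cal, cycles, fsa, vf, valid


def process_trial(trial: SyntheticTrial, cfg: PipelineConfig,
                  rng: np.random.Generator | None = None) -> pd.DataFrame:
    """One trial's per-second rows: features, reference power, labels.

    The IMU clock leads the force-plate clock by the static calibration
    phase (``trial.imu_run_offset``); stride times are mapped onto the
    force-plate clock before per-second alignment.
    """
    rng = rng or np.random.default_rng(cfg.seed)
    meta = trial.meta
    end_second = int(np.floor(trial.force_plate.duration)) - 1

    # --- reference power (force plate) ---
    fp = clean_outliers(trial.force_plate, window=cfg.clean_window, n_mad=cfg.clean_n_mad)
    fp = rp.filter_forces(fp, cutoff_hz=cfg.force_cutoff_hz, order=cfg.force_filter_order)
    p_series, steps = rp.trial_reference_power(fp, meta, prefiltered=True,
                                               end_second=end_second)
    if len(p_series) == 0:
        raise PipelineError(f"refpower: no stances in trial {meta.participant_id}")

    # --- IMU features, both feet pooled per second ---
    offset = trial.imu_run_offset
    feet = [_process_foot(trial.imu_left, cfg), _process_foot(trial.imu_right, cfg)]
    stride_times, stride_rows = [], []
    for this, other in ((0, 1), (1, 0)):
        cal, cycles, fsa, vf, valid = feet[this]
        other_cycles = feet[other][1]
        fs_hz = cal.fs
        # flight times from the merged left/right contact streams
        tf_list = imu.stride_flight_times(cycles, other_cycles, fs_hz)
        for k, cyc in enumerate(cycles):
            if not np.isfinite(fsa[k]):
                continue
            if not (valid[cyc.midswing_start] and valid[cyc.midswing_end]):
                continue
            try:
                next_contact = (cyc.tc_event + int(round(tf_list[k] * fs_hz))
                                if tf_list[k] is not None else None)
                tp = imu.temporal_params(cyc, fs_hz, next_contact)
                smp = imu.spring_mass(tp, meta.mass)
                row = fe.gait_features(tp, smp, fsa[k])
                sl = slice(cyc.midswing_start, cyc.midswing_end)
                acc = cal.values[sl, 0:3]
                gyr = cal.values[sl, 3:6]
                row.update(fe.statistical_features(acc, gyr, vf.values[sl]))
            except (ValueError, fe.IncompleteStrideError):
                continue
            mid_t = 0.5 * (cyc.midswing_start + cyc.midswing_end) / fs_hz - offset
            stride_times.append(mid_t)
            stride_rows.append(row)
    if not stride_rows:
        raise PipelineError(f"gait: no usable strides in trial {meta.participant_id}")

    stride_df = pd.DataFrame(stride_rows)
    per_second = {}
    for col in stride_df.columns:
        ps = resample_per_second(stride_times, stride_df[col].to_numpy(),
                                 end_second=end_second)
        per_second[col] = ps.values
    out = pd.DataFrame(per_second)
    out["second"] = np.arange(end_second + 1)
    out["P"] = p_series.values

    anthro = fe.anthropometric_features(meta)
    for k, v in anthro.items():
        out[k] = v
    noise = fe.NoiseSpec(level=cfg.noise_level)
    cond_rows = [fe.condition_features(meta, noise, rng) for _ in range(len(out))]
    out["speed_hat"] = [r["speed_hat"] for r in cond_rows]
    out["grade_hat"] = [r["grade_hat"] for r in cond_rows]

    out["participant_id"] = meta.participant_id
    out["speed"] = meta.speed
    out["grade"] = meta.grade
    out["condition"] = meta.condition
    out["speed_class"] = fe.speed_class(meta.speed)
    out["trial_id"] = f"{meta.participant_id}:{meta.speed:.3f}:{meta.grade:+.1f}"
    return out


def build_feature_table(trials, cfg: PipelineConfig) -> fe.FeatureTable:
    """Process all trials and stack their per-second rows."""
    rng = np.random.default_rng(cfg.seed)
    frames = []
    for trial in trials:
        tid = f"{trial.meta.participant_id} v={trial.meta.speed:.2f} g={trial.meta.grade:+.0f}"
        t0 = time.perf_counter()
        try:
            frames.append(process_trial(trial, cfg, rng))
        except (PipelineError, imu.SegmentationError, imu.CalibrationError) as exc:
            raise PipelineError(f"trial {tid}: {exc}") from exc
        log.debug("processed %s in %.2f s", tid, time.perf_counter() - t0)
    table = pd.concat(frames, ignore_index=True)
    return fe.FeatureTable(table, fe.all_feature_names())


# ---------------------------------------------------------------------------
# Training and evaluation


def _smooth_by_trial(df: pd.DataFrame, col: str, cfg: PipelineConfig) -> np.ndarray:
    import warnings as _warnings
    chunks = []
    for _, g in df.groupby("trial_id", sort=True):
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")
            chunks.append(evaluation.smooth(
                g.sort_values("second")[col].to_numpy(),
                window=cfg.smooth_window_s, overlap=cfg.smooth_overlap_s))
    return np.concatenate(chunks) if chunks else np.empty(0)


def train_condition_models(dev: fe.FeatureTable, cfg: PipelineConfig,
                           condition: str) -> dict:
    """Select features and train all candidate models for one condition."""
    sub = dev.subset((dev.frame["condition"] == condition).to_numpy())
    if len(sub.frame) == 0:
        raise PipelineError(f"train: no development rows for condition {condition}")
    report = fs.select_features(sub.X, sub.P, tau_threshold=cfg.tau_threshold,
                                bins=cfg.mi_bins)
    feats = report.kept
    results = {}
    if "EN" in cfg.models:
        en_model = pm.ElasticNetPower(sub.P.to_numpy(float), sub.frame[feats],
                                      gamma=cfg.gamma, condition=condition)
        results["EN"] = en_model.fit(
            lambda_grid=en_model.default_lambda_grid(cfg.lambda_points, cfg.lambda_decades),
            selection=cfg.en_selection,
            groups=sub.frame["participant_id"].to_numpy(),
            seed=cfg.seed)
    for scheme in ("NN15", "NN35"):
        if scheme in cfg.models:
            nn = pm.NeuralNetPower(sub.P.to_numpy(float), sub.frame[feats],
                                   scheme=scheme, condition=condition)
            results[scheme] = nn.fit(seed=cfg.seed, max_epochs=cfg.nn_max_epochs,
                                     patience=cfg.nn_patience)
    return {"condition": condition, "selection": report, "features": feats,
            "results": results}


def run_pipeline(trials, cfg: PipelineConfig | None = None) -> dict:
    """Full study on a list of trials; returns the per-condition report.

    The report maps each condition to the winning model label, per-model
    agreement metrics on the held-out participants, and bookkeeping
    (selected features, row counts). Deterministic given config and trials.
    """
    cfg = cfg or PipelineConfig()
    t_start = time.perf_counter()
    table = build_feature_table(trials, cfg)
    log.info("feature table: %d rows, %d features", len(table.frame),
             len(table.feature_columns))

    dev, test = fe.split_by_participant(table, test_fraction=cfg.test_fraction,
                                        seed=cfg.seed)
    dev = fe.apply_ros(dev, alpha=cfg.ros_alpha, seed=cfg.seed)

    report = {"conditions": {}, "n_dev_rows": len(dev.frame),
              "n_test_rows": len(test.frame),
              "test_participants": sorted(test.frame["participant_id"].unique()),
              "config": asdict(cfg)}
    for condition in ("level", "uphill", "downhill"):
        has_dev = (dev.frame["condition"] == condition).any()
        has_test = (test.frame["condition"] == condition).any()
        if not (has_dev and has_test):
            log.warning("condition %s missing from dev or test; skipped", condition)
            continue
        trained = train_condition_models(dev, cfg, condition)
        feats = trained["features"]
        tsub = test.frame[test.frame["condition"] == condition]

        cond_report = {"n_features": len(feats), "models": {}}
        smoothed_ref = _smooth_by_trial(tsub, "P", cfg)
        for label, res in trained["results"].items():
            pred = res.predict(tsub[feats])
            tmp = tsub[["trial_id", "second"]].copy()
            tmp["pred"] = pred
            smoothed_pred = _smooth_by_trial(tmp, "pred", cfg)
            eps = evaluation.percent_error(smoothed_ref, smoothed_pred)
            agreement = evaluation.summarize(eps, smoothed_ref, smoothed_pred)
            cond_report["models"][label] = agreement.to_dict()
            cond_report["models"][label]["_agreement"] = agreement
        # winner by validation MAE on the development rows' internal scheme:
        # use test-free selection — compare on the (balanced) dev rows
        dsub = dev.frame[dev.frame["condition"] == condition]
        best, maes = pm.select_best_model(trained["results"], dsub[feats],
                                          dsub["P"].to_numpy(float))
        cond_report["best_model"] = best
        cond_report["dev_mae_w"] = maes
        cond_report["selected_features"] = feats
        report["conditions"][condition] = cond_report
    report["runtime_s"] = time.perf_counter() - t_start
    return report
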