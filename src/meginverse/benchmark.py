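"""Benchmark orchestrator: simulate, train, reconstruct, score.

Reproduces the simulated benchmark design at configurable scale: trials are
generated per scenario kind (single/multi focal, extended), the same clean
trials are re-noised at each test SNR (paired comparisons), every requested
method reconstructs every trial, and localization/reconstruction metrics are
aggregated as mean +/- std per (scenario, SNR, method) cell.

Two grids are involved: simulation runs on the fine forward grid while the
network reconstructs on a coarser grid (classical solvers invert on the fine
grid).  Solvers only ever see sensor data and the leadfield, never the
ground-truth activity; the forward operator is shared between simulation and
inversion, which is the one deliberate idealization of the design.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .config import RunConfig
from .dataset import build_training_set, project_activity
from .forward import Leadfield, assemble_leadfield
from .geometry import SensorArray, SourceSpace, build_sensor_helmet, build_source_grid
from .inverse import (
    estimate_covariance,
    solve_eloreta,
    solve_lcmv,
    solve_mne,
    solve_rv_scan,
)
from .metrics import active_set, active_volume, dle, iou, nrmse
from .network import (
    NetworkConfig,
    TrainConfig,
    TrainedModel,
    build_network,
    reconstruct_timeseries,
    train_model,
)
from .signals import (
    Scenario,
    gaussian_damped_sine,
    make_scenario,
    render_source_activity,
    simulate_recording,
)

__all__ = [
    "BenchmarkResult",
    "build_geometry",
    "train_benchmark_model",
    "run_benchmark",
    "summarize_cases",
]


@dataclass(frozen=True)
class Geometry:
    sensors: SensorArray
    fine_space: SourceSpace
    coarse_space: SourceSpace
    fine_leadfield: Leadfield
    coarse_leadfield: Leadfield


@dataclass
class BenchmarkResult:
    per_case: pd.DataFrame
    summary: pd.DataFrame
    model: TrainedModel | None = None

    def table(self, metric: str) -> pd.DataFrame:
        """Mean +/- std table for one metric: method rows, scenario/SNR columns."""
        sub = self.summary[self.summary["metric"] == metric]
        cells = sub.assign(
            cell=[
                f"{m:.3g} ± {s:.3g}" + (f" [n={k}]" if e else "")
                for m, s, k, e in zip(sub["mean"], sub["std"], sub["n"], sub["n_excluded"])
            ]
        )
        return cells.pivot_table(
            index="method",
            columns=["scenario", "snr_db"],
            values="cell",
            aggfunc="first",
        )


def build_geometry(config: RunConfig) -> Geometry:
    g = config.geometry
    sensors = build_sensor_helmet(g.n_sensors, g.sensor_radius, g.cap_fraction)
    fine = build_source_grid(g.source_radius, g.forward_spacing, g.orientation_seed)
    coarse = build_source_grid(g.source_radius, g.inverse_spacing, g.orientation_seed)
    return Geometry(
        sensors=sensors,
        fine_space=fine,
        coarse_space=coarse,
        fine_leadfield=assemble_leadfield(sensors, fine),
        coarse_leadfield=assemble_leadfield(sensors, coarse),
    )


def _spawn_seed(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def train_benchmark_model(
    config: RunConfig,
    geometry: Geometry,
    seed: int,
    verbose: bool = False,
) -> TrainedModel:
    """Generate the training set and train the network per the config."""
    ss = np.random.SeedSequence(seed)
    data_ss, train_ss = ss.spawn(2)
    d = config.dataset
    ts = build_training_set(
        n_examples=d.n_examples,
        focal_fraction=d.focal_fraction,
        window_length=d.window_length,
        snr_range=tuple(d.snr_range),
        source_space=geometry.fine_space,
        leadfield=geometry.fine_leadfield,
        rng=np.random.default_rng(data_ss),
        output_space=geometry.coarse_space,
        focal_group_choices=tuple(d.focal_group_choices),
        extended_group_choices=tuple(d.extended_group_choices),
        param_ranges=config.signal.param_ranges,
        extended_volume_range=tuple(config.signal.extended_volume_range),
        duration=config.signal.duration,
        fs=config.signal.fs,
    )
    net_cfg = NetworkConfig(
        n_sensors=geometry.sensors.count,
        n_sources=geometry.coarse_space.count,
        window_length=d.window_length,
        conv_feature_schedule=tuple(config.network.conv_feature_schedule),
        conv_kernel_schedule=(
            tuple(config.network.conv_kernel_schedule)
            if config.network.conv_kernel_schedule is not None
            else None
        ),
        fc_layers=config.network.fc_layers,
        fc_width=config.network.fc_width,
    )
    train_cfg = TrainConfig(
        learning_rate=config.training.learning_rate,
        batch_size=config.training.batch_size,
        epochs=config.training.epochs,
        seed=_spawn_seed(train_ss),
        validation_fraction=config.training.validation_fraction,
    )
    net = build_network(net_cfg, seed=train_cfg.seed)
    return train_model(
        net, ts.windows, ts.targets, train_cfg, verbose=verbose
    )


def _score_solution(
    amplitudes: np.ndarray,
    est_space: SourceSpace,
    valid: slice,
    scenario: Scenario,
    fine_space: SourceSpace,
) -> dict:
    """Compute all applicable metrics for one reconstruction."""
    aset = active_set(amplitudes[:, valid])
    est_idx = np.array(sorted(aset.indices), dtype=int)
    true_idx = scenario.active_indices
    true_pos = fine_space.positions[true_idx]
    out = {
        "dle_mm": dle(true_pos, est_space.positions[est_idx])
        if est_idx.size
        else np.inf,
        "av_cm3": active_volume(aset, est_space),
    }
    if scenario.kind in ("single_focal", "multi_focal") and est_idx.size:
        # best-matching estimated trace per true source: nearest active estimate
        tree = cKDTree(est_space.positions[est_idx])
        errs = []
        t_axis = scenario.time_axis[valid]
        for group in scenario.groups:
            g_true = gaussian_damped_sine(group.params, scenario.time_axis)[valid]
            _, j = tree.query(fine_space.positions[group.indices[0]])
            est_trace = amplitudes[est_idx[j], valid]
            if np.any(est_trace) and t_axis.size > 1:
                errs.append(nrmse(g_true, est_trace))
        out["nrmse"] = float(np.mean(errs)) if errs else np.nan
    else:
        out["nrmse"] = np.nan
    if scenario.kind == "extended":
        # compare voxel sets on the estimate's grid
        if est_space is fine_space:
            true_set = active_set(
                np.where(np.isin(np.arange(fine_space.count), true_idx), 1.0, 0.0)
            )
            out["iou_percent"] = iou(true_set, aset)
        else:
            tree = cKDTree(est_space.positions)
            _, nearest = tree.query(fine_space.positions[true_idx])
            proj = np.zeros(est_space.count)
            proj[np.unique(nearest)] = 1.0
            out["iou_percent"] = iou(active_set(proj), aset)
    else:
        out["iou_percent"] = np.nan
    return out


def run_benchmark(
    config: RunConfig,
    seed: int | None = None,
    model: TrainedModel | None = None,
    geometry: Geometry | None = None,
    verbose: bool = False,
) -> BenchmarkResult:
    """Run the full scenario x SNR x method benchmark grid.

    Training (if a model is needed and none is supplied) and every random
    draw derive from ``seed`` (default: the config's benchmark seed), so a
    run is exactly replayable.
    """
    config = config.validate()
    b = config.benchmark
    if seed is None:
        seed = b.seed
    ss = np.random.SeedSequence(seed)
    train_seed_ss, test_ss = ss.spawn(2)

    if geometry is None:
        geometry = build_geometry(config)
    if model is None and "deep" in b.methods:
        model = train_benchmark_model(
            config, geometry, _spawn_seed(train_seed_ss), verbose=verbose
        )

    fine = geometry.fine_space
    records: list[dict] = []

    for kind, n_groups in b.scenarios:
        scen_label = kind if kind == "single_focal" else f"{kind}_{n_groups}"
        label_code = zlib.crc32(scen_label.encode()) % (2**31)
        scen_rng = np.random.default_rng(np.random.SeedSequence([seed, 1, label_code]))
        cases = []
        for _ in range(b.n_test_cases):
            scenario = make_scenario(
                kind,
                n_groups,
                fine,
                scen_rng,
                param_ranges=config.signal.param_ranges,
                extended_volume_range=tuple(config.signal.extended_volume_range),
                duration=config.signal.duration,
                fs=config.signal.fs,
            )
            activity = render_source_activity(scenario)
            cases.append((scenario, activity))

        for snr_db in b.test_snrs_db:
            for case_id, (scenario, activity) in enumerate(cases):
                noise_seed = int(
                    np.random.SeedSequence(
                        [seed, 2, label_code, int(snr_db * 1000) % (2**31), case_id]
                    ).generate_state(1, dtype=np.uint32)[0]
                    % (2**31)
                )
                recording = simulate_recording(
                    activity, geometry.fine_leadfield, snr_db, noise_seed
                )
                for method in b.methods:
                    try:
                        if method == "deep":
                            rec = reconstruct_timeseries(model, recording)
                            scores = _score_solution(
                                rec.activity.amplitudes,
                                geometry.coarse_space,
                                rec.valid,
                                scenario,
                                fine,
                            )
                        else:
                            if method == "lcmv":
                                cov = estimate_covariance(recording)
                                sol = solve_lcmv(geometry.fine_leadfield, cov, recording)
                            elif method == "mne":
                                sol = solve_mne(geometry.fine_leadfield, recording)
                            elif method == "eloreta":
                                sol = solve_eloreta(geometry.fine_leadfield, recording)
                            elif method == "rv":
                                sol = solve_rv_scan(geometry.fine_leadfield, recording)
                            scores = _score_solution(
                                sol.amplitudes,
                                fine,
                                slice(0, recording.n_samples),
                                scenario,
                                fine,
                            )
                        failed = False
                    except Exception as exc:  # recorded, excluded from aggregates
                        scores = {
                            "dle_mm": np.nan,
                            "av_cm3": np.nan,
                            "nrmse": np.nan,
                            "iou_percent": np.nan,
                        }
                        failed = True
                        if verbose:
                            print(f"{method} failed on {scen_label}/{case_id}: {exc}")
                    records.append(
                        {
                            "scenario": scen_label,
                            "kind": kind,
                            "n_groups": n_groups,
                            "snr_db": snr_db,
                            "case": case_id,
                            "method": method,
                            "noise_seed": noise_seed,
                            "failed": failed,
                            **scores,
                        }
                    )

    per_case = pd.DataFrame.from_records(records)
    return BenchmarkResult(
        per_case=per_case, summary=summarize_cases(per_case), model=model
    )


def summarize_cases(per_case: pd.DataFrame) -> pd.DataFrame:
    """Aggregate per-case metrics into mean +/- std rows.

    Non-finite values (failed solves, empty active sets) are excluded from
    the mean and reported in ``n_excluded`` so silent failures stay visible.
    """
    rows = []
    metric_cols = ["dle_mm", "av_cm3", "nrmse", "iou_percent"]
    for (scenario, snr_db, method), group in per_case.groupby(
        ["scenario", "snr_db", "method"], sort=False
    ):
        for metric in metric_cols:
            values = group[metric].to_numpy(dtype=float)
            finite = values[np.isfinite(values)]
            if finite.size == 0:
                continue
            rows.append(
                {
                    "scenario": scenario,
                    "snr_db": snr_db,
                    "method": method,
                    "metric": metric,
                    "mean": float(finite.mean()),
                    "std": float(finite.std(ddof=1)) if finite.size > 1 else 0.0,
                    "n": int(finite.size),
                    "n_excluded": int(values.size - finite.size),
                }
            )
    return pd.DataFrame.from_records(rows)
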