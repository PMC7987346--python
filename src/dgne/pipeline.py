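"""End-to-end session pipeline and condition contrasts.

``run_pipeline`` orchestrates every analysis stage over one session (loaded
from a bundle or simulated) under a single configuration with one master seed
that expands into per-stage seeds by a fixed counter scheme; stage failures
are isolated and recorded, and dependent stages are skipped.  All results are
written as machine-readable tables plus a summary.
"""

from __future__ import annotations

import json
import os
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from . import behavior as beh
from . import ensembles as ens
from . import geometry as geo
from . import mpp as mppmod
from . import network_events as ne
from . import tuning as tun
from .core_io import SessionRecording, read_session, validate_session
from .synthetic import GeneratorParams, generate_session

__all__ = ["PipelineConfig", "run_pipeline", "compare_conditions"]

PIPELINE_VERSION = "1"

# fixed per-stage offsets from the master seed
_STAGE_SEEDS = {
    "simulate": 0,
    "threshold": 1,
    "state_stats": 2,
    "orthogonality": 3,
    "cluster_null": 4,
    "place": 5,
    "speed": 6,
    "geometry": 7,
}


@dataclass
class PipelineConfig:
    """Declarative pipeline configuration (YAML-serializable)."""

    input_path: str | None = None          # session bundle; None -> simulate
    simulate: bool = True
    generator: dict = field(default_factory=dict)   # GeneratorParams overrides
    out_dir: str | None = None
    seed: int = 0
    stages: tuple[str, ...] = (
        "network_events", "ensembles", "tuning", "mpp", "pupil", "geometry",
    )
    n_shuffles: int = 1000
    alpha_threshold: float = 0.001
    alpha_place: float = 0.05
    shuffle_method: str = "redistribute"
    threshold_rule: str = "ratio"
    ne_window_s: float = 2.0
    run_threshold_cm_s: float = 4.0
    min_run_s: float = 2.5
    rest_includes_short_bouts: bool = False
    mpp_tau_s: float = 1.5

    def validate(self) -> None:
        for a in (self.alpha_threshold, self.alpha_place):
            if not 0 < a < 1:
                raise ValueError("alpha values must lie in (0, 1)")
        if self.n_shuffles < 1:
            raise ValueError("n_shuffles must be positive")

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "stages" in data:
            data["stages"] = tuple(data["stages"])
        return cls(**data)


def _stage_seed(master: int, stage: str) -> int:
    return int((master * 1000 + _STAGE_SEEDS[stage]) % (2**31))


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all enabled stages on one session; return the report dict.

    The report carries per-stage tables (as plain lists/arrays) and a summary
    of the headline per-session quantities; when ``config.out_dir`` is set,
    tables are also written as TSV and the summary as JSON.
    """
    config.validate()
    log: list[str] = [f"pipeline version {PIPELINE_VERSION}", f"master seed {config.seed}"]
    report: dict = {"version": PIPELINE_VERSION, "config": asdict(config), "errors": {}}

    if config.input_path:
        session = read_session(config.input_path)
        gt = None
    else:
        params = GeneratorParams(**config.generator)
        session, gt = generate_session(params, seed=_stage_seed(config.seed, "simulate"))
    log.append(f"session {session.session_id}: {session.n_cells} cells x {session.n_frames} frames")
    problems = validate_session(session)
    if problems:
        raise ValueError("invalid session: " + "; ".join(problems))

    epochs = beh.segment_locomotion(
        session.speed, session.frame_rate, config.run_threshold_cm_s,
        config.min_run_s, config.rest_includes_short_bouts,
    )
    report["epochs"] = {"run": list(epochs.run), "rest": list(epochs.rest)}
    summary: dict = {"session_id": session.session_id,
                     "n_cells": session.n_cells, "n_frames": session.n_frames}

    ne_set = None
    if "network_events" in config.stages:
        try:
            thr, curves = ne.size_threshold(
                session.raster, epochs, n_shuffles=config.n_shuffles,
                alpha=config.alpha_threshold, method=config.shuffle_method,
                threshold_rule=config.threshold_rule,
                seed=_stage_seed(config.seed, "threshold"),
            )
            if not np.isfinite(thr):
                raise RuntimeError("no finite NE size threshold for this session")
            ne_set = ne.detect_network_events(session.raster, thr, null_curves=curves)
            stats = ne.ne_state_stats(
                ne_set, epochs, session.frame_rate,
                seed=_stage_seed(config.seed, "state_stats"),
            )
            summary.update(
                ne_threshold=thr,
                n_nes=len(ne_set),
                ne_freq_run_per_min=stats["freq_per_min_run"],
                ne_freq_rest_per_min=stats["freq_per_min_rest"],
                ne_mean_size=float(ne_set.sizes.mean()) if len(ne_set) else np.nan,
                ne_mean_participation_frac=(
                    float(ne_set.sizes.mean()) / session.n_cells if len(ne_set) else np.nan
                ),
            )
            report["ne_state_stats"] = {
                k: v for k, v in stats.items() if np.isscalar(v) or isinstance(v, dict)
            }
        except Exception as err:  # noqa: BLE001 - stage isolation is the contract
            report["errors"]["network_events"] = str(err)
            log.append(f"network_events failed: {err}")

    pm = None
    if ne_set is not None and len(ne_set) >= 2:
        pm = ens.participation_matrix(ne_set, session.n_cells)

    if "ensembles" in config.stages:
        if pm is None:
            report["errors"]["ensembles"] = "skipped: no usable NE set"
        else:
            try:
                frac, _, p_orth = ens.orthogonal_fraction_test(
                    pm.P, n_shuffles=config.n_shuffles,
                    seed=_stage_seed(config.seed, "orthogonality"),
                )
                r_thr = ens.cluster_threshold_null(
                    pm.P, n_shuffles=config.n_shuffles,
                    seed=_stage_seed(config.seed, "cluster_null"),
                )
                clusters = ens.hierarchical_clusters(pm.P, r_thr)
                summary.update(
                    orthogonal_fraction=frac, orthogonal_p=p_orth,
                    cluster_r_threshold=r_thr, n_clusters=clusters.n_clusters,
                    mean_cluster_size=(
                        float(clusters.sizes.mean()) if clusters.n_clusters else np.nan
                    ),
                )
                report["clusters"] = clusters
            except Exception as err:  # noqa: BLE001
                report["errors"]["ensembles"] = str(err)
                log.append(f"ensembles failed: {err}")

    place_ids: set[int] = set()
    speed_ids: set[int] = set()
    if "tuning" in config.stages:
        try:
            place_rows, speed_rows = [], []
            running_active = 0
            run_mask = epochs.mask("run")
            for c in range(session.n_cells):
                onsets = np.flatnonzero(session.raster[c])
                if run_mask[onsets].any():
                    running_active += 1
                pr = tun.place_cell_test(
                    onsets, session.position, epochs, session.belt_length,
                    session.frame_rate, n_shuffles=config.n_shuffles,
                    alpha=config.alpha_place,
                    seed=_stage_seed(config.seed, "place") + c,
                )
                place_rows.append((c, pr.vector_length, pr.preferred_cm, pr.p_value, pr.is_place))
                if pr.is_place:
                    place_ids.add(c)
                if session.dff is not None:
                    sr = tun.speed_cell_test(
                        session.dff[c], session.speed,
                        n_shuffles=config.n_shuffles, frame_rate=session.frame_rate,
                        seed=_stage_seed(config.seed, "speed") + c,
                    )
                    speed_rows.append((c, sr.r, sr.shuffle_pass_fraction, sr.is_speed))
                    if sr.is_speed:
                        speed_ids.add(c)
            active = int(np.count_nonzero(session.raster.sum(axis=1)))
            report["place_cells"] = pd.DataFrame(
                place_rows, columns=["cell_id", "vector_length", "preferred_cm", "p", "is_place"]
            )
            report["speed_cells"] = pd.DataFrame(
                speed_rows, columns=["cell_id", "r", "shuffle_pass_fraction", "is_speed"]
            )
            summary.update(
                n_place=len(place_ids), n_speed=len(speed_ids),
                frac_place_all=len(place_ids) / active if active else np.nan,
                frac_place_running=(
                    len(place_ids) / running_active if running_active else np.nan
                ),
                frac_speed_all=len(speed_ids) / active if active else np.nan,
                frac_speed_running=(
                    len(speed_ids) / running_active if running_active else np.nan
                ),
            )
            if pm is not None:
                summary.update(tun.tuning_ne_incorporation(place_ids, speed_ids, pm))
                if "clusters" in report:
                    summary.update(
                        {f"cluster_{k}": v for k, v in ens.cluster_tuning_overlap(
                            report["clusters"], place_ids, speed_ids
                        ).items()}
                    )
        except Exception as err:  # noqa: BLE001
            report["errors"]["tuning"] = str(err)
            log.append(f"tuning failed: {err}")

    if "mpp" in config.stages:
        try:
            raw = session.require("mpp")
            dff_bulk = mppmod.bulk_dff(raw, session.frame_rate)
            events = mppmod.deconvolve_bulk(dff_bulk, session.frame_rate, config.mpp_tau_s)
            estats = mppmod.bulk_event_state_stats(events, epochs, session.frame_rate)
            summary.update(
                mpp_n_events=len(events),
                mpp_freq_run=estats["freq_per_min_run"],
                mpp_freq_rest=estats["freq_per_min_rest"],
                mpp_large_freq_run=estats["large_freq_per_min_run"],
                mpp_large_freq_rest=estats["large_freq_per_min_rest"],
            )
            gc_sum = session.raster.sum(axis=0).astype(float)
            lags, cc = mppmod.mpp_gc_crosscorr(dff_bulk, gc_sum, epochs, session.frame_rate)
            summary["mpp_gc_peak_lag_s"] = float(lags[int(np.argmax(cc))])
            summary["mpp_gc_peak_cc"] = float(cc.max())
            g = mppmod.granger_test(dff_bulk[epochs.mask("rest")], gc_sum[epochs.mask("rest")])
            summary.update(granger_order=g.order, granger_F=g.f_stat, granger_p=g.p_value)
            if ne_set is not None and len(ne_set) and len(events):
                delays = mppmod.ne_mpp_delay(ne_set.ne_frames, events, session.frame_rate)
                summary["ne_mpp_median_delay_s"] = float(np.median(delays))
            report["mpp_events"] = events
        except Exception as err:  # noqa: BLE001
            report["errors"]["mpp"] = str(err)
            log.append(f"mpp failed: {err}")

    if "pupil" in config.stages:
        try:
            raw = session.require("pupil")
            pupil = beh.preprocess_pupil(
                raw, session.blink, native_rate=session.frame_rate,
                target_rate=session.frame_rate,
            )
            frames = ne_set.ne_frames if ne_set is not None else np.array([], dtype=int)
            pstats = beh.pupil_state_stats(pupil, epochs, frames, session.frame_rate)
            summary.update({f"pupil_{k}": v for k, v in pstats.items()})
        except Exception as err:  # noqa: BLE001
            report["errors"]["pupil"] = str(err)
            log.append(f"pupil failed: {err}")

    if "geometry" in config.stages:
        if ne_set is None or not len(ne_set) or session.dff is None:
            report["errors"]["geometry"] = "skipped: needs dff and a detected NE set"
        else:
            try:
                X, kept = geo.zscore_rows(session.dff)
                sim = geo.geometry_shuffle_test(
                    X, epochs, ne_set.ne_frames, session.frame_rate,
                    ne_window_s=config.ne_window_s, n_shuffles=config.n_shuffles,
                    seed=_stage_seed(config.seed, "geometry"),
                )
                summary.update(
                    projected_variance_ratio=sim.projected_variance_ratio,
                    s_pca=sim.s_pca, eros=sim.eros,
                    k_run=sim.k_run, k_net=sim.k_net,
                )
                for m, ps in sim.p_values.items():
                    for meas, p in ps.items():
                        summary[f"p_{meas}_{m}"] = p
                report["similarity"] = sim
                X_run, _ = geo.extract_state_matrices(
                    X, epochs, ne_set.ne_frames, session.frame_rate, config.ne_window_s
                )
                basis_run = geo.pca_basis(X_run)
                laps = beh.laps_from_position(session.position, session.belt_length)
                run_frames = epochs.frames("run")
                lap_run = beh.LapIndex(
                    lap=laps.lap[run_frames], within_lap_cm=laps.within_lap_cm[run_frames]
                )
                try:
                    _, _, peak = geo.weight_lap_autocorr(
                        basis_run.W, lap_run, session.belt_length
                    )
                    summary["weight_autocorr_lap1"] = peak
                except ValueError as err:
                    log.append(f"lap autocorrelation unavailable: {err}")
            except Exception as err:  # noqa: BLE001
                report["errors"]["geometry"] = str(err)
                log.append(f"geometry failed: {err}")

    report["summary"] = summary
    report["ne_set"] = ne_set
    report["ground_truth"] = gt
    report["log"] = log

    if config.out_dir:
        _write_report(report, config.out_dir)
    return report


def _jsonable(v):
    if isinstance(v, (np.floating, np.integer)):
        return v.item()
    if isinstance(v, np.ndarray):
        return v.tolist()
    if isinstance(v, dict):
        return {k: _jsonable(x) for k, x in v.items()}
    return v


def _write_report(report: dict, out_dir: str) -> None:
    os.makedirs(out_dir, exist_ok=True)
    with open(os.path.join(out_dir, "summary.json"), "w") as fh:
        json.dump({k: _jsonable(v) for k, v in report["summary"].items()}, fh, indent=1)
    with open(os.path.join(out_dir, "pipeline.log"), "w") as fh:
        fh.write("\n".join(report["log"]) + "\n")
    ne_set = report.get("ne_set")
    if ne_set is not None and len(ne_set):
        pd.DataFrame({
            "ne_id": np.arange(len(ne_set)),
            "peak_frame": ne_set.ne_frames,
            "size": ne_set.sizes,
        }).to_csv(os.path.join(out_dir, "network_events.tsv"), sep="\t", index=False)
        rows = [(i, c) for i, mem in enumerate(ne_set.ne_members) for c in sorted(mem)]
        pd.DataFrame(rows, columns=["ne_id", "cell_id"]).to_csv(
            os.path.join(out_dir, "ne_members.tsv"), sep="\t", index=False
        )
        for m, curve in ne_set.null_curves.items():
            pd.DataFrame({
                "size": curve["sizes"], "shuffle_mean": curve["shuffle_mean"],
                "shuffle_sd": curve["shuffle_sd"], "real": curve["real"],
            }).to_csv(
                os.path.join(out_dir, f"ne_null_curves_{m}.tsv"), sep="\t", index=False
            )
    if "clusters" in report:
        cl = report["clusters"]
        pd.DataFrame({
            "cell_id": np.arange(cl.labels.size), "cluster_id": cl.labels,
        }).to_csv(os.path.join(out_dir, "clusters.tsv"), sep="\t", index=False)
    for key in ("place_cells", "speed_cells"):
        if key in report:
            report[key].to_csv(os.path.join(out_dir, f"{key}.tsv"), sep="\t", index=False)
    ev = report.get("mpp_events")
    if ev is not None and len(ev):
        pd.DataFrame({"frame": ev.frames, "amplitude": ev.amplitudes}).to_csv(
            os.path.join(out_dir, "mpp_events.tsv"), sep="\t", index=False
        )
    sim = report.get("similarity")
    if sim is not None:
        rows = []
        for meas, obs in (
            ("pvr", sim.projected_variance_ratio), ("s_pca", sim.s_pca), ("eros", sim.eros)
        ):
            row = {"measure": meas, "observed": obs, "k_run": sim.k_run, "k_net": sim.k_net}
            for m, ps in sim.p_values.items():
                row[f"p_{m}"] = ps[meas]
            rows.append(row)
        pd.DataFrame(rows).to_csv(
            os.path.join(out_dir, "similarity.tsv"), sep="\t", index=False
        )


def compare_conditions(report_a: dict, report_b: dict) -> pd.DataFrame:
    """Two-condition contrasts (e.g. baseline vs cue-enriched).

    Rank-sum tests on NE size and per-cell participation distributions, and a
    chi-square contrast on the place-cell NE-incorporation fractions.
    """
    from scipy import stats as sstats

    if report_a.get("version") != report_b.get("version"):
        raise ValueError("pipeline version mismatch between reports")
    ca = report_a.get("config", {}).get("n_shuffles")
    cb = report_b.get("config", {}).get("n_shuffles")
    if ca != cb:
        warnings.warn(f"reports used different shuffle counts ({ca} vs {cb})")
    rows = []
    nes_a, nes_b = report_a.get("ne_set"), report_b.get("ne_set")
    if nes_a is not None and nes_b is not None and len(nes_a) and len(nes_b):
        u, p = sstats.mannwhitneyu(nes_a.sizes, nes_b.sizes, alternative="two-sided")
        rows.append(("ne_size", float(nes_a.sizes.mean()), float(nes_b.sizes.mean()),
                     "mannwhitneyu", float(u), float(p)))
        pa = np.array([len(m) for m in nes_a.ne_members])  # noqa: F841 (sizes alias)
        part_a = ens.participation_matrix(nes_a, report_a["summary"]["n_cells"]).P.sum(axis=1)
        part_b = ens.participation_matrix(nes_b, report_b["summary"]["n_cells"]).P.sum(axis=1)
        u2, p2 = sstats.mannwhitneyu(part_a, part_b, alternative="two-sided")
        rows.append(("cell_participation", float(part_a.mean()), float(part_b.mean()),
                     "mannwhitneyu", float(u2), float(p2)))
    sa, sb = report_a["summary"], report_b["summary"]
    if sa.get("n_place") and sb.get("n_place"):
        in_a = int(round(sa["frac_place_in_ne"] * sa["n_place"]))
        in_b = int(round(sb["frac_place_in_ne"] * sb["n_place"]))
        table = np.array([
            [in_a, sa["n_place"] - in_a],
            [in_b, sb["n_place"] - in_b],
        ])
        if (table.sum(axis=1) > 0).all() and (table.sum(axis=0) > 0).all():
            chi2, p, _, _ = sstats.chi2_contingency(table)
            rows.append(("place_in_ne", sa["frac_place_in_ne"], sb["frac_place_in_ne"],
                         "chi2", float(chi2), float(p)))
    return pd.DataFrame(
        rows, columns=["quantity", "value_a", "value_b", "test", "statistic", "p"]
    )
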