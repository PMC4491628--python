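"""Desk-scale reproductions of the model's six evaluation settings.

All experiments run on synthetic articulated motion (three kinds, four
canonical views) with the default parameter block. Each function takes a
:class:`~biomotion.config.RunConfig`, is fully seed-reproducible, and
returns a plain dict of results; pass ``outdir`` to also write tidy CSV
metrics and a YAML manifest.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .config import RunConfig
from .inference import exclusiveness
from .patterns import WinnerRecord, free_run
from .pipeline import MotionModel
from .synthetic import (
    GaitParams, ViewTransform, canonical_views, generate_motion,
    random_rotation, rotation_about_vertical, subject_params,
)

__all__ = [
    "exp_single_motion", "exp_multiview", "exp_perspective",
    "exp_bistable", "exp_feature_inference", "condensed_cycle",
    "smooth_winners", "dominant_cycle", "cycles_equivalent",
]


def _write(outdir, name: str, frame: pd.DataFrame) -> None:
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        frame.to_csv(outdir / name, index=False)


def _manifest(outdir, cfg: RunConfig) -> None:
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        cfg.write_manifest(outdir / "manifest.yaml")


def condensed_cycle(winners: np.ndarray) -> list[int]:
    """Collapse consecutive duplicates in a winner sequence."""
    w = np.asarray(winners)
    if w.size == 0:
        return []
    keep = np.r_[True, w[1:] != w[:-1]]
    return list(w[keep])


def smooth_winners(winners: np.ndarray, window: int = 9) -> np.ndarray:
    """Sliding-window majority filter over a winner sequence.

    Two patterns encoding adjacent segments of a trajectory can flutter at
    the hand-over for a few steps under the Cauchy noise; a short majority
    filter recovers the macroscopic dwell structure without affecting
    dwells longer than the window.
    """
    w = np.asarray(winners)
    out = np.empty_like(w)
    half = window // 2
    for i in range(len(w)):
        a, b = max(0, i - half), min(len(w), i + half + 1)
        out[i] = np.bincount(w[a:b]).argmax()
    return out


def dominant_cycle(winners: np.ndarray, window: int = 9) -> list[int]:
    """The layer's dominant winner cycle.

    Smooths and condenses the sequence, then follows each pattern's most
    frequent successor starting from the most frequent winner until the
    start repeats. This is robust to occasional shortcut transitions and
    hand-over flutter.
    """
    from collections import Counter

    seq = condensed_cycle(smooth_winners(winners, window))
    if not seq:
        return []
    succ: dict[int, Counter] = {}
    for a, b in zip(seq[:-1], seq[1:]):
        succ.setdefault(a, Counter())[b] += 1
    start = Counter(seq).most_common(1)[0][0]
    cycle = [start]
    cur = start
    for _ in range(len(set(seq)) + 1):
        if cur not in succ:
            break
        cur = succ[cur].most_common(1)[0][0]
        if cur == cycle[0]:
            break
        cycle.append(cur)
    return [int(c) for c in cycle]


def cycles_equivalent(a: list[int], b: list[int]) -> bool:
    """Whether two winner cycles traverse their shared patterns in the same
    cyclic order.

    Patterns appearing in only one cycle (a pattern may or may not be
    visited on a given traversal when two patterns encode overlapping
    trajectory segments) are ignored, but the shared patterns must cover
    most of both cycles and appear in the same order up to rotation.
    """
    common = set(a) & set(b)
    ra = [x for x in a if x in common]
    rb = [x for x in b if x in common]
    if not ra and not rb:
        return not a and not b
    if len(ra) != len(rb) or len(common) < max(3, round(0.6 * max(len(a), len(b)))):
        return False
    doubled = rb + rb
    return any(doubled[i : i + len(ra)] == ra for i in range(len(rb)))


def _train_schedule(model: MotionModel, cfg: RunConfig, kinds, views,
                    collect_labels: bool = False):
    """Consecutive training trials: kinds x views, ``n_repetitions`` times.

    Returns per-(kind, view) winner counts from the final repetition, used
    to attribute patterns to conditions.
    """
    counts_by_cond: dict[int, np.ndarray] = {}
    for rep in range(cfg.n_repetitions):
        for ki, kind in enumerate(kinds):
            for vi, view in enumerate(views):
                params = GaitParams(seed=int(cfg.seed + 1000 * rep + 10 * ki + vi))
                seq = generate_motion(kind, params, T=cfg.interval_frames)
                rec = model.train_sequence(seq, view=view)
                label = ki * len(views) + vi
                if collect_labels and rep == cfg.n_repetitions - 1:
                    counts_by_cond[label] = rec.histogram(model.layer.n_patterns)
    return counts_by_cond


# ---------------------------------------------------------------------------
# 1. single motion: pattern growth, histogram convergence, free run

def exp_single_motion(cfg: RunConfig | None = None, outdir=None) -> dict:
    """Learn one cyclic motion, then replay it without sensory input.

    Trains a single synthetic walking-like trial for ``n_repetitions``
    intervals, tracks the winner histogram per interval and the pattern
    count, then clears all gains and free-runs the layer for the same
    number of intervals, comparing the replayed winner cycle to the
    stimulus-driven one.
    """
    cfg = cfg or RunConfig(experiment="single_motion")
    model = MotionModel(params=cfg.params, seed=cfg.seed)
    T = cfg.interval_frames

    # a single recorded trial is presented repeatedly
    seq = generate_motion("gaitA", GaitParams(seed=int(cfg.seed)), T=T)
    hists, counts, last_rec = [], [], None
    for rep in range(cfg.n_repetitions):
        last_rec = model.train_sequence(seq)
        hists.append(last_rec.histogram(model.layer.n_patterns))
        counts.append(model.layer.n_trained)

    width = max(len(h) for h in hists)
    H = np.vstack([np.pad(h, (0, width - len(h))) for h in hists])
    l1 = np.abs(np.diff(H, axis=0)).sum(axis=1)
    conv = np.flatnonzero(l1 < 0.05 * T)
    convergence_rep = int(conv[0] + 1) if conv.size else None

    run = free_run(model.layer, steps=cfg.n_repetitions * T, reset_sequence=True)
    trained_cycle = dominant_cycle(last_rec.winners)
    free_cycle = dominant_cycle(run.winners)

    result = {
        "n_patterns": model.layer.n_trained,
        "pattern_counts": counts,
        "histograms": H,
        "histogram_l1_change": l1,
        "convergence_repetition": convergence_rep,
        "trained_cycle": trained_cycle,
        "free_run_cycle": free_cycle,
        "cycle_reproduced": cycles_equivalent(trained_cycle, free_cycle),
        "free_run_histogram": run.histogram(model.layer.n_patterns),
    }
    _manifest(outdir, cfg)
    _write(outdir, "winner_histograms.csv",
           pd.DataFrame(H, columns=[f"p{i}" for i in range(width)]).assign(
               repetition=np.arange(1, cfg.n_repetitions + 1)))
    return result


# ---------------------------------------------------------------------------
# 2. multiple movements x views: exclusiveness

def exp_multiview(cfg: RunConfig | None = None, outdir=None) -> dict:
    """Encode 3 motion kinds x 4 views; measure winning exclusiveness.

    After consecutive training, novel test trials (different morphology
    and posture-noise seeds) of the 12 view-dependent movements drive the
    frozen network; the exclusiveness of every winning pattern over the 12
    condition labels is reported.
    """
    cfg = cfg or RunConfig(experiment="multiview")
    model = MotionModel(params=cfg.params, seed=cfg.seed)
    views = canonical_views()
    _train_schedule(model, cfg, cfg.motion_kinds, views)

    winners, labels = [], []
    for subject in (1, 2):
        for ki, kind in enumerate(cfg.motion_kinds):
            for vi, view in enumerate(views):
                params = subject_params(
                    subject, GaitParams(seed=int(cfg.seed + 77_000 + 10 * ki + vi + subject))
                )
                seq = generate_motion(kind, params, T=cfg.interval_frames)
                label = ki * len(views) + vi
                rec = model.test_sequence(seq, view=view, label=label)
                winners.append(rec.winners)
                labels.append(rec.labels)
    record = WinnerRecord(np.concatenate(winners), np.concatenate(labels))
    scores = exclusiveness(record)
    vals = np.array(list(scores.values()))

    result = {
        "n_patterns": model.layer.n_trained,
        "exclusiveness": scores,
        "n_exclusive": int(np.count_nonzero(vals >= 1.0)),
        "n_above_075": int(np.count_nonzero(vals > 0.75)),
        "n_above_05": int(np.count_nonzero(vals > 0.5)),
        "fraction_above_05": float(np.mean(vals > 0.5)) if vals.size else 0.0,
    }
    _manifest(outdir, cfg)
    _write(outdir, "exclusiveness.csv",
           pd.DataFrame({"pattern": list(scores), "exclusiveness": vals}))
    return result


# ---------------------------------------------------------------------------
# 3. perspective-taking under random rotations

def exp_perspective(cfg: RunConfig | None = None, n_runs: int = 50,
                    steps: int = 5000, success_deg: float = 35.0,
                    outdir=None, model: MotionModel | None = None) -> dict:
    """Adopt Haar-random unknown perspectives of familiar motions.

    Trains on 3 kinds x 4 views, then runs ``n_runs`` independent test
    presentations: a novel-subject trial of a trained kind, rotated by an
    independent Haar-uniform rotation, observed for ``steps`` time steps
    with perspective adaptation enabled. A run succeeds when the minimum
    orientation difference to any trained view falls below ``success_deg``
    degrees at the end.
    """
    cfg = cfg or RunConfig(experiment="perspective")
    if model is None:
        model = MotionModel(params=cfg.params, seed=cfg.seed)
        _train_schedule(model, cfg, cfg.motion_kinds, canonical_views())
    view_mats = [v.rotation for v in canonical_views()]

    dvis_list, dpro_list, R_list = [], [], []
    for r in range(n_runs):
        kind = cfg.motion_kinds[r % len(cfg.motion_kinds)]
        params = subject_params(1 + r % 2, GaitParams(seed=int(cfg.seed + 50_000 + r)))
        seq = generate_motion(kind, params, T=steps)
        R_nu = random_rotation(int(cfg.seed + 90_000 + r))
        dvis, dpro = model.preprocess(seq, view=ViewTransform(rotation=R_nu))
        dvis_list.append(dvis)
        dpro_list.append(dpro)
        R_list.append(R_nu)

    dvis = np.stack(dvis_list)
    dpro = np.stack(dpro_list)
    R_nu = np.stack(R_list)
    model.layer.reset_sequence_state()
    res = model.adapt_perspective(dvis, dpro, R_nu, view_mats, record_every=25)

    od_final = np.degrees(res.final_od_min)
    success = od_final < success_deg
    reached_view = np.argmin(res.od_per_view, axis=1)

    result = {
        "n_runs": n_runs,
        "steps": steps,
        "success_rate": float(np.mean(success)),
        "final_od_deg": od_final,
        "reached_view": reached_view,
        "views_reached_counts": np.bincount(reached_view[success], minlength=4),
        "od_min_trajectory_deg": np.degrees(res.od_min),
        "n_patterns": model.layer.n_trained,
    }
    _manifest(outdir, cfg)
    _write(outdir, "perspective_runs.csv", pd.DataFrame({
        "run": np.arange(n_runs), "final_od_deg": od_final,
        "success": success, "reached_view": reached_view,
    }))
    return result


# ---------------------------------------------------------------------------
# 4. bistable 2D projections

def exp_bistable(cfg: RunConfig | None = None, outdir=None) -> dict:
    """Heading recognition of 2D-projected walkers, with and without mirror.

    Trains the egocentric and facing views of the asymmetric walking-like
    motion, attributes each pattern to the view it won under during
    training, then tests six setups: {3D, 2D-projected} x {original} and
    2D-projected x mirrored, for both views. The mirrored 2D projection
    must flip the recognized heading.
    """
    cfg = cfg or RunConfig(experiment="bistable")
    model = MotionModel(params=cfg.params, seed=cfg.seed)
    ego = ViewTransform()
    facing = ViewTransform(rotation=rotation_about_vertical(np.pi))
    counts = _train_schedule(model, cfg, ("gaitA",), [ego, facing], collect_labels=True)

    P = model.layer.n_patterns
    ego_wins = counts.get(0, np.zeros(P, dtype=int))
    facing_wins = counts.get(1, np.zeros(P, dtype=int))
    ego_wins = np.pad(ego_wins, (0, P - len(ego_wins)))
    facing_wins = np.pad(facing_wins, (0, P - len(facing_wins)))
    group = np.where(ego_wins >= facing_wins, 0, 1)  # 0: ego, 1: facing

    def recognize(view: ViewTransform) -> tuple[int, float]:
        params = GaitParams(seed=int(cfg.seed + 31_337))
        seq = generate_motion("gaitA", params, T=cfg.interval_frames)
        rec = model.test_sequence(seq, view=view, label=0)
        votes = np.bincount(group[rec.winners], minlength=2)
        total = votes.sum()
        return int(np.argmax(votes)), float(votes.max() / total) if total else 0.0

    setups = {
        "3d_ego": ViewTransform(),
        "3d_facing": ViewTransform(rotation=facing.rotation),
        "2d_ego": ViewTransform(project_2d=True),
        "2d_facing": ViewTransform(rotation=facing.rotation, project_2d=True),
        "2d_mirror_ego": ViewTransform(project_2d=True, mirror_horizontal=True),
        "2d_mirror_facing": ViewTransform(rotation=facing.rotation, project_2d=True,
                                          mirror_horizontal=True),
    }
    table = {name: recognize(view) for name, view in setups.items()}
    recognized = {name: ("ego" if g == 0 else "facing") for name, (g, _) in table.items()}

    result = {
        "recognized": recognized,
        "vote_fractions": {name: frac for name, (_, frac) in table.items()},
        "correct_3d": recognized["3d_ego"] == "ego" and recognized["3d_facing"] == "facing",
        "correct_2d": recognized["2d_ego"] == "ego" and recognized["2d_facing"] == "facing",
        "mirror_flips": recognized["2d_mirror_ego"] == "facing"
                        and recognized["2d_mirror_facing"] == "ego",
        "n_patterns": model.layer.n_trained,
    }
    _manifest(outdir, cfg)
    _write(outdir, "bistable.csv", pd.DataFrame({
        "setup": list(table), "recognized": [recognized[k] for k in table],
        "vote_fraction": [table[k][1] for k in table],
    }))
    return result


# ---------------------------------------------------------------------------
# 5. inferring proprioception from vision under an unknown view

def exp_feature_inference(cfg: RunConfig | None = None, steps: int = 5000,
                          outdir=None) -> dict:
    """Infer unobservable proprioception while adopting an adverse view.

    Trains the egocentric walking-like motion with full drive, then
    observes it rotated 180 degrees about the walking direction followed by
    45 degrees about the vertical axis (near-worst-case orientation), under
    three conditions: full drive, vision only, and vision only with frozen
    perspective (negative control). Reports the proprioceptive RMS
    trajectory of the winner's prediction against a full-drive shadow pass,
    and the OD trajectory to the trained view.
    """
    cfg = cfg or RunConfig(experiment="feature_inference")
    model = MotionModel(params=cfg.params, seed=cfg.seed)
    for rep in range(cfg.n_repetitions):
        params = GaitParams(seed=int(cfg.seed + rep))
        seq = generate_motion("gaitA", params, T=cfg.interval_frames)
        model.train_sequence(seq)

    R_nu = rotation_about_vertical(np.pi / 4.0) @ np.diag([1.0, -1.0, -1.0])
    params = GaitParams(seed=int(cfg.seed + 123))
    seq = generate_motion("gaitA", params, T=steps)
    dvis, dpro = model.preprocess(seq, view=ViewTransform(rotation=R_nu))
    dvis, dpro = dvis[None], dpro[None]
    R = R_nu[None]
    views = [np.eye(3)]

    conditions = {}
    for name, (proprio, adapt) in {
        "full_drive": (True, True),
        "vision_only": (False, True),
        "vision_only_frozen": (False, False),
    }.items():
        model.layer.reset_sequence_state()
        res = model.adapt_perspective(dvis, dpro, R, views, proprio_drive=proprio,
                                      adapt=adapt, shadow_proprio=True,
                                      record_every=25)
        tail = max(1, steps // 10)
        conditions[name] = {
            "final_rms": float(res.proprio_rms[0, -tail:].mean()),
            "initial_rms": float(res.proprio_rms[0, : tail].mean()),
            "final_od_deg": float(np.degrees(res.od_min[0, -1])),
            "rms_trajectory": res.proprio_rms[0],
            "od_trajectory_deg": np.degrees(res.od_min[0]),
        }

    result = {"conditions": conditions, "n_patterns": model.layer.n_trained}
    _manifest(outdir, cfg)
    _write(outdir, "feature_inference.csv", pd.DataFrame({
        "condition": list(conditions),
        "final_rms": [c["final_rms"] for c in conditions.values()],
        "final_od_deg": [c["final_od_deg"] for c in conditions.values()],
    }))
    return result
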