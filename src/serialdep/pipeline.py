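"""End-to-end simulated-experiment workflow and its configuration.

A run is fully determined by a :class:`RunConfig` (serializable to YAML) and
executes simulate -> behavior analysis -> decoding -> neural bias -> stats,
writing versioned outputs (CSV/NPZ/JSON) plus a structured log into a run
directory.  Every output references the config hash, and identical configs
produce byte-identical numeric outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import behavior as beh
from . import neuralbias as nb
from . import stats as st
from .containers import EpochsData
from .decoding import ClassBins, align_evidence, build_features, cosine_evidence, decode_cv, window_mean
from .simulate import (
    BehaviorParams,
    NeuralParams,
    generate_behavior,
    generate_epochs,
    generate_trial_table,
    read_trial_table,
    write_trial_table,
)

log = logging.getLogger("serialdep")


@dataclass(frozen=True)
class DecodingConfig:
    window_len: int = 15          # samples; 150 ms at the default 100 Hz
    n_folds: int = 10
    var_kept: float = 0.90
    n_classes: int = 10
    tmin: float = None            # optional crop of decoded time points
    tmax: float = None
    decim: int = 1


@dataclass(frozen=True)
class BiasConfig:
    within_range: tuple = nb.WITHIN_TRIAL_RANGE
    between_range: tuple = nb.BETWEEN_TRIAL_RANGE
    window: tuple = (0.25, 0.60)


@dataclass(frozen=True)
class StatsConfig:
    n_iter: int = 2000
    alpha: float = 0.05


@dataclass(frozen=True)
class RunConfig:
    seed: int = 0
    n_trials: int = 400
    block_size: int = 50
    condition_mix: tuple = (0.25, 0.25, 0.25, 0.25)
    behavior: BehaviorParams = field(default_factory=BehaviorParams)
    neural: NeuralParams = field(default_factory=NeuralParams)
    decoding: DecodingConfig = field(default_factory=DecodingConfig)
    bias: BiasConfig = field(default_factory=BiasConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)

    def to_dict(self):
        return asdict(self)

    def to_yaml(self, path):
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_dict(cls, d):
        d = dict(d)
        for key, sub in (
            ("behavior", BehaviorParams),
            ("neural", NeuralParams),
            ("decoding", DecodingConfig),
            ("bias", BiasConfig),
            ("stats", StatsConfig),
        ):
            if key in d and isinstance(d[key], dict):
                kw = dict(d[key])
                for f in dataclasses.fields(sub):
                    if f.name in kw and isinstance(kw[f.name], list):
                        kw[f.name] = tuple(kw[f.name])
                d[key] = sub(**kw)
        if isinstance(d.get("condition_mix"), list):
            d["condition_mix"] = tuple(d["condition_mix"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path):
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    @property
    def config_hash(self):
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha1(payload.encode()).hexdigest()[:12]


class PipelineError(RuntimeError):
    """A pipeline stage failed; partial outputs remain in the run directory."""

    def __init__(self, stage, original):
        super().__init__(f"stage '{stage}' failed: {original}")
        self.stage = stage
        self.original = original


def _setup_logging(outdir):
    handler = logging.FileHandler(outdir / "log.txt")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    return handler


def stage_simulate(config: RunConfig, outdir: Path):
    table = generate_trial_table(
        config.n_trials, config.block_size, config.condition_mix, seed=config.seed
    )
    table = generate_behavior(table, config.behavior, seed=config.seed + 1)
    write_trial_table(table, outdir / "trials.csv")
    for ev_name in ("grating1", "grating2"):
        epochs = generate_epochs(table, config.neural, which_event=ev_name)
        epochs.save(outdir / f"epochs_{ev_name}")
    log.info("simulate: %d trials, %d blocks", len(table), table["block_index"].nunique())
    return table


def stage_behavior(config: RunConfig, outdir: Path, table=None):
    if table is None:
        table = read_trial_table(outdir / "trials.csv")
    errors = beh.circular_error(table["response"], table["target_ori"])
    report = {"mean_abs_error_deg": float(np.mean(np.abs(errors)))}

    # between-trial bias: first trial of each block excluded
    btw = table[table["prev_target_ori"].notna()]
    d_btw = beh.circular_error(btw["prev_target_ori"], btw["target_ori"])
    e_btw = beh.circular_error(btw["response"], btw["target_ori"])
    curve_btw = beh.bias_curve(e_btw, d_btw)
    curve_btw.to_csv(outdir / "bias_between.csv")
    null_btw = st.signflip_shuffle_null(
        lambda d, e: beh.summed_bias(e, d), [d_btw], [e_btw],
        n_iter=config.stats.n_iter, seed=config.seed + 10,
    )
    report["between"] = {"summed_bias_deg": curve_btw.summed_bias, **null_btw.to_json()}
    pd.DataFrame({"delta": d_btw, "error": e_btw}).to_csv(
        outdir / "between_trials_raw.csv", index=False
    )

    # within-trial bias: two-item trials only
    win = table[table["nontarget_ori"].notna()]
    d_win = beh.circular_error(win["nontarget_ori"], win["target_ori"])
    e_win = beh.circular_error(win["response"], win["target_ori"])
    curve_win = beh.bias_curve(e_win, d_win)
    curve_win.to_csv(outdir / "bias_within.csv")
    null_win = st.signflip_shuffle_null(
        lambda d, e: beh.summed_bias(e, d), [d_win], [e_win],
        n_iter=config.stats.n_iter, seed=config.seed + 11,
    )
    report["within"] = {"summed_bias_deg": curve_win.summed_bias, **null_win.to_json()}
    pd.DataFrame({"delta": d_win, "error": e_win}).to_csv(
        outdir / "within_trials_raw.csv", index=False
    )

    e_nt = np.where(
        table["nontarget_ori"].notna(),
        beh.circular_error(table["response"], table["nontarget_ori"].fillna(0.0)),
        np.nan,
    )
    fit = beh.fit_mixture(errors, e_nt)
    fit.to_json(outdir / "mixture.json")
    report["mixture"] = fit.to_json()
    (outdir / "behavior_report.json").write_text(json.dumps(report, indent=2))
    log.info("behavior: summed bias between=%.3f within=%.3f",
             curve_btw.summed_bias, curve_win.summed_bias)
    return report


def _decode_event(config: RunConfig, epochs, labels, seed):
    feats = build_features(epochs, window_len=config.decoding.window_len)
    feats = feats.crop(config.decoding.tmin, config.decoding.tmax, config.decoding.decim)
    bins = ClassBins(config.decoding.n_classes)
    return decode_cv(
        feats, labels, bins,
        n_folds=config.decoding.n_folds, var_kept=config.decoding.var_kept, seed=seed,
    )


def stage_decode(config: RunConfig, outdir: Path, table=None):
    """Decode each grating event and the combined (stacked) presentations.

    The combined decoder is trained on all stimulus presentations (grating-1
    and grating-2 epochs of trials where that grating was shown, stacked
    along the trial axis) and backs the between-trial analyses; the
    grating-2 decoder backs the within-trial analyses.
    """
    if table is None:
        table = read_trial_table(outdir / "trials.csv")
    results = {}
    stacks = {"data": [], "labels": [], "trial": [], "event": []}
    times = None
    for ev_name, col in (("grating1", "ori1"), ("grating2", "ori2")):
        epochs = EpochsData.load(outdir / f"epochs_{ev_name}.npz")
        present = table[col].notna().to_numpy()
        sub = EpochsData(
            epochs.data[present], epochs.times, epochs.sfreq,
            epochs.channel_names, epochs.channel_types, epochs.channel_positions,
            dict(epochs.info),
        )
        labels = table.loc[present, col].to_numpy(dtype=float)
        ev = _decode_event(config, sub, labels, seed=config.seed + 20)
        times = ev.times
        sc = cosine_evidence(align_evidence(ev, labels))
        np.savez(
            outdir / f"evidence_{ev_name}.npz",
            evidence=ev.evidence, times=ev.times, labels=labels,
            trial_index=table.loc[present, "trial_index"].to_numpy(),
            cv_fold_of_trial=ev.cv_fold_of_trial,
        )
        pd.DataFrame({"time": ev.times, "cosine_evidence": sc.mean(axis=0)}).to_csv(
            outdir / f"cosine_{ev_name}.csv", index=False
        )
        results[ev_name] = {
            "window_mean": window_mean(sc, ev.times, config.bias.window),
            "n_trials": int(present.sum()),
            "n_discriminant": ev.info["n_discriminant"],
        }
        stacks["data"].append(sub.data)
        stacks["labels"].append(labels)
        stacks["trial"].append(table.loc[present, "trial_index"].to_numpy())
        stacks["event"].append(np.full(int(present.sum()), 1 if ev_name == "grating1" else 2))
        epochs_meta = sub

    comb = EpochsData(
        np.concatenate(stacks["data"]), epochs_meta.times, epochs_meta.sfreq,
        epochs_meta.channel_names, epochs_meta.channel_types,
        epochs_meta.channel_positions, {"which_event": "combined"},
    )
    labels = np.concatenate(stacks["labels"])
    ev = _decode_event(config, comb, labels, seed=config.seed + 21)
    np.savez(
        outdir / "evidence_combined.npz",
        evidence=ev.evidence, times=ev.times, labels=labels,
        trial_index=np.concatenate(stacks["trial"]),
        event=np.concatenate(stacks["event"]),
        cv_fold_of_trial=ev.cv_fold_of_trial,
    )
    results["combined"] = {
        "window_mean": window_mean(cosine_evidence(align_evidence(ev, labels)), ev.times, config.bias.window),
        "n_presentations": int(labels.size),
    }
    (outdir / "decode_report.json").write_text(json.dumps(results, indent=2))
    log.info("decode: %s", {k: round(v["window_mean"], 4) for k, v in results.items()})
    return results, ev, table, times


def stage_bias(config: RunConfig, outdir: Path, table=None):
    """Neural asymmetry/bias scores and cross-decoding with sign-flip nulls."""
    from .decoding import EvidenceTensor

    if table is None:
        table = read_trial_table(outdir / "trials.csv")
    bins = ClassBins(config.decoding.n_classes)
    report = {}

    # within-trial: grating-2 evidence, same-trial inducer
    with np.load(outdir / "evidence_grating2.npz") as f:
        ev2 = EvidenceTensor(f["evidence"], bins, f["times"], f["cv_fold_of_trial"], f["labels"])
        tidx2 = f["trial_index"]
    sub2 = table.set_index("trial_index").loc[tidx2].reset_index()
    try:
        sel = nb.select_inducer_trials(
            sub2.assign(trial_index=np.arange(len(sub2))),
            "same_trial_other_grating", config.bias.within_range,
            event="grating2", closed="neither",
        )
        rel = align_evidence(ev2, sub2["ori2"].to_numpy(dtype=float))
        asym = nb.asymmetry_score(rel, sel, window=config.bias.window)
        asym.to_frame().to_csv(outdir / "neural_bias_within.csv", index=False)
        tsel = (asym.times >= config.bias.window[0] - 1e-9) & (asym.times <= config.bias.window[1] + 1e-9)
        null = st.signflip_shuffle_null(
            nb.signed_group_difference,
            [asym.trial_deltas], [asym.trial_asym[:, tsel].mean(axis=1)],
            n_iter=config.stats.n_iter, seed=config.seed + 30,
        )
        report["within"] = {**asym.summary(), **null.to_json(), "exclusions": sel.exclusions}
    except ValueError as e:
        report["within"] = {"skipped": str(e)}

    # between-trial: combined evidence, previous-trial target inducer
    with np.load(outdir / "evidence_combined.npz") as f:
        evc = EvidenceTensor(f["evidence"], bins, f["times"], f["cv_fold_of_trial"], f["labels"])
        tidx = f["trial_index"]
        labels = f["labels"]
    prev = table.set_index("trial_index")["prev_target_ori"].reindex(tidx).to_numpy(dtype=float)
    deltas = np.where(np.isfinite(prev), nb.signed_diff(np.where(np.isfinite(prev), prev, 0.0), labels), np.nan)
    lo, hi = config.bias.between_range
    keep = np.isfinite(deltas) & (np.abs(deltas) > lo) & (np.abs(deltas) <= hi) & (deltas != 0)
    sel_b = nb.InducerSelection(
        trial_index=np.flatnonzero(keep), deltas=deltas[keep],
        inducer="prev_trial_target", delta_range=tuple(config.bias.between_range),
        exclusions={"excluded": int((~keep).sum())},
    )
    rel_b = align_evidence(evc, labels)
    asym_b = nb.asymmetry_score(rel_b, sel_b, window=config.bias.window)
    asym_b.to_frame().to_csv(outdir / "neural_bias_between.csv", index=False)
    tselb = (asym_b.times >= config.bias.window[0] - 1e-9) & (asym_b.times <= config.bias.window[1] + 1e-9)
    null_b = st.signflip_shuffle_null(
        nb.signed_group_difference,
        [asym_b.trial_deltas], [asym_b.trial_asym[:, tselb].mean(axis=1)],
        n_iter=config.stats.n_iter, seed=config.seed + 31,
    )
    report["between"] = {**asym_b.summary(), **null_b.to_json(), "exclusions": sel_b.exclusions}

    # cross-decoding of the previous target from the combined evidence
    scores, rel_x = nb.cross_decode_evidence(evc, prev)
    xnull = st.alignment_shuffle_null(
        evc, prev, window=config.bias.window,
        n_iter=min(config.stats.n_iter, 500), seed=config.seed + 32,
    )
    pd.DataFrame({"time": rel_x.times, "cross_decoding": scores.mean(axis=0)}).to_csv(
        outdir / "cross_decoding.csv", index=False
    )
    report["cross_decoding"] = {
        "window_mean": window_mean(scores, rel_x.times, config.bias.window),
        "n_trials": int(rel_x.trial_index.size),
        **xnull.to_json(),
    }
    (outdir / "neural_report.json").write_text(json.dumps(report, indent=2))
    log.info("bias: between window_mean=%.4f z=%.2f",
             report["between"]["window_mean"], report["between"]["z"])
    return report


def run_pipeline(config: RunConfig, outdir):
    """Execute all stages; returns the collated report dictionary."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = _setup_logging(outdir)
    config.to_yaml(outdir / "config.yaml")
    report = {"config_hash": config.config_hash, "stages": {}}
    t_all = time.time()
    try:
        stage_defs = [
            ("simulate", lambda: stage_simulate(config, outdir)),
            ("behavior", lambda: stage_behavior(config, outdir)),
            ("decode", lambda: stage_decode(config, outdir)),
            ("bias", lambda: stage_bias(config, outdir)),
        ]
        for name, fn in stage_defs:
            t0 = time.time()
            try:
                out = fn()
            except Exception as e:  # noqa: BLE001 - annotate stage and re-raise
                log.error("stage %s failed: %s", name, e)
                (outdir / "report.json").write_text(json.dumps(report, indent=2))
                raise PipelineError(name, e) from e
            report["stages"][name] = {"runtime_s": round(time.time() - t0, 3)}
            if name == "behavior":
                report["behavior"] = out
            elif name == "decode":
                report["decoding"] = out[0]
            elif name == "bias":
                report["neural"] = out
        report["total_runtime_s"] = round(time.time() - t_all, 3)
        (outdir / "report.json").write_text(json.dumps(report, indent=2))
        log.info("pipeline complete in %.1fs (config %s)", time.time() - t_all, config.config_hash)
        return report
    finally:
        log.removeHandler(handler)
        handler.close()
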