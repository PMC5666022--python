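"""Batch experiment runner with presets for the standard analyses.

Each preset bundles a parameter set with the analyses run on its output:
event logs, the interval distribution P(DT), fluctuation scaling, tail-model
fits with Akaike weights and goodness of fit, and structure aspect ratios.
Artefacts are plain CSV/JSON and fully determined by (preset, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import observables as obs
from . import stats as st
from .params import ConfigError, SimParams
from .simulate import events_frame, metrics_frame, run_trials


@dataclass
class ExperimentSpec:
    """One named experiment: parameters plus requested analyses."""
    name: str
    params: SimParams
    n_trials_for_fits: int = 5    # trials pooled for tail fitting
    outputs: tuple = ("events", "metrics", "histogram", "fits",
                      "fluctuation", "aspect")


def presets(seed: int = 0) -> dict:
    """The standard experiment battery.

    * ``defaults``   — TM model at default parameters, 100 trials
      (interval distribution, fluctuation scaling, aspect ratio).
    * ``tm_fits`` / ``ntm_fits`` — tail-model selection on 5 pooled trials
      of the TM and NTM models.
    * ``threshold3`` / ``threshold7`` — TM with the initial threshold moved
      to 3 or 7.
    * ``broad_movement`` — TM with threshold 3 and diffuse descent
      (0.50/0.25/0.25), which suppresses short interdrop intervals.
    * ``multi_height`` — TM with entry drawn from three heights at and
      below the rod.

    Aliases fig2/fig3/fig4a-d/fig5/s3 name the same presets by the figure
    they reproduce.
    """
    base = SimParams(seed=seed)
    specs = {
        "defaults": ExperimentSpec("defaults", base),
        "tm_fits": ExperimentSpec("tm_fits", base.with_(n_trials=5)),
        "ntm_fits": ExperimentSpec("ntm_fits",
                                   base.with_(variant="NTM", n_trials=5)),
        "threshold3": ExperimentSpec("threshold3",
                                     base.with_(threshold0=3.0, n_trials=5)),
        "threshold7": ExperimentSpec("threshold7",
                                     base.with_(threshold0=7.0, n_trials=5)),
        "broad_movement": ExperimentSpec(
            "broad_movement",
            base.with_(threshold0=3.0, prob_y_minus=0.5,
                       prob_x_plus=0.25, prob_x_minus=0.25)),
        "multi_height": ExperimentSpec(
            "multi_height",
            base.with_(entry_positions=((500, 500), (500, 499), (500, 498)),
                       n_trials=5)),
    }
    aliases = {"fig2": "defaults", "fig3": "defaults", "fig4a": "tm_fits",
               "fig4b": "ntm_fits", "fig4c": "threshold3",
               "fig4d": "threshold7", "fig5": "broad_movement",
               "s3": "multi_height"}
    for alias, target in aliases.items():
        specs[alias] = specs[target]
    return specs


def summarise(results, params: SimParams) -> dict:
    """Machine-readable summary of a batch of trials."""
    series = obs.intervals_per_trial(results)
    sizes = obs.pooled_sizes(series)
    n_events = [len(r.events) for r in results]
    summary = {
        "variant": params.variant,
        "n_trials": len(results),
        "droplets_per_trial": float(np.mean(n_events)) if n_events else 0.0,
        "mean_droplet_size": float(sizes.mean()) if sizes.size else None,
        "sd_droplet_size": float(sizes.std(ddof=1)) if sizes.size > 1 else None,
    }

    # fluctuation scaling, averaged over trials long enough to analyse
    alphas = []
    for s in series:
        if len(s.dt) >= 12:
            res = st.fluctuation_function(s.dt)
            if np.isfinite(res.alpha):
                alphas.append(res.alpha)
    summary["alpha"] = float(np.mean(alphas)) if alphas else None

    # tail-model selection on pooled increment magnitudes
    mags = obs.pooled_increment_magnitudes(series)
    if mags.size >= 5 and np.any(mags > 1):
        sel = st.compare_tail_models(mags, x_min=1.0)
        summary["n_increments"] = int(mags.size)
        summary["mu"] = sel["power_law"].parameter
        summary["lambda"] = sel["exponential"].parameter
        summary["aic_weight_power_law"] = sel["akaike_weights"][st.POWER_LAW]
        summary["preferred_model"] = sel["preferred"]
        summary["g_statistic"] = sel["gof"].g_statistic
        summary["g_df"] = sel["gof"].df
        summary["g_p_value"] = sel["gof"].p_value

    try:
        width, height = obs.aspect_ratio_track(metrics_frame(results))
        summary["mean_max_width"] = width
        summary["mean_max_height"] = height
    except (ValueError, KeyError):
        pass
    return summary


def run_experiment(spec: ExperimentSpec, out_dir, n_trials: int | None = None) -> dict:
    """Execute a spec and write its artefacts; returns the summary dict."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results = run_trials(spec.params, n_trials=n_trials)
    try:
        events_frame(results).to_csv(out / f"{spec.name}_events.csv", index=False)
        metrics_frame(results).to_csv(out / f"{spec.name}_metrics.csv", index=False)
        series = obs.intervals_per_trial(results)
        pooled_dt = np.concatenate([s.dt for s in series]) if series else np.array([])
        if pooled_dt.size:
            hist = obs.interval_histogram(pooled_dt)
            hist.rename_axis("dt").rename("p").to_csv(out / f"{spec.name}_pdt.csv")
        summary = summarise(results, spec.params)
        with open(out / f"{spec.name}_summary.json", "w") as fh:
            json.dump(summary, fh, indent=2)
    except OSError as exc:
        raise OSError(f"writing artefacts for {spec.name!r} under {out}: {exc}") from exc
    return summary
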