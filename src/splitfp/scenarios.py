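"""Canonical simulation scenarios for slope-limit and recovery studies.

The equilibrium model's headline predictions — log-log slope 2 when the
effective K_D is far above cellular fragment concentrations, slope 1 when
far below, and raw slope 1 for a proportionally co-produced full-length
control — are statements about an idealized population in which the two
fragments are expressed in near-fixed proportion and autofluorescence is
negligible next to the dimmest complemented signal.  The scenarios here
encode that idealization once so that tests, analysis drivers and the
reproduction script all run the *same* study conditions:

* expression spans 4 decades (log10 sd = 1 around a median of 100 units),
* FP_1-10 tracks the FP_11 species at ratio 2 with correlation 0.95
  (the conditional log-log relation has slope 1, so the equilibrium
  model's slope is the regression estimand),
* autofluorescence is ~1e-6 of the median signal — "low" in the sense
  that the positivity threshold derived from untransfected cells does not
  truncate the complemented-signal axis, which would bias OLS,
* no doublets, all cells transfected; the gates still run and remove
  events only at random with respect to expression.

Under these conditions the full pipeline's rescaled slope matches
``predicted_slope`` within a few hundredths across at least six decades
of K_D.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .flow import run_flow_analysis
from .model import SlopeTheoryInput, predicted_slope
from .simulate.flow import (
    TransfectionSimConfig,
    simulate_flow_experiment,
    simulate_full_length_control,
    simulate_untransfected,
)

__all__ = [
    "limit_scenario_config",
    "run_slope_scenario",
    "predicted_slope_for_scenario",
]


def limit_scenario_config(
    kd_multiple: float, seed: int, n_events: int = 20000
) -> TransfectionSimConfig:
    """Config for a limit-regime run with K_D = ``kd_multiple`` x median concentration."""
    base = TransfectionSimConfig(
        n_events=n_events,
        kd=1.0,  # placeholder, set below from the median
        log10_b_mean=2.0,
        log10_b_sd=1.0,
        expression_ratio=2.0,
        rho=0.95,
        autofluor_green_mean=1e-6,
        autofluor_green_sd=5e-7,
        autofluor_blue_mean=1e-6,
        autofluor_blue_sd=5e-7,
        transfected_fraction=1.0,
        doublet_fraction=0.0,
        seed=seed,
    )
    return replace(base, kd=kd_multiple * base.median_b)


def run_slope_scenario(
    kd_multiple: float,
    seeds: tuple[int, ...] = (0, 1, 2, 3, 4),
    n_events: int = 20000,
) -> dict:
    """Full-pipeline slope estimate in a limit regime, averaged over seeds.

    For each seed, simulates a split sample, a full-length control and an
    untransfected control under identical conditions, runs the complete
    pipeline (saturation filter, scatter and singlet gates, log transform,
    untransfected thresholds, control rescaling, OLS) and collects the
    rescaled split slope and the raw control slope.

    Returns means and per-seed values of both.
    """
    rescaled, raw_control = [], []
    for seed in seeds:
        cfg = limit_scenario_config(kd_multiple, seed, n_events)
        split_table, _ = simulate_flow_experiment(cfg)
        control = simulate_full_length_control(replace(cfg, seed=seed + 10_000))
        untrans = simulate_untransfected(replace(cfg, seed=seed + 20_000))
        report = run_flow_analysis(
            {"split": split_table, "control": control, "untransfected": untrans},
            untransfected="untransfected",
            full_length="control",
        )
        rescaled.append(report["samples"]["split"]["fit"]["rescaled_slope"])
        raw_control.append(report["samples"]["control"]["fit"]["raw_slope"])
    return {
        "kd_multiple": kd_multiple,
        "rescaled_slope_mean": float(np.mean(rescaled)),
        "rescaled_slopes": rescaled,
        "control_raw_slope_mean": float(np.mean(raw_control)),
        "control_raw_slopes": raw_control,
        "seeds": list(seeds),
        "n_events": n_events,
    }


def predicted_slope_for_scenario(
    kd_multiple: float, config: TransfectionSimConfig | None = None
) -> float:
    """Closed-form slope prediction matched to a scenario's fitted range.

    Evaluates :func:`splitfp.model.predicted_slope` over the central 95%
    of the simulated FP_11 concentration distribution (the range the
    pipeline effectively fits), at the scenario's expression ratio.
    """
    cfg = config or limit_scenario_config(kd_multiple, seed=0)
    lo = 10.0 ** (cfg.log10_b_mean - 1.96 * cfg.log10_b_sd)
    hi = 10.0 ** (cfg.log10_b_mean + 1.96 * cfg.log10_b_sd)
    return predicted_slope(
        SlopeTheoryInput(
            kd=kd_multiple * cfg.median_b,
            expression_ratio=cfg.expression_ratio,
            b_range=(lo, hi),
        )
    )
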