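"""Reference study designs built on the pipeline.

Two designs mirror a normative-database study on healthy adult eyes:

* the *normative cohort study*: one full-size cohort (default 397 eyes)
  pushed through render -> degrade -> segment -> measure, summarised by
  the headline normative quantities (average grayscale, average
  thickness, the nasal-sector depression and its significance) and the
  determinant regression;
* the *parameter-recovery study*: many scaled-down replicate cohorts,
  each refit with the multivariable model, to characterise the sampling
  distribution of the recovered effect sizes and the coverage of their
  confidence intervals.

All randomness descends from one master seed through
``numpy.random.SeedSequence`` substreams, so each study is a pure
function of its arguments.
"""

from __future__ import annotations

import numpy as np

from . import cohortstats
from .pipeline import PipelineConfig, run_pipeline
from .synthdata import GenerativeParams

#: The four generative determinants of average pRNFL grayscale and the
#: effect sizes the default generator assigns them (gray levels per
#: covariate unit).
GENERATIVE_EFFECTS = {"age": -0.053, "al": -0.664, "rpe_gray": 0.372, "imageq": 0.658}


def _subseed(master: int, *path: int) -> int:
    """Derive a 31-bit child seed from the master via SeedSequence."""
    state = np.random.SeedSequence([int(master), *map(int, path)]).generate_state(1)
    return int(state[0] >> 1)


def _recovery_fit(analyzed) -> cohortstats.RegressionResult:
    """The determinant model used for parameter recovery.

    Carry-forward follows the univariable screen; the four generative
    determinants are forced so that every replicate reports a slope for
    each of them even when a scaled-down cohort leaves one short of the
    screening threshold.
    """
    screen = cohortstats.univariable_screen(analyzed)
    return cohortstats.multivariable_fit(
        analyzed,
        carry_forward=screen.carry_forward(),
        forced=tuple(GENERATIVE_EFFECTS),
    )


def normative_cohort_study(seed: int = 1, n_eyes: int = 397) -> dict:
    """One full-size end-to-end cohort; returns the headline summary."""
    run_seed = _subseed(seed, 1)
    cfg = PipelineConfig(
        n_eyes=n_eyes, seed=run_seed, params=GenerativeParams(seed=run_seed)
    )
    manifest = run_pipeline(cfg)
    cohort = manifest["cohort"]
    analyzed = cohort[cohort["excluded"] == ""]
    comparison = cohortstats.compare_sectors(analyzed)
    fit = _recovery_fit(analyzed)
    return {
        "n_analyzed": int(len(analyzed)),
        "gray_mean": float(analyzed["gray_mean"].mean()),
        "thick_mean": float(analyzed["thick_mean"].mean()),
        "gray_N": float(analyzed["gray_N"].mean()),
        "nasal_lowest_significant": cohortstats.nasal_lowest_significant(
            comparison, alpha=0.001
        ),
        "fit": fit,
        "manifest": manifest,
    }


def parameter_recovery_study(
    seed: int = 1, n_reps: int = 50, n_per_rep: int = 100
) -> dict:
    """Replicate cohorts at reduced size; slope recovery and CI coverage.

    Returns per-covariate arrays of slope estimates, their mean, and the
    fraction of replicates whose 95% CI covers the generative value.
    """
    slopes = {k: [] for k in GENERATIVE_EFFECTS}
    covered = {k: 0 for k in GENERATIVE_EFFECTS}
    for rep in range(n_reps):
        rep_seed = _subseed(seed, 2, rep)
        cfg = PipelineConfig(
            n_eyes=n_per_rep, seed=rep_seed, params=GenerativeParams(seed=rep_seed)
        )
        manifest = run_pipeline(cfg)
        cohort = manifest["cohort"]
        analyzed = cohort[cohort["excluded"] == ""]
        fit = _recovery_fit(analyzed)
        for name, true in GENERATIVE_EFFECTS.items():
            r = fit.covariates[name]
            slopes[name].append(r.slope)
            lo, hi = r.ci95
            covered[name] += int(lo <= true <= hi)
    out = {
        "n_reps": n_reps,
        "n_per_rep": n_per_rep,
        "slopes": {k: np.asarray(v) for k, v in slopes.items()},
        "mean_slope": {k: float(np.mean(v)) for k, v in slopes.items()},
        "ci_coverage": {k: covered[k] / n_reps for k in covered},
    }
    return out
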