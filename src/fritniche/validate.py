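"""Ground-truth recovery experiments on synthetic data.

These bundle the standard self-checks of the pipeline: can the ensemble,
under the default study conditions, separate a virtual species from
background (member AUCs), and does the response-curve optimum land on the
species' true environmental optimum? They are used by the test suite and
the reproduction script, and are handy smoke tests after any change.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .occurrences import OccurrenceSet, extract_env
from .sdm import EnsembleSDM, EnsembleSDMResults, fit_sre, sample_pseudo_absences
from .synth import gen_env_stack, gen_virtual_species, sample_occurrences


@dataclass
class RecoveryReport:
    """Outcome of the virtual-species recovery experiment."""

    results: EnsembleSDMResults
    mean_auc: dict[str, float]
    optimum_error_sigma: dict[str, float]  # |recovered - true| / sigma
    truth_optima: dict[str, float]
    truth_widths: dict[str, float]


def virtual_species_recovery(
    seed: int = 1,
    n_rows: int = 100,
    n_cols: int = 100,
    n_presence: int = 200,
    n_runs: int = 15,
    algorithms=("sre", "glm"),
) -> RecoveryReport:
    """Fit the ensemble to a two-variable virtual species and measure how
    well it recovers the truth.

    The stack holds two informative, spatially autocorrelated layers
    (temperature-like and precipitation-like); the species responds to both
    with Gaussian optima. Presences are sampled proportionally to true
    suitability; pseudo-absences come from outside the presence envelope,
    one per presence. Returns per-member mean test AUC over ``n_runs``
    splits and the response-curve optimum error in units of the true
    response width sigma.
    """
    names = ["bio01", "bio12"]
    optima = {"bio01": 14.0, "bio12": 900.0}
    widths = {"bio01": 2.0, "bio12": 120.0}
    stack = gen_env_stack(n_rows, n_cols, 2, corr_length=5.0,
                          means=[12.0, 800.0], sds=[4.0, 250.0],
                          seed=seed, names=names)
    truth = gen_virtual_species(stack, [optima[n] for n in names],
                                [widths[n] for n in names], [1.0, 1.0])
    occ = sample_occurrences(truth, n_presence, duplicate_rate=0.0,
                             seed=seed + 1)
    presence_env = extract_env(stack, occ)
    sre = fit_sre(presence_env)
    absences = sample_pseudo_absences(stack, sre, n=len(occ), seed=seed + 2,
                                      exclude=occ)
    env = extract_env(stack, OccurrenceSet.concat([occ, absences]))
    res = EnsembleSDM(env, algorithms=algorithms, n_runs=n_runs,
                      seed=seed + 3).fit()
    mean_auc = res.scores.groupby("algorithm")["auc"].mean().to_dict()
    err = {}
    for var in names:
        sr = res.suitable_range(var)
        err[var] = abs(sr.optimum - optima[var]) / widths[var]
    return RecoveryReport(res, mean_auc, err, optima, widths)
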