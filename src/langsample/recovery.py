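"""Parameter-recovery and model-selection simulation studies.

These drive :mod:`langsample.simulate` and :mod:`langsample.models` end to
end: cohorts are drawn from the mixed model with known fixed effects, the
same model is refit by REML to each replicate, and the estimates (or the
outcome of the interaction-screening procedure) are collected.  Used both by
the test suite and by ``scripts/acceptance.py``.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Mapping

import numpy as np
import pandas as pd

from .models import (
    BASE_TERMS,
    ModelSpec,
    fit_random_intercept_lmm,
    prepare_records,
    select_final_model,
)
from .simulate import SimCohortConfig, REFERENCE_BETAS, simulate_cohort_scores

__all__ = ["generating_spec", "recovery_study", "selection_study"]


def generating_spec(outcome: str, betas: Mapping[str, float]) -> ModelSpec:
    """The ModelSpec matching a factor's generating fixed-effect vector."""
    extra = tuple(t for t in betas if t not in BASE_TERMS and t != "intercept")
    return ModelSpec(outcome=outcome, fixed_terms=BASE_TERMS + extra)


def _spawn_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.SeedSequence(seed).generate_state(n) % (2**31 - 1)


def recovery_study(
    outcome: str,
    n_replicates: int,
    seed: int,
    config: SimCohortConfig | None = None,
) -> pd.DataFrame:
    """Simulate ``n_replicates`` cohorts for one factor and refit each.

    Returns one row per replicate with the REML estimate of every term of
    the generating model.  The mean of each column is the Monte-Carlo
    estimate whose agreement with the generating coefficient quantifies
    recovery.
    """
    base_cfg = config if config is not None else SimCohortConfig()
    spec = generating_spec(outcome, base_cfg.betas[outcome])
    rows = []
    for rep_seed in _spawn_seeds(seed, n_replicates):
        cfg = replace(base_cfg, seed=int(rep_seed))
        records = prepare_records(simulate_cohort_scores(cfg))
        fit = fit_random_intercept_lmm(records, spec)
        row = fit.params.to_dict()
        row["tau2"] = fit.tau2
        row["sigma2"] = fit.sigma2
        rows.append(row)
    return pd.DataFrame(rows)


def selection_study(
    outcome: str,
    n_replicates: int,
    seed: int,
    config: SimCohortConfig | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Run the interaction-screening procedure on simulated cohorts.

    Returns one row per replicate with a boolean column per diagnosis
    interaction indicating whether it was retained.  With interaction-free
    generating betas the ``age_centered:dx`` retention rate estimates the
    procedure's false-retention rate; with the published Semantic or Fluency
    betas it estimates the power to keep the age-by-diagnosis term.
    """
    base_cfg = config if config is not None else SimCohortConfig()
    rows = []
    for rep_seed in _spawn_seeds(seed, n_replicates):
        cfg = replace(base_cfg, seed=int(rep_seed))
        records = prepare_records(simulate_cohort_scores(cfg))
        sel = select_final_model(
            records, outcome, alpha=alpha, include_secondary=False
        )
        rows.append(
            {
                term: term in sel.retained_interactions
                for term in sel.interaction_pvalues
            }
        )
    return pd.DataFrame(rows)


def interaction_free_config(seed: int = 0) -> SimCohortConfig:
    """Default cohort config with every diagnosis interaction removed."""
    betas = {
        f: {t: b for t, b in REFERENCE_BETAS[f].items() if ":" not in t}
        for f in REFERENCE_BETAS
    }
    return SimCohortConfig(betas=betas, seed=seed)
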