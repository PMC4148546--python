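"""Synthetic cohorts with planted outcome-linked genes.

Expression is i.i.d. standard normal per gene; a small planted set of
informative genes drives a latent per-patient risk score, half with positive
and half with negative sign so both the risk and protective signature sets
are exercised.  Survival endpoints draw exponential event times whose hazard
is proportional to exp(risk), with independent exponential censoring; binary
endpoints draw responder status from a logistic model on the same latent
score.  Everything is reproducible from the config seed, and the written
files use the exact TSV formats the loaders read.

Default rates target a node-negative breast-cancer-like cohort: baseline
hazard 0.004 events/month puts roughly 35-40% of patients past an event
within the 120-month horizon, censoring hazard 0.002/month keeps loss to
follow-up mild, and the binary intercept of -1 gives ~27% responders, in
line with pathological-response rates to neoadjuvant chemotherapy.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .expression import (
    DEFAULT_HORIZON_MONTHS,
    ResponseRecord,
    SurvivalRecord,
    write_clinical_table,
    write_expression_matrix,
)


@dataclass(frozen=True)
class SimulationConfig:
    """Cohort-generator settings.

    effect_size is each informative gene's contribution to the log-hazard
    (survival mode) or log-odds (binary mode) per standardized-expression
    unit; hazards are per month.
    """

    n_genes: int = 1000
    n_samples: int = 200
    n_informative: int = 12
    effect_size: float = 0.5
    baseline_hazard: float = 0.004
    censoring_rate: float = 0.002
    horizon_months: float = DEFAULT_HORIZON_MONTHS
    response_intercept: float = -1.0
    seed: int | None = None
    endpoint_mode: str = "survival"

    def __post_init__(self):
        if self.n_informative > self.n_genes:
            raise ValueError("n_informative exceeds n_genes")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.baseline_hazard <= 0 or self.censoring_rate <= 0:
            raise ValueError("hazards must be positive")
        if self.endpoint_mode not in ("survival", "binary"):
            raise ValueError(f"unknown endpoint_mode {self.endpoint_mode!r}")


def _draw_expression(cfg: SimulationConfig, rng: np.random.Generator,
                     truth: pd.DataFrame | None = None):
    gene_ids = [f"G{i:05d}" for i in range(cfg.n_genes)]
    sample_ids = [f"S{i:04d}" for i in range(cfg.n_samples)]
    x = rng.standard_normal((cfg.n_genes, cfg.n_samples))
    m = pd.DataFrame(x, index=pd.Index(gene_ids, name="ID"), columns=sample_ids)

    if truth is None:
        informative = rng.choice(cfg.n_genes, size=cfg.n_informative, replace=False)
        informative = np.sort(informative)
        # half risk (+1), half protective (-1); odd counts give the extra to +1
        signs = np.ones(cfg.n_informative, dtype=int)
        signs[cfg.n_informative - cfg.n_informative // 2:] = -1
        truth = pd.DataFrame(
            {"gene_id": [gene_ids[i] for i in informative], "sign": signs}
        )
    else:
        # reuse planted structure, e.g. for an independent validation cohort
        missing = [g for g in truth["gene_id"] if g not in m.index]
        if missing:
            raise ValueError(f"truth genes outside the gene universe: {missing[:5]}")
        informative = m.index.get_indexer(truth["gene_id"])
        signs = truth["sign"].to_numpy()
    risk = cfg.effect_size * (signs @ x[informative])
    return m, truth, risk


def simulate_survival_cohort(cfg: SimulationConfig, truth: pd.DataFrame | None = None):
    """Expression matrix, survival records, and the planted-gene truth table.

    Event time ~ Exponential(baseline_hazard * exp(risk)); censoring time
    ~ Exponential(censoring_rate); observed follow-up is the minimum with an
    event indicator.  Pass a ``truth`` table from an earlier cohort to plant
    the same informative genes (an independent validation cohort).
    """
    rng = np.random.default_rng(cfg.seed)
    m, truth, risk = _draw_expression(cfg, rng, truth=truth)
    hazard = cfg.baseline_hazard * np.exp(risk)
    t_event = rng.exponential(1.0 / hazard)
    t_cens = rng.exponential(1.0 / cfg.censoring_rate, size=cfg.n_samples)
    time = np.minimum(t_event, t_cens)
    event = t_event <= t_cens
    records = [
        SurvivalRecord(sid, float(t), bool(e))
        for sid, t, e in zip(m.columns, time, event)
    ]
    return m, records, truth


def simulate_response_cohort(cfg: SimulationConfig, truth: pd.DataFrame | None = None):
    """Expression matrix, RCB response records, and the truth table.

    P(responder) = logistic(intercept + risk); responders get RCB 0 or I and
    non-responders II or III, the within-pair class uniform.  ``truth``
    replants a previous cohort's informative genes.
    """
    rng = np.random.default_rng(cfg.seed)
    m, truth, risk = _draw_expression(cfg, rng, truth=truth)
    p_resp = 1.0 / (1.0 + np.exp(-(cfg.response_intercept + risk)))
    responder = rng.random(cfg.n_samples) < p_resp
    sub = rng.integers(0, 2, size=cfg.n_samples)
    classes = np.where(
        responder, np.where(sub == 0, "0", "I"), np.where(sub == 0, "II", "III")
    )
    records = [
        ResponseRecord(sid, str(c)) for sid, c in zip(m.columns, classes)
    ]
    return m, records, truth


def write_cohort(m: pd.DataFrame, records, truth: pd.DataFrame, outdir) -> dict:
    """Write expression.tsv, clinical.tsv and truth.tsv; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": outdir / "expression.tsv",
        "clinical": outdir / "clinical.tsv",
        "truth": outdir / "truth.tsv",
    }
    write_expression_matrix(m, paths["expression"])
    write_clinical_table(records, paths["clinical"])
    truth.to_csv(paths["truth"], sep="\t", index=False)
    return paths
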