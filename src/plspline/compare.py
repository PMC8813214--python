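"""Model-comparison harness: six PLS-spline variants against PLS-Cox.

One 70:30 train/test split and one PLS decomposition (per component count)
feed all seven fits, so differences in AIC/BIC isolate the survival stage:
flexible parametric fits on the hazard, odds and normal scales with zero and
one internal knot, and the Cox benchmark.  Criteria are computed on the
training fit; the held-out partition is additionally scored with
out-of-sample log-likelihood.  Note the Cox row's criteria come from the
partial likelihood while the spline rows use full likelihoods.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import scales as _sc
from .cox import partial_log_likelihood_at
from .data import SurvivalData
from .pls import CompositeFit, _component_data, _extract_for_survival, fit_pls_cox, fit_pls_spline, project
from .rp import log_likelihood_at
from .simulate import split_train_test

__all__ = ["ComparisonTable", "run_comparison", "plot_information_criteria"]

SPLINE_GRID = tuple(
    (f"RP_pls{tag}_{k}", scale, k)
    for tag, scale in (("H", _sc.HAZARD), ("O", _sc.ODDS), ("N", _sc.NORMAL))
    for k in (0, 1)
)
COX_LABEL = "PLS-Cox"
MODEL_LABELS = tuple(label for label, _, _ in SPLINE_GRID) + (COX_LABEL,)


@dataclass
class ComparisonTable:
    """Result of one comparison run.

    ``table`` has one row per model (label, scale, knots, components,
    train/test log-likelihoods, AIC, BIC, convergence flag); ``ranking``
    lists converged model labels by ascending AIC.
    """

    table: pd.DataFrame
    ranking: list[str]
    fits: dict[str, CompositeFit] = field(default_factory=dict)
    seed: int = 0
    train_n: int = 0
    test_n: int = 0

    @property
    def best(self) -> str:
        return self.ranking[0]

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    def to_json(self, path) -> None:
        doc = {
            "seed": self.seed,
            "train_n": self.train_n,
            "test_n": self.test_n,
            "ranking": self.ranking,
            "models": self.table.to_dict(orient="records"),
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=2)


def run_comparison(
    data: SurvivalData,
    C: int = 2,
    train_fraction: float = 0.7,
    seed: int = 0,
) -> ComparisonTable:
    """Split, extract once, fit all seven models, tabulate AIC/BIC and rank.

    Non-converged fits are kept in the table but flagged and excluded from
    the ranking; if no fit converges an error is raised.
    """
    train, test = split_train_test(data, train_fraction, seed)
    decomposition = _extract_for_survival(train, C)
    test_scores = project(decomposition, test.covariates)
    test_on_scores = SurvivalData(
        time=test.time,
        status=test.status,
        covariates=test_scores,
        covariate_names=[f"comp{c + 1}" for c in range(C)],
    )

    rows = []
    fits: dict[str, CompositeFit] = {}
    for label, scale, k in SPLINE_GRID:
        composite = fit_pls_spline(train, C, scale, k, decomposition=decomposition)
        stage = composite.survival_stage
        rows.append(
            {
                "model": label,
                "scale": scale,
                "n_internal_knots": k,
                "C": C,
                "log_likelihood": stage.log_likelihood,
                "test_log_likelihood": log_likelihood_at(stage, test_on_scores),
                "aic": stage.aic,
                "bic": stage.bic,
                "converged": bool(stage.converged),
            }
        )
        fits[label] = composite

    composite = fit_pls_cox(train, C, decomposition=decomposition)
    stage = composite.survival_stage
    rows.append(
        {
            "model": COX_LABEL,
            "scale": "cox",
            "n_internal_knots": None,
            "C": C,
            "log_likelihood": stage.partial_log_likelihood,
            "test_log_likelihood": partial_log_likelihood_at(test_on_scores, stage.beta),
            "aic": stage.aic,
            "bic": stage.bic,
            "converged": bool(stage.converged),
        }
    )
    fits[COX_LABEL] = composite

    table = pd.DataFrame(rows)
    converged = table[table["converged"]]
    if converged.empty:
        raise RuntimeError("no model converged; cannot rank")
    ranking = converged.sort_values("aic", kind="stable")["model"].tolist()
    return ComparisonTable(
        table=table,
        ranking=ranking,
        fits=fits,
        seed=seed,
        train_n=train.n,
        test_n=test.n,
    )


def plot_information_criteria(result: ComparisonTable, path, criterion: str = "aic") -> None:
    """Minimal bar plot of AIC or BIC across the seven models."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    tab = result.table
    fig, ax = plt.subplots(figsize=(7, 4))
    ax.bar(tab["model"], tab[criterion.lower()])
    ax.set_ylabel(criterion.upper())
    ax.set_xlabel("model")
    ax.tick_params(axis="x", rotation=45)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
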