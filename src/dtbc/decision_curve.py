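"""Decision-curve analysis for the neck-dissection decision.

At a threshold probability pt — the risk of occult nodal metastasis at
which a clinician is indifferent between operating and not — the net
benefit of acting on a risk model is

    NB(pt) = TP/n - FP/n * pt / (1 - pt)

with patients treated when their predicted probability is at least pt.
Treat-none has net benefit zero by definition; treat-all has
``prevalence - (1 - prevalence) * pt/(1 - pt)``.  The net reduction in
unnecessary interventions per 100 patients relative to treat-all is

    (NB_model - NB_all) * (1 - pt)/pt * 100.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "DecisionCurve",
    "net_benefit",
    "net_benefit_all",
    "net_reduction",
    "decision_curve",
]


def _check_pt(pt: float) -> None:
    if not 0.0 < pt < 1.0:
        raise ValueError(f"threshold probability must lie in (0, 1); got {pt}")


def net_benefit(labels: np.ndarray, probs: np.ndarray, pt: float) -> float:
    """Net benefit of treating patients whose predicted risk is >= pt."""
    _check_pt(pt)
    y = np.asarray(labels, dtype=float)
    p = np.asarray(probs, dtype=float)
    if y.shape != p.shape:
        raise ValueError("labels and probs must have the same length")
    n = len(y)
    treat = p >= pt
    tp = float(np.count_nonzero(treat & (y == 1)))
    fp = float(np.count_nonzero(treat & (y == 0)))
    return tp / n - (fp / n) * pt / (1.0 - pt)


def net_benefit_all(prevalence: float, pt: float) -> float:
    """Net benefit of the treat-all strategy at threshold probability pt."""
    if not 0.0 <= prevalence <= 1.0:
        raise ValueError("prevalence must lie in [0, 1]")
    _check_pt(pt)
    return prevalence - (1.0 - prevalence) * pt / (1.0 - pt)


def net_reduction(labels: np.ndarray, probs: np.ndarray, pt: float) -> float:
    """Interventions avoided per 100 patients vs treat-all, no metastasis missed."""
    _check_pt(pt)
    y = np.asarray(labels, dtype=float)
    nb_model = net_benefit(y, probs, pt)
    nb_all = net_benefit_all(float(np.mean(y)), pt)
    return (nb_model - nb_all) * (1.0 - pt) / pt * 100.0


@dataclass(frozen=True)
class DecisionCurve:
    """Net benefit and net reduction per threshold probability per strategy."""

    thresholds: np.ndarray
    net_benefit: pd.DataFrame  # index pt, one column per strategy (+ references)
    net_reduction_per100: pd.DataFrame  # vs treat-all; reference strategies included

    def to_frame(self) -> pd.DataFrame:
        nb = self.net_benefit.add_prefix("nb_")
        nr = self.net_reduction_per100.add_prefix("net_reduction_")
        return pd.concat([nb, nr], axis=1)


def decision_curve(
    labels: np.ndarray,
    strategy_scores: Mapping[str, np.ndarray],
    pt_grid: np.ndarray | None = None,
) -> DecisionCurve:
    """Tabulate net benefit and net reduction over a threshold grid.

    ``strategy_scores`` maps strategy names to predicted probabilities;
    ``treat_all`` and ``treat_none`` reference rows are always included.
    The default grid spans 1%..50% in 1% steps, the clinically relevant
    range for the neck-dissection decision.
    """
    if not strategy_scores:
        raise ValueError("need at least one strategy")
    y = np.asarray(labels, dtype=float)
    prev = float(np.mean(y))
    if pt_grid is None:
        pt_grid = np.round(np.arange(0.01, 0.501, 0.01), 10)
    pt_grid = np.asarray(pt_grid, dtype=float)
    nb = {name: [] for name in strategy_scores}
    nb["treat_all"] = []
    nb["treat_none"] = []
    nr = {name: [] for name in strategy_scores}
    nr["treat_all"] = []
    nr["treat_none"] = []
    for pt in pt_grid:
        nb_all = net_benefit_all(prev, pt)
        nb["treat_all"].append(nb_all)
        nb["treat_none"].append(0.0)
        nr["treat_all"].append(0.0)
        nr["treat_none"].append(-nb_all * (1.0 - pt) / pt * 100.0)
        for name, scores in strategy_scores.items():
            nb_s = net_benefit(y, scores, pt)
            nb[name].append(nb_s)
            nr[name].append((nb_s - nb_all) * (1.0 - pt) / pt * 100.0)
    return DecisionCurve(
        thresholds=pt_grid,
        net_benefit=pd.DataFrame(nb, index=pt_grid),
        net_reduction_per100=pd.DataFrame(nr, index=pt_grid),
    )
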