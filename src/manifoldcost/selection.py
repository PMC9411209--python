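"""Cost-guided backward elimination of state variables.

Starting from the full set of Q state variables, each iteration removes the
variable whose removal yields the lowest topology cost for the q-dimensional
PCA projection of the remaining subset (scaling recomputed on the subset,
dependent variables held fixed).  Q - q iterations are allowed so the data is
never reduced below the target manifold dimensionality; the returned subset
is the one from the iteration with the global minimum cost, with the
untouched full set recorded as iteration 0 so that "remove nothing" can win.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_is_fitted

from .cost import ManifoldCost
from .preprocess import _as_matrix, apply_normalization, compute_scaling
from .projection import pca_basis, project

__all__ = ["CostGuidedFeatureSelector", "FeatureSelectionTrace", "select_features"]

logger = logging.getLogger(__name__)


@dataclass
class FeatureSelectionTrace:
    """Per-iteration record of the backward-elimination search."""

    iterations: list[dict] = field(default_factory=list)
    best_iteration: int = 0
    optimal_subset: list[str] = field(default_factory=list)

    def add(self, removed: str | None, cost: float, remaining: list[str]):
        self.iterations.append(
            {
                "iteration": len(self.iterations),
                "removed_variable": removed,
                "cost": float(cost),
                "remaining": list(remaining),
            }
        )

    @property
    def costs(self) -> np.ndarray:
        return np.array([it["cost"] for it in self.iterations])

    def finalize(self):
        self.best_iteration = int(np.argmin(self.costs))
        self.optimal_subset = list(self.iterations[self.best_iteration]["remaining"])
        return self

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "iteration": it["iteration"],
                    "removed_variable": it["removed_variable"] or "",
                    "cost": it["cost"],
                }
                for it in self.iterations
            ]
        )

    def to_dict(self) -> dict:
        return {
            "iterations": self.iterations,
            "best_iteration": self.best_iteration,
            "optimal_subset": self.optimal_subset,
        }


def _projection_cost(X, names, q, scaling, cost_options, phi) -> float:
    centers, scales = compute_scaling(X, scaling)
    Xn = apply_normalization(X, centers, scales)
    A, _ = pca_basis(Xn, q)
    eta = project(Xn, A)
    return ManifoldCost(**cost_options).fit(eta, phi).cost_


class CostGuidedFeatureSelector(SelectorMixin, BaseEstimator):
    """Select the state-variable subset whose PCA projection minimizes cost.

    Parameters
    ----------
    n_components : int
        Target manifold dimensionality q (must be < Q).
    scaling : str, default="auto"
        Scaling applied to each candidate subset before PCA; centers and
        scale factors are recomputed on the subset at every evaluation.
    cost_options : dict, optional
        Keyword arguments forwarded to :class:`~manifoldcost.cost.ManifoldCost`
        (r, b, norm, peak_shift, sigma grid, ...).

    Attributes
    ----------
    trace_ : FeatureSelectionTrace
        Iteration 0 is the full set; ties between equal-cost removals go to
        the lower-index column (logged).
    support_ : ndarray of bool, shape (Q,)
    best_cost_ : float

    Notes
    -----
    The dependent variables ``phi`` passed to ``fit`` are held fixed: a
    variable eliminated from the state-space still participates as a
    regression target.
    """

    def __init__(
        self,
        n_components: int = 2,
        scaling: str = "auto",
        cost_options: dict | None = None,
    ):
        self.n_components = n_components
        self.scaling = scaling
        self.cost_options = cost_options

    def fit(self, X, phi):
        X, names = _as_matrix(X)
        phi, _ = _as_matrix(phi)
        Q = X.shape[1]
        q = self.n_components
        if q >= Q:
            raise ValueError(
                f"target dimension q={q} must be smaller than Q={Q} variables"
            )
        options = dict(self.cost_options or {})

        trace = FeatureSelectionTrace()
        remaining = list(range(Q))
        trace.add(
            None,
            _projection_cost(X, names, q, self.scaling, options, phi),
            [names[j] for j in remaining],
        )

        for _ in range(Q - q):
            candidate_costs: list[tuple[float, int]] = []
            for drop in remaining:
                cols = [j for j in remaining if j != drop]
                try:
                    c = _projection_cost(
                        X[:, cols], [names[j] for j in cols], q,
                        self.scaling, options, phi,
                    )
                except ValueError as exc:
                    logger.warning(
                        "skipping removal of %r: %s", names[drop], exc
                    )
                    continue
                candidate_costs.append((c, drop))
            if not candidate_costs:
                logger.warning("no viable removal candidate; stopping early")
                break
            best_cost = min(c for c, _ in candidate_costs)
            tied = [j for c, j in candidate_costs if c == best_cost]
            if len(tied) > 1:
                logger.info(
                    "cost tie between %s; removing lowest-index column",
                    [names[j] for j in tied],
                )
            removed = min(tied)
            remaining = [j for j in remaining if j != removed]
            trace.add(names[removed], best_cost, [names[j] for j in remaining])

        self.trace_ = trace.finalize()
        self.best_cost_ = float(trace.costs[trace.best_iteration])
        support = np.zeros(Q, dtype=bool)
        keep = set(self.trace_.optimal_subset)
        for j, name in enumerate(names):
            support[j] = name in keep
        self.support_ = support
        self.feature_names_in_ = np.asarray(names, dtype=object)
        self.n_features_in_ = Q
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "support_")
        return self.support_


def select_features(
    X, phi, q: int, scaling: str = "auto", **cost_options
) -> FeatureSelectionTrace:
    """Run backward elimination and return the iteration trace."""
    selector = CostGuidedFeatureSelector(
        n_components=q, scaling=scaling, cost_options=cost_options or None
    )
    return selector.fit(X, phi).trace_
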