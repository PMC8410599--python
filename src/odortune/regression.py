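"""Exhaustive low-dimensional regression ranking of ligand descriptors.

Which physicochemical properties predict agonism? Every single descriptor
(11 one-dimensional models) and every unordered pair (C(11,2) = 55
two-dimensional models) is fitted by ordinary least squares against the
activity index over the descriptor-complete ligands, and models are
ranked by R² — the square of the Pearson correlation between observed
and modelled activity (identical to the coefficient of determination for
OLS with intercept). Ligands with any missing descriptor are excluded
up front and itemized in an exclusion report.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from sklearn.linear_model import LinearRegression

from .errors import InsufficientDataError, InvalidParameterError
from .synth import DESCRIPTOR_NAMES

__all__ = [
    "RegressionResult",
    "filter_complete",
    "fit_linear_model",
    "r_squared",
    "enumerate_and_rank",
    "DescriptorScan",
]


def filter_complete(
    panel: pd.DataFrame, descriptor_names=DESCRIPTOR_NAMES
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Retain ligands with a full descriptor record.

    Returns (retained panel, exclusion report listing each dropped ligand
    once with its missing descriptor fields). Aborts when nothing remains.
    """
    descriptor_names = [d for d in descriptor_names if d in panel.columns]
    if not descriptor_names:
        raise InvalidParameterError("panel carries none of the descriptor columns")
    missing_mask = panel[descriptor_names].isna()
    dropped = panel.loc[missing_mask.any(axis=1)]
    report = pd.DataFrame(
        {
            "ligand_id": dropped["ligand_id"].to_numpy(),
            "missing_descriptors": [
                ",".join(missing_mask.columns[row])
                for row in missing_mask.loc[dropped.index].to_numpy()
            ],
        }
    )
    retained = panel.loc[~missing_mask.any(axis=1)].reset_index(drop=True)
    if retained.empty:
        raise InsufficientDataError(
            "no ligand has a complete descriptor record; analysis aborted"
        )
    return retained, report


def fit_linear_model(X, y) -> tuple[np.ndarray, float, bool]:
    """OLS with intercept minimizing the residual sum of squares.

    Returns (coefficients [slopes..., intercept], R², rank_deficient).
    Rank-deficient designs are flagged with NaN coefficients so the caller
    can exclude them from ranking.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n < p + 1:
        raise InsufficientDataError(f"need >= {p + 1} rows for {p} descriptors, got {n}")
    if np.isnan(X).any() or np.isnan(y).any():
        raise InvalidParameterError("missing values must be filtered before fitting")
    design = np.column_stack([X, np.ones(n)])
    if np.linalg.matrix_rank(design) < p + 1:
        return np.full(p + 1, np.nan), 0.0, True
    model = LinearRegression().fit(X, y)
    coefs = np.append(model.coef_, model.intercept_)
    r2, _ = r_squared(y, model.predict(X), return_flag=True)
    return coefs, r2, False


def r_squared(observed, modelled, *, return_flag: bool = False):
    """Square of the Pearson correlation between observed and modelled values.

    Vectors of zero variance make the correlation undefined; such cases
    are reported as R² = 0 with a degeneracy flag so rankings stay total.
    """
    obs = np.asarray(observed, dtype=float)
    mod = np.asarray(modelled, dtype=float)
    if obs.shape != mod.shape or obs.ndim != 1:
        raise InvalidParameterError("observed and modelled must be equal-length vectors")
    if obs.size < 3:
        raise InsufficientDataError("R² needs at least 3 observations")
    degenerate = np.var(obs) == 0.0 or np.var(mod) == 0.0
    if degenerate:
        value = 0.0
    else:
        value = float(np.corrcoef(obs, mod)[0, 1] ** 2)
    if return_flag:
        return value, bool(degenerate)
    return value


@dataclass(frozen=True)
class RegressionResult:
    descriptor_subset: tuple[str, ...]
    coefficients: np.ndarray       # slopes then intercept
    r_squared: float
    rank: int
    rank_deficient: bool = False
    degenerate: bool = False


def enumerate_and_rank(
    panel: pd.DataFrame,
    dimensions=(1, 2),
    *,
    target: str = "activity_index",
    descriptor_names=DESCRIPTOR_NAMES,
) -> pd.DataFrame:
    """Fit and rank every descriptor subset of the requested sizes.

    The panel must already be descriptor-complete (see
    :func:`filter_complete`). Results are sorted by descending R², ties
    broken lexicographically by descriptor names; rank-deficient fits sort
    to the bottom and carry no rank.
    """
    descriptor_names = [d for d in descriptor_names if d in panel.columns]
    y = panel[target].to_numpy(dtype=float)

    rows = []
    for dim in sorted(dimensions):
        for subset in combinations(descriptor_names, dim):
            X = panel[list(subset)].to_numpy(dtype=float)
            coefs, r2, deficient = fit_linear_model(X, y)
            degenerate = (not deficient) and np.var(y) == 0.0
            rows.append(
                {
                    "n_descriptors": dim,
                    "descriptors": "+".join(subset),
                    "r_squared": r2,
                    "rank_deficient": deficient,
                    "degenerate": degenerate,
                    "intercept": coefs[-1],
                    "coefficients": ";".join(f"{c:.6g}" for c in coefs[:-1]),
                }
            )
    out = pd.DataFrame(rows)
    out["_sortkey"] = list(zip(out["rank_deficient"], -out["r_squared"], out["descriptors"]))
    out = out.sort_values("_sortkey").drop(columns="_sortkey").reset_index(drop=True)
    ranks = np.full(len(out), -1)
    ranks[~out["rank_deficient"].to_numpy()] = np.arange(
        1, int((~out["rank_deficient"]).sum()) + 1
    )
    out["rank"] = ranks
    return out


class DescriptorScan:
    """Model-style wrapper: a ligand panel scanned over descriptor subsets.

    ``DescriptorScan(panel).fit()`` filters to descriptor-complete
    ligands, enumerates all 1-D and 2-D OLS models and returns the ranked
    results table; the exclusion report is kept on the instance.
    """

    def __init__(self, panel: pd.DataFrame, target: str = "activity_index",
                 descriptor_names=DESCRIPTOR_NAMES):
        self.panel = panel
        self.target = target
        self.descriptor_names = descriptor_names
        self.exclusions_: pd.DataFrame | None = None
        self.retained_: pd.DataFrame | None = None

    def fit(self, dimensions=(1, 2)) -> pd.DataFrame:
        self.retained_, self.exclusions_ = filter_complete(
            self.panel, self.descriptor_names
        )
        return enumerate_and_rank(
            self.retained_, dimensions,
            target=self.target, descriptor_names=self.descriptor_names,
        )
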