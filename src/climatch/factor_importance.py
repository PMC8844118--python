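"""Relative influence of experimental factors on modeling outcomes.

The experiment crosses species niche type, dataset version, grid
resolution, emission scenario, climate model (GCM) and timeframe. To rank
these factors, outcome values (standardized variable importance,
predicted-simulated r, or future between-version differences) are
assembled into a long table and regressed on the one-hot-encoded factors
with a 1000-tree random forest; factor importance is the permutation
score (1 - correlation between original and factor-permuted predictions,
the dummy columns of a factor permuted jointly as a block), standardized
to percentages.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

__all__ = ["OutcomeTable", "FactorImportanceResult", "assemble_outcomes", "rf_factor_importance"]

FACTOR_COLUMNS = (
    "species_tag",
    "version_tag",
    "resolution_tag",
    "gcm_tag",
    "scenario_tag",
    "timeframe_tag",
)


@dataclass
class OutcomeTable:
    """Long-format outcomes: one response column plus categorical factors."""

    data: pd.DataFrame
    response: str
    factors: tuple[str, ...]


@dataclass
class FactorImportanceResult:
    """Mean (+/- sd over permutation repeats) factor importance, percent."""

    table: pd.DataFrame  # columns: factor, mean_importance_pct, sd_pct
    n_trees: int
    n_permutations: int
    degenerate: bool = False  # constant response: all-zero importances


def assemble_outcomes(
    records: pd.DataFrame,
    response_kind: str,
    factors: Sequence[str] = FACTOR_COLUMNS,
) -> OutcomeTable:
    """Build an outcome table from a records frame.

    ``records`` must contain a ``response_kind`` column with the response
    values plus any subset of the factor columns. Factors with fewer than
    two observed levels are uninformative and excluded with a warning.
    """
    if response_kind not in records.columns:
        raise KeyError(f"records lack response column {response_kind!r}")
    if records[response_kind].isna().any():
        raise ValueError("missing response values")
    kept = []
    for f in factors:
        if f not in records.columns:
            continue
        if records[f].nunique() >= 2:
            kept.append(f)
        else:
            warnings.warn(f"factor {f!r} has a single level; excluded", stacklevel=2)
    if not kept:
        raise ValueError("no informative factors (all have a single level)")
    cols = [response_kind] + kept
    return OutcomeTable(
        data=records[cols].reset_index(drop=True),
        response=response_kind,
        factors=tuple(kept),
    )


def rf_factor_importance(
    table: OutcomeTable,
    n_trees: int = 1000,
    mtry: int | None = None,
    n_perm: int = 5,
    seed: int = 0,
) -> FactorImportanceResult:
    """Regression-forest permutation importance of experimental factors.

    ``mtry`` defaults to the regression-forest convention floor(p/3) with
    a minimum of 1, p counting the one-hot columns.
    """
    df = table.data
    if len(df) < 50:
        raise ValueError("need at least 50 rows")
    y = df[table.response].to_numpy(dtype=float)
    X = pd.get_dummies(df[list(table.factors)].astype(str), prefix_sep="::")
    col_of_factor = {
        f: [c for c in X.columns if c.startswith(f + "::")] for f in table.factors
    }
    p = X.shape[1]
    if mtry is None:
        mtry = max(1, p // 3)

    if np.std(y) == 0:
        warnings.warn("constant response; all factor importances set to 0", stacklevel=2)
        out = pd.DataFrame(
            {"factor": list(table.factors), "mean_importance_pct": 0.0, "sd_pct": 0.0}
        )
        return FactorImportanceResult(out, n_trees, n_perm, degenerate=True)

    rf = RandomForestRegressor(
        n_estimators=n_trees, max_features=mtry, random_state=seed
    ).fit(X.to_numpy(dtype=float), y)
    pred0 = rf.predict(X.to_numpy(dtype=float))
    rng = np.random.default_rng(seed)

    means, sds = {}, {}
    for f in table.factors:
        scores = []
        cols = col_of_factor[f]
        for _ in range(n_perm):
            Xp = X.copy()
            perm = rng.permutation(len(Xp))
            Xp.loc[:, cols] = X.loc[:, cols].to_numpy()[perm]  # block permutation
            pred1 = rf.predict(Xp.to_numpy(dtype=float))
            if np.std(pred0) == 0 or np.std(pred1) == 0:
                scores.append(float(np.mean(np.abs(pred0 - pred1))))
            else:
                scores.append(1.0 - float(np.corrcoef(pred0, pred1)[0, 1]))
        means[f] = max(0.0, float(np.mean(scores)))
        sds[f] = float(np.std(scores, ddof=1)) if n_perm > 1 else 0.0

    total = sum(means.values())
    scale = 100.0 / total if total > 0 else 0.0
    out = pd.DataFrame(
        {
            "factor": list(table.factors),
            "mean_importance_pct": [means[f] * scale for f in table.factors],
            "sd_pct": [sds[f] * scale for f in table.factors],
        }
    )
    return FactorImportanceResult(out, n_trees, n_perm, degenerate=total == 0)
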