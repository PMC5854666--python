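"""Collinearity screening of candidate climate predictors.

Retains a subset of candidate variables such that every retained pair has
|Pearson r| strictly below a threshold (default 0.6), by a greedy scan in a
documented priority order. Tree-type species additionally carry the two
categorical soil covariates, which bypass the correlation screen.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEFAULT_THRESHOLD = 0.6

# three climate variables for the vertebrate taxa, four for plants —
# configurable caps on the number retained per taxon
DEFAULT_MAX_VARS = {"bird": 3, "amphibian": 3, "tree": 4, "other_plant": 4}

SOIL_COVARIATES = ("deposit", "drainage")


@dataclass(frozen=True)
class PredictorSet:
    """Retained predictors for one taxon group."""

    taxon: str
    retained: tuple[str, ...]
    correlation: pd.DataFrame
    threshold: float
    categorical: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        sub = self.correlation.loc[list(self.retained), list(self.retained)]
        off = sub.to_numpy()[~np.eye(len(self.retained), dtype=bool)]
        if off.size and np.abs(off).max() >= self.threshold:
            raise ValueError("retained set violates the correlation bound")

    @property
    def max_abs_retained_correlation(self) -> float:
        if len(self.retained) < 2:
            return 0.0
        sub = self.correlation.loc[list(self.retained),
                                   list(self.retained)].to_numpy()
        return float(np.abs(sub[~np.eye(len(self.retained),
                                        dtype=bool)]).max())


def pairwise_correlation(layers: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation matrix of climate variables over cells.

    ``layers`` is cells x variables. Raises if fewer than 2 variables or 3
    cells, or if any variable is constant (its correlations are undefined).
    """
    if layers.shape[1] < 2:
        raise ValueError("need at least 2 variables")
    if layers.shape[0] < 3:
        raise ValueError("need at least 3 cells")
    sd = layers.std(ddof=0)
    constant = sd[sd == 0].index.tolist()
    if constant:
        raise ValueError(
            "constant variable(s) with undefined correlations: "
            + ", ".join(repr(c) for c in constant))
    corr = layers.corr(method="pearson")
    np.fill_diagonal(corr.values, 1.0)
    return corr


def correlation_filter(corr: pd.DataFrame,
                       threshold: float = DEFAULT_THRESHOLD,
                       priority: list[str] | None = None,
                       max_vars: int | None = None) -> list[str]:
    """Greedy screen: keep a variable iff |r| < threshold vs all kept so far.

    Variables are scanned in ``priority`` order (default: the matrix's
    column order). The threshold comparison is strict, so a pair at exactly
    the threshold is rejected. ``max_vars`` optionally caps the number
    retained.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must be in (0, 1]")
    candidates = list(corr.columns)
    if priority is None:
        priority = candidates
    if set(priority) != set(candidates):
        raise ValueError("priority order must cover all candidates exactly")
    retained: list[str] = []
    for var in priority:
        if max_vars is not None and len(retained) >= max_vars:
            break
        if all(abs(float(corr.loc[var, kept])) < threshold
               for kept in retained):
            retained.append(var)
    return retained


def select_predictors(layers: pd.DataFrame,
                      taxon: str,
                      candidates: list[str] | None = None,
                      threshold: float = DEFAULT_THRESHOLD,
                      priority: list[str] | None = None,
                      max_vars: dict[str, int] | None = None,
                      ) -> PredictorSet:
    """Assemble the per-taxon predictor set (climate; + soil for trees)."""
    caps = dict(DEFAULT_MAX_VARS if max_vars is None else max_vars)
    cols = candidates if candidates is not None else list(layers.columns)
    corr = pairwise_correlation(layers[cols])
    retained = correlation_filter(corr, threshold=threshold,
                                  priority=priority,
                                  max_vars=caps.get(taxon))
    categorical = SOIL_COVARIATES if taxon == "tree" else ()
    return PredictorSet(taxon=taxon, retained=tuple(retained),
                        correlation=corr, threshold=threshold,
                        categorical=tuple(categorical))


def predictor_report(sets: dict[str, PredictorSet]) -> pd.DataFrame:
    """Flat retained-set report, one row per taxon/variable."""
    rows = []
    for taxon, ps in sets.items():
        for rank, var in enumerate(ps.retained):
            rows.append({"taxon": taxon, "rank": rank, "variable": var,
                         "kind": "climate", "threshold": ps.threshold})
        for var in ps.categorical:
            rows.append({"taxon": taxon, "rank": -1, "variable": var,
                         "kind": "categorical", "threshold": ps.threshold})
    return pd.DataFrame(rows)
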