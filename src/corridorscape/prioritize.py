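"""Four-level importance classification of sources and corridors.

Ecological sources are ranked by their dPC (percent contribution to the
probability of connectivity; higher is more important); corridors by
their cost-weighted distance standardized to [0, 1] by (x - min) /
(max - min) (lower cost transmits more, so lower is more important).
Items are binned by percentile rank of the score distribution into four
classes — 1 (rank <= 25), 2 (25-50], 3 (50-75], 4 (> 75, most
important) — with ties sharing the mean rank and hence the class.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .corridors import CorridorNetwork


def _classify(percentile: np.ndarray) -> np.ndarray:
    """Percentile ranks to classes 1-4 (boundary goes to the lower class)."""
    cls = np.ones(len(percentile), dtype=int)
    cls[percentile > 25] = 2
    cls[percentile > 50] = 3
    cls[percentile > 75] = 4
    return cls


def _rank_table(ids, scores: np.ndarray, higher_better: bool) -> pd.DataFrame:
    scores = np.asarray(scores, dtype=float)
    oriented = scores if higher_better else -scores
    pct = rankdata(oriented) / len(scores) * 100.0
    return pd.DataFrame(
        {"id": list(ids), "score": scores, "percentile": pct, "importance_class": _classify(pct)}
    )


def rank_sources(dpc_values: dict | pd.Series) -> pd.DataFrame:
    """Importance ranking of sources by dPC (higher dPC = more important)."""
    if isinstance(dpc_values, dict):
        dpc_values = pd.Series(dpc_values)
    if len(dpc_values) < 1:
        raise ValueError("no dPC values to rank")
    return _rank_table(dpc_values.index, dpc_values.to_numpy(), higher_better=True)


def rank_corridors(network: CorridorNetwork) -> pd.DataFrame:
    """Importance ranking of corridors by standardized cost-weighted distance.

    Scores are lcp costs standardized to [0, 1]; lower standardized cost
    means higher importance. A single corridor is class 4 by convention;
    equal costs degenerate to one shared class with a warning.
    """
    if network.count < 1:
        raise ValueError("no corridors to rank")
    ids = [f"{a}-{b}" for a, b in (c.source_pair for c in network.corridors)]
    costs = np.array([c.lcp_cost for c in network.corridors], dtype=float)
    if network.count == 1:
        warnings.warn("single corridor: assigned class 4 by convention", stacklevel=2)
        return pd.DataFrame(
            {"id": ids, "score": [0.0], "percentile": [100.0], "importance_class": [4]}
        )
    span = costs.max() - costs.min()
    if span == 0:
        warnings.warn("all corridor costs equal; degenerate single-class ranking", stacklevel=2)
        std = np.zeros_like(costs)
    else:
        std = (costs - costs.min()) / span
    return _rank_table(ids, std, higher_better=False)


def percent_decline(v_start: float, v_end: float) -> float:
    """Percent decline 100 * (v_start - v_end) / v_start, to 2 decimals."""
    if v_start <= 0:
        raise ValueError("baseline value must be positive")
    return round(100.0 * (v_start - v_end) / v_start, 2)
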