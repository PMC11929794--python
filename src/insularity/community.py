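"""Response variables from the community matrix: generalist richness (GR),
quartz-specialist richness (QS), and the percentage of specialists (QS%).

The community matrix is an island × species presence/absence table; each
species carries a habitat-specialist flag assigned upstream (from floras /
expert knowledge — that procedure is an input here, not part of the
pipeline).  GR is total richness minus QS.  QS% is kept as a proportion
together with its (successes = QS, trials = total) pair, because modelling
a percentage with a binomial GLM needs the trial counts.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = [
    "validate_community",
    "compute_diversity",
    "archipelago_totals",
]


def validate_community(cm: pd.DataFrame, traits: pd.Series) -> pd.Series:
    """Check the incidence matrix is binary and every species has a trait
    entry; returns the boolean specialist flags aligned to cm's columns."""
    values = cm.to_numpy()
    if not np.isin(values, (0, 1)).all():
        raise ValueError("community matrix must be binary (0/1 incidence)")
    if cm.columns.duplicated().any():
        raise ValueError("duplicate species ids in community matrix")
    missing = [s for s in cm.columns if s not in traits.index]
    if missing:
        raise ValueError(f"species without a trait entry: {missing}")
    return traits.reindex(cm.columns).astype(bool)


def compute_diversity(cm: pd.DataFrame, traits: pd.Series) -> pd.DataFrame:
    """Per-island diversity table.

    Parameters
    ----------
    cm : DataFrame
        Islands (rows, index = island_id) × species (columns), 0/1.
    traits : Series
        species_id → quartz_specialist (bool/0/1), covering every species.

    Returns columns total_richness, gr, qs, qs_pct (proportion in [0, 1];
    NaN with a warning for empty islands, where a percentage is undefined).
    """
    spec = validate_community(cm, traits)
    total = cm.sum(axis=1).astype(int)
    qs = cm.loc[:, spec.to_numpy()].sum(axis=1).astype(int)
    gr = total - qs
    with np.errstate(invalid="ignore", divide="ignore"):
        qs_pct = qs / total
    if (total == 0).any():
        empty = list(cm.index[total == 0])
        warnings.warn(f"islands with zero species, QS%% undefined: {empty}")
        qs_pct[total == 0] = np.nan
    return pd.DataFrame(
        {
            "island_id": cm.index.astype(str),
            "total_richness": total.to_numpy(),
            "gr": gr.to_numpy(),
            "qs": qs.to_numpy(),
            "qs_pct": qs_pct.to_numpy(),
        }
    ).set_index("island_id")


def archipelago_totals(cm: pd.DataFrame, traits: pd.Series) -> tuple[int, int]:
    """(total species, total specialists) counting only species that occur
    on at least one island."""
    spec = validate_community(cm, traits)
    occurs = cm.sum(axis=0) > 0
    return int(occurs.sum()), int((occurs & spec.to_numpy()).sum())
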