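"""Per-syndrome relevance ranking and filter baselines.

Each syndrome feature f_i receives three scores against the positive score
(ps) target:

* ``mcc(f_i, ps) = 1 - |corr(f_i, ps)|`` — a correlation-derived
  dissimilarity; smaller means the feature tracks the target more closely;
* ``pe(f_i)`` — the cross-validated LS-SVR error with every feature EXCEPT
  f_i; a large pe means the model misses f_i, so f_i is predictive;
* ``fr(f_i) = (mcc_i + (1 - pe_i / max_j pe_j)) / 2`` — the combined score
  in [0, 1]; smaller fr means higher rank.

Thresholding fr yields filter-style subsets; `cfm_baseline` is the plain
correlation filter operating directly on symptom columns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .hierarchy import SymptomTable
from .lssvr import LSSVRConfig, cv_mse

__all__ = [
    "RankingRecord",
    "mcc_score",
    "pe_score",
    "fr_scores",
    "rank_features",
    "rank_table",
    "threshold_subset",
    "cfm_baseline",
]


@dataclass
class RankingRecord:
    feature_id: str
    mcc: float
    pe: float
    fr: float = float("nan")
    rank: int = 0


def mcc_score(feature: np.ndarray, ps: np.ndarray) -> float:
    """1 - |Pearson correlation| between a feature and the positive score.

    Zero-variance features carry no linear information: they score the worst
    possible value 1 (with a warning).
    """
    feature = np.asarray(feature, dtype=float).ravel()
    ps = np.asarray(ps, dtype=float).ravel()
    if feature.shape != ps.shape:
        raise ValueError("feature and target must have equal length")
    if np.std(feature) == 0 or np.std(ps) == 0:
        warnings.warn("zero-variance input: mcc set to 1", stacklevel=2)
        return 1.0
    r = np.corrcoef(feature, ps)[0, 1]
    return float(1.0 - abs(r))


def pe_score(
    dataset: np.ndarray,
    ps: np.ndarray,
    feature_index: int,
    config: LSSVRConfig,
) -> float:
    """Leave-one-feature-out cross-validated MSE (all columns but one)."""
    dataset = np.atleast_2d(np.asarray(dataset, dtype=float))
    D = dataset.shape[1]
    if D < 2:
        raise ValueError("cannot remove the sole feature")
    if not 0 <= feature_index < D:
        raise IndexError(f"feature index {feature_index} out of range")
    keep = [j for j in range(D) if j != feature_index]
    return cv_mse(dataset[:, keep], ps, config)


def fr_scores(mcc: np.ndarray, pe: np.ndarray) -> np.ndarray:
    """Combine mcc and pe into fr_i = (mcc_i + (1 - pe_i/max_j pe_j)) / 2."""
    mcc = np.asarray(mcc, dtype=float).ravel()
    pe = np.asarray(pe, dtype=float).ravel()
    if mcc.shape != pe.shape:
        raise ValueError("mcc and pe must have equal length")
    max_pe = pe.max()
    if max_pe <= 0:
        raise ValueError("max pe must be positive to normalize")
    return (mcc + (1.0 - pe / max_pe)) / 2.0


def rank_features(records: list[RankingRecord]) -> list[RankingRecord]:
    """Assign ranks 1..D by ascending fr; ties keep input feature order."""
    fr = fr_scores(
        np.array([r.mcc for r in records]), np.array([r.pe for r in records])
    )
    order = sorted(range(len(records)), key=lambda i: (fr[i], i))
    out = [replace(r, fr=float(f)) for r, f in zip(records, fr)]
    for rank, i in enumerate(order, start=1):
        out[i].rank = rank
    return out


def rank_table(records: list[RankingRecord]) -> pd.DataFrame:
    """Ranking report (feature, mcc, pe, fr, rank) sorted by rank."""
    ranked = rank_features(records)
    df = pd.DataFrame(
        {
            "feature": [r.feature_id for r in ranked],
            "mcc": [r.mcc for r in ranked],
            "pe": [r.pe for r in ranked],
            "fr": [r.fr for r in ranked],
            "rank": [r.rank for r in ranked],
        }
    )
    return df.sort_values("rank").reset_index(drop=True)


def threshold_subset(records: list[RankingRecord], theta: float) -> list[str]:
    """Features whose fr is strictly below ``theta``, in input order."""
    ranked = rank_features(records)
    return [r.feature_id for r in ranked if r.fr < theta]


def cfm_baseline(table: SymptomTable, top_fraction: float) -> list[str]:
    """Correlation-based filter: ceil(top_fraction * D) columns with the
    largest |Pearson correlation| to the positive score, strongest first."""
    if not 0 < top_fraction <= 1:
        raise ValueError("top_fraction must lie in (0, 1]")
    k = int(np.ceil(top_fraction * table.n_symptoms))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # constant columns
        corrs = np.array(
            [
                abs(np.corrcoef(table.values[:, j].astype(float),
                                table.positive_score)[0, 1])
                for j in range(table.n_symptoms)
            ]
        )
    corrs = np.nan_to_num(corrs)
    order = sorted(range(table.n_symptoms), key=lambda j: (-corrs[j], j))
    return [table.column_names[j] for j in order[:k]]
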