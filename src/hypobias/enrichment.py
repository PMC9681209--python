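"""Cohort-level classification of astrocyte-signature enrichment.

A sample is called ACS-enriched when (1) its ACS score exceeds the cohort
mean ACS score and (2) its ACS score is at least 10% greater than every
competing OPC signature score. The 10% margin is multiplicative
(acs >= 1.1 * opc), which presumes non-negative normalised scores; if
negative scores are present a warning is emitted and the margin falls back
to an additive 0.1 * |opc|.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

MARGIN = 1.1


class EnrichmentClassifier(BaseEstimator):
    """Two-rule enrichment call against a fitted cohort mean.

    Parameters
    ----------
    acs_col : name of the ACS score column.
    opc_cols : names of the competing OPC score columns; ``None`` means
        every column other than ``acs_col``.
    margin : multiplicative margin over each OPC score (default 1.1).

    Attributes
    ----------
    cohort_mean_acs_ : mean ACS score of the fitted cohort (all scored
        samples, missing values excluded).
    """

    def __init__(self, acs_col: str = "ACS", opc_cols=None, margin: float = MARGIN):
        self.acs_col = acs_col
        self.opc_cols = opc_cols
        self.margin = margin

    def _validate(self, scores: pd.DataFrame):
        if self.acs_col not in scores.columns:
            raise ValueError(f"score table lacks column {self.acs_col!r}")
        opc = (
            list(self.opc_cols)
            if self.opc_cols is not None
            else [c for c in scores.columns if c != self.acs_col]
        )
        missing = set(opc) - set(scores.columns)
        if missing:
            raise ValueError(f"score table lacks OPC columns {sorted(missing)}")
        return opc

    def fit(self, scores: pd.DataFrame, y=None):
        self._validate(scores)
        self.cohort_mean_acs_ = float(scores[self.acs_col].mean())
        return self

    def decisions(self, scores: pd.DataFrame) -> pd.DataFrame:
        """Per-sample decision table: acs_score, max_opc_score,
        cohort_mean_acs, enriched."""
        opc_cols = self._validate(scores)
        acs = scores[self.acs_col].to_numpy(dtype=float)
        opc = scores[opc_cols].to_numpy(dtype=float)
        if (acs < 0).any() or (opc < 0).any():
            warnings.warn(
                "negative enrichment scores: multiplicative 10% margin is "
                "ill-defined, using additive 0.1*|opc| fallback",
                stacklevel=2,
            )
            clears = acs[:, None] >= opc + (self.margin - 1.0) * np.abs(opc)
        else:
            clears = acs[:, None] >= self.margin * opc
        enriched = (acs > self.cohort_mean_acs_) & clears.all(axis=1)
        return pd.DataFrame(
            {
                "acs_score": acs,
                "max_opc_score": opc.max(axis=1),
                "cohort_mean_acs": self.cohort_mean_acs_,
                "enriched": enriched,
            },
            index=scores.index,
        )

    def predict(self, scores: pd.DataFrame) -> np.ndarray:
        return self.decisions(scores)["enriched"].to_numpy()


def classify_enrichment(
    scores: pd.DataFrame, acs_col: str = "ACS", opc_cols=None
) -> pd.DataFrame:
    """Fit the cohort mean on `scores` and return the decision table."""
    clf = EnrichmentClassifier(acs_col=acs_col, opc_cols=opc_cols)
    return clf.fit(scores).decisions(scores)
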