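"""Pre-processing of OTU count tables ahead of ordination.

Three steps, each exposed both as a scikit-learn transformer and as a thin
function over the domain types:

1. total-sum scaling (TSS) — per-sample division by library size, giving
   relative abundances;
2. prevalence partition — OTUs present in fewer than ``min_samples`` samples
   are *scarce* and set aside, the rest are *ubiquitous*;
3. Pareto scaling — column centering followed by division by the square root
   of the column standard deviation.

All matrices here are oriented samples x OTUs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .io_formats import OtuTable, ValidationError

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class AbundanceMatrix:
    """Relative abundances, samples x OTUs, each row summing to 1."""

    values: pd.DataFrame  # index sample_id, columns otu_id

    def __post_init__(self) -> None:
        arr = self.values.to_numpy(dtype=float)
        if (arr < 0).any() or (arr > 1).any():
            raise ValidationError("relative abundances must lie in [0, 1]")
        sums = arr.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-12, rtol=0):
            bad = self.values.index[np.abs(sums - 1.0) > 1e-12].tolist()
            raise ValidationError(f"rows not summing to 1: {bad}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def otu_ids(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class PrevalencePartition:
    """Ubiquitous / scarce split of the OTU set at a prevalence threshold."""

    ubiquitous: list[str]
    scarce: list[str]
    min_samples: int

    def __post_init__(self) -> None:
        if set(self.ubiquitous) & set(self.scarce):
            raise ValidationError("ubiquitous and scarce sets overlap")


@dataclass
class ScaledMatrix:
    """Pareto-scaled matrix (samples x kept OTUs) with scaling parameters."""

    values: pd.DataFrame
    center: pd.Series  # per-column means removed
    scale: pd.Series   # per-column sqrt(sd) divisors
    dropped: list[str] = field(default_factory=list)  # zero-variance columns

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def otu_ids(self) -> list[str]:
        return list(self.values.columns)


# ---------------------------------------------------------------------------
# scikit-learn transformers
# ---------------------------------------------------------------------------

class TotalSumScaler(TransformerMixin, BaseEstimator):
    """Divide each sample (row) by its total count.

    Stateless; ``fit`` only validates.  Zero-total rows are rejected because
    a library with no reads carries no compositional information.
    """

    def fit(self, X, y=None):
        X = self._validate(X)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        X = self._validate(X)
        arr = np.asarray(X, dtype=float)
        out = arr / arr.sum(axis=1, keepdims=True)
        if isinstance(X, pd.DataFrame):
            return pd.DataFrame(out, index=X.index, columns=X.columns)
        return out

    @staticmethod
    def _validate(X):
        arr = np.asarray(X, dtype=float)
        if arr.ndim != 2:
            raise ValidationError("expected a 2-D samples x OTUs matrix")
        if (arr < 0).any():
            raise ValidationError("counts must be non-negative")
        totals = arr.sum(axis=1)
        if (totals == 0).any():
            if isinstance(X, pd.DataFrame):
                bad = X.index[totals == 0].tolist()
            else:
                bad = np.nonzero(totals == 0)[0].tolist()
            raise ValidationError(f"samples with zero total count: {bad}")
        return X


class PrevalenceFilter(TransformerMixin, BaseEstimator):
    """Keep OTUs present (abundance > 0) in at least ``min_samples`` samples."""

    def __init__(self, min_samples: int = 2):
        self.min_samples = min_samples

    def fit(self, X, y=None):
        if self.min_samples < 1:
            raise ValidationError("min_samples must be >= 1")
        arr = np.asarray(X, dtype=float)
        prevalence = (arr > 0).sum(axis=0)
        self.support_ = prevalence >= self.min_samples
        self.prevalence_ = prevalence
        self.n_features_in_ = arr.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "support_")
        if isinstance(X, pd.DataFrame):
            return X.loc[:, self.support_]
        return np.asarray(X)[:, self.support_]


class ParetoScaler(TransformerMixin, BaseEstimator):
    """Center each column and divide by the square root of its sample sd.

    The sd uses the n-1 denominator.  Columns with zero variance carry no
    dispersion information and are dropped (recorded in ``dropped_``); a
    Pareto-scaled column retains variance equal to its original sd.
    """

    def fit(self, X, y=None):
        arr = np.asarray(X, dtype=float)
        mean = arr.mean(axis=0)
        sd = arr.std(axis=0, ddof=1)
        # constant columns (max == min) have zero variance up to float fuzz
        keep = arr.max(axis=0) > arr.min(axis=0)
        if not keep.any():
            raise ValidationError("all columns have zero variance")
        if (~keep).any():
            if isinstance(X, pd.DataFrame):
                dropped = X.columns[~keep].tolist()
            else:
                dropped = np.nonzero(~keep)[0].tolist()
            logger.warning("dropping %d zero-variance columns: %s", len(dropped), dropped)
            self.dropped_ = list(dropped)
        else:
            self.dropped_ = []
        self.support_ = keep
        self.mean_ = mean[keep]
        self.scale_ = np.sqrt(sd[keep])
        self.n_features_in_ = arr.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "mean_")
        arr = np.asarray(X, dtype=float)[:, self.support_]
        out = (arr - self.mean_) / self.scale_
        if isinstance(X, pd.DataFrame):
            return pd.DataFrame(out, index=X.index, columns=X.columns[self.support_])
        return out


# ---------------------------------------------------------------------------
# Domain-type wrappers
# ---------------------------------------------------------------------------

def total_sum_scale(table: OtuTable) -> AbundanceMatrix:
    """Step 1a: convert counts to per-sample relative abundances."""
    counts = table.counts.T  # samples x OTUs
    rel = TotalSumScaler().fit_transform(counts)
    return AbundanceMatrix(values=rel)


def prevalence_partition(abund: AbundanceMatrix, min_samples: int = 2) -> PrevalencePartition:
    """Step 1b: split OTUs into ubiquitous (kept) and scarce (set aside)."""
    filt = PrevalenceFilter(min_samples=min_samples).fit(abund.values)
    cols = np.asarray(abund.otu_ids, dtype=object)
    return PrevalencePartition(
        ubiquitous=list(cols[filt.support_]),
        scarce=list(cols[~filt.support_]),
        min_samples=min_samples,
    )


def pareto_scale(abund: AbundanceMatrix, keep: list[str]) -> ScaledMatrix:
    """Step 2a: Pareto-scale the retained OTU columns."""
    unknown = set(keep) - set(abund.otu_ids)
    if unknown:
        raise ValidationError(f"keep list contains unknown OTUs: {sorted(unknown)}")
    sub = abund.values.loc[:, list(keep)]
    scaler = ParetoScaler().fit(sub)
    scaled = scaler.transform(sub)
    kept_cols = sub.columns[scaler.support_]
    return ScaledMatrix(
        values=scaled,
        center=pd.Series(scaler.mean_, index=kept_cols),
        scale=pd.Series(scaler.scale_, index=kept_cols),
        dropped=scaler.dropped_,
    )
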