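"""Compound retention rules and abundance transformations.

Two filtering rules are applied to the raw peak table before any
statistics: a blank-control rule that discards compounds appearing in
solvent/swab blanks at similar-or-higher mean concentration than in the
animal samples (these are contaminants or otherwise exogenous), and a
rarity rule that discards compounds quantifiable (area > 0) in fewer
than ``min_samples`` samples. "Similar or higher" is operationalized as
``blank_mean >= blank_ratio * sample_mean`` with ``blank_ratio = 1.0``
by default, where the sample mean is taken over samples in which the
compound is present.

Retained areas are then standardized to relative abundances (percent of
the per-sample total over retained compounds). Two transformation
chains serve the two analysis branches:

* similarity chain: natural ``log(x + 1)`` of the percentages, feeding
  Bray-Curtis dissimilarities;
* model chain: ``log(arcsin(sqrt(x / 100)) + 0.01)``, i.e. an
  arcsine-square-root of the proportion followed by a shifted log,
  feeding the Gaussian mixed model. The composition order is
  configurable because either order keeps values finite on [0, 100].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .profile_io import PeakTable

__all__ = [
    "CompoundFilterReport",
    "filter_compounds",
    "apply_filter",
    "standardize",
    "transform_similarity",
    "transform_model",
    "ztransform",
    "RETAINED",
    "EXCLUDED_BLANK",
    "EXCLUDED_RARE",
]

RETAINED = "retained"
EXCLUDED_BLANK = "excluded_blank"
EXCLUDED_RARE = "excluded_rare"


class PreprocessError(ValueError):
    pass


@dataclass
class CompoundFilterReport:
    """Per-compound filtering outcome."""

    table: pd.DataFrame  # index compound_id; status, blank_mean, sample_mean, n_samples_present

    @property
    def retained(self) -> list[str]:
        return self.table.index[self.table["status"] == RETAINED].tolist()

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", float_format="%.12g")


def filter_compounds(
    peaks: PeakTable,
    blanks: PeakTable | None,
    min_samples: int = 3,
    blank_ratio: float = 1.0,
) -> CompoundFilterReport:
    """Classify each compound as retained / excluded_blank / excluded_rare.

    The blank rule is evaluated first; compounds surviving it are then
    checked for rarity. A compound absent from every animal sample has
    no defined sample mean and falls to the rarity rule.
    """
    if blanks is not None:
        if not blanks.sample_ids:
            raise PreprocessError("blank filtering requested but blank table has no samples")
        if list(blanks.compound_ids) != list(peaks.compound_ids):
            raise PreprocessError("blank table compound axis differs from peak table")
        blank_mean = blanks.areas.mean(axis=0)
    else:
        blank_mean = np.zeros(len(peaks.compound_ids))

    present = peaks.areas > 0
    n_present = present.sum(axis=0)
    with np.errstate(invalid="ignore"):
        sample_mean = np.where(
            n_present > 0,
            peaks.areas.sum(axis=0) / np.maximum(n_present, 1),
            0.0,
        )
    status = np.full(len(peaks.compound_ids), RETAINED, dtype=object)
    blank_excluded = (n_present > 0) & (blank_mean >= blank_ratio * sample_mean) & (blank_mean > 0)
    status[blank_excluded] = EXCLUDED_BLANK
    rare = ~blank_excluded & (n_present < min_samples)
    status[rare] = EXCLUDED_RARE
    table = pd.DataFrame(
        {
            "status": status,
            "blank_mean": blank_mean,
            "sample_mean": sample_mean,
            "n_samples_present": n_present,
        },
        index=pd.Index(peaks.compound_ids, name="compound_id"),
    )
    return CompoundFilterReport(table)


def apply_filter(peaks: PeakTable, report: CompoundFilterReport) -> PeakTable:
    """Subset a peak table to the retained compounds."""
    return peaks.subset_compounds(report.retained)


def standardize(peaks: PeakTable) -> PeakTable:
    """Relative abundances: percent of the per-sample total area.

    Each row of the output sums to 100; zeros stay zero. Standardization
    is meaningful only after compound filtering, i.e. the totals are over
    retained compounds.
    """
    totals = peaks.areas.sum(axis=1)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        names = [peaks.sample_ids[i] for i in zero]
        raise PreprocessError(f"all-zero samples cannot be standardized: {names}")
    rel = peaks.areas / totals[:, None] * 100.0
    return PeakTable(list(peaks.sample_ids), list(peaks.compound_ids), rel,
                     is_blank=None if peaks.is_blank is None else peaks.is_blank.copy())


def transform_similarity(rel: np.ndarray | PeakTable) -> np.ndarray:
    """log(x + 1) of relative abundances, for Bray-Curtis input."""
    x = rel.areas if isinstance(rel, PeakTable) else np.asarray(rel, dtype=float)
    return np.log1p(x)


def transform_model(rel: np.ndarray | PeakTable, order: str = "arcsine_then_log") -> np.ndarray:
    """Variance-stabilizing transform of percentages for the mixed model.

    order = "arcsine_then_log": log(arcsin(sqrt(x/100)) + 0.01)  (default)
    order = "log_then_arcsine": arcsin(sqrt(log(x + 0.01) normalized))
        is ill-defined for percentages, so the alternative offered is
        arcsine of the proportion after a shifted log of the percentage
        mapped back to [0, 1]: arcsin(sqrt((log(x + 0.01) - log(0.01)) /
        (log(100.01) - log(0.01)))).
    """
    x = rel.areas if isinstance(rel, PeakTable) else np.asarray(rel, dtype=float)
    if np.any((x < 0) | (x > 100)):
        raise PreprocessError("relative abundances must lie in [0, 100]")
    if order == "arcsine_then_log":
        return np.log(np.arcsin(np.sqrt(x / 100.0)) + 0.01)
    if order == "log_then_arcsine":
        lo, hi = np.log(0.01), np.log(100.01)
        return np.arcsin(np.sqrt((np.log(x + 0.01) - lo) / (hi - lo)))
    raise ValueError(f"unknown transform order {order!r}")


def ztransform(values) -> np.ndarray:
    """Center to mean 0 and scale to sample SD 1 (ddof=1)."""
    x = np.asarray(values, dtype=float)
    if x.size < 2 or np.all(x == x.flat[0]):
        raise PreprocessError("z-transform needs at least two distinct values")
    return (x - x.mean()) / x.std(ddof=1)
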