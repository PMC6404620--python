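"""Benjamini-Hochberg FDR across markers with a nominal hard floor.

The step-up BH rule rejects the markers with the m smallest p-values up
to the largest rank k satisfying P_(k) <= k * alpha / m.  On top of
that, rejection additionally requires the *nominal* p-value to be at or
below a fixed floor (default 0.01): the floor can only remove
rejections, guarding against liberal calls when many markers are
mediocre.  Ties share the maximal qualifying rank.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

log = logging.getLogger(__name__)


@dataclass
class FdrResult:
    """Per-marker BH + floor decisions.

    ``table`` columns: p, rank, bh_threshold, bh_pass, floor_pass,
    reject.  NaN p-values are excluded from m and never rejected.
    """

    table: pd.DataFrame
    m: int
    alpha_fdr: float
    floor: float

    @property
    def reject(self) -> pd.Series:
        return self.table["reject"]

    @property
    def n_reject(self) -> int:
        return int(self.table["reject"].sum())


def bh_with_floor(
    pvals, alpha_fdr: float = 0.05, floor: float = 0.01
) -> FdrResult:
    """Step-up BH across ``pvals`` intersected with nominal P <= floor."""
    p = pd.Series(pvals, dtype=float)
    finite = p.notna()
    if not finite.all():
        log.warning("%d NaN p-values excluded from FDR m", int((~finite).sum()))
    vals = p[finite].to_numpy()
    if ((vals < 0) | (vals > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = len(vals)

    bh_pass = np.zeros(m, dtype=bool)
    ranks = np.zeros(m)
    if m:
        order = np.argsort(vals, kind="stable")
        sorted_p = vals[order]
        ks = np.arange(1, m + 1)
        passing = sorted_p <= ks * alpha_fdr / m
        kmax = ks[passing].max() if passing.any() else 0
        bh_sorted = ks <= kmax
        bh_pass[order] = bh_sorted
        ranks = rankdata(vals, method="max")  # ties share the maximal rank

    table = pd.DataFrame(index=p.index)
    table["p"] = p
    table["rank"] = np.nan
    table.loc[finite, "rank"] = ranks
    table["bh_threshold"] = table["rank"] * alpha_fdr / m if m else np.nan
    table["bh_pass"] = False
    table.loc[finite, "bh_pass"] = bh_pass
    table["floor_pass"] = p <= floor
    table["reject"] = table["bh_pass"] & table["floor_pass"]
    return FdrResult(table=table, m=m, alpha_fdr=alpha_fdr, floor=floor)
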