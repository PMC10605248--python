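"""Concordance of regional DEGs with reference lens-cell-type gene sets.

Differentially expressed genes between an organoid's internal and
external regions are cross-tabulated against reference fiber-cell (FC)
and lens-epithelial-cell (LEC) gene sets: if the internal region is
fiber-like and the external region epithelium-like, internal-up DEGs
should fall preferentially in the FC set and external-up DEGs in the
LEC set.  Association is tested with the Pearson chi-squared statistic
on the 2x2 table,

    chi2 = n * (ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d)),   df = 1,

with expected cell counts row * col / n under independence (the values
"in brackets" alongside observed counts), and an optional Yates
continuity correction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from .errors import AnalysisError, InputError
from .expression import DEResult

__all__ = [
    "ContingencyTable2x2",
    "chi_square_2x2",
    "classify_degs",
    "fc_lec_overlay",
]


@dataclass
class ContingencyTable2x2:
    """Observed 2x2 counts with expectations and the chi-squared test.

    Rows are DEG direction (internal-up, external-up), columns reference
    identity (FC-enriched, LEC-enriched).  ``expected[i][j]`` is
    row_i * col_j / n.
    """

    observed: np.ndarray  # shape (2, 2): [[a, b], [c, d]]
    expected: np.ndarray
    chi_square: float
    p_value: float
    continuity_correction: bool
    row_labels: tuple[str, str] = ("internal_up", "external_up")
    col_labels: tuple[str, str] = ("FC", "LEC")

    def to_frame(self) -> pd.DataFrame:
        cells = [
            [
                f"{int(self.observed[i, j])} ({self.expected[i, j]:.1f})"
                for j in range(2)
            ]
            for i in range(2)
        ]
        return pd.DataFrame(cells, index=self.row_labels, columns=self.col_labels)


def chi_square_2x2(
    a: int, b: int, c: int, d: int, continuity: bool = False
) -> ContingencyTable2x2:
    """Pearson chi-squared test of independence on a 2x2 table.

    With ``continuity`` the Yates correction subtracts n/2 from
    |ad - bc| (floored at 0) before squaring.  Requires all margins
    positive.
    """
    obs = np.array([[a, b], [c, d]], dtype=float)
    if (obs < 0).any():
        raise InputError("cell counts must be non-negative")
    n = obs.sum()
    if n == 0:
        raise InputError("empty table")
    rows = obs.sum(axis=1)
    cols = obs.sum(axis=0)
    if (rows == 0).any() or (cols == 0).any():
        raise InputError("chi-squared undefined: a row or column margin is zero")
    expected = np.outer(rows, cols) / n
    diff = abs(a * d - b * c)
    if continuity:
        diff = max(0.0, diff - n / 2.0)
    chi2 = n * diff**2 / (rows[0] * rows[1] * cols[0] * cols[1])
    p = float(stats.chi2.sf(chi2, df=1))
    return ContingencyTable2x2(
        observed=np.array([[a, b], [c, d]], dtype=float),
        expected=expected,
        chi_square=float(chi2),
        p_value=p,
        continuity_correction=continuity,
    )


def _exclusive_sets(
    fc_set: Iterable[str], lec_set: Iterable[str]
) -> tuple[set[str], set[str], set[str]]:
    fc, lec = set(fc_set), set(lec_set)
    ambiguous = fc & lec
    return fc - ambiguous, lec - ambiguous, ambiguous


def classify_degs(
    de: DEResult,
    fc_set: Iterable[str],
    lec_set: Iterable[str],
    continuity: bool = False,
) -> tuple[ContingencyTable2x2, pd.DataFrame]:
    """Cross-tabulate DEG direction against reference identity.

    DEGs (call != ns) outside both reference sets are excluded; genes in
    both sets are ambiguous and dropped (reported in the annotated
    table's ``identity`` column as 'ambiguous').  ``up_A`` is taken as
    the internal-up direction (group A of the DE contrast), ``up_B`` as
    external-up.  Returns the tested table and a per-gene annotation.
    """
    fc, lec, ambiguous = _exclusive_sets(fc_set, lec_set)
    deg = de.table[de.table["call"] != "ns"]
    identity = pd.Series("neither", index=deg.index, name="identity")
    identity[deg.index.isin(fc)] = "FC"
    identity[deg.index.isin(lec)] = "LEC"
    identity[deg.index.isin(ambiguous)] = "ambiguous"
    annotated = deg.assign(identity=identity)

    kept = annotated[annotated["identity"].isin(["FC", "LEC"])]
    if kept.empty:
        raise AnalysisError("no DEG falls in either reference set")
    a = int(((kept["call"] == "up_A") & (kept["identity"] == "FC")).sum())
    b = int(((kept["call"] == "up_A") & (kept["identity"] == "LEC")).sum())
    c = int(((kept["call"] == "up_B") & (kept["identity"] == "FC")).sum())
    d = int(((kept["call"] == "up_B") & (kept["identity"] == "LEC")).sum())
    table = chi_square_2x2(a, b, c, d, continuity=continuity)
    return table, annotated


def fc_lec_overlay(
    de: DEResult,
    fc_set: Iterable[str],
    lec_set: Iterable[str],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Annotate every DEG with its reference identity and summarise fold changes.

    Returns the per-gene overlay table (log2fc, fdr, identity in
    {FC, LEC, neither}) and a per-identity summary with mean log2fc plus
    a Mann-Whitney rank test between FC- and LEC-labelled fold changes.
    The summary is empty (with a warning) when no gene has an identity.
    """
    fc, lec, ambiguous = _exclusive_sets(fc_set, lec_set)
    deg = de.table[de.table["call"] != "ns"]
    identity = pd.Series("neither", index=deg.index, name="identity")
    identity[deg.index.isin(fc)] = "FC"
    identity[deg.index.isin(lec)] = "LEC"
    identity[deg.index.isin(ambiguous)] = "neither"
    overlay = deg[["log2fc", "fdr"]].assign(identity=identity)

    labelled = overlay[overlay["identity"] != "neither"]
    if labelled.empty:
        import warnings

        warnings.warn("no DEG carries an FC/LEC identity; empty summary", stacklevel=2)
        return overlay, pd.DataFrame(
            columns=["identity", "n", "mean_log2fc", "rank_p"]
        )
    rows = []
    fc_vals = labelled.loc[labelled["identity"] == "FC", "log2fc"].to_numpy()
    lec_vals = labelled.loc[labelled["identity"] == "LEC", "log2fc"].to_numpy()
    rank_p = np.nan
    if len(fc_vals) and len(lec_vals):
        rank_p = float(stats.mannwhitneyu(fc_vals, lec_vals).pvalue)
    for ident, vals in (("FC", fc_vals), ("LEC", lec_vals)):
        rows.append(
            {
                "identity": ident,
                "n": len(vals),
                "mean_log2fc": vals.mean() if len(vals) else np.nan,
                "rank_p": rank_p,
            }
        )
    return overlay, pd.DataFrame(rows)
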