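"""Paired two-condition differential expression.

Per feature: the Wilcoxon signed-rank test on within-pair differences and the
log2 fold change (mean of condition A minus mean of condition B, both already
on log2 scale).  Conventions, pinned for reproducibility and echoed into
output metadata:

* zero differences are discarded before ranking (Wilcoxon's convention);
  retaining them is available via ``zero_method="keep"``, which ranks zeros
  but assigns them to neither sign;
* the p-value is exact (full null distribution of W by convolution) when the
  number of non-zero differences is <= 25 and their magnitudes are tie-free,
  otherwise a normal approximation with tie-corrected variance and a 0.5
  continuity correction;
* significance is strict: p < alpha;
* no multiplicity adjustment enters the significant set — a Benjamini-
  Hochberg column is emitted for context only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core_data import DataError, ExpressionMatrix, SampleMetadata

EXACT_MAX_N = 25


@dataclass
class PairedDesign:
    """Ordered (sample_A, sample_B) pairs for two condition labels."""

    pairs: list            # list of (sample_id_A, sample_id_B)
    label_a: str = "A"
    label_b: str = "B"

    def __post_init__(self) -> None:
        flat = [s for pair in self.pairs for s in pair]
        if len(set(flat)) != len(flat):
            raise DataError("a sample appears in more than one pair")
        if not self.pairs:
            raise DataError("design has no pairs")

    @classmethod
    def from_metadata(cls, meta: SampleMetadata, label_a: str, label_b: str) -> "PairedDesign":
        meta.check_paired()
        tab = meta.table.dropna(subset=["pair_id"])
        tab = tab[tab["pair_id"].astype(str).str.len() > 0]
        pairs = []
        for pid, grp in sorted(tab.groupby("pair_id"), key=lambda kv: str(kv[0])):
            by_group = dict(zip(grp["group"], grp["sample_id"]))
            if label_a not in by_group or label_b not in by_group:
                raise DataError(f"pair {pid!r} lacks groups {label_a!r}/{label_b!r}")
            pairs.append((by_group[label_a], by_group[label_b]))
        return cls(pairs, label_a, label_b)

    def check_matrix(self, mat: ExpressionMatrix) -> None:
        have = set(mat.sample_ids)
        missing = [s for pair in self.pairs for s in pair if s not in have]
        if missing:
            raise DataError(f"design samples absent from matrix: {missing[:5]}")


def log2_fold_change(mat: ExpressionMatrix, design: PairedDesign) -> pd.Series:
    """Mean log2 expression in condition A minus mean in condition B, per feature."""
    design.check_matrix(mat)
    a_ids = [p[0] for p in design.pairs]
    b_ids = [p[1] for p in design.pairs]
    if not a_ids or not b_ids:
        raise DataError("both conditions must be non-empty")
    fc = mat.data[a_ids].mean(axis=1) - mat.data[b_ids].mean(axis=1)
    fc.name = "log2fc"
    return fc


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank
# ---------------------------------------------------------------------------

@dataclass
class WilcoxonResult:
    statistic: float       # W = sum of ranks of positive differences
    p: float               # two-sided
    n_used: int            # non-zero differences entering the ranking
    method: str            # "exact" | "approx" | "degenerate"


def _exact_null_counts(n: int) -> np.ndarray:
    """Counts of subsets of {1..n} attaining each rank-sum 0..n(n+1)/2."""
    total = n * (n + 1) // 2
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in range(1, n + 1):
        counts[r:] += counts[:-r].copy()
    return counts


def wilcoxon_signed_rank(diffs: Sequence[float], zero_method: str = "discard",
                         mode: str = "auto") -> WilcoxonResult:
    """Two-sided Wilcoxon signed-rank test on paired differences.

    Returns W (sum of ranks of positive differences over midranks of |diffs|)
    and the two-sided p-value.  ``mode`` may force ``"exact"`` (tie-free,
    n <= 25 only) or ``"approx"``.
    """
    d = np.asarray(diffs, float)
    if d.size < 1:
        raise DataError("need at least one difference")
    if zero_method not in ("discard", "keep"):
        raise DataError(f"unknown zero_method {zero_method!r}")
    if zero_method == "discard":
        d = d[d != 0]
    if d.size == 0 or np.all(d == 0):
        return WilcoxonResult(0.0, 1.0, 0, "degenerate")
    absd = np.abs(d)
    ranks = stats.rankdata(absd)
    w_pos = float(ranks[d > 0].sum())
    n = d.size
    has_ties = np.unique(absd).size != n
    if mode == "auto":
        mode = "exact" if (n <= EXACT_MAX_N and not has_ties and zero_method == "discard"
                           and np.all(d != 0)) else "approx"
    if mode == "exact":
        if has_ties or np.any(d == 0):
            raise DataError("exact mode requires tie-free non-zero differences")
        counts = _exact_null_counts(n)
        total = counts.sum()
        w = int(round(w_pos))
        cdf = counts[: w + 1].sum() / total
        sf = counts[w:].sum() / total
        p = min(1.0, 2 * min(cdf, sf))
        return WilcoxonResult(w_pos, p, n, "exact")
    # normal approximation, tie-corrected variance, 0.5 continuity correction
    n_zero = int((d == 0).sum())           # nonzero only under zero_method="keep"
    n_nz = n - n_zero
    mu = (n * (n + 1) - n_zero * (n_zero + 1)) / 4
    var = (n * (n + 1) * (2 * n + 1) - n_zero * (n_zero + 1) * (2 * n_zero + 1)) / 24
    _, tie_counts = np.unique(absd[d != 0], return_counts=True)
    var -= (tie_counts ** 3 - tie_counts).sum() / 48
    if var <= 0:
        return WilcoxonResult(w_pos, 1.0, n_nz, "degenerate")
    delta = w_pos - mu
    z = (delta - 0.5 * np.sign(delta)) / np.sqrt(var)
    p = min(1.0, 2 * stats.norm.sf(abs(z)))
    return WilcoxonResult(w_pos, float(p), n_nz, "approx")


def differential_table(mat: ExpressionMatrix, design: PairedDesign,
                       alpha: float = 0.05, zero_method: str = "discard"):
    """Per-feature paired Wilcoxon test and log2 fold change.

    Returns ``(table, significant)`` where the table has columns
    ``feature_id, n_pairs_used, W, p, p_bh, log2fc`` and ``significant`` is
    the set of features with p strictly below ``alpha`` (raw p; the BH column
    is reporting-only).
    """
    if not (0 < alpha < 1):
        raise DataError("alpha must lie in (0, 1)")
    design.check_matrix(mat)
    a_ids = [p[0] for p in design.pairs]
    b_ids = [p[1] for p in design.pairs]
    diffs = mat.data[a_ids].to_numpy() - mat.data[b_ids].to_numpy()
    fc = log2_fold_change(mat, design)
    rows = []
    for i, fid in enumerate(mat.feature_ids):
        res = wilcoxon_signed_rank(diffs[i], zero_method=zero_method)
        rows.append((fid, res.n_used, res.statistic, res.p))
    tab = pd.DataFrame(rows, columns=["feature_id", "n_pairs_used", "W", "p"])
    tab["p_bh"] = multipletests(tab["p"].to_numpy(), method="fdr_bh")[1]
    tab["log2fc"] = fc.to_numpy()
    significant = set(tab.loc[tab["p"] < alpha, "feature_id"])
    return tab, significant


def write_differential_tsv(tab: pd.DataFrame, path, header_lines=()) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        tab[["feature_id", "n_pairs_used", "W", "p", "p_bh", "log2fc"]].to_csv(
            fh, sep="\t", index=False, lineterminator="\n")
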