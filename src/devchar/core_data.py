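"""Core data containers, text I/O, probe collapse, standardization and smoothing.

Expression values are log2-scale normalized intensities held in a pandas
DataFrame (features x samples).  Sample metadata places every sample on a
single monotone age axis in days (prenatal ages as days post conception,
postnatal ages offset by gestation length) and carries replicate, group and
pair labels for the time-series and paired designs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

METADATA_COLUMNS = ["sample_id", "age_days", "replicate_id", "group", "pair_id"]


class DataError(ValueError):
    """Raised when an input file or container violates a structural invariant."""


@dataclass
class ExpressionMatrix:
    """A features x samples matrix of log2-scale expression values.

    Parameters
    ----------
    data
        DataFrame indexed by feature identifier with one column per sample.
    feature_level
        ``"probe"`` for platform-level probe sets, ``"gene"`` after collapse.
    """

    data: pd.DataFrame
    feature_level: str = "probe"

    def __post_init__(self) -> None:
        if self.feature_level not in ("probe", "gene"):
            raise DataError(f"feature_level must be 'probe' or 'gene', got {self.feature_level!r}")
        self.validate()

    def validate(self) -> None:
        idx = self.data.index
        cols = self.data.columns
        if idx.has_duplicates:
            dups = idx[idx.duplicated()].unique().tolist()
            raise DataError(f"duplicate feature ids: {dups[:5]}")
        if cols.has_duplicates:
            dups = cols[cols.duplicated()].unique().tolist()
            raise DataError(f"duplicate sample ids: {dups[:5]}")
        values = self.data.to_numpy()
        if values.size and not np.isfinite(values).all():
            bad = np.argwhere(~np.isfinite(values))[0]
            raise DataError(
                f"non-finite value at feature {idx[bad[0]]!r}, sample {cols[bad[1]]!r}"
            )

    @property
    def feature_ids(self) -> list:
        return self.data.index.tolist()

    @property
    def sample_ids(self) -> list:
        return self.data.columns.tolist()

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape


@dataclass
class SampleMetadata:
    """Per-sample age, replicate, group and pair annotations."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in METADATA_COLUMNS if c not in self.table.columns]
        if missing:
            raise DataError(f"metadata missing columns: {missing}")
        sid = self.table["sample_id"]
        if sid.duplicated().any():
            raise DataError(f"duplicate sample_id in metadata: {sid[sid.duplicated()].tolist()[:5]}")
        ages = pd.to_numeric(self.table["age_days"], errors="coerce")
        if (ages.dropna() < 0).any():
            raise DataError("age_days must be non-negative")
        self.table = self.table.copy()
        self.table["age_days"] = ages

    def for_samples(self, sample_ids: Sequence) -> "SampleMetadata":
        sub = self.table.set_index("sample_id").loc[list(sample_ids)].reset_index()
        return SampleMetadata(sub)

    def check_matches(self, mat: ExpressionMatrix) -> None:
        meta_ids = set(self.table["sample_id"])
        missing = [s for s in mat.sample_ids if s not in meta_ids]
        if missing:
            raise DataError(f"samples absent from metadata: {missing[:5]}")

    def check_paired(self) -> None:
        tab = self.table.dropna(subset=["pair_id"])
        tab = tab[tab["pair_id"].astype(str).str.len() > 0]
        for pid, grp in tab.groupby("pair_id"):
            if len(grp) != 2 or grp["group"].nunique() != 2:
                raise DataError(
                    f"pair {pid!r} must have exactly two samples with distinct groups"
                )


@dataclass
class ProbeGeneMap:
    """Many-to-one mapping from probe identifiers to gene identifiers."""

    table: pd.DataFrame  # columns probe_id, gene_id

    def __post_init__(self) -> None:
        for col in ("probe_id", "gene_id"):
            if col not in self.table.columns:
                raise DataError(f"probe map missing column {col!r}")
        dup = self.table["probe_id"].duplicated()
        if dup.any():
            raise DataError(
                f"probe ids mapping to more than one gene: "
                f"{self.table.loc[dup, 'probe_id'].tolist()[:5]}"
            )

    @property
    def probe_to_gene(self) -> dict:
        return dict(zip(self.table["probe_id"], self.table["gene_id"]))

    @property
    def gene_ids(self) -> list:
        return sorted(self.table["gene_id"].unique().tolist())


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_NA_TOKENS = {"", "na", "nan", "null", "none", "n/a"}


def read_expression_tsv(path, feature_level: str = "probe", drop_missing: bool = True) -> ExpressionMatrix:
    """Read a tab-delimited expression matrix.

    First column holds feature ids, the header row holds sample ids, the body
    is numeric.  Lines starting with ``#`` are treated as comments.  Features
    containing missing values are dropped with a logged count; any other
    non-numeric cell is a parse error naming the offending row and column.
    """
    try:
        raw = pd.read_csv(path, sep="\t", comment="#", index_col=0, dtype=str)
    except pd.errors.ParserError as exc:
        raise DataError(f"malformed expression table {path}: {exc}") from exc
    if raw.columns.size == 0:
        raise DataError(f"{path}: no sample columns found")
    numeric = raw.apply(lambda col: pd.to_numeric(col, errors="coerce"))
    # distinguish genuinely missing tokens from junk cells
    junk = numeric.isna() & ~raw.isna() & ~raw.apply(
        lambda col: col.astype(str).str.strip().str.lower().isin(_NA_TOKENS)
    )
    if junk.to_numpy().any():
        i, j = np.argwhere(junk.to_numpy())[0]
        raise DataError(
            f"{path}: non-numeric value {raw.iat[i, j]!r} at feature "
            f"{raw.index[i]!r}, sample {raw.columns[j]!r}"
        )
    # re-parse numerically with correctly-rounded conversion so written values
    # round-trip bit-exactly (to_numeric's fast path can be off by one ulp)
    numeric = pd.read_csv(path, sep="\t", comment="#", index_col=0,
                          float_precision="round_trip")
    numeric = numeric.apply(lambda col: pd.to_numeric(col, errors="coerce")
                            if col.dtype == object else col)
    has_na = numeric.isna().any(axis=1)
    if has_na.any():
        if not drop_missing:
            raise DataError(f"{path}: missing values in {int(has_na.sum())} features")
        logger.info("dropping %d features with missing values", int(has_na.sum()))
        numeric = numeric.loc[~has_na]
    numeric.index.name = "feature_id"
    return ExpressionMatrix(numeric.astype(float), feature_level=feature_level)


def write_expression_tsv(mat: ExpressionMatrix, path, header_lines: Iterable[str] = ()) -> None:
    """Write a matrix as TSV; values use full repr precision and round-trip exactly."""
    with open(path, "w", encoding="utf-8") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        out = mat.data.copy()
        out.index.name = "feature_id"
        out.to_csv(fh, sep="\t", lineterminator="\n")


def read_metadata_tsv(path) -> SampleMetadata:
    tab = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    tab["age_days"] = pd.to_numeric(tab.get("age_days"), errors="coerce")
    return SampleMetadata(tab)


def write_metadata_tsv(meta: SampleMetadata, path, header_lines: Iterable[str] = ()) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        meta.table.to_csv(fh, sep="\t", index=False, lineterminator="\n")


def read_probe_map_tsv(path) -> ProbeGeneMap:
    tab = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if list(tab.columns[:2]) != ["probe_id", "gene_id"]:
        tab = pd.read_csv(path, sep="\t", comment="#", dtype=str,
                          header=None, names=["probe_id", "gene_id"])
    return ProbeGeneMap(tab[["probe_id", "gene_id"]])


def write_probe_map_tsv(pmap: ProbeGeneMap, path) -> None:
    pmap.table.to_csv(path, sep="\t", index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# Replicate correlation and probe collapse
# ---------------------------------------------------------------------------

def replicate_profile_correlation(mat: ExpressionMatrix, meta: SampleMetadata) -> pd.DataFrame:
    """Pearson correlation between the two replicate time-series profiles of each feature.

    The two replicates must cover a common grid of ages, each age once per
    replicate.  Features whose profile is constant in either replicate get a
    NaN correlation (flagged undefined).

    Returns a DataFrame with columns ``feature_id`` and ``correlation``.
    """
    meta.check_matches(mat)
    tab = meta.table.set_index("sample_id").loc[mat.sample_ids]
    reps = sorted(tab["replicate_id"].dropna().unique().tolist())
    if len(reps) != 2:
        raise DataError(f"expected exactly 2 replicate series, found {reps}")
    grids = {}
    for rep in reps:
        sub = tab[tab["replicate_id"] == rep].sort_values(["age_days"], kind="mergesort")
        ages = sub["age_days"].to_numpy(float)
        if np.unique(ages).size != ages.size:
            raise DataError(f"replicate {rep!r} has repeated ages")
        grids[rep] = (ages, sub.index.tolist())
    a0, s0 = grids[reps[0]]
    a1, s1 = grids[reps[1]]
    if a0.size != a1.size or not np.allclose(a0, a1):
        raise DataError("replicate age grids do not match")
    x = mat.data[s0].to_numpy()
    y = mat.data[s1].to_numpy()
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean(axis=1, keepdims=True)
    sx = np.sqrt((xc ** 2).sum(axis=1))
    sy = np.sqrt((yc ** 2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = (xc * yc).sum(axis=1) / (sx * sy)
    corr[(sx == 0) | (sy == 0)] = np.nan
    return pd.DataFrame({"feature_id": mat.feature_ids, "correlation": corr})


def _select_representatives(scores: pd.DataFrame, pmap: ProbeGeneMap,
                            score_col: str, ascending: bool) -> pd.DataFrame:
    """One probe per gene: best score, ties broken by lexicographically smallest probe_id."""
    merged = scores.merge(pmap.table, left_on="feature_id", right_on="probe_id", how="inner")
    fill = np.inf if ascending else -np.inf
    merged["_score"] = merged[score_col].fillna(fill)
    merged["_pid"] = merged["probe_id"].astype(str)
    merged = merged.sort_values(["gene_id", "_score", "_pid"],
                                ascending=[True, ascending, True], kind="mergesort")
    return merged.groupby("gene_id", sort=True).head(1)


def collapse_by_replicate_correlation(mat: ExpressionMatrix, pmap: ProbeGeneMap,
                                      corr: pd.DataFrame) -> ExpressionMatrix:
    """Collapse a probe-level matrix to gene level.

    Each gene is represented by its probe with the maximum replicate-profile
    correlation; single-probe genes pass through unchanged.  Probes absent
    from the map are excluded (count logged).  Output rows are ordered by
    gene id for determinism.
    """
    if mat.feature_level != "probe":
        raise DataError("collapse expects a probe-level matrix")
    known = set(pmap.table["probe_id"])
    unmapped = [p for p in mat.feature_ids if p not in known]
    if unmapped:
        logger.info("excluding %d probes absent from the probe map", len(unmapped))
    scores = corr[corr["feature_id"].isin(set(mat.feature_ids))]
    best = _select_representatives(scores, pmap, "correlation", ascending=False)
    data = mat.data.loc[best["probe_id"].tolist()]
    data.index = pd.Index(best["gene_id"].tolist(), name="feature_id")
    return ExpressionMatrix(data, feature_level="gene")


def collapse_by_min_pvalue(de_table: pd.DataFrame, pmap: ProbeGeneMap) -> pd.DataFrame:
    """Collapse a probe-level differential-expression table to gene level.

    Keeps the minimum-p probe row per gene (ties: lexicographically smallest
    probe_id) and adds a ``gene_id`` column; all other columns pass through.
    """
    if "feature_id" not in de_table.columns or "p" not in de_table.columns:
        raise DataError("differential table must have feature_id and p columns")
    p = de_table["p"].to_numpy(float)
    if np.nanmin(p) < 0 or np.nanmax(p) > 1:
        raise DataError("p values must lie in [0, 1]")
    best = _select_representatives(de_table, pmap, "p", ascending=True)
    out = best.drop(columns=["_score", "_pid", "probe_id"]).reset_index(drop=True)
    cols = ["gene_id"] + [c for c in out.columns if c != "gene_id"]
    return out[cols]


# ---------------------------------------------------------------------------
# Standardization and smoothing
# ---------------------------------------------------------------------------

def standardize_columns(mat: ExpressionMatrix, ddof: int = 1) -> ExpressionMatrix:
    """Scale every sample column to mean 0 and variance 1 across features.

    Uses the sample-variance denominator (n - ddof).  A zero-variance column
    is an error naming the sample.
    """
    x = mat.values.astype(float)
    mean = x.mean(axis=0)
    var = x.var(axis=0, ddof=ddof)
    zero = np.flatnonzero(var == 0)
    if zero.size:
        raise DataError(f"zero-variance sample column: {mat.sample_ids[zero[0]]!r}")
    z = (x - mean) / np.sqrt(var)
    return ExpressionMatrix(pd.DataFrame(z, index=mat.data.index, columns=mat.data.columns),
                            feature_level=mat.feature_level)


def local_regression_smooth(profile: np.ndarray, ages: np.ndarray,
                            span: float = 0.7, degree: int = 1) -> np.ndarray:
    """Locally weighted polynomial smoothing of one expression profile over age.

    At each observed age the ``span``-nearest neighbours (k = ceil(span * n))
    are tricube-weighted by distance and a degree-``degree`` polynomial is fit
    by weighted least squares; the fit is evaluated at that age.  Reproduces
    polynomials up to ``degree`` exactly.
    """
    y = np.asarray(profile, float)
    x = np.asarray(ages, float)
    n = y.size
    if x.size != n:
        raise DataError("profile and ages must have equal length")
    if n < max(4, degree + 2):
        raise DataError(f"need at least {max(4, degree + 2)} points for degree {degree}")
    if not (0 < span <= 1):
        raise DataError("span must lie in (0, 1]")
    order = np.argsort(x, kind="mergesort")
    xs, ys = x[order], y[order]
    if np.any(np.diff(xs) <= 0):
        raise DataError("ages must be strictly increasing after sorting")
    k = int(np.ceil(span * n))
    if k < degree + 2:
        raise DataError(f"span {span} covers {k} points; need at least {degree + 2}")
    fitted = np.empty(n)
    for i, x0 in enumerate(xs):
        d = np.abs(xs - x0)
        h = np.partition(d, k - 1)[k - 1]
        with np.errstate(divide="ignore", invalid="ignore"):
            u = np.where(h > 0, d / h, 0.0)
        w = np.clip(1 - u ** 3, 0, None) ** 3
        active = w > 0
        if active.sum() < degree + 1:  # farthest neighbour gets weight 0
            idx = np.argsort(d, kind="mergesort")[: degree + 1]
            active = np.zeros(n, bool)
            active[idx] = True
            w[idx] = np.maximum(w[idx], 1e-12)
        coeffs = np.polynomial.polynomial.polyfit(
            xs[active] - x0, ys[active], degree, w=np.sqrt(w[active])
        )
        fitted[i] = coeffs[0]
    out = np.empty(n)
    out[order] = fitted
    return out
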