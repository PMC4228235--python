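"""Gene-set assembly and 2x2 over-representation inference.

Given two gene sets inside an explicit universe (all genes measured on the
platform after probe collapse), the overlap is summarized by a 2x2 table

              in B      not in B
    in A        a           b
    not in A    c           d

and tested with the two-sided Fisher exact test.  The point estimates are the
cross-product (sample) odds ratio ad/bc and the conditional maximum-likelihood
odds ratio (the noncentral hypergeometric likelihood maximizer with all
margins fixed).  Two 95% interval methods are provided, both derived from the
noncentral hypergeometric distribution of cell `a`:

* ``cornfield`` (default): Cornfield's chi-square inversion of the conditional
  mean and variance with a 0.5 continuity correction — the convention of
  classic epidemiological software, and the method whose bounds match
  published contingency analyses this pipeline is designed to reproduce;
* ``exact``: tail inversion, solving P(X >= a | psi) = alpha/2 for the lower
  bound and P(X <= a | psi) = alpha/2 for the upper — the convention of
  R's ``fisher.test``.

All routines share one log-space hypergeometric kernel; root finding is
monotone bisection/Brent to relative tolerance 1e-8.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.special import gammaln, logsumexp
from scipy.stats import norm

from .core_data import DataError

logger = logging.getLogger(__name__)

_REL_TOL = 1e-8


# ---------------------------------------------------------------------------
# Gene sets
# ---------------------------------------------------------------------------

@dataclass
class GeneSet:
    """Named collection of gene ids with per-gene provenance tags."""

    name: str
    genes: set
    provenance: dict = field(default_factory=dict)  # gene -> set of tags

    def __post_init__(self) -> None:
        self.genes = set(self.genes)
        if not self.genes:
            raise DataError(f"gene set {self.name!r} is empty")

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class UnionSetResult:
    gene_set: GeneSet
    supervised: set
    unsupervised: set
    intersection: set


def assemble_union_set(supervised_lists, unsupervised_lists, name: str = "union") -> UnionSetResult:
    """Union of supervised (literature/ontology) and unsupervised (data-driven)
    gene lists, tagging each gene with the provenance of every list containing it."""
    if not supervised_lists or not unsupervised_lists:
        raise DataError("need at least one supervised and one unsupervised list")
    sup = set().union(*(gs.genes for gs in supervised_lists))
    unsup = set().union(*(gs.genes for gs in unsupervised_lists))
    provenance = {}
    for g in sup | unsup:
        tags = set()
        if g in sup:
            tags.add("supervised")
        if g in unsup:
            tags.add("unsupervised")
        provenance[g] = tags
    gs = GeneSet(name, sup | unsup, provenance)
    return UnionSetResult(gs, sup, unsup, sup & unsup)


def read_gmt(path) -> list:
    """Read gene sets from a GMT file (name <TAB> description <TAB> members...)."""
    sets = []
    with open(path, encoding="utf-8") as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise DataError(f"{path}:{ln}: GMT line needs name, description, members")
            sets.append(GeneSet(parts[0], set(p for p in parts[2:] if p)))
    return sets


def write_gmt(gene_sets, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for gs in gene_sets:
            fh.write("\t".join([gs.name, ""] + sorted(map(str, gs.genes))) + "\n")


# ---------------------------------------------------------------------------
# Contingency table and the noncentral hypergeometric kernel
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ContingencyTable:
    """2x2 counts: a = |A∩B|, b = |A\\B|, c = |B\\A|, d = |U\\(A∪B)|."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v >= 0):
                raise DataError(f"cell {name} must be a non-negative integer, got {v!r}")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def margins(self) -> tuple:
        return (self.a + self.b, self.c + self.d, self.a + self.c, self.b + self.d)

    @property
    def support(self) -> np.ndarray:
        m1, m2, n1, _ = self.margins
        return np.arange(max(0, n1 - m2), min(m1, n1) + 1)

    def transpose(self) -> "ContingencyTable":
        return ContingencyTable(self.a, self.c, self.b, self.d)


def build_contingency(set_a: GeneSet, set_b: GeneSet, universe) -> ContingencyTable:
    """Cross-tabulate two gene sets within an explicit universe.

    Members outside the universe are dropped with a logged count.
    """
    uni = set(universe)
    if not uni:
        raise DataError("universe is empty")
    a_in = set_a.genes & uni
    b_in = set_b.genes & uni
    dropped = len(set_a.genes - uni) + len(set_b.genes - uni)
    if dropped:
        logger.info("dropped %d set members outside the universe", dropped)
    a = len(a_in & b_in)
    b = len(a_in - b_in)
    c = len(b_in - a_in)
    d = len(uni) - len(a_in | b_in)
    return ContingencyTable(a, b, c, d)


def _log_hyper_weights(t: ContingencyTable):
    """Log central-hypergeometric weights over the support of cell a."""
    m1, m2, n1, _ = t.margins
    x = t.support
    lw = (gammaln(m1 + 1) - gammaln(x + 1) - gammaln(m1 - x + 1)
          + gammaln(m2 + 1) - gammaln(n1 - x + 1) - gammaln(m2 - n1 + x + 1))
    return x, lw


def _conditional_pmf(t: ContingencyTable, log_psi: float):
    """Normalized noncentral hypergeometric pmf of cell a at odds ratio e^log_psi."""
    x, lw = _log_hyper_weights(t)
    lw = lw + x * log_psi
    w = np.exp(lw - logsumexp(lw))
    return x, w


def fisher_two_sided(t: ContingencyTable) -> float:
    """Two-sided Fisher exact p by the point-probability rule.

    Sums the probabilities of all tables (same margins) whose probability does
    not exceed the observed table's, with the customary 1e-7 relative slack on
    the comparison.
    """
    x, lw = _log_hyper_weights(t)
    lp = lw - logsumexp(lw)
    obs = lp[x == t.a][0]
    mask = lp <= obs + np.log1p(1e-7)
    p = float(np.exp(logsumexp(lp[mask])))
    return min(1.0, max(p, np.exp(obs)))


def odds_ratio_sample(t: ContingencyTable) -> float:
    """Cross-product odds ratio ad/bc; inf when bc = 0 and ad > 0, nan for 0/0."""
    num = t.a * t.d
    den = t.b * t.c
    if den == 0:
        return np.nan if num == 0 else np.inf
    return num / den


def _conditional_mean(t: ContingencyTable, log_psi: float) -> float:
    x, w = _conditional_pmf(t, log_psi)
    return float((x * w).sum())


def _bracket(f, x0: float, lo_limit: float = -300.0, hi_limit: float = 300.0):
    """Expand around x0 until f changes sign; f must be monotone."""
    step = 1.0
    lo = hi = x0
    flo = fhi = f(x0)
    while flo > 0 and lo > lo_limit:
        lo -= step
        step *= 2
        flo = f(lo)
    step = 1.0
    while fhi < 0 and hi < hi_limit:
        hi += step
        step *= 2
        fhi = f(hi)
    if flo > 0 or fhi < 0:
        raise DataError("root bracketing failed")
    return lo, hi


def odds_ratio_cmle(t: ContingencyTable) -> float:
    """Conditional maximum-likelihood odds ratio.

    Solves E_psi[X] = a, the score equation of the noncentral hypergeometric
    likelihood with all margins fixed; 0 / inf at the support boundaries.
    """
    sup = t.support
    if t.a == sup[0] and t.a == sup[-1]:
        return np.nan  # degenerate support
    if t.a == sup[0]:
        return 0.0
    if t.a == sup[-1]:
        return np.inf
    f = lambda lp: _conditional_mean(t, lp) - t.a
    start = np.log(odds_ratio_sample(t)) if np.isfinite(odds_ratio_sample(t)) and odds_ratio_sample(t) > 0 else 0.0
    lo, hi = _bracket(f, start)
    root = brentq(f, lo, hi, xtol=1e-12, rtol=_REL_TOL)
    return float(np.exp(root))


def exact_ci(t: ContingencyTable, level: float = 0.95) -> tuple:
    """Exact conditional confidence interval for the odds ratio by tail inversion.

    Lower bound: P(X >= a | psi) = (1-level)/2; upper bound:
    P(X <= a | psi) = (1-level)/2.  Bounds at the support boundary are 0/inf.
    """
    _check_level(level)
    alpha = (1 - level) / 2
    sup = t.support
    if sup.size == 1:
        return (0.0, np.inf)

    def upper_tail(lp):
        x, w = _conditional_pmf(t, lp)
        return float(w[x >= t.a].sum())

    def lower_tail(lp):
        x, w = _conditional_pmf(t, lp)
        return float(w[x <= t.a].sum())

    if t.a == sup[0]:
        low = 0.0
    else:
        f = lambda lp: upper_tail(lp) - alpha
        lo, hi = _bracket(f, 0.0)
        low = float(np.exp(brentq(f, lo, hi, xtol=1e-12, rtol=_REL_TOL)))
    if t.a == sup[-1]:
        high = np.inf
    else:
        g = lambda lp: alpha - lower_tail(lp)
        lo, hi = _bracket(g, 0.0)
        high = float(np.exp(brentq(g, lo, hi, xtol=1e-12, rtol=_REL_TOL)))
    return (low, high)


def cornfield_ci(t: ContingencyTable, level: float = 0.95, continuity: bool = True) -> tuple:
    """Cornfield's confidence interval for the odds ratio.

    Inverts the chi-square statistic (a - E_psi[X] -/+ cc)^2 / Var_psi[X] = z^2
    built from the conditional (noncentral hypergeometric) mean and variance,
    with continuity correction cc = 0.5 by default.
    """
    _check_level(level)
    z2 = norm.ppf(1 - (1 - level) / 2) ** 2
    cc = 0.5 if continuity else 0.0
    sup = t.support
    if sup.size == 1:
        return (0.0, np.inf)

    def moments(lp):
        x, w = _conditional_pmf(t, lp)
        mu = float((x * w).sum())
        return mu, float((w * (x - mu) ** 2).sum())

    center = odds_ratio_cmle(t)
    log_center = np.log(center) if 0 < center < np.inf else 0.0

    def f_low(lp):
        mu, var = moments(lp)
        # increasing in psi: negative below the lower bound
        return z2 - (t.a - mu - cc) ** 2 / var if t.a - mu - cc > 0 else z2

    def f_high(lp):
        mu, var = moments(lp)
        return (t.a - mu + cc) ** 2 / var - z2 if mu - t.a - cc > 0 else -z2

    if t.a == sup[0]:
        low = 0.0
    else:
        lo, hi = _bracket(f_low, log_center)
        low = float(np.exp(brentq(f_low, lo, hi, xtol=1e-12, rtol=_REL_TOL)))
    if t.a == sup[-1]:
        high = np.inf
    else:
        lo, hi = _bracket(f_high, log_center)
        high = float(np.exp(brentq(f_high, lo, hi, xtol=1e-12, rtol=_REL_TOL)))
    return (low, high)


def _check_level(level: float) -> None:
    if not (0 < level < 1):
        raise DataError("confidence level must lie in (0, 1)")


# ---------------------------------------------------------------------------
# Composite enrichment
# ---------------------------------------------------------------------------

@dataclass
class EnrichmentResult:
    """Full over-representation record for one pair of gene sets."""

    table: ContingencyTable
    p_two_sided: float
    or_sample: float
    or_cmle: float
    ci95: tuple                    # interval by ci_method
    ci95_exact: tuple              # exact tail-inversion interval, always reported
    level: float = 0.95
    ci_method: str = "cornfield"
    universe_size: int = 0

    def to_dict(self) -> dict:
        t = self.table

        def _num(v):
            return None if v is None or (isinstance(v, float) and np.isnan(v)) else (
                "inf" if v == np.inf else float(v))
        return {
            "cells": {"a": t.a, "b": t.b, "c": t.c, "d": t.d},
            "universe_size": self.universe_size or t.total,
            "p_two_sided": float(self.p_two_sided),
            "or_sample": _num(self.or_sample),
            "or_cmle": _num(self.or_cmle),
            "level": self.level,
            "ci_method": self.ci_method,
            "ci": [_num(self.ci95[0]), _num(self.ci95[1])],
            "ci_exact": [_num(self.ci95_exact[0]), _num(self.ci95_exact[1])],
            "p_method": "fisher_two_sided_point_probability",
        }

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), **kw)


def enrich_table(t: ContingencyTable, level: float = 0.95,
                 ci_method: str = "cornfield") -> EnrichmentResult:
    """All enrichment statistics for a prebuilt 2x2 table."""
    if ci_method not in ("cornfield", "exact"):
        raise DataError(f"unknown ci_method {ci_method!r}")
    exact = exact_ci(t, level)
    ci = cornfield_ci(t, level) if ci_method == "cornfield" else exact
    return EnrichmentResult(
        table=t,
        p_two_sided=fisher_two_sided(t),
        or_sample=odds_ratio_sample(t),
        or_cmle=odds_ratio_cmle(t),
        ci95=ci,
        ci95_exact=exact,
        level=level,
        ci_method=ci_method,
        universe_size=t.total,
    )


def enrich(set_a: GeneSet, set_b: GeneSet, universe, level: float = 0.95,
           ci_method: str = "cornfield") -> EnrichmentResult:
    """Over-representation of set A among set B within the universe."""
    t = build_contingency(set_a, set_b, universe)
    res = enrich_table(t, level=level, ci_method=ci_method)
    res.universe_size = len(set(universe))
    return res


def contingency_from_counts(overlap: int, size_a: int, size_b: int,
                            universe_size: int) -> ContingencyTable:
    """Reconstruct the 2x2 table from printed summary counts."""
    a = overlap
    b = size_a - overlap
    c = size_b - overlap
    d = universe_size - size_a - size_b + overlap
    if min(b, c, d) < 0:
        raise DataError("inconsistent counts: negative cell")
    return ContingencyTable(a, b, c, d)
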