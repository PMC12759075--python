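"""Cross-condition and feature-level statistics for protein call sets.

Contingency tables with Fisher's exact test (two-sided, probability-mass
rule), Pearson chi-square across feature groups, enrichment ratios,
two/three-set overlap summaries, and Kolmogorov-Smirnov comparison of a
per-protein numeric score between classes.  Identifier joins use the
caller's protein/gene symbols; unmapped ids are logged and dropped, never
silently matched.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .structure_calls import STATUS_EXCLUDED, STATUS_PERTURBED

__all__ = [
    "ContingencyTable2x2",
    "CrosstabResult",
    "OverlapSummary",
    "EnrichmentResult",
    "ChiSquareResult",
    "BinnedFractions",
    "fisher_exact",
    "chi_square_groups",
    "crosstab_status",
    "overlap_summary",
    "feature_enrichment",
    "binned_fraction_unperturbed",
    "ks_two_sample",
    "default_bins",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ContingencyTable2x2:
    """2x2 contingency table.  Cell layout::

        [[a, b],
         [c, d]]

    with ``a`` = row-1/col-1 etc.  Labels are free-form strings.
    """

    a: int
    b: int
    c: int
    d: int
    row_labels: tuple[str, str] = ("row1", "row2")
    col_labels: tuple[str, str] = ("col1", "col2")

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency cells must be non-negative")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def margins(self) -> tuple[int, int, int, int]:
        return (self.a + self.b, self.c + self.d, self.a + self.c, self.b + self.d)

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=np.int64)


def fisher_exact(table: ContingencyTable2x2) -> float:
    """Two-sided Fisher's exact p for a 2x2 table.

    Exact hypergeometric enumeration with the probability-mass rule (sum of
    all tables with fixed margins whose probability does not exceed the
    observed table's).  A zero margin makes the test undefined; by
    convention p = 1 is returned with a warning.
    """
    if min(table.margins) == 0:
        warnings.warn(
            "Fisher's exact test with a zero margin; returning p=1",
            stacklevel=2,
        )
        return 1.0
    _, p = stats.fisher_exact(table.as_array(), alternative="two-sided")
    return float(p)


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    df: int
    p: float
    low_expected: bool = False


def chi_square_groups(
    group_counts: Sequence[tuple[int, int]]
) -> ChiSquareResult:
    """Pearson chi-square across k groups of (n_success, n_total) pairs.

    Tests homogeneity of the success proportion across groups on the
    k x 2 table [[success, failure], ...]; df = k - 1.  An expected cell
    below 1 triggers a low-count warning but the statistic is still
    computed.
    """
    if len(group_counts) < 2:
        raise ValueError("chi_square_groups needs >= 2 groups")
    succ = np.array([g[0] for g in group_counts], dtype=float)
    total = np.array([g[1] for g in group_counts], dtype=float)
    if np.any(total <= 0):
        raise ValueError("group totals must be positive")
    if np.any(succ > total) or np.any(succ < 0):
        raise ValueError("successes must lie in [0, total]")
    table = np.column_stack([succ, total - succ])
    # guard the degenerate all-success / all-failure column before scipy
    if table[:, 0].sum() == 0 or table[:, 1].sum() == 0:
        return ChiSquareResult(0.0, len(group_counts) - 1, 1.0)
    res = stats.chi2_contingency(table, correction=False)
    low = bool((res.expected_freq < 1).any())
    if low:
        warnings.warn("chi-square with expected cell count < 1", stacklevel=2)
    return ChiSquareResult(float(res.statistic), int(res.dof), float(res.pvalue), low)


@dataclass(frozen=True)
class CrosstabResult:
    table: ContingencyTable2x2
    fisher_p: float
    n: int  # size of the jointly assessed universe


def crosstab_status(
    calls_x: Mapping[str, str],
    calls_y: Mapping[str, str],
    positive: str = STATUS_PERTURBED,
    labels: tuple[str, str] = ("x", "y"),
) -> CrosstabResult:
    """Cross-correlate two per-protein status maps.

    Only proteins confidently assessed (non-excluded) in BOTH maps enter
    the table.  Cells: a = positive in both, b = positive in x only,
    c = positive in y only, d = positive in neither; Fisher p attached.
    """
    universe = [
        pid
        for pid in calls_x
        if pid in calls_y
        and calls_x[pid] != STATUS_EXCLUDED
        and calls_y[pid] != STATUS_EXCLUDED
    ]
    if not universe:
        raise ValueError("no proteins confidently assessed in both call sets")
    x_pos = {pid for pid in universe if calls_x[pid] == positive}
    y_pos = {pid for pid in universe if calls_y[pid] == positive}
    a = len(x_pos & y_pos)
    b = len(x_pos - y_pos)
    c = len(y_pos - x_pos)
    d = len(universe) - a - b - c
    table = ContingencyTable2x2(
        a, b, c, d,
        row_labels=(f"{labels[0]}:{positive}", f"{labels[0]}:not"),
        col_labels=(f"{labels[1]}:{positive}", f"{labels[1]}:not"),
    )
    return CrosstabResult(table, fisher_exact(table), len(universe))


@dataclass(frozen=True)
class OverlapSummary:
    """Venn region cardinalities for 2 or 3 named sets.

    ``regions`` maps a region label (e.g. ``"A"``, ``"A&B"``, ``"A&B&C"``)
    to the count of elements belonging to exactly that combination of
    sets.  ``percent_shared`` (two sets only) is
    100 * |intersection| / |union|.
    """

    names: tuple[str, ...]
    regions: dict[str, int]
    union: int
    percent_shared: float | None = None


def overlap_summary(
    sets: Mapping[str, Iterable[str]], universe: Iterable[str] | None = None
) -> OverlapSummary:
    """Exact Venn region counts for two or three named protein sets."""
    named = {name: set(s) for name, s in sets.items()}
    if universe is not None:
        uni = set(universe)
        named = {name: s & uni for name, s in named.items()}
    names = tuple(named)
    if len(names) not in (2, 3):
        raise ValueError("overlap_summary handles 2 or 3 sets")
    union: set[str] = set().union(*named.values())
    regions: dict[str, int] = {}
    for k in range(1, len(names) + 1):
        for combo in itertools.combinations(names, k):
            inside = set.intersection(*(named[n] for n in combo))
            outside = set().union(
                *(named[n] for n in names if n not in combo), set()
            )
            regions["&".join(combo)] = len(inside - outside)
    percent_shared = None
    if len(names) == 2 and union:
        inter = named[names[0]] & named[names[1]]
        percent_shared = 100.0 * len(inter) / len(union)
    return OverlapSummary(names, regions, len(union), percent_shared)


@dataclass(frozen=True)
class EnrichmentResult:
    feature: str
    ratio: float | None
    fisher_p: float | None
    table: ContingencyTable2x2
    subset_frequency: float | None = None
    background_frequency: float | None = None


def feature_enrichment(
    subset: Iterable[str],
    background: Iterable[str],
    feature_flags: Mapping[str, bool] | Callable[[str], bool],
    feature_name: str = "feature",
) -> EnrichmentResult:
    """Enrichment of a binary protein feature inside a subset.

    The ratio is the feature frequency within the subset divided by its
    overall frequency in the background (which must contain the subset);
    the Fisher p comes from the (in-subset x has-feature) 2x2 table built
    over the background.  A feature absent from the background yields an
    undefined (None) ratio.
    """
    sub = set(subset)
    bg = set(background)
    if not sub <= bg:
        raise ValueError("subset must be contained in background")
    if callable(feature_flags):
        has = {pid for pid in bg if feature_flags(pid)}
    else:
        unmapped = bg - set(feature_flags)
        if unmapped:
            logger.info(
                "%d background proteins lack a %s annotation; dropped",
                len(unmapped), feature_name,
            )
            bg = bg - unmapped
            sub = sub - unmapped
        has = {pid for pid in bg if feature_flags[pid]}
    a = len(sub & has)
    b = len(sub - has)
    c = len(has - sub)
    d = len(bg) - a - b - c
    table = ContingencyTable2x2(
        a, b, c, d,
        row_labels=("in_subset", "not_in_subset"),
        col_labels=(f"has_{feature_name}", f"no_{feature_name}"),
    )
    if not has or not bg or not sub:
        return EnrichmentResult(feature_name, None, None, table)
    freq_sub = a / len(sub)
    freq_bg = len(has) / len(bg)
    return EnrichmentResult(
        feature_name,
        ratio=freq_sub / freq_bg,
        fisher_p=fisher_exact(table),
        table=table,
        subset_frequency=freq_sub,
        background_frequency=freq_bg,
    )


# ---------------------------------------------------------------------------
# binned fractions


def default_bins(column: str) -> list[float] | None:
    """Default bin edges for the standard annotation axes.

    pI: 0.5-pH steps over 4-11; molecular weight: 20-kDa steps with a
    dedicated > 80 kDa top bin; domain count: 1, 2, 3, >= 4.  These are
    package defaults, configurable by the caller.
    """
    if column == "pI":
        return list(np.arange(4.0, 11.5, 0.5))
    if column == "mw_kda":
        return [0.0, 20.0, 40.0, 60.0, 80.0, float("inf")]
    if column == "n_domains":
        return [1, 2, 3, 4, float("inf")]
    return None


@dataclass(frozen=True)
class BinnedFractions:
    frame: pd.DataFrame  # columns: bin, n_unperturbed, n_total, fraction_unperturbed
    chi_square: ChiSquareResult | None


def binned_fraction_unperturbed(
    calls: Mapping[str, str],
    annotations: pd.DataFrame,
    column: str,
    bins: Sequence[float] | None = None,
) -> BinnedFractions:
    """Fraction of non-excluded proteins that remain unperturbed, grouped
    by bins of a numeric annotation column, with a chi-square test for
    homogeneity across bins.  Empty bins are dropped from both the table
    and the test; with fewer than two occupied bins no test is run.
    """
    status = pd.Series(dict(calls), name="status")
    status = status[status != STATUS_EXCLUDED]
    ann = annotations.set_index("protein_id")
    joined = ann.join(status, how="inner")
    dropped = len(status) - len(joined)
    if dropped:
        logger.info("%d called proteins lack annotations; dropped", dropped)
    if joined.empty:
        return BinnedFractions(
            pd.DataFrame(columns=["bin", "n_unperturbed", "n_total",
                                  "fraction_unperturbed"]),
            None,
        )
    values = joined[column]
    if bins is None:
        bins = default_bins(column)
    if bins is None:
        grouping = values.astype(str)
    else:
        grouping = pd.cut(values.astype(float), bins=list(bins),
                          include_lowest=True, right=False).astype(str)
    unpert = (joined["status"] != STATUS_PERTURBED)
    agg = (
        pd.DataFrame({"bin": grouping, "unpert": unpert})
        .groupby("bin", observed=True)
        .agg(n_unperturbed=("unpert", "sum"), n_total=("unpert", "size"))
        .reset_index()
    )
    agg = agg[agg["bin"] != "nan"]
    agg = agg[agg["n_total"] > 0].reset_index(drop=True)
    agg["fraction_unperturbed"] = agg["n_unperturbed"] / agg["n_total"]
    chi = None
    if len(agg) >= 2:
        chi = chi_square_groups(
            list(zip(agg["n_unperturbed"].astype(int), agg["n_total"].astype(int)))
        )
    return BinnedFractions(agg, chi)


def ks_two_sample(
    scores_a: Iterable[float], scores_b: Iterable[float]
) -> tuple[float, float]:
    """Two-sided two-sample Kolmogorov-Smirnov test.

    Exact null distribution when both samples have n <= 10 (equivalent to
    permutation enumeration for tie-free data), asymptotic otherwise.
    Returns ``(D, p)``.
    """
    a = np.asarray(list(scores_a), dtype=float)
    b = np.asarray(list(scores_b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("ks_two_sample requires non-empty samples")
    method = "exact" if (a.size <= 10 and b.size <= 10) else "asymp"
    res = stats.ks_2samp(a, b, method=method)
    return float(res.statistic), float(res.pvalue)
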