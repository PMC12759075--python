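"""Per-cut-site differential proteolytic susceptibility.

Implements the LiP-MS inference chain between an ion-level quantification
table and per-site statistics: imputation of condition-exclusive ions,
ion-to-cut-site merging, Welch's unequal-variance t-test on log2
intensities, normalization to protein abundance estimated from
trypsin-only control samples, and Benjamini-Hochberg FDR correction
applied within each protein across its cut-sites ("protein-wise").

All statistics run on log2-transformed merged intensities; a fold change
is the difference of group means of log2 intensities.  A site is
significant when its abundance-normalized |log2 fold change| reaches
log2(fold_change_min) AND its adjusted p-value is strictly below alpha.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .peptide_map import ProteinSeq, Trypticity, map_ions_to_sites

__all__ = [
    "ThresholdConfig",
    "SampleInfo",
    "StudyDesign",
    "DifferentialResult",
    "DesignError",
    "impute_missing",
    "merge_ions_to_cutsites",
    "welch_test",
    "welch_test_matrix",
    "bh_adjust",
    "bh_adjust_grouped",
    "protein_abundance_lfq",
    "normalize_to_abundance",
    "apply_significance",
    "run_differential",
]

logger = logging.getLogger(__name__)

TREATMENT_LIP = "LiP"
TREATMENT_CONTROL = "trypsin_only"

#: stable column order of the cut-site result table
CUTSITE_COLUMNS = [
    "protein_id",
    "site_id",
    "site_origin",
    "site_position",
    "n_ions",
    "imputed",
    "normalized",
    "log2fc_raw",
    "log2fc_norm",
    "t_stat",
    "df",
    "p_raw",
    "p_adj",
    "significant",
]

ABUNDANCE_COLUMNS = [
    "protein_id",
    "log2fc",
    "t_stat",
    "df",
    "p_raw",
    "p_adj",
    "significant_change",
]


class DesignError(ValueError):
    """Raised when a study design cannot support the requested comparison."""


class ConfigurationError(ValueError):
    """Raised for invalid threshold configuration values."""


@dataclass(frozen=True)
class ThresholdConfig:
    """Significance thresholds for the differential analysis.

    Defaults encode the conservative criteria used throughout: a >2-fold
    abundance-normalized change with Welch p < 0.05 after protein-wise BH
    correction marks a significant site; a protein needs >= 2 significant
    sites to be called perturbed and >= 2 quantified sites to be assessed
    at all.
    """

    fold_change_min: float = 2.0
    alpha: float = 0.05
    min_significant_sites: int = 2
    min_quantified_sites: int = 2
    imputation_quantile: float = 0.01
    min_observed_per_group: int = 2
    bh_scope: str = "protein"  # "protein" (protein-wise) or "global"

    def __post_init__(self) -> None:
        if not self.fold_change_min > 1:
            raise ConfigurationError("fold_change_min must be > 1")
        if not 0 < self.alpha < 1:
            raise ConfigurationError("alpha must be in (0, 1)")
        if self.min_significant_sites < 1:
            raise ConfigurationError("min_significant_sites must be >= 1")
        if self.min_quantified_sites < 1:
            raise ConfigurationError("min_quantified_sites must be >= 1")
        if not 0 < self.imputation_quantile < 1:
            raise ConfigurationError("imputation_quantile must be in (0, 1)")
        if self.min_observed_per_group < 1:
            raise ConfigurationError("min_observed_per_group must be >= 1")
        if self.bh_scope not in ("protein", "global"):
            raise ConfigurationError("bh_scope must be 'protein' or 'global'")

    @property
    def log2_fold_change_min(self) -> float:
        return math.log2(self.fold_change_min)


@dataclass(frozen=True)
class SampleInfo:
    sample_id: str
    condition: str
    treatment: str
    replicate: int


@dataclass(frozen=True)
class StudyDesign:
    """Maps sample columns to (condition, treatment, replicate) and names
    the pairwise comparison (test vs. reference condition)."""

    samples: tuple[SampleInfo, ...]
    comparison: tuple[str, str]

    def __post_init__(self) -> None:
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise DesignError("duplicate sample ids in design")
        for s in self.samples:
            if s.treatment not in (TREATMENT_LIP, TREATMENT_CONTROL):
                raise DesignError(
                    f"{s.sample_id}: treatment must be "
                    f"'{TREATMENT_LIP}' or '{TREATMENT_CONTROL}'"
                )
        for cond, treat in {
            (s.condition, s.treatment) for s in self.samples
        }:
            reps = [
                s.replicate
                for s in self.samples
                if s.condition == cond and s.treatment == treat
            ]
            if len(set(reps)) != len(reps):
                raise DesignError(
                    f"replicate labels not unique within ({cond}, {treat})"
                )

    @property
    def test_condition(self) -> str:
        return self.comparison[0]

    @property
    def reference_condition(self) -> str:
        return self.comparison[1]

    def samples_for(self, condition: str, treatment: str) -> list[str]:
        return [
            s.sample_id
            for s in self.samples
            if s.condition == condition and s.treatment == treatment
        ]

    def validate_comparison(
        self, min_replicates: int = 2, treatment: str = TREATMENT_LIP
    ) -> None:
        for cond in self.comparison:
            n = len(self.samples_for(cond, treatment))
            if n < min_replicates:
                raise DesignError(
                    f"condition {cond!r} has {n} {treatment} replicate(s); "
                    f"need >= {min_replicates} for a comparison"
                )

    def swapped(self) -> "StudyDesign":
        """The same design with test and reference conditions exchanged."""
        return replace(self, comparison=(self.comparison[1], self.comparison[0]))

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, comparison: tuple[str, str]) -> "StudyDesign":
        samples = tuple(
            SampleInfo(
                str(r.sample_id), str(r.condition), str(r.treatment), int(r.replicate)
            )
            for r in frame.itertuples()
        )
        return cls(samples, comparison)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": [s.sample_id for s in self.samples],
                "condition": [s.condition for s in self.samples],
                "treatment": [s.treatment for s in self.samples],
                "replicate": [s.replicate for s in self.samples],
            }
        )


# ---------------------------------------------------------------------------
# imputation


def imputation_floor(
    table: pd.DataFrame, sample_cols: Sequence[str], quantile: float
) -> float:
    """Dataset-wide imputation floor: the given quantile of all non-missing
    intensities in the listed sample columns."""
    values = table[list(sample_cols)].to_numpy(dtype=float).ravel()
    values = values[np.isfinite(values)]
    if values.size == 0:
        raise ConfigurationError("cannot derive imputation floor: no intensities")
    floor = float(np.quantile(values, quantile))
    if not floor > 0:
        raise ConfigurationError(f"imputation floor must be positive, got {floor}")
    return floor


def impute_missing(
    table: pd.DataFrame,
    test_samples: Sequence[str],
    ref_samples: Sequence[str],
    cfg: ThresholdConfig,
    floor: float | None = None,
) -> pd.DataFrame:
    """Handle condition-exclusive and under-observed ions.

    An ion observed in >= ``min_observed_per_group`` replicates of one group
    and zero of the other has the empty group's intensities set to the
    dataset-wide floor (``imputed`` flag set) so that an exclusive ion —
    where PK could cut in only one condition — yields a large, capped fold
    change instead of being lost.  Ions observed in fewer than
    ``min_observed_per_group`` replicates in *both* groups are dropped.
    Everything else passes through unchanged.
    """
    test_samples = list(test_samples)
    ref_samples = list(ref_samples)
    if floor is None:
        floor = imputation_floor(
            table, test_samples + ref_samples, cfg.imputation_quantile
        )
    if not floor > 0:
        raise ConfigurationError(f"imputation floor must be positive, got {floor}")
    m = cfg.min_observed_per_group
    obs_t = table[test_samples].notna().sum(axis=1)
    obs_r = table[ref_samples].notna().sum(axis=1)
    keep = (obs_t >= m) | (obs_r >= m)
    fill_ref = keep & (obs_t >= m) & (obs_r == 0)
    fill_test = keep & (obs_r >= m) & (obs_t == 0)
    out = table.loc[keep].copy()
    out.loc[fill_ref[keep], ref_samples] = floor
    out.loc[fill_test[keep], test_samples] = floor
    out["imputed"] = (fill_ref | fill_test)[keep]
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("dropped %d under-observed ions", n_dropped)
    return out


# ---------------------------------------------------------------------------
# ion -> cut-site merging


def merge_ions_to_cutsites(
    ions: pd.DataFrame, sample_cols: Sequence[str]
) -> pd.DataFrame:
    """Sum ion intensities per (protein, cut-site) and per sample.

    ``ions`` must already carry ``site_id``/``site_origin``/``site_position``
    columns (see :func:`lipdiff.peptide_map.map_ions_to_sites`).  A sample
    with no observed ion for a site stays missing (NaN); partial sums use
    the observed ions only.
    """
    sample_cols = list(sample_cols)
    if ions.empty:
        empty = pd.DataFrame(
            columns=["protein_id", "site_id", "site_origin", "site_position",
                     "n_ions", "imputed", *sample_cols]
        )
        return empty
    grouped = ions.groupby(["protein_id", "site_id"], sort=True)
    sums = grouped[sample_cols].sum(min_count=1)
    meta = grouped.agg(
        site_origin=("site_origin", "first"),
        site_position=("site_position", "first"),
        n_ions=("ion_key", "nunique") if "ion_key" in ions.columns else ("site_id", "size"),
        imputed=("imputed", "any") if "imputed" in ions.columns else ("site_id", lambda s: False),
    )
    out = pd.concat([meta, sums], axis=1).reset_index()
    return out


# ---------------------------------------------------------------------------
# Welch's t-test (vectorized, NaN-aware)


def welch_test_matrix(
    a: np.ndarray, b: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Row-wise Welch's unequal-variance two-sided t-test.

    ``a`` and ``b`` are (n_rows, n_replicates) arrays; NaN entries are
    treated as missing.  Rows need >= 2 observed values per group; rows
    that fail this yield NaN statistics.  Degenerate rows where both
    groups are constant give p = 1 when the means agree (no evidence of
    change) and p = 0 otherwise.

    Returns ``(t, df, p)`` arrays.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n1 = np.sum(np.isfinite(a), axis=1).astype(float)
    n2 = np.sum(np.isfinite(b), axis=1).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        m1 = np.nanmean(np.where(np.isfinite(a), a, np.nan), axis=1)
        m2 = np.nanmean(np.where(np.isfinite(b), b, np.nan), axis=1)
        v1 = _nanvar_ddof1(a, n1, m1)
        v2 = _nanvar_ddof1(b, n2, m2)
        se2 = v1 / n1 + v2 / n2
        t = (m1 - m2) / np.sqrt(se2)
        df = se2**2 / (
            (v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1)
        )
        p = 2.0 * stats.t.sf(np.abs(t), df)
    usable = (n1 >= 2) & (n2 >= 2)
    degenerate = usable & (se2 == 0)
    equal_means = degenerate & (m1 == m2)
    t = np.where(equal_means, 0.0, t)
    t = np.where(degenerate & ~equal_means, np.where(m1 > m2, np.inf, -np.inf), t)
    df = np.where(degenerate, n1 + n2 - 2.0, df)
    p = np.where(equal_means, 1.0, p)
    p = np.where(degenerate & ~equal_means, 0.0, p)
    t = np.where(usable, t, np.nan)
    df = np.where(usable, df, np.nan)
    p = np.where(usable, p, np.nan)
    return t, df, p


def _nanvar_ddof1(x: np.ndarray, n: np.ndarray, mean: np.ndarray) -> np.ndarray:
    dev = np.where(np.isfinite(x), x - mean[:, None], 0.0)
    ss = np.sum(dev * dev, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        return ss / (n - 1)


def welch_test(a: Iterable[float], b: Iterable[float]) -> tuple[float, float, float]:
    """Welch's t-test for two groups of log2 intensities.

    Returns ``(t, df, p)``.  Raises :class:`DesignError` for groups with
    fewer than two finite values; two constant, equal groups give p = 1 by
    convention.
    """
    a_arr = np.asarray(list(a), dtype=float)
    b_arr = np.asarray(list(b), dtype=float)
    if np.sum(np.isfinite(a_arr)) < 2 or np.sum(np.isfinite(b_arr)) < 2:
        raise DesignError("welch_test requires >= 2 finite values per group")
    t, df, p = welch_test_matrix(a_arr[None, :], b_arr[None, :])
    return float(t[0]), float(df[0]), float(p[0])


# ---------------------------------------------------------------------------
# Benjamini-Hochberg


def bh_adjust(pvalues: Iterable[float]) -> np.ndarray:
    """Standard Benjamini-Hochberg step-up adjustment with monotonicity
    enforcement.  Input order is preserved."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(n, dtype=float)
    out[order] = adj
    return out


def bh_adjust_grouped(pvalues: pd.Series, groups: pd.Series) -> pd.Series:
    """BH adjustment applied independently within each group (the
    "protein-wise" FDR: each protein's cut-sites form one family)."""
    out = pd.Series(np.nan, index=pvalues.index, dtype=float)
    for _, idx in pvalues.groupby(groups, sort=False).indices.items():
        take = pvalues.index[idx]
        out.loc[take] = bh_adjust(pvalues.loc[take].to_numpy())
    return out


# ---------------------------------------------------------------------------
# protein abundance from trypsin-only controls


def protein_abundance_lfq(
    control_ions: pd.DataFrame,
    design: StudyDesign,
    proteome: Iterable[ProteinSeq],
    cfg: ThresholdConfig,
) -> pd.DataFrame:
    """Protein-level abundance differential from trypsin-only controls.

    Per-protein, per-sample abundance is the sum of fully tryptic ion
    intensities (a label-free summary with the property that a uniform
    abundance shift moves every peptide of the protein equally).  log2 fold
    change and Welch p are computed across replicates, BH-adjusted across
    proteins; a significant change means |log2fc| >= 1 and adjusted
    p < 0.05.  Proteins with fewer than ``min_observed_per_group`` observed
    replicates in either group are absent from the output (their sites are
    flagged unnormalized downstream).
    """
    test_cols = design.samples_for(design.test_condition, TREATMENT_CONTROL)
    ref_cols = design.samples_for(design.reference_condition, TREATMENT_CONTROL)
    result = pd.DataFrame(columns=ABUNDANCE_COLUMNS)
    if control_ions.empty or not test_cols or not ref_cols:
        return result
    annotated = map_ions_to_sites(control_ions, proteome)
    full = annotated[annotated["trypticity"] == Trypticity.FULL.value]
    if full.empty:
        return result
    sums = full.groupby("protein_id", sort=True)[test_cols + ref_cols].sum(min_count=1)
    m = cfg.min_observed_per_group
    obs_t = sums[test_cols].notna().sum(axis=1)
    obs_r = sums[ref_cols].notna().sum(axis=1)
    sums = sums[(obs_t >= max(m, 2)) & (obs_r >= max(m, 2))]
    if sums.empty:
        return result
    log_t = np.log2(sums[test_cols].to_numpy(dtype=float))
    log_r = np.log2(sums[ref_cols].to_numpy(dtype=float))
    t, df, p = welch_test_matrix(log_t, log_r)
    log2fc = np.nanmean(log_t, axis=1) - np.nanmean(log_r, axis=1)
    out = pd.DataFrame(
        {
            "protein_id": sums.index,
            "log2fc": log2fc,
            "t_stat": t,
            "df": df,
            "p_raw": p,
        }
    )
    out = out[np.isfinite(out["p_raw"])].reset_index(drop=True)
    out["p_adj"] = bh_adjust(out["p_raw"].to_numpy()) if len(out) else []
    out["significant_change"] = (np.abs(out["log2fc"]) >= 1.0) & (out["p_adj"] < 0.05)
    return out[ABUNDANCE_COLUMNS]


def normalize_to_abundance(
    cutsites: pd.DataFrame, abundance: pd.DataFrame
) -> pd.DataFrame:
    """Subtract the protein-level log2 abundance ratio from each site's raw
    log2 fold change.  Sites of proteins absent from the abundance table
    keep their raw value and are flagged ``normalized=False``."""
    out = cutsites.copy()
    if abundance.empty:
        out["log2fc_norm"] = out["log2fc_raw"]
        out["normalized"] = False
        return out
    ab = abundance.set_index("protein_id")["log2fc"]
    shift = out["protein_id"].map(ab)
    out["normalized"] = shift.notna()
    out["log2fc_norm"] = out["log2fc_raw"] - shift.fillna(0.0)
    return out


def apply_significance(cutsites: pd.DataFrame, cfg: ThresholdConfig) -> pd.DataFrame:
    """(Re-)derive the per-site significance flag from fold change and
    adjusted p: |log2fc_norm| >= log2(fold_change_min) and p_adj < alpha
    (strict, per the '< 0.05' criterion)."""
    out = cutsites.copy()
    out["significant"] = (
        (np.abs(out["log2fc_norm"]) >= cfg.log2_fold_change_min)
        & (out["p_adj"] < cfg.alpha)
    ).fillna(False).astype(bool)
    return out


@dataclass
class DifferentialResult:
    """Bundle of the per-site table, the protein abundance table and the
    imputation floor used."""

    cutsites: pd.DataFrame
    abundance: pd.DataFrame
    floor: float | None = None


def run_differential(
    lip_ions: pd.DataFrame,
    control_ions: pd.DataFrame,
    design: StudyDesign,
    proteome: Iterable[ProteinSeq],
    cfg: ThresholdConfig | None = None,
    normalize: bool = True,
) -> DifferentialResult:
    """Full per-site differential pipeline.

    impute -> assign ions to cut-sites -> merge -> Welch on log2 merged
    intensities -> normalize to protein abundance -> protein-wise BH ->
    significance flags.  Deterministic given inputs.

    ``normalize=False`` skips protein-abundance normalization (used for
    in vitro refolding comparisons, where no abundance rebalancing between
    conditions is expected).
    """
    cfg = cfg or ThresholdConfig()
    design.validate_comparison(min_replicates=2, treatment=TREATMENT_LIP)
    proteome = list(proteome) if not isinstance(proteome, dict) else proteome
    test_cols = design.samples_for(design.test_condition, TREATMENT_LIP)
    ref_cols = design.samples_for(design.reference_condition, TREATMENT_LIP)
    empty = pd.DataFrame(columns=CUTSITE_COLUMNS)
    if lip_ions.empty:
        return DifferentialResult(empty, pd.DataFrame(columns=ABUNDANCE_COLUMNS))

    missing = [c for c in test_cols + ref_cols if c not in lip_ions.columns]
    if missing:
        raise DesignError(f"ion table lacks sample columns {missing}")
    if "ion_key" not in lip_ions.columns:
        lip_ions = lip_ions.copy()
        lip_ions["ion_key"] = (
            lip_ions["peptide"].astype(str)
            + "/" + lip_ions["charge"].astype(str)
            + "/" + lip_ions["mod_key"].astype(str)
        )

    floor = imputation_floor(lip_ions, test_cols + ref_cols, cfg.imputation_quantile)
    imputed = impute_missing(lip_ions, test_cols, ref_cols, cfg, floor=floor)
    if imputed.empty:
        return DifferentialResult(empty, pd.DataFrame(columns=ABUNDANCE_COLUMNS), floor)
    annotated = map_ions_to_sites(imputed, proteome)
    merged = merge_ions_to_cutsites(annotated, test_cols + ref_cols)

    log_t = np.log2(merged[test_cols].to_numpy(dtype=float))
    log_r = np.log2(merged[ref_cols].to_numpy(dtype=float))
    n_t = np.sum(np.isfinite(log_t), axis=1)
    n_r = np.sum(np.isfinite(log_r), axis=1)
    usable = (n_t >= 2) & (n_r >= 2)
    merged = merged.loc[usable].reset_index(drop=True)
    log_t, log_r = log_t[usable], log_r[usable]
    if merged.empty:
        return DifferentialResult(empty, pd.DataFrame(columns=ABUNDANCE_COLUMNS), floor)

    t, df, p = welch_test_matrix(log_t, log_r)
    merged["log2fc_raw"] = np.nanmean(log_t, axis=1) - np.nanmean(log_r, axis=1)
    merged["t_stat"] = t
    merged["df"] = df
    merged["p_raw"] = p

    if normalize:
        abundance = protein_abundance_lfq(control_ions, design, proteome, cfg)
    else:
        abundance = pd.DataFrame(columns=ABUNDANCE_COLUMNS)
    merged = normalize_to_abundance(merged, abundance)
    if not normalize:
        # raw value is the final value by construction; do not flag
        merged["normalized"] = True

    if cfg.bh_scope == "protein":
        merged["p_adj"] = bh_adjust_grouped(merged["p_raw"], merged["protein_id"])
    else:
        merged["p_adj"] = bh_adjust(merged["p_raw"].to_numpy())
    merged = apply_significance(merged, cfg)
    return DifferentialResult(merged[CUTSITE_COLUMNS], abundance, floor)
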