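"""Per-protein categorical calls from per-site statistics.

A protein is *perturbed* under a comparison when two or more of its
cut-sites changed significantly, *unperturbed* when it has enough
quantified sites but fewer than two significant ones, and *excluded*
when too few sites were quantified to assess it at all.  The same logic,
with the labels refolder/nonrefolder, classifies in vitro refolding
experiments (refolded vs. native at a given time point); significance of
a site is decided entirely upstream and never re-tested here.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import pandas as pd

from .differential import ThresholdConfig

__all__ = [
    "STATUS_PERTURBED",
    "STATUS_UNPERTURBED",
    "STATUS_EXCLUDED",
    "CONTEXT_IN_VIVO",
    "CONTEXT_REFOLDING",
    "ProteinCall",
    "CallSummary",
    "call_protein",
    "call_proteome",
    "summarize_calls",
    "calls_to_status_map",
]

STATUS_PERTURBED = "perturbed"
STATUS_UNPERTURBED = "unperturbed"
STATUS_EXCLUDED = "excluded"

CONTEXT_IN_VIVO = "in_vivo_perturbation"
CONTEXT_REFOLDING = "refolding"

CALL_COLUMNS = [
    "protein_id",
    "context",
    "status",
    "n_quantified_sites",
    "n_significant_sites",
]


@dataclass(frozen=True)
class ProteinCall:
    protein_id: str
    status: str
    n_quantified_sites: int
    n_significant_sites: int
    context: str = CONTEXT_IN_VIVO


def _status(n_quantified: int, n_significant: int, cfg: ThresholdConfig) -> str:
    if n_quantified < cfg.min_quantified_sites:
        return STATUS_EXCLUDED
    if n_significant >= cfg.min_significant_sites:
        return STATUS_PERTURBED
    return STATUS_UNPERTURBED


def call_protein(
    sites: pd.DataFrame,
    cfg: ThresholdConfig | None = None,
    context: str = CONTEXT_IN_VIVO,
) -> ProteinCall:
    """Call one protein from its cut-site results.

    ``sites`` is the per-site table restricted to one protein (it may be
    empty, which yields an excluded call with zero counts).
    """
    cfg = cfg or ThresholdConfig()
    if sites.empty:
        return ProteinCall("", STATUS_EXCLUDED, 0, 0, context)
    ids = sites["protein_id"].unique()
    if len(ids) != 1:
        raise ValueError(f"call_protein got sites for several proteins: {ids}")
    n_q = int(len(sites))
    n_s = int(sites["significant"].sum())
    return ProteinCall(str(ids[0]), _status(n_q, n_s, cfg), n_q, n_s, context)


@dataclass(frozen=True)
class CallSummary:
    """Counts of call outcomes and the headline percentage perturbed among
    confidently assessed (non-excluded) proteins."""

    n_perturbed: int
    n_unperturbed: int
    n_excluded: int

    @property
    def n_assessed(self) -> int:
        return self.n_perturbed + self.n_unperturbed

    @property
    def percent_perturbed(self) -> float | None:
        if self.n_assessed == 0:
            return None
        return 100.0 * self.n_perturbed / self.n_assessed

    @property
    def percent_unperturbed(self) -> float | None:
        if self.n_assessed == 0:
            return None
        return 100.0 * self.n_unperturbed / self.n_assessed


def call_proteome(
    cutsites: pd.DataFrame,
    cfg: ThresholdConfig | None = None,
    context: str = CONTEXT_IN_VIVO,
) -> tuple[pd.DataFrame, CallSummary]:
    """Call every protein present in a cut-site result table.

    Returns the per-protein call table (stable column order, sorted by
    protein id) and a :class:`CallSummary`.
    """
    cfg = cfg or ThresholdConfig()
    if cutsites.empty:
        calls = pd.DataFrame(columns=CALL_COLUMNS)
        return calls, CallSummary(0, 0, 0)
    grouped = cutsites.groupby("protein_id", sort=True)
    calls = grouped.agg(
        n_quantified_sites=("site_id", "size"),
        n_significant_sites=("significant", "sum"),
    ).reset_index()
    calls["n_significant_sites"] = calls["n_significant_sites"].astype(int)
    calls["status"] = [
        _status(q, s, cfg)
        for q, s in zip(calls["n_quantified_sites"], calls["n_significant_sites"])
    ]
    calls["context"] = context
    calls = calls[CALL_COLUMNS]
    return calls, summarize_calls(calls)


def summarize_calls(calls: pd.DataFrame) -> CallSummary:
    counts = calls["status"].value_counts() if len(calls) else {}
    return CallSummary(
        n_perturbed=int(counts.get(STATUS_PERTURBED, 0)),
        n_unperturbed=int(counts.get(STATUS_UNPERTURBED, 0)),
        n_excluded=int(counts.get(STATUS_EXCLUDED, 0)),
    )


def calls_to_status_map(calls: pd.DataFrame) -> Mapping[str, str]:
    """protein_id -> status mapping used by the comparative module."""
    return dict(zip(calls["protein_id"], calls["status"]))
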