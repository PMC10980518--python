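"""Screening gates for DEGs/DMs and Venn partitioning of the three contrasts.

Transcripts pass at FDR <= 0.05 and |log2FC| >= 1; metabolites pass at
VIP >= 1 with fold change >= 2 (up) or <= 0.5 (down), FC derived from the
stored log2FC as 2**log2fc.  Features significant in all three contrasts
(the triple-intersection Venn region) are the "common" set eligible for
mode classification; features significant only under the combined stress
are the SWL-unique set whose log2FC dispersion motivates the sigma = 0.50
tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable

import numpy as np

from stressmodes.tables_io import ContrastTable


@dataclass(frozen=True)
class SignificanceCriteria:
    """Screening gates for differential features.

    fdr_max : FDR ceiling for transcripts (default 0.05).
    min_abs_log2fc : magnitude floor on transcript log2FC (default 1.0;
        the screen's exact printed value is not fixed upstream, so it is
        configurable).
    fc_up / fc_down : fold-change gates for metabolites (defaults 2.0 / 0.5).
    vip_min : OPLS-DA VIP floor for metabolites (default 1.0).
    """

    fdr_max: float = 0.05
    min_abs_log2fc: float = 1.0
    fc_up: float = 2.0
    fc_down: float = 0.5
    vip_min: float = 1.0

    def __post_init__(self) -> None:
        if not 0 < self.fdr_max <= 1:
            raise ValueError("fdr_max must lie in (0, 1]")
        if self.min_abs_log2fc < 0:
            raise ValueError("min_abs_log2fc must be >= 0")
        if self.fc_up <= 1:
            raise ValueError("fc_up must exceed 1")
        if not 0 < self.fc_down < 1:
            raise ValueError("fc_down must lie in (0, 1)")
        if self.vip_min < 0:
            raise ValueError("vip_min must be >= 0")


@dataclass
class RegulatedSet:
    """Features passing the gates for one contrast, with up/down status."""

    contrast_label: str
    members: Dict[str, str]  # feature_id -> "up" | "down"

    @property
    def ids(self) -> set[str]:
        return set(self.members)

    def __len__(self) -> int:
        return len(self.members)


Signature = FrozenSet[str]

REGION_SIGNATURES: tuple[Signature, ...] = (
    frozenset({"ST"}),
    frozenset({"WL"}),
    frozenset({"SWL"}),
    frozenset({"ST", "WL"}),
    frozenset({"ST", "SWL"}),
    frozenset({"WL", "SWL"}),
    frozenset({"ST", "WL", "SWL"}),
)


@dataclass
class VennPartition:
    """The seven disjoint membership regions of the three regulated sets."""

    regions: Dict[Signature, set[str]] = field(default_factory=dict)

    @property
    def common(self) -> set[str]:
        """Features significant in all three contrasts."""
        return self.regions[frozenset({"ST", "WL", "SWL"})]

    def unique(self, label: str) -> set[str]:
        """Features significant only under ``label``."""
        return self.regions[frozenset({label})]

    def counts(self) -> Dict[str, int]:
        return {
            "+".join(sorted(sig)): len(ids) for sig, ids in self.regions.items()
        }


def select_deg(table: ContrastTable, criteria: SignificanceCriteria | None = None) -> RegulatedSet:
    """Screen transcripts: FDR <= fdr_max and |log2FC| >= min_abs_log2fc."""
    criteria = criteria or SignificanceCriteria()
    if table.feature_kind != "transcript":
        raise ValueError("select_deg expects a transcript table")
    if "fdr" not in table.data.columns:
        raise ValueError("no fdr column; run adjust_pvalues first")
    fdr = table.data["fdr"].to_numpy(dtype=float)
    lfc = table.data["log2fc"].to_numpy(dtype=float)
    keep = (fdr <= criteria.fdr_max) & (np.abs(lfc) >= criteria.min_abs_log2fc)
    members = {
        fid: ("up" if f > 0 else "down")
        for fid, f, k in zip(table.data.index, lfc, keep)
        if k
    }
    return RegulatedSet(table.contrast_label, members)


def select_dm(table: ContrastTable, criteria: SignificanceCriteria | None = None) -> RegulatedSet:
    """Screen metabolites: VIP >= vip_min and FC >= fc_up or FC <= fc_down."""
    criteria = criteria or SignificanceCriteria()
    if table.feature_kind != "metabolite":
        raise ValueError("select_dm expects a metabolite table")
    if "vip" not in table.data.columns:
        raise ValueError("no vip column in metabolite table")
    vip = table.data["vip"].to_numpy(dtype=float)
    lfc = table.data["log2fc"].to_numpy(dtype=float)
    fc = np.exp2(lfc)
    keep = (vip >= criteria.vip_min) & ((fc >= criteria.fc_up) | (fc <= criteria.fc_down))
    members = {
        fid: ("up" if f >= criteria.fc_up else "down")
        for fid, f, k in zip(table.data.index, fc, keep)
        if k
    }
    return RegulatedSet(table.contrast_label, members)


def venn_partition(st: RegulatedSet, wl: RegulatedSet, swl: RegulatedSet) -> VennPartition:
    """Split the three significant-feature sets into their 7 disjoint regions."""
    by_label = {"ST": st.ids, "WL": wl.ids, "SWL": swl.ids}
    regions: Dict[Signature, set[str]] = {sig: set() for sig in REGION_SIGNATURES}
    for fid in by_label["ST"] | by_label["WL"] | by_label["SWL"]:
        sig = frozenset(lbl for lbl, ids in by_label.items() if fid in ids)
        regions[sig].add(fid)
    return VennPartition(regions)


def estimate_sigma(swl_unique_log2fc: Iterable[float]) -> float:
    """Sample standard deviation of SWL-unique log2FC values.

    A data-driven alternative to the fixed default tolerance sigma = 0.50;
    the classifier default remains 0.50 regardless.
    """
    values = np.asarray(list(swl_unique_log2fc), dtype=float)
    if values.size < 2:
        raise ValueError("need at least 2 values to estimate a standard deviation")
    if not np.isfinite(values).all():
        raise ValueError("log2fc values must be finite")
    return float(np.std(values, ddof=1))
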