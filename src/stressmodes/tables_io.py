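"""Read, validate and write the delimited differential tables.

A contrast table holds one stress-vs-control comparison (ST, WL or SWL) with
one row per feature: log2 fold change, a p-value and/or BH-adjusted FDR, an
optional OPLS-DA VIP score and free-text annotation.  Everything downstream
(screening, Venn partitioning, mode classification) consumes these tables.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

CONTRAST_LABELS = ("ST", "WL", "SWL")
FEATURE_KINDS = ("transcript", "metabolite")

#: default mapping from logical column role -> header name in the file
DEFAULT_COLUMNS: Mapping[str, str] = {
    "id": "id",
    "log2fc": "log2fc",
    "pvalue": "pvalue",
    "fdr": "fdr",
    "vip": "vip",
    "annotation": "annotation",
}


class TableFormatError(ValueError):
    """Raised when a differential table violates its contract."""


@dataclass
class ContrastTable:
    """One stress-vs-control differential table.

    Parameters
    ----------
    contrast_label : str
        One of ``"ST"``, ``"WL"``, ``"SWL"``.
    feature_kind : str
        ``"transcript"`` or ``"metabolite"``.
    data : pandas.DataFrame
        Indexed by feature id; columns ``log2fc`` plus any of ``pvalue``,
        ``fdr``, ``vip``, ``annotation``.
    """

    contrast_label: str
    feature_kind: str
    data: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        if self.contrast_label not in CONTRAST_LABELS:
            raise TableFormatError(
                f"contrast_label must be one of {CONTRAST_LABELS}, "
                f"got {self.contrast_label!r}"
            )
        if self.feature_kind not in FEATURE_KINDS:
            raise TableFormatError(
                f"feature_kind must be one of {FEATURE_KINDS}, "
                f"got {self.feature_kind!r}"
            )
        if "log2fc" not in self.data.columns:
            raise TableFormatError("table is missing the log2fc column")
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise TableFormatError(f"duplicate feature ids: {dups}")
        # metabolite screening may rest on FC and VIP alone
        if (
            self.feature_kind == "transcript"
            and "pvalue" not in self.data.columns
            and "fdr" not in self.data.columns
        ):
            raise TableFormatError("transcript table needs a pvalue or fdr column")
        if not np.isfinite(self.data["log2fc"].to_numpy(dtype=float)).all():
            raise TableFormatError("log2fc contains non-finite values")
        if "vip" in self.data.columns:
            vip = self.data["vip"].to_numpy(dtype=float)
            if np.any(vip[~np.isnan(vip)] < 0):
                raise TableFormatError("vip values must be non-negative")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    def log2fc(self, feature_id: str) -> float:
        return float(self.data.at[feature_id, "log2fc"])


def _delimiter_for(path: Path, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_contrast_table(
    path: str | Path,
    contrast_label: str,
    feature_kind: str,
    columns: Mapping[str, str] | None = None,
    delimiter: str | None = None,
) -> ContrastTable:
    """Read a delimited differential table into a validated :class:`ContrastTable`.

    The delimiter is inferred from the extension (``.csv`` -> comma, anything
    else -> tab) unless given explicitly.  ``columns`` maps logical roles
    (``id``, ``log2fc``, ``pvalue``, ``fdr``, ``vip``, ``annotation``) to the
    header names actually present.  Rows with a non-finite or unparseable
    log2fc are dropped with a warning, mirroring upstream filtering of
    unquantified features; a duplicated feature id is an error because silent
    aggregation would corrupt Venn membership.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such table: {path}")
    colmap = dict(DEFAULT_COLUMNS)
    if columns:
        colmap.update(columns)

    raw = pd.read_csv(path, sep=_delimiter_for(path, delimiter), dtype=str)
    for role in ("id", "log2fc"):
        if colmap[role] not in raw.columns:
            raise TableFormatError(
                f"{path}: missing mandatory column {colmap[role]!r} (role {role!r})"
            )

    out = pd.DataFrame(index=raw[colmap["id"]].astype(str).rename("feature_id"))
    numeric_roles = ["log2fc", "pvalue", "fdr", "vip"]
    for role in numeric_roles:
        name = colmap[role]
        if name in raw.columns:
            try:
                out[role] = pd.to_numeric(raw[name].values, errors="raise")
            except (ValueError, TypeError):
                if role == "log2fc":
                    # NA/unparseable effect sizes mark unquantified features
                    out[role] = pd.to_numeric(raw[name].values, errors="coerce")
                else:
                    raise TableFormatError(
                        f"{path}: unparseable numeric cell in column {name!r}"
                    )
    if colmap["annotation"] in raw.columns:
        out["annotation"] = raw[colmap["annotation"]].values

    bad = ~np.isfinite(out["log2fc"].to_numpy(dtype=float))
    if bad.any():
        dropped = out.index[bad].tolist()
        logger.warning(
            "%s: dropping %d row(s) with non-finite log2fc: %s",
            path, int(bad.sum()), dropped,
        )
        warnings.warn(
            f"{path}: dropped {int(bad.sum())} row(s) with non-finite log2fc",
            UserWarning,
            stacklevel=2,
        )
        out = out.loc[~bad]

    if out.index.has_duplicates:
        dups = out.index[out.index.duplicated()].unique().tolist()
        raise TableFormatError(f"{path}: duplicate feature ids: {dups}")

    pvals = [v for v in out.columns if v in ("pvalue", "fdr")]
    if not pvals and feature_kind == "transcript":
        raise TableFormatError(f"{path}: neither pvalue nor fdr column present")
    for role in pvals:
        vals = out[role].to_numpy(dtype=float)
        finite = vals[~np.isnan(vals)]
        if np.any((finite < 0) | (finite > 1)):
            raise TableFormatError(f"{path}: {role} outside [0, 1]")

    return ContrastTable(contrast_label, feature_kind, out)


def adjust_pvalues(table: ContrastTable) -> ContrastTable:
    """Fill the ``fdr`` column by Benjamini–Hochberg step-up over all rows.

    Requires a complete ``pvalue`` column and no pre-existing ``fdr``; the
    FDR column, once present, is what the screening gate reads (the raw
    p-values are kept but ignored downstream).
    """
    if "fdr" in table.data.columns:
        raise TableFormatError("table already carries an fdr column")
    if "pvalue" not in table.data.columns:
        raise TableFormatError("no pvalue column to adjust")
    p = table.data["pvalue"].to_numpy(dtype=float)
    if np.any(np.isnan(p)) or np.any((p < 0) | (p > 1)):
        raise TableFormatError("pvalues must all lie in [0, 1]")
    _, fdr, _, _ = multipletests(p, method="fdr_bh")
    data = table.data.copy()
    data["fdr"] = fdr
    return ContrastTable(table.contrast_label, table.feature_kind, data)


ASSIGNMENT_COLUMNS = (
    "feature_id",
    "mode",
    "f_st",
    "f_wl",
    "f_swl",
    "additive_expectation",
    "d_st",
    "d_wl",
    "d_sum",
    "rule_path",
)


def write_assignments(
    assignments: Iterable,
    path: str | Path,
    delimiter: str | None = None,
) -> None:
    """Write mode assignments as a delimited table (numbers to 6 sig. digits)."""
    path = Path(path)
    rows = [
        {
            "feature_id": a.feature_id,
            "mode": a.mode,
            "f_st": a.f_st,
            "f_wl": a.f_wl,
            "f_swl": a.f_swl,
            "additive_expectation": a.additive_expectation,
            "d_st": a.d_st,
            "d_wl": a.d_wl,
            "d_sum": a.d_sum,
            "rule_path": a.rule_path,
        }
        for a in assignments
    ]
    df = pd.DataFrame(rows, columns=ASSIGNMENT_COLUMNS)
    df.to_csv(path, sep=_delimiter_for(path, delimiter), index=False,
              float_format="%.6g")


def read_assignments(path: str | Path, delimiter: str | None = None) -> pd.DataFrame:
    """Read back a table written by :func:`write_assignments`."""
    path = Path(path)
    df = pd.read_csv(path, sep=_delimiter_for(path, delimiter))
    missing = set(ASSIGNMENT_COLUMNS) - set(df.columns)
    if missing:
        raise TableFormatError(f"{path}: missing assignment columns {sorted(missing)}")
    return df


def write_assignments_json(assignments: Sequence, path: str | Path) -> None:
    """Export assignments plus per-mode counts as a JSON summary document."""
    counts: dict[str, int] = {}
    for a in assignments:
        counts[a.mode] = counts.get(a.mode, 0) + 1
    doc = {
        "n_features": len(assignments),
        "mode_counts": counts,
        "assignments": [
            {
                "feature_id": a.feature_id,
                "mode": a.mode,
                "f_st": a.f_st,
                "f_wl": a.f_wl,
                "f_swl": a.f_swl,
                "additive_expectation": a.additive_expectation,
                "rule_path": a.rule_path,
            }
            for a in assignments
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=2))
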