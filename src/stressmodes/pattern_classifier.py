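"""Assign commonly regulated features to combined-stress pattern modes.

Each feature significant under ST, WL and SWL carries a log2FC triple
(f_st, f_wl, f_swl).  Writing S = f_st + f_wl for the additive expectation
and sigma for the tolerance band (default 0.50), the triple is classified
by a fixed-precedence decision tree:

1. both single-stress signs opposite the SWL sign  -> antagonistic
2. exactly one single-stress sign opposite         -> unilateral
3. all three same sign:
   a. |f_st - f_swl| <= sigma and |f_wl - f_swl| <= sigma -> neutral
   b. exactly one of the two differences <= sigma         -> dominant
   c. otherwise:
      i.   |f_swl| - |S| > sigma                  -> synergistic (amplified)
      ii.  ||f_swl| - |S|| <= sigma               -> additive
      iii. |f_swl| < max(|f_st|, |f_wl|) - sigma  -> minor
      iv.  otherwise                              -> non_assigned

The sub-additive gap (iv) holds triples whose combined response falls short
of the additive expectation by more than sigma without dropping below both
single-stress magnitudes.  A triple with any zero component signals a
feature that should not have passed screening and routes to non_assigned.
All comparisons are symmetric in the two single stresses and invariant to
flipping the sign of the whole triple.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

from stressmodes.tables_io import ContrastTable

MODES = (
    "synergistic",
    "additive",
    "dominant",
    "neutral",
    "minor",
    "unilateral",
    "antagonistic",
)
NON_ASSIGNED = "non_assigned"
ALL_LABELS = MODES + (NON_ASSIGNED,)


@dataclass(frozen=True)
class ClassifierConfig:
    """Tolerance band on the log2FC scale; the study default is 0.50."""

    sigma: float = 0.50

    def __post_init__(self) -> None:
        if not (self.sigma > 0 and math.isfinite(self.sigma)):
            raise ValueError("sigma must be a positive finite number")


@dataclass(frozen=True)
class TripleProfile:
    """Aligned log2FC values of one feature across the three contrasts."""

    feature_id: str
    f_st: float
    f_wl: float
    f_swl: float

    def __post_init__(self) -> None:
        for name in ("f_st", "f_wl", "f_swl"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite for {self.feature_id!r}")


@dataclass(frozen=True)
class ModeAssignment:
    """A feature's pattern mode plus recomputable diagnostics.

    ``additive_expectation`` is S = f_st + f_wl; ``d_st``/``d_wl`` are the
    absolute offsets of each single-stress log2FC from the SWL log2FC;
    ``d_sum`` is the signed amplification |f_swl| - |S|; ``rule_path``
    records the decision branch taken.
    """

    feature_id: str
    mode: str
    f_st: float
    f_wl: float
    f_swl: float
    additive_expectation: float
    d_st: float
    d_wl: float
    d_sum: float
    rule_path: str


def classify_feature(profile: TripleProfile, config: ClassifierConfig | None = None) -> ModeAssignment:
    """Classify one log2FC triple into a pattern mode.

    Deterministic and total: every finite triple maps to exactly one of the
    seven modes or non_assigned, following the precedence documented in the
    module docstring.
    """
    config = config or ClassifierConfig()
    sigma = config.sigma
    f_st, f_wl, f_swl = profile.f_st, profile.f_wl, profile.f_swl

    s_total = f_st + f_wl
    d_st = abs(f_st - f_swl)
    d_wl = abs(f_wl - f_swl)
    d_sum = abs(f_swl) - abs(s_total)

    def make(mode: str, rule_path: str) -> ModeAssignment:
        return ModeAssignment(
            feature_id=profile.feature_id,
            mode=mode,
            f_st=f_st,
            f_wl=f_wl,
            f_swl=f_swl,
            additive_expectation=s_total,
            d_st=d_st,
            d_wl=d_wl,
            d_sum=d_sum,
            rule_path=rule_path,
        )

    if f_st == 0 or f_wl == 0 or f_swl == 0:
        return make(NON_ASSIGNED, "zero-sign")

    st_opposite = (f_st > 0) != (f_swl > 0)
    wl_opposite = (f_wl > 0) != (f_swl > 0)
    if st_opposite and wl_opposite:
        return make("antagonistic", "sign:both-opposite")
    if st_opposite or wl_opposite:
        return make("unilateral", "sign:one-opposite")

    st_within = d_st <= sigma
    wl_within = d_wl <= sigma
    if st_within and wl_within:
        return make("neutral", "band:both-within")
    if st_within or wl_within:
        which = "st" if st_within else "wl"
        return make("dominant", f"band:{which}-within")

    if d_sum > sigma:
        return make("synergistic", "sum:amplified")
    if abs(d_sum) <= sigma:
        return make("additive", "sum:within")
    if abs(f_swl) < max(abs(f_st), abs(f_wl)) - sigma:
        return make("minor", "magnitude:below-single")
    return make(NON_ASSIGNED, "gap:sub-additive")


def classify_all(
    profiles: Iterable[TripleProfile],
    config: ClassifierConfig | None = None,
) -> list[ModeAssignment]:
    """Classify a collection of profiles; order-preserving and deterministic."""
    config = config or ClassifierConfig()
    seen: set[str] = set()
    out: list[ModeAssignment] = []
    for profile in profiles:
        if profile.feature_id in seen:
            raise ValueError(f"duplicate feature id {profile.feature_id!r}")
        seen.add(profile.feature_id)
        out.append(classify_feature(profile, config))
    return out


def build_triples(
    st: ContrastTable,
    wl: ContrastTable,
    swl: ContrastTable,
    common_ids: Iterable[str],
) -> list[TripleProfile]:
    """Assemble log2FC triples for the common features, in sorted id order."""
    ids: Sequence[str] = sorted(set(common_ids))
    profiles = []
    for fid in ids:
        for label, table in (("ST", st), ("WL", wl), ("SWL", swl)):
            if fid not in table.data.index:
                raise KeyError(f"feature {fid!r} missing from the {label} table")
        profiles.append(
            TripleProfile(fid, st.log2fc(fid), wl.log2fc(fid), swl.log2fc(fid))
        )
    return profiles
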