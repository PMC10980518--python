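"""Planted-truth simulator for the combined-stress pipeline.

Generates three aligned differential tables (ST, WL, SWL vs control) whose
features fall into three strata:

* common responders — significant in all three contrasts, with log2FC
  triples drawn by rejection sampling inside a requested pattern-mode
  region, keeping a clearance ``margin`` from every decision boundary at
  the classifier tolerance sigma, so the noiseless planted label is
  recovered with certainty;
* unique responders — significant in exactly one contrast;
* null features — sub-threshold everywhere.

FDR and VIP values are decorative draws consistent with the screening
gates (the pipeline begins downstream of differential testing), and the
whole dataset is reproducible from the seed.  The default per-contrast
unique-responder counts keep the combined stress far ahead of either
single stress, the asymmetry characteristic of combined-stress
transcriptomes, at desk scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, Mapping, NamedTuple

import numpy as np
import pandas as pd

from stressmodes.pattern_classifier import MODES, NON_ASSIGNED, ModeAssignment
from stressmodes.tables_io import ContrastTable

PLANTABLE_MODES = MODES + (NON_ASSIGNED,)
UNIQUE_LABELS = ("unique-ST", "unique-WL", "unique-SWL")
NULL_LABEL = "null"

_MAX_ATTEMPTS = 100_000


@dataclass(frozen=True)
class SimulationSpec:
    """Parameters of one simulated dataset.

    ``margin`` is the minimum clearance of each noiseless planted triple
    from every decision boundary of its mode at tolerance ``sigma``;
    ``effect_range`` bounds the log2FC magnitudes of significant features
    and must clear the default DEG magnitude gate.
    """

    n_per_mode: Mapping[str, int] = field(
        default_factory=lambda: {m: 10 for m in MODES}
    )
    n_unique: Mapping[str, int] = field(
        default_factory=lambda: {"ST": 27, "WL": 41, "SWL": 140}
    )
    n_null: int = 100
    sigma: float = 0.50
    margin: float = 0.30
    noise_sd: float = 0.0
    effect_range: tuple[float, float] = (1.2, 4.0)
    seed: int = 0
    feature_kind: str = "transcript"

    def __post_init__(self) -> None:
        if self.margin <= 0:
            raise ValueError("margin must be positive")
        if self.margin >= self.sigma:
            raise ValueError("margin must be smaller than sigma")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        lo, hi = self.effect_range
        if not 0 < lo < hi:
            raise ValueError("effect_range must be an increasing positive interval")
        if lo <= 1.0:
            raise ValueError(
                "effect_range lower bound must exceed the default DEG "
                "magnitude gate (1.0)"
            )
        unknown = set(self.n_per_mode) - set(PLANTABLE_MODES)
        if unknown:
            raise ValueError(f"unknown modes in n_per_mode: {sorted(unknown)}")
        if any(n < 0 for n in self.n_per_mode.values()):
            raise ValueError("mode counts must be non-negative")
        if set(self.n_unique) - {"ST", "WL", "SWL"}:
            raise ValueError("n_unique keys must be contrast labels")


@dataclass
class PlantedTruth:
    """feature_id -> planted mode, unique-<contrast>, or null."""

    labels: Dict[str, str]

    @property
    def common_ids(self) -> set[str]:
        return {f for f, lab in self.labels.items() if lab in PLANTABLE_MODES}

    def __len__(self) -> int:
        return len(self.labels)


class SimulatedDataset(NamedTuple):
    st: ContrastTable
    wl: ContrastTable
    swl: ContrastTable
    truth: PlantedTruth


# --- mode regions with margin -------------------------------------------
# Each predicate states the closed-form region a noiseless triple must
# occupy, with every inequality of the classifier's decision path for that
# mode strengthened by the margin delta.  Written as independent membership
# tests (no shared control flow with the classifier) so the generator also
# serves as an oracle of the mode geometry.

def _same_sign(x: float, y: float, z: float) -> bool:
    return (x > 0) == (z > 0) and (y > 0) == (z > 0)


def _r_antagonistic(x, y, z, s, d):
    return (x > 0) != (z > 0) and (y > 0) != (z > 0)


def _r_unilateral(x, y, z, s, d):
    return ((x > 0) != (z > 0)) != ((y > 0) != (z > 0))


def _r_neutral(x, y, z, s, d):
    return _same_sign(x, y, z) and abs(x - z) <= s - d and abs(y - z) <= s - d


def _r_dominant(x, y, z, s, d):
    if not _same_sign(x, y, z):
        return False
    near_st = abs(x - z) <= s - d and abs(y - z) >= s + d
    near_wl = abs(y - z) <= s - d and abs(x - z) >= s + d
    return near_st or near_wl


def _both_bands_clear(x, y, z, s, d):
    return abs(x - z) >= s + d and abs(y - z) >= s + d


def _r_synergistic(x, y, z, s, d):
    return (
        _same_sign(x, y, z)
        and _both_bands_clear(x, y, z, s, d)
        and abs(z) - abs(x + y) >= s + d
    )


def _r_additive(x, y, z, s, d):
    return (
        _same_sign(x, y, z)
        and _both_bands_clear(x, y, z, s, d)
        and abs(abs(z) - abs(x + y)) <= s - d
    )


def _r_minor(x, y, z, s, d):
    return (
        _same_sign(x, y, z)
        and _both_bands_clear(x, y, z, s, d)
        and abs(z) - abs(x + y) <= -(s + d)
        and abs(z) <= max(abs(x), abs(y)) - s - d
    )


def _r_non_assigned(x, y, z, s, d):
    # sub-additive gap: short of additivity yet not below both singles
    return (
        _same_sign(x, y, z)
        and _both_bands_clear(x, y, z, s, d)
        and abs(z) - abs(x + y) <= -(s + d)
        and abs(z) >= max(abs(x), abs(y)) - s + d
    )


MODE_REGIONS: Dict[str, Callable[..., bool]] = {
    "antagonistic": _r_antagonistic,
    "unilateral": _r_unilateral,
    "neutral": _r_neutral,
    "dominant": _r_dominant,
    "synergistic": _r_synergistic,
    "additive": _r_additive,
    "minor": _r_minor,
    NON_ASSIGNED: _r_non_assigned,
}

_SIGN_PATTERNS: Dict[str, tuple[tuple[int, int, int], ...]] = {
    "antagonistic": ((-1, -1, 1),),
    "unilateral": ((-1, 1, 1), (1, -1, 1)),
}


def _sample_mode_triple(
    mode: str, spec: SimulationSpec, rng: np.random.Generator
) -> tuple[float, float, float]:
    """Rejection-sample one noiseless triple inside the margin-shrunk region."""
    lo, hi = spec.effect_range
    region = MODE_REGIONS[mode]
    same_sign_patterns = ((1, 1, 1),)
    patterns = _SIGN_PATTERNS.get(mode, same_sign_patterns)
    for _ in range(_MAX_ATTEMPTS):
        sx, sy, sz = patterns[rng.integers(len(patterns))]
        flip = 1 if rng.random() < 0.5 else -1  # SWL direction +-1 equiprobable
        mags = rng.uniform(lo, hi, size=3)
        x, y, z = flip * sx * mags[0], flip * sy * mags[1], flip * sz * mags[2]
        if region(x, y, z, spec.sigma, spec.margin):
            return float(x), float(y), float(z)
    raise RuntimeError(
        f"could not place a triple for mode {mode!r} with margin "
        f"{spec.margin} inside effect_range {spec.effect_range}; "
        "the spec is infeasible"
    )


def _significant_stats(rng: np.random.Generator) -> tuple[float, float]:
    """(fdr, vip) consistent with passing the screening gates."""
    fdr = float(rng.uniform(0.0, 0.04)) or 1e-6
    vip = float(rng.uniform(1.1, 3.0))
    return fdr, vip


def _null_stats(rng: np.random.Generator) -> tuple[float, float, float]:
    """(log2fc, fdr, vip) for a sub-threshold entry."""
    lfc = float(rng.uniform(-0.5, 0.5))
    fdr = float(rng.uniform(0.2, 1.0))
    vip = float(rng.uniform(0.2, 0.9))
    return lfc, fdr, vip


def simulate_dataset(spec: SimulationSpec) -> SimulatedDataset:
    """Generate the three aligned contrast tables plus the planted truth."""
    rng = np.random.default_rng(spec.seed)
    rows: Dict[str, list] = {"ST": [], "WL": [], "SWL": []}
    labels: Dict[str, str] = {}
    counter = 0

    def next_id() -> str:
        nonlocal counter
        counter += 1
        return f"f{counter:06d}"

    # common responders, grouped by mode in the canonical order
    for mode in PLANTABLE_MODES:
        for _ in range(int(spec.n_per_mode.get(mode, 0))):
            fid = next_id()
            labels[fid] = mode
            x, y, z = _sample_mode_triple(mode, spec, rng)
            noisy = np.array([x, y, z])
            if spec.noise_sd > 0:
                noisy = noisy + rng.normal(0.0, spec.noise_sd, size=3)
            for value, label in zip(noisy, ("ST", "WL", "SWL")):
                fdr, vip = _significant_stats(rng)
                rows[label].append((fid, float(value), fdr, vip))

    # unique responders: significant in exactly one contrast
    for label in ("ST", "WL", "SWL"):
        for _ in range(int(spec.n_unique.get(label, 0))):
            fid = next_id()
            labels[fid] = f"unique-{label}"
            for contrast in ("ST", "WL", "SWL"):
                if contrast == label:
                    sign = 1.0 if rng.random() < 0.5 else -1.0
                    lfc = sign * float(rng.uniform(*spec.effect_range))
                    fdr, vip = _significant_stats(rng)
                    rows[contrast].append((fid, lfc, fdr, vip))
                else:
                    rows[contrast].append((fid, *_null_stats(rng)))

    # null features: sub-threshold in all three contrasts
    for _ in range(int(spec.n_null)):
        fid = next_id()
        labels[fid] = NULL_LABEL
        for contrast in ("ST", "WL", "SWL"):
            rows[contrast].append((fid, *_null_stats(rng)))

    tables = {}
    for contrast in ("ST", "WL", "SWL"):
        df = pd.DataFrame(
            rows[contrast], columns=["feature_id", "log2fc", "fdr", "vip"]
        ).set_index("feature_id")
        tables[contrast] = ContrastTable(contrast, spec.feature_kind, df)

    return SimulatedDataset(
        tables["ST"], tables["WL"], tables["SWL"], PlantedTruth(labels)
    )


def recovery_rate(
    truth: PlantedTruth, assignments: list[ModeAssignment]
) -> float:
    """Fraction of common features whose assigned mode matches the planted one."""
    common = truth.common_ids
    assigned_ids = {a.feature_id for a in assignments}
    if assigned_ids != common:
        raise ValueError(
            "assignments must cover exactly the planted common features "
            f"({len(assigned_ids)} assigned vs {len(common)} planted)"
        )
    if not common:
        return 1.0
    hits = sum(1 for a in assignments if truth.labels[a.feature_id] == a.mode)
    return hits / len(common)
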