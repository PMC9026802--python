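"""Synthetic patient cohorts calibrated to published group statistics.

Each predictor is summarized in the source cohort only by its per-subtype
median and inter-quartiles, so the generator fits a two-parameter
distribution to those three numbers per (subtype, variable) cell:

* log-normal for the strictly positive, right-skewed predictors (the six
  perfusion variables and the three size variables): location = ln(median)
  matches the median exactly; scale = ln(q3/q1) / (2 z_{0.75}) is the
  least-squares compromise on the two log-quartile equations.
* quantile-matched normal for age: location = median; scale =
  (q3 - q1) / (2 z_{0.75}); negative draws are resampled (truncation).

Variables are drawn independently within subtype (only marginals are
published; no correlation structure is available). Sub-labels
(Hodgkin/non-Hodgkin, invasive/noninvasive) are assigned by count within
their parent subtype, carrying no feature shift of their own.

The ``table2_*`` helpers package the published cohort table: per-subtype
medians/IQRs for the 10 predictors, converted from the printed scales to
the column units used throughout (ttp_s in s, volume_mm3 in mm^3,
surface_mm2 in mm^2, maxdiam_mm in mm; the rate/fraction/concentration
columns stay on the printed 1e-3 scale).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import norm

Z_UPPER_QUARTILE = float(norm.ppf(0.75))

FEATURE_COLUMNS = (
    "age_yr", "ktrans", "kep", "vp", "ve", "ttp_s", "cmax",
    "volume_mm3", "surface_mm2", "maxdiam_mm",
)
LABEL_COLUMNS = ("subtype", "subtype_fine")

_FAMILIES = {name: ("quantile-matched-normal" if name == "age_yr" else "log-normal")
             for name in FEATURE_COLUMNS}


@dataclass(frozen=True)
class GroupDistributionSpec:
    """Median and inter-quartiles of one predictor in one subtype group."""

    variable_name: str
    median: float
    q1: float
    q3: float
    family: str = "log-normal"

    def __post_init__(self) -> None:
        if self.family not in ("log-normal", "quantile-matched-normal"):
            raise ValueError(f"unknown family '{self.family}'")
        if not (self.q1 <= self.median <= self.q3) or self.q1 >= self.q3:
            # q1 == median can occur from display rounding; a collapsed IQR cannot
            raise ValueError("need q1 <= median <= q3 with q1 < q3")
        if self.family == "log-normal" and min(self.q1, self.median, self.q3) <= 0:
            raise ValueError("log-normal family needs strictly positive quantiles")


@dataclass(frozen=True)
class QuantileMatchedDistribution:
    """Fitted two-parameter distribution with exact-median calibration."""

    family: str
    location: float
    scale: float

    @property
    def median(self) -> float:
        if self.family == "log-normal":
            return float(np.exp(self.location))
        return self.location

    @property
    def quartiles(self) -> Tuple[float, float]:
        z = Z_UPPER_QUARTILE
        if self.family == "log-normal":
            return (float(np.exp(self.location - z * self.scale)),
                    float(np.exp(self.location + z * self.scale)))
        return (self.location - z * self.scale, self.location + z * self.scale)

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.family == "log-normal":
            return np.exp(rng.normal(self.location, self.scale, size=n))
        out = rng.normal(self.location, self.scale, size=n)
        # truncation at zero: resample negative draws
        bad = out < 0
        while np.any(bad):
            out[bad] = rng.normal(self.location, self.scale, size=int(bad.sum()))
            bad = out < 0
        return out


def solve_quantile_match(spec: GroupDistributionSpec) -> QuantileMatchedDistribution:
    """Fit the two-parameter family to (q1, median, q3).

    The median is matched exactly by construction; the IQR is matched
    exactly only when the quartiles are symmetric about the median (in log
    space for the log-normal), otherwise the scale is the least-squares
    compromise between the two quartile equations.
    """
    z = Z_UPPER_QUARTILE
    if spec.family == "log-normal":
        return QuantileMatchedDistribution(
            family=spec.family,
            location=float(np.log(spec.median)),
            scale=float(np.log(spec.q3 / spec.q1) / (2.0 * z)),
        )
    return QuantileMatchedDistribution(
        family=spec.family,
        location=float(spec.median),
        scale=float((spec.q3 - spec.q1) / (2.0 * z)),
    )


@dataclass(frozen=True)
class CohortSpec:
    """Counts and per-subtype distribution specs for one synthetic cohort.

    ``groups`` maps subtype -> (count, {variable -> GroupDistributionSpec});
    ``fine_labels`` optionally maps subtype -> {fine label -> count}, which
    must sum to the parent count.
    """

    groups: Dict[str, Tuple[int, Dict[str, GroupDistributionSpec]]]
    fine_labels: Dict[str, Dict[str, int]] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        for subtype, (count, dists) in self.groups.items():
            if count < 0:
                raise ValueError(f"negative count for '{subtype}'")
            if count > 0:
                missing = set(FEATURE_COLUMNS) - set(dists)
                if missing:
                    raise ValueError(f"'{subtype}' missing specs for {sorted(missing)}")
        for subtype, fines in self.fine_labels.items():
            if subtype not in self.groups:
                raise ValueError(f"fine labels for unknown subtype '{subtype}'")
            if sum(fines.values()) != self.groups[subtype][0]:
                raise ValueError(f"fine-label counts for '{subtype}' must sum to the subtype count")
            if any(v < 0 for v in fines.values()):
                raise ValueError("fine-label counts must be non-negative")

    @property
    def n_total(self) -> int:
        return sum(count for count, _ in self.groups.values())


def sample_cohort(spec: CohortSpec, seed: Optional[int] = None) -> pd.DataFrame:
    """Draw one synthetic feature table (one row per patient).

    Deterministic given the seed: subtypes and variables are visited in
    fixed declaration order from a single generator stream. Zero total
    patients yields an empty table with the full header.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    frames: List[pd.DataFrame] = []
    for subtype, (count, dists) in spec.groups.items():
        if count == 0:
            continue
        data = {}
        for var in FEATURE_COLUMNS:
            dist = solve_quantile_match(dists[var])
            data[var] = dist.sample(rng, count)
        df = pd.DataFrame(data)
        df.insert(0, "subtype", subtype)
        fines = spec.fine_labels.get(subtype)
        if fines:
            labels = np.concatenate([np.repeat(k, v) for k, v in fines.items()])
        else:
            labels = np.repeat(subtype, count)
        df.insert(1, "subtype_fine", labels)
        frames.append(df)
    if not frames:
        return pd.DataFrame(columns=list(LABEL_COLUMNS) + list(FEATURE_COLUMNS))
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# packaged cohort preset: published per-subtype medians (q1, q3)
#
# Values are stored in column units. Printed-scale conversions applied here:
# ttp x100 (10^2 s -> s), volume x1e4 (10^4 mm^3 -> mm^3), surface x1e4,
# maxdiam x100 (10^2 mm -> mm). ktrans/kep (1e-3 min^-1), vp/ve (1e-3) and
# cmax (1e-3 mM) keep their printed 1e-3 scale: the downstream cutoffs are
# published on that same scale.

_T2 = {
    # var: {group: (median, q1, q3)} in printed units
    "age_yr":      {"lymphoma": (30, 26, 48), "tet": (59, 52, 65),
                    "thymoma": (56, 49, 65), "thymic_carcinoma": (62, 55, 69)},
    "ktrans":      {"lymphoma": (0.34, 0.11, 1.13), "tet": (0.46, 0.22, 0.62),
                    "thymoma": (0.36, 0.17, 0.58), "thymic_carcinoma": (0.51, 0.45, 1.50)},
    "kep":         {"lymphoma": (0.86, 0.67, 1.73), "tet": (1.70, 0.90, 2.96),
                    "thymoma": (2.72, 1.14, 4.71), "thymic_carcinoma": (0.93, 0.72, 1.38)},
    "vp":          {"lymphoma": (0.01, 0.01, 0.03), "tet": (0.02, 0.01, 0.05),
                    "thymoma": (0.02, 0.01, 0.05), "thymic_carcinoma": (0.03, 0.02, 0.07)},
    "ve":          {"lymphoma": (0.39, 0.13, 1.01), "tet": (0.20, 0.08, 0.54),
                    "thymoma": (0.13, 0.06, 0.31), "thymic_carcinoma": (0.52, 0.20, 2.36)},
    "ttp_s":       {"lymphoma": (1.29, 1.05, 1.96), "tet": (1.09, 0.76, 1.75),
                    "thymoma": (0.89, 0.66, 1.29), "thymic_carcinoma": (1.72, 1.01, 1.96)},
    "cmax":        {"lymphoma": (32, 18, 47), "tet": (21, 11, 38),
                    "thymoma": (17, 9, 33), "thymic_carcinoma": (31, 16, 70)},
    "volume_mm3":  {"lymphoma": (4.50, 2.06, 6.37), "tet": (1.21, 0.57, 4.52),
                    "thymoma": (1.10, 0.49, 4.40), "thymic_carcinoma": (1.60, 0.67, 5.06)},
    "surface_mm2": {"lymphoma": (2.49, 1.55, 3.84), "tet": (0.80, 0.44, 2.78),
                    "thymoma": (0.72, 0.42, 2.86), "thymic_carcinoma": (1.14, 0.55, 2.80)},
    "maxdiam_mm":  {"lymphoma": (0.76, 0.65, 1.02), "tet": (0.45, 0.35, 0.71),
                    "thymoma": (0.43, 0.35, 0.72), "thymic_carcinoma": (0.51, 0.41, 0.72)},
}

_PRINT_SCALE = {"ttp_s": 100.0, "volume_mm3": 1e4, "surface_mm2": 1e4, "maxdiam_mm": 100.0}

COHORT_COUNTS = {"lymphoma": 17, "thymoma": 31, "thymic_carcinoma": 14}
FINE_COUNTS = {
    "lymphoma": {"hodgkin": 6, "non_hodgkin": 11},
    "thymoma": {"invasive": 6, "noninvasive": 25},
}


def table2_group_spec(group: str, variable: str) -> GroupDistributionSpec:
    """Distribution spec for one (group, variable) cell of the packaged table.

    Groups: lymphoma, tet, thymoma, thymic_carcinoma. Values in column units.
    """
    med, q1, q3 = _T2[variable][group]
    scale = _PRINT_SCALE.get(variable, 1.0)
    return GroupDistributionSpec(
        variable_name=variable,
        median=med * scale, q1=q1 * scale, q3=q3 * scale,
        family=_FAMILIES[variable],
    )


def table2_cohort_spec(seed: int = 0) -> CohortSpec:
    """The packaged three-subtype cohort (17 lymphoma, 31 thymoma,
    14 thymic carcinoma) calibrated to the published group statistics."""
    groups = {}
    for subtype, count in COHORT_COUNTS.items():
        dists = {v: table2_group_spec(subtype, v) for v in FEATURE_COLUMNS}
        groups[subtype] = (count, dists)
    return CohortSpec(groups=groups, fine_labels=dict(FINE_COUNTS), seed=seed)


# ---------------------------------------------------------------------------
# cohort selection flow

PAPER_EXCLUSIONS = (
    ("distinct-imaging diagnosis (germ cell tumor, metastasis, cyst, hyperplasia, ectopic thyroid)", 41),
    ("chemotherapy before MRI", 7),
    ("mass smaller than 2 cm", 3),
    ("contrast agent contraindicated (renal insufficiency)", 1),
)
INITIAL_SCREENED = 114


def exclusion_flow(initial: int = INITIAL_SCREENED,
                   exclusions: Sequence[Tuple[str, int]] = PAPER_EXCLUSIONS) -> int:
    """Apply an exclusion cascade to the initially screened count."""
    n = initial
    for reason, count in exclusions:
        if count < 0:
            raise ValueError(f"negative exclusion count for '{reason}'")
        n -= count
    if n < 0:
        raise ValueError("exclusions exceed the initial count")
    return n
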