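"""FACT-G scoring, 0-100 rescaling, additive tariff evaluation and descriptives.

The FACT-G (version 4) has 27 Likert items (0-4) in four domains: physical
well-being (PWB, 7 items), social/family well-being (SWB, 7 items), emotional
well-being (EWB, 6 items) and functional well-being (FWB, 7 items).  Domain
scores are item sums after reversing negatively worded items (a reversed item
contributes ``4 - response``), prorated for missing answers following FACIT
guidance: a domain is valid when more than half of its items were answered, in
which case the answered-item sum is scaled up by ``n_items / n_answered``; the
global score (0-108) is the sum of the four domain scores and is valid only
when every domain is valid and at least 80% of all 27 items were answered.

Preference-based instruments (EQ-5D-3L, SF-6D) are handled as level profiles
scored through a user-supplied additive tariff: ``utility = intercept - sum of
per-dimension level decrements - sum of aggregate-term contributions``.  The
tariff engine is generic; country value-set coefficients are configuration,
not package data.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import yaml
from scipy import stats as sps

__all__ = [
    "ITEM_CODES",
    "DOMAIN_ITEMS",
    "DOMAIN_MAX",
    "DEFAULT_REVERSED_ITEMS",
    "ItemResponseSet",
    "DomainScores",
    "HealthStateProfile",
    "AggregateTerm",
    "TariffSpec",
    "score_factg",
    "rescale_scores",
    "inverse_rescale",
    "apply_tariff",
    "describe_scores",
    "load_tariff",
]

#: FACT-G v4 item codes in instrument order.
ITEM_CODES: tuple[str, ...] = tuple(
    f"GP{i}" for i in range(1, 8)
) + tuple(f"GS{i}" for i in range(1, 8)) + tuple(
    f"GE{i}" for i in range(1, 7)
) + tuple(f"GF{i}" for i in range(1, 8))

DOMAIN_ITEMS: dict[str, tuple[str, ...]] = {
    "pwb": ITEM_CODES[0:7],
    "swb": ITEM_CODES[7:14],
    "ewb": ITEM_CODES[14:20],
    "fwb": ITEM_CODES[20:27],
}

DOMAIN_MAX: dict[str, int] = {"pwb": 28, "swb": 28, "ewb": 24, "fwb": 28, "global": 108}

#: FACIT v4 polarity: every PWB item and every EWB item except GE2
#: ("I am satisfied with how I am coping with my illness") is negatively
#: worded and therefore reverse-scored.  Overridable per response set.
DEFAULT_REVERSED_ITEMS: frozenset[str] = frozenset(
    DOMAIN_ITEMS["pwb"] + tuple(c for c in DOMAIN_ITEMS["ewb"] if c != "GE2")
)

_MIN_DOMAIN_FRACTION = 0.5   # strictly more than half the items answered
_MIN_OVERALL_FRACTION = 0.8  # at least 80% of all 27 items for the global score


@dataclass(frozen=True)
class ItemResponseSet:
    """One patient's FACT-G item responses.

    ``responses`` maps item code -> integer 0-4; missing items are simply
    absent (or ``None``).  ``reversed_items`` is the set of negatively worded
    items whose contribution is ``4 - response``.
    """

    patient_id: str
    responses: Mapping[str, Optional[int]]
    reversed_items: frozenset[str] = DEFAULT_REVERSED_ITEMS

    def __post_init__(self) -> None:
        unknown = set(self.responses) - set(ITEM_CODES)
        if unknown:
            raise ValueError(f"unknown FACT-G item codes: {sorted(unknown)}")
        bad_rev = set(self.reversed_items) - set(ITEM_CODES)
        if bad_rev:
            raise ValueError(f"polarity map names unknown items: {sorted(bad_rev)}")
        for code, value in self.responses.items():
            if value is None:
                continue
            if not float(value).is_integer() or not 0 <= int(value) <= 4:
                raise ValueError(
                    f"item {code}: response {value!r} outside the 0-4 Likert range"
                )

    def contribution(self, code: str) -> Optional[int]:
        """Scored contribution of one item (reverse-coded where applicable)."""
        value = self.responses.get(code)
        if value is None:
            return None
        value = int(value)
        return 4 - value if code in self.reversed_items else value


@dataclass(frozen=True)
class DomainScores:
    """Raw FACT-G domain and global scores; ``nan`` marks an invalid score.

    Invariant: when all four domains are valid, ``global_score`` equals their
    sum (proration can make it fractional).
    """

    pwb: float
    swb: float
    ewb: float
    fwb: float
    global_score: float
    patient_id: Optional[str] = None

    def __post_init__(self) -> None:
        for name in ("pwb", "swb", "ewb", "fwb"):
            value = getattr(self, name)
            if not math.isnan(value) and not 0.0 <= value <= DOMAIN_MAX[name] + 1e-9:
                raise ValueError(
                    f"{name} score {value} outside [0, {DOMAIN_MAX[name]}]"
                )
        g = self.global_score
        if not math.isnan(g) and not 0.0 <= g <= DOMAIN_MAX["global"] + 1e-9:
            raise ValueError(f"global score {g} outside [0, 108]")
        domains = [self.pwb, self.swb, self.ewb, self.fwb]
        if not math.isnan(g) and all(not math.isnan(d) for d in domains):
            if abs(g - sum(domains)) > 1e-6:
                raise ValueError(
                    "global score must equal the sum of valid domain scores"
                )

    @property
    def valid(self) -> dict[str, bool]:
        return {
            name: not math.isnan(getattr(self, name))
            for name in ("pwb", "swb", "ewb", "fwb")
        } | {"global": not math.isnan(self.global_score)}


def score_factg(items: ItemResponseSet) -> DomainScores:
    """Score a 27-item FACT-G response set into prorated domain/global scores."""
    domain_scores: dict[str, float] = {}
    answered_total = 0
    for domain, codes in DOMAIN_ITEMS.items():
        contribs = [items.contribution(c) for c in codes]
        answered = [c for c in contribs if c is not None]
        answered_total += len(answered)
        if len(answered) > _MIN_DOMAIN_FRACTION * len(codes):
            domain_scores[domain] = sum(answered) * len(codes) / len(answered)
        else:
            domain_scores[domain] = float("nan")
    if (
        all(not math.isnan(v) for v in domain_scores.values())
        and answered_total >= _MIN_OVERALL_FRACTION * len(ITEM_CODES)
    ):
        global_score = sum(domain_scores.values())
    else:
        global_score = float("nan")
    return DomainScores(
        pwb=domain_scores["pwb"],
        swb=domain_scores["swb"],
        ewb=domain_scores["ewb"],
        fwb=domain_scores["fwb"],
        global_score=global_score,
        patient_id=items.patient_id,
    )


def rescale_scores(scores: DomainScores) -> dict[str, float]:
    """Linearly rescale raw scores to 0-100 by each scale's maximum.

    Returns a mapping with keys ``pwb``, ``swb``, ``ewb``, ``fwb``,
    ``global``; invalid (nan) scores stay nan.
    """
    out: dict[str, float] = {}
    for name in ("pwb", "swb", "ewb", "fwb"):
        out[name] = getattr(scores, name) * 100.0 / DOMAIN_MAX[name]
    out["global"] = scores.global_score * 100.0 / DOMAIN_MAX["global"]
    return out


def inverse_rescale(
    rescaled: Mapping[str, float], patient_id: Optional[str] = None
) -> DomainScores:
    """Map 0-100 rescaled scores back onto their raw ranges."""
    raw = {name: rescaled[name] * DOMAIN_MAX[name] / 100.0 for name in
           ("pwb", "swb", "ewb", "fwb")}
    return DomainScores(
        **raw,
        global_score=rescaled["global"] * DOMAIN_MAX["global"] / 100.0,
        patient_id=patient_id,
    )


# ---------------------------------------------------------------------------
# Preference-instrument level profiles and additive tariffs

#: Declared level counts per dimension.  EQ-5D-3L: 5 dimensions x 3 levels
#: (243 states).  SF-6D: 6 dimensions with 6/4/5/6/5/5 levels (18,000 states).
INSTRUMENT_LEVELS: dict[str, tuple[int, ...]] = {
    "EQ5D3L": (3, 3, 3, 3, 3),
    "SF6D": (6, 4, 5, 6, 5, 5),
}


@dataclass(frozen=True)
class HealthStateProfile:
    """A level vector describing one health state of a preference instrument."""

    instrument: str
    levels: tuple[int, ...]
    level_counts: Optional[tuple[int, ...]] = None

    def __post_init__(self) -> None:
        counts = self.level_counts or INSTRUMENT_LEVELS.get(self.instrument)
        if counts is None:
            raise ValueError(
                f"unknown instrument {self.instrument!r}; pass level_counts"
            )
        object.__setattr__(self, "level_counts", tuple(counts))
        if len(self.levels) != len(counts):
            raise ValueError(
                f"profile has {len(self.levels)} dimensions, "
                f"instrument declares {len(counts)}"
            )
        for i, (lvl, cnt) in enumerate(zip(self.levels, counts)):
            if not 1 <= lvl <= cnt:
                raise ValueError(
                    f"dimension {i}: level {lvl} outside 1..{cnt}"
                )


@dataclass(frozen=True)
class AggregateTerm:
    """A named feature of the whole level vector with a subtracted coefficient.

    Kinds: ``any_at_worst`` (indicator that any dimension sits at its worst
    level), ``count_at_worst``, ``count_at_or_above`` (dimensions at or above
    ``level``), and their squares ``count_at_worst_squared`` /
    ``count_at_or_above_squared``.
    """

    kind: str
    coefficient: float
    level: Optional[int] = None

    _KINDS = (
        "any_at_worst",
        "count_at_worst",
        "count_at_worst_squared",
        "count_at_or_above",
        "count_at_or_above_squared",
    )

    def __post_init__(self) -> None:
        if self.kind not in self._KINDS:
            raise ValueError(f"unknown aggregate term kind {self.kind!r}")
        if self.kind.startswith("count_at_or_above") and self.level is None:
            raise ValueError(f"{self.kind} requires a level threshold")

    def value(self, levels: Sequence[int], counts: Sequence[int]) -> float:
        worst = sum(1 for lvl, cnt in zip(levels, counts) if lvl == cnt)
        if self.kind == "any_at_worst":
            return float(worst > 0)
        if self.kind == "count_at_worst":
            return float(worst)
        if self.kind == "count_at_worst_squared":
            return float(worst**2)
        above = sum(1 for lvl in levels if lvl >= self.level)
        if self.kind == "count_at_or_above":
            return float(above)
        return float(above**2)


@dataclass(frozen=True)
class TariffSpec:
    """Additive value-set specification for a preference instrument.

    ``decrements[d][l-1]`` is the utility decrement for dimension ``d`` at
    level ``l``; level-1 decrements must be zero so the all-ones profile
    evaluates to the intercept.
    """

    name: str
    dimensions: tuple[str, ...]
    level_counts: tuple[int, ...]
    decrements: tuple[tuple[float, ...], ...]
    intercept: float = 1.0
    aggregate_terms: tuple[AggregateTerm, ...] = ()
    utility_range: tuple[float, float] = (-1.0, 1.0)

    def __post_init__(self) -> None:
        if not (len(self.dimensions) == len(self.level_counts) == len(self.decrements)):
            raise ValueError("dimensions, level_counts and decrements must align")
        for d, (cnt, decs) in enumerate(zip(self.level_counts, self.decrements)):
            if len(decs) != cnt:
                raise ValueError(
                    f"dimension {self.dimensions[d]}: {len(decs)} decrements "
                    f"for {cnt} levels"
                )
            if decs[0] != 0.0:
                raise ValueError(
                    f"dimension {self.dimensions[d]}: level-1 decrement must be 0"
                )


def apply_tariff(profile: HealthStateProfile, tariff: TariffSpec) -> float:
    """Evaluate an additive tariff on a level profile.

    A result outside the tariff's declared utility range raises a warning
    (value sets are routinely applied slightly out of their anchoring range),
    never an error.
    """
    if tuple(profile.level_counts) != tuple(tariff.level_counts):
        raise ValueError(
            f"profile level counts {profile.level_counts} do not match "
            f"tariff {tariff.name!r} level counts {tariff.level_counts}"
        )
    utility = tariff.intercept
    for lvl, decs in zip(profile.levels, tariff.decrements):
        utility -= decs[lvl - 1]
    for term in tariff.aggregate_terms:
        utility -= term.coefficient * term.value(profile.levels, tariff.level_counts)
    lo, hi = tariff.utility_range
    if not lo - 1e-12 <= utility <= hi + 1e-12:
        warnings.warn(
            f"tariff {tariff.name!r}: utility {utility:.4f} outside declared "
            f"range [{lo}, {hi}]",
            stacklevel=2,
        )
    return utility


def load_tariff(path) -> TariffSpec:
    """Read a tariff specification from a YAML config file."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    terms = tuple(
        AggregateTerm(
            kind=t["kind"], coefficient=float(t["coefficient"]),
            level=t.get("level"),
        )
        for t in cfg.get("aggregate_terms", [])
    )
    return TariffSpec(
        name=cfg["name"],
        dimensions=tuple(cfg["dimensions"]),
        level_counts=tuple(int(c) for c in cfg["level_counts"]),
        decrements=tuple(tuple(float(x) for x in row) for row in cfg["decrements"]),
        intercept=float(cfg.get("intercept", 1.0)),
        aggregate_terms=terms,
        utility_range=tuple(cfg.get("utility_range", (-1.0, 1.0))),  # type: ignore[arg-type]
    )


def describe_scores(
    values: Sequence[float],
    minimum: Optional[float] = None,
    maximum: Optional[float] = None,
) -> dict[str, float]:
    """Descriptive summary of a score or utility vector.

    Returns n, mean, SD (n-1 denominator), median, min, max, floor/ceiling
    percentages relative to the theoretical ``minimum``/``maximum`` (when
    given) and the moment skewness coefficient m3/m2^1.5 (nan, with
    ``skewness_defined = False``, for constant input).
    """
    arr = np.asarray(values, dtype=float)
    arr = arr[~np.isnan(arr)]
    if arr.size < 2:
        raise ValueError("describe_scores needs at least 2 non-missing values")
    sd = float(np.std(arr, ddof=1))
    out: dict[str, float] = {
        "n": int(arr.size),
        "mean": float(np.mean(arr)),
        "sd": sd,
        "median": float(np.median(arr)),
        "min": float(np.min(arr)),
        "max": float(np.max(arr)),
    }
    if minimum is not None:
        out["floor_pct"] = float(np.mean(arr == minimum) * 100.0)
    if maximum is not None:
        out["ceiling_pct"] = float(np.mean(arr == maximum) * 100.0)
    if sd == 0.0:
        out["skewness"] = float("nan")
        out["skewness_defined"] = False
    else:
        out["skewness"] = float(sps.skew(arr, bias=True))
        out["skewness_defined"] = True
    return out
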