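"""Mamdani fuzzy inference mapping e-nose sensor signals to odor intensity.

An 8-channel gas-sensor array produces one maximum (stop-flow) signal per
channel per sample.  The pipeline is the classic Mamdani stack:

1. **Calibration** — for every (sensor, intensity level) cell of a labeled
   training set, a Gaussian membership function is fitted from the sample
   mean and standard deviation of the signals at that level.
2. **Rule learning** — Wang–Mendel style: each training sample proposes a
   rule whose antecedent assigns each sensor its maximum-membership level
   and whose consequent is the sample's label, with degree = product of the
   winning memberships; identical antecedents are conflict-resolved by
   degree, and one homogeneous rule per level ("IF every sensor at level L
   THEN OI = L") is always present.
3. **Inference** — fuzzify the incoming signals, fire each rule with
   AND = min, clip the consequent output set at the firing strength
   (implication = min), aggregate rules by pointwise max, and defuzzify by
   the centroid (center of gravity) of the aggregate over the VDI axis
   [0, 6].

Output fuzzy sets are Gaussians centered on the integer VDI levels with a
common standard deviation (default 0.4; see the methods note for why the
default is narrower than half a level).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .perceptual import mspe

__all__ = [
    "GaussianMF",
    "SensorMembershipSet",
    "FuzzyRule",
    "RuleBase",
    "LabeledSample",
    "OutputConfig",
    "CalibrationError",
    "NoRuleFiredError",
    "calibrate_membership",
    "fuzzify",
    "default_output_mfs",
    "learn_rules",
    "infer",
    "validate",
    "ValidationReport",
    "FuzzyOdorModel",
]


class CalibrationError(ValueError):
    """Raised when a (sensor, level) calibration cell is unusable."""


class NoRuleFiredError(RuntimeError):
    """Raised when no rule fires above the configured floor."""

    def __init__(self, message: str, strengths: dict | None = None):
        super().__init__(message)
        self.strengths = strengths or {}


@dataclass(frozen=True)
class GaussianMF:
    """Gaussian membership function exp(−(x − mean)²/(2·sd²)) ∈ (0, 1]."""

    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ValueError(f"sd must be > 0, got {self.sd}")

    def membership(self, x):
        x = np.asarray(x, dtype=float)
        out = np.exp(-((x - self.mean) ** 2) / (2.0 * self.sd**2))
        return float(out) if out.ndim == 0 else out

    __call__ = membership


@dataclass(frozen=True)
class LabeledSample:
    """One training sample: a full set of sensor signals plus its VDI label."""

    signals: Mapping[str, float]
    oi_label: int
    sample_id: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "signals", dict(self.signals))
        if not self.signals:
            raise ValueError("a sample needs at least one sensor signal")


class SensorMembershipSet:
    """Per-sensor, per-level Gaussian membership functions.

    The trained levels must form a contiguous integer range and every
    configured sensor must carry an MF for every trained level.
    """

    def __init__(self, mfs: Mapping[str, Mapping[int, GaussianMF]]):
        self._mfs = {s: dict(levels) for s, levels in mfs.items()}
        if not self._mfs:
            raise ValueError("empty membership set")
        level_sets = {frozenset(levels) for levels in self._mfs.values()}
        if len(level_sets) != 1:
            raise CalibrationError("all sensors must share the same trained levels")
        levels = sorted(next(iter(level_sets)))
        if levels != list(range(levels[0], levels[-1] + 1)):
            raise CalibrationError(f"trained levels {levels} are not contiguous")
        self._levels = levels

    @property
    def sensors(self) -> list[str]:
        return list(self._mfs)

    @property
    def levels(self) -> list[int]:
        return list(self._levels)

    def mf(self, sensor: str, level: int) -> GaussianMF:
        return self._mfs[sensor][level]

    def fuzzify(self, sensor: str, value: float) -> dict[int, float]:
        if sensor not in self._mfs:
            raise KeyError(f"unknown sensor {sensor!r}; configured: {self.sensors}")
        return {lv: mf.membership(value) for lv, mf in self._mfs[sensor].items()}

    def to_dict(self) -> dict:
        return {s: {str(lv): {"mean": mf.mean, "sd": mf.sd}
                    for lv, mf in levels.items()}
                for s, levels in self._mfs.items()}

    @classmethod
    def from_dict(cls, d: Mapping) -> "SensorMembershipSet":
        return cls({s: {int(lv): GaussianMF(v["mean"], v["sd"])
                        for lv, v in levels.items()}
                    for s, levels in d.items()})


@dataclass(frozen=True)
class FuzzyRule:
    """IF (each sensor in its antecedent level) THEN (OI in consequent level).

    ``degree`` records the training support (product of winning
    memberships at learning time); it is used only for conflict resolution
    between rules sharing an antecedent, not during inference.
    """

    antecedent: Mapping[str, int]
    consequent: int
    degree: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "antecedent", dict(self.antecedent))
        if not 0.0 < self.degree <= 1.0:
            raise ValueError(f"degree must be in (0, 1], got {self.degree}")

    def key(self) -> tuple:
        return tuple(sorted(self.antecedent.items()))


@dataclass
class RuleBase:
    """A conflict-free list of rules (no two share an antecedent)."""

    rules: list[FuzzyRule]

    def __post_init__(self) -> None:
        keys = [r.key() for r in self.rules]
        if len(set(keys)) != len(keys):
            raise ValueError("rule base contains duplicate antecedents")

    def __len__(self) -> int:
        return len(self.rules)

    def to_list(self) -> list[dict]:
        return [{"antecedent": dict(r.antecedent), "consequent": r.consequent,
                 "degree": r.degree} for r in self.rules]

    @classmethod
    def from_list(cls, items: Iterable[Mapping]) -> "RuleBase":
        return cls([FuzzyRule({s: int(lv) for s, lv in it["antecedent"].items()},
                              int(it["consequent"]), float(it.get("degree", 1.0)))
                    for it in items])


@dataclass(frozen=True)
class OutputConfig:
    """Output-side configuration of the Mamdani engine.

    ``output_sd`` is the common width of the Gaussian output sets centered
    on integer VDI levels; ``support`` is the centroid integration range
    (the VDI axis); ``grid_step`` the discretization; ``firing_floor`` the
    threshold below which a run is reported as "no rule fired".
    """

    output_sd: float = 0.4
    support: tuple[float, float] = (0.0, 6.0)
    grid_step: float = 0.01
    firing_floor: float = 1e-6

    def __post_init__(self) -> None:
        if self.output_sd <= 0 or self.grid_step <= 0:
            raise ValueError("output_sd and grid_step must be > 0")
        if self.support[1] <= self.support[0]:
            raise ValueError("empty support interval")


def default_output_mfs(levels: Sequence[int] = range(0, 7),
                       sd: float = 0.4) -> dict[int, GaussianMF]:
    """Gaussian output sets centered at integer VDI levels with common sd."""
    return {int(lv): GaussianMF(float(lv), sd) for lv in levels}


def calibrate_membership(training: Sequence[LabeledSample],
                         sd_floor: float | None = None) -> SensorMembershipSet:
    """Fit per-(sensor, level) Gaussian MFs from a labeled training set.

    Each MF takes the sample mean and sample standard deviation (n−1) of
    that sensor's signals at that level.  Cells with fewer than two samples
    raise a :class:`CalibrationError` naming the cell.  Standard deviations
    below ``sd_floor`` (default: 1% of the sensor's observed signal range,
    with a small absolute fallback for constant sensors) are raised to the
    floor so that replicate-identical training data still yields proper
    membership functions.
    """
    if not training:
        raise CalibrationError("empty training set")
    sensors = sorted(training[0].signals)
    for s in training:
        if sorted(s.signals) != sensors:
            raise CalibrationError("all samples must carry the same sensor set")
    levels = sorted({s.oi_label for s in training})
    if levels != list(range(levels[0], levels[-1] + 1)):
        raise CalibrationError(f"trained levels {levels} are not contiguous")

    by_cell: dict[tuple[str, int], list[float]] = {}
    for samp in training:
        for sensor, value in samp.signals.items():
            by_cell.setdefault((sensor, samp.oi_label), []).append(float(value))

    mfs: dict[str, dict[int, GaussianMF]] = {s: {} for s in sensors}
    for sensor in sensors:
        values = [v for (sen, _), vals in by_cell.items() if sen == sensor for v in vals]
        span = max(values) - min(values)
        floor = sd_floor if sd_floor is not None else max(0.01 * span, 1e-6)
        for level in levels:
            cell = by_cell.get((sensor, level), [])
            if len(cell) < 2:
                raise CalibrationError(
                    f"sensor {sensor!r} at level {level}: {len(cell)} sample(s), "
                    "need >= 2")
            sd = float(np.std(cell, ddof=1))
            mfs[sensor][level] = GaussianMF(float(np.mean(cell)), max(sd, floor))
    return SensorMembershipSet(mfs)


def fuzzify(value: float, mfs: Mapping[int, GaussianMF]) -> dict[int, float]:
    """Membership degree of a crisp signal in each level's fuzzy set."""
    return {lv: mf.membership(value) for lv, mf in mfs.items()}


def learn_rules(training: Sequence[LabeledSample],
                mfs: SensorMembershipSet,
                include_homogeneous: bool = True) -> RuleBase:
    """Wang–Mendel rule learning from labeled samples.

    Every sample proposes one rule (antecedent: each sensor's
    maximum-membership level, ties to the lower level; consequent: the
    label; degree: product of the winning memberships).  Among rules with
    the same antecedent the highest degree survives.  Homogeneous rules
    ("all sensors at L ⇒ L") are appended last and take precedence over any
    conflicting learned rule, so the canonical diagonal of the rule table
    is always present.
    """
    if not training:
        raise ValueError("empty training set")
    best: dict[tuple, FuzzyRule] = {}
    for samp in training:
        antecedent: dict[str, int] = {}
        degree = 1.0
        for sensor in mfs.sensors:
            degrees = mfs.fuzzify(sensor, samp.signals[sensor])
            win = max(sorted(degrees), key=lambda lv: degrees[lv])
            antecedent[sensor] = win
            degree *= degrees[win]
        rule = FuzzyRule(antecedent, samp.oi_label, max(degree, 1e-300))
        k = rule.key()
        if k not in best or rule.degree > best[k].degree:
            best[k] = rule
    if include_homogeneous:
        for level in mfs.levels:
            rule = FuzzyRule({s: level for s in mfs.sensors}, level, 1.0)
            best[rule.key()] = rule
    return RuleBase(sorted(best.values(), key=lambda r: (r.consequent, r.key())))


def _firing_strength(rule: FuzzyRule, signals: Mapping[str, float],
                     mfs: SensorMembershipSet) -> float:
    return min(mfs.mf(s, rule.antecedent[s]).membership(x)
               for s, x in signals.items())


def infer(signals: Mapping[str, float],
          rulebase: RuleBase,
          mfs: SensorMembershipSet,
          output_mfs: Mapping[int, GaussianMF] | None = None,
          config: OutputConfig = OutputConfig()) -> float:
    """Mamdani inference: min-AND, min-implication, max-aggregation, centroid.

    Returns the continuous odor intensity given one signal per configured
    sensor.  Raises :class:`NoRuleFiredError` (with per-rule diagnostics)
    when every firing strength is below ``config.firing_floor``.
    """
    signals = dict(signals)
    missing = set(mfs.sensors) - set(signals)
    extra = set(signals) - set(mfs.sensors)
    if missing or extra:
        raise KeyError(f"signal/sensor mismatch: missing {sorted(missing)}, "
                       f"unknown {sorted(extra)}")
    if output_mfs is None:
        output_mfs = default_output_mfs(sd=config.output_sd)

    strengths = {r.key(): _firing_strength(r, signals, mfs) for r in rulebase.rules}
    if max(strengths.values(), default=0.0) < config.firing_floor:
        raise NoRuleFiredError(
            f"no rule fired above {config.firing_floor:g}", strengths)

    lo, hi = config.support
    grid = np.arange(lo, hi + config.grid_step / 2, config.grid_step)
    aggregate = np.zeros_like(grid)
    for rule in rulebase.rules:
        h = strengths[rule.key()]
        if h <= 0.0:
            continue
        clipped = np.minimum(h, output_mfs[rule.consequent].membership(grid))
        np.maximum(aggregate, clipped, out=aggregate)
    # trapezoidal moments: the aggregate is nonzero at the support ends,
    # where a plain Riemann sum loses first-order accuracy
    mass = np.trapezoid(aggregate, grid)
    if mass <= 0.0:
        raise NoRuleFiredError("aggregated output function has zero mass", strengths)
    return float(np.trapezoid(grid * aggregate, grid) / mass)


@dataclass
class ValidationReport:
    """Paired measured-vs-predicted table with its mean squared error."""

    table: pd.DataFrame  # columns: measured, predicted, residual
    mspe: float

    def plot(self, ax=None):
        """Measured-vs-predicted scatter with the identity line."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.scatter(self.table["measured"], self.table["predicted"])
        span = [self.table.min().min(), self.table.max().max()]
        ax.plot(span, span, ls="--", c="k", lw=1)
        ax.set_xlabel("measured OI (sensory)")
        ax.set_ylabel("predicted OI (e-nose)")
        return ax


def validate(predictions: Sequence[float], sensory: Sequence[float]) -> ValidationReport:
    """Compare fuzzy predictions against sensory panel intensities."""
    p = [float(x) for x in predictions]
    m = [float(x) for x in sensory]
    if len(p) != len(m):
        raise ValueError(f"length mismatch: {len(p)} predictions vs {len(m)} sensory")
    table = pd.DataFrame({"measured": m, "predicted": p})
    table["residual"] = table["predicted"] - table["measured"]
    return ValidationReport(table=table, mspe=mspe(p, m))


class FuzzyOdorModel:
    """Calibrated membership set + rule base + output config, as one object.

    The convenience bundle used by the CLI and examples: train from labeled
    samples, infer on new signal vectors, persist to/from JSON.
    """

    def __init__(self, mfs: SensorMembershipSet, rulebase: RuleBase,
                 config: OutputConfig = OutputConfig()):
        self.mfs = mfs
        self.rulebase = rulebase
        self.config = config
        self.output_mfs = default_output_mfs(sd=config.output_sd)

    @classmethod
    def train(cls, training: Sequence[LabeledSample],
              config: OutputConfig = OutputConfig(),
              sd_floor: float | None = None) -> "FuzzyOdorModel":
        mfs = calibrate_membership(training, sd_floor=sd_floor)
        return cls(mfs, learn_rules(training, mfs), config)

    def infer(self, signals: Mapping[str, float]) -> float:
        return infer(signals, self.rulebase, self.mfs,
                     output_mfs=self.output_mfs, config=self.config)

    def to_json(self) -> str:
        return json.dumps({
            "membership": self.mfs.to_dict(),
            "rules": self.rulebase.to_list(),
            "output": {"sd": self.config.output_sd,
                       "support": list(self.config.support),
                       "grid_step": self.config.grid_step,
                       "firing_floor": self.config.firing_floor},
        }, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "FuzzyOdorModel":
        d = json.loads(text)
        out = d.get("output", {})
        config = OutputConfig(
            output_sd=out.get("sd", 0.4),
            support=tuple(out.get("support", (0.0, 6.0))),
            grid_step=out.get("grid_step", 0.01),
            firing_floor=out.get("firing_floor", 1e-6),
        )
        return cls(SensorMembershipSet.from_dict(d["membership"]),
                   RuleBase.from_list(d["rules"]), config)
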