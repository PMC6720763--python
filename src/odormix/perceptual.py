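"""Perceptual models for the odor intensity of binary mixtures.

Given the intensities OI_A and OI_B that two odorants would elicit alone,
four classical models predict the mixture intensity OI_AB:

* **vectorial** — OI_AB = sqrt(OI_A² + OI_B² + 2·OI_A·OI_B·cosα); the two
  component intensities add like vectors at an angle α, and cosα in
  [−1, 1] is the odor interaction coefficient (negative = mutual
  suppression, positive = synergy).
* **Euclidean additivity** — the vectorial model with cosα = 0; serves as
  the no-interaction reference.
* **U model** — OI_AB = OI_A + OI_B + 2·cosα·sqrt(OI_A·OI_B).
* **UPL model** — the U model with cosα derived purely from the
  components' Stevens exponents: cosα_X = 2**(n_X − 1) − 1 per component,
  combined as an intensity-weighted mean.  No mixture sensory data enters.

The vectorial and U coefficients are estimated from panel data by the
algebraic inverses of the prediction formulas; estimates that fall outside
[−1, 1] (possible with noisy panel means) are clamped with a structured
warning rather than rejected.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Model",
    "CoefficientRangeWarning",
    "InteractionCoefficient",
    "InteractionMatrix",
    "MixtureObservation",
    "predict_vectorial",
    "predict_euclidean",
    "predict_u",
    "predict_mixture",
    "estimate_cos_vectorial",
    "estimate_cos_u",
    "upl_single_cos",
    "upl_pair_cos",
    "implied_mixture_oi",
    "mspe",
    "build_interaction_matrix",
    "upl_interaction_matrix",
]

Model = Literal["vectorial", "euclidean", "u", "upl"]


class CoefficientRangeWarning(UserWarning):
    """An estimated interaction coefficient fell outside [-1, 1] and was clamped."""


@dataclass(frozen=True)
class InteractionCoefficient:
    """A pairwise odor interaction coefficient cosα for one model.

    ``oi_level`` records the odor-intensity level of the sensory design the
    coefficient was estimated at (the vectorial and U coefficients are
    level-specific in principle; UPL coefficients are level-free).
    ``clamped`` is True when the raw estimate fell outside [-1, 1].
    """

    odorant_a: str
    odorant_b: str
    cos_ab: float
    model: str
    oi_level: int | None = None
    clamped: bool = False

    def __post_init__(self) -> None:
        if not -1.0 <= self.cos_ab <= 1.0:
            raise ValueError(f"cos_ab must lie in [-1, 1], got {self.cos_ab}")

    @property
    def pair(self) -> frozenset[str]:
        return frozenset((self.odorant_a, self.odorant_b))

    def __float__(self) -> float:
        return float(self.cos_ab)


@dataclass(frozen=True)
class MixtureObservation:
    """Panel observation of one binary mixture.

    ``oi_a`` and ``oi_b`` are the intensities the components elicit alone
    (by design, the level the mixture was generated at); ``oi_ab_sensory``
    is the panel-mean rated intensity of the mixture.
    """

    oi_a: float
    oi_b: float
    oi_ab_sensory: float
    n_replicates: int = 1

    def __post_init__(self) -> None:
        if min(self.oi_a, self.oi_b, self.oi_ab_sensory) < 0:
            raise ValueError("odor intensities must be >= 0")


def _check_cos(cos_ab: float) -> float:
    if not -1.0 <= cos_ab <= 1.0:
        raise ValueError(f"interaction coefficient must lie in [-1, 1], got {cos_ab}")
    return float(cos_ab)


def _check_oi(*values: float) -> None:
    for v in values:
        if v < 0:
            raise ValueError(f"odor intensities must be >= 0, got {v}")


def predict_vectorial(oi_a: float, oi_b: float, cos_ab: float) -> float:
    """Vectorial model: sqrt(OI_A² + OI_B² + 2·OI_A·OI_B·cosα).

    The radicand is bounded below by (OI_A − OI_B)² >= 0, so the square
    root is always defined for cosα in [-1, 1].
    """
    _check_oi(oi_a, oi_b)
    cos_ab = _check_cos(cos_ab)
    radicand = oi_a**2 + oi_b**2 + 2.0 * oi_a * oi_b * cos_ab
    return math.sqrt(max(radicand, 0.0))


def predict_euclidean(oi_a: float, oi_b: float) -> float:
    """Euclidean additivity: sqrt(OI_A² + OI_B²) — the cosα = 0 reference."""
    _check_oi(oi_a, oi_b)
    return math.hypot(oi_a, oi_b)


def predict_u(oi_a: float, oi_b: float, cos_ab: float) -> float:
    """U model: OI_A + OI_B + 2·cosα·sqrt(OI_A·OI_B).

    Bounded below by (sqrt(OI_A) − sqrt(OI_B))² >= 0.
    """
    _check_oi(oi_a, oi_b)
    cos_ab = _check_cos(cos_ab)
    return oi_a + oi_b + 2.0 * cos_ab * math.sqrt(oi_a * oi_b)


def predict_mixture(model: Model, oi_a: float, oi_b: float,
                    cos_ab: float | None = None) -> float:
    """Dispatch to the named model (euclidean needs no coefficient)."""
    if model == "euclidean":
        return predict_euclidean(oi_a, oi_b)
    if cos_ab is None:
        raise ValueError(f"model {model!r} requires an interaction coefficient")
    if model in ("u", "upl"):
        return predict_u(oi_a, oi_b, cos_ab)
    if model == "vectorial":
        return predict_vectorial(oi_a, oi_b, cos_ab)
    raise ValueError(f"unknown model {model!r}")


def _clamped(raw: float) -> tuple[float, bool]:
    if -1.0 <= raw <= 1.0:
        return raw, False
    warnings.warn(
        f"estimated interaction coefficient {raw:.4g} outside [-1, 1]; clamped",
        CoefficientRangeWarning, stacklevel=3)
    return min(1.0, max(-1.0, raw)), True


def estimate_cos_vectorial(obs: MixtureObservation,
                           odorant_a: str = "A", odorant_b: str = "B",
                           oi_level: int | None = None) -> InteractionCoefficient:
    """Invert the vectorial model: cosα = (OI_AB² − OI_A² − OI_B²)/(2·OI_A·OI_B)."""
    if obs.oi_a * obs.oi_b == 0:
        raise ZeroDivisionError(
            "interaction coefficient undefined when a component intensity is 0")
    raw = (obs.oi_ab_sensory**2 - obs.oi_a**2 - obs.oi_b**2) / (2.0 * obs.oi_a * obs.oi_b)
    cos, clamped = _clamped(raw)
    return InteractionCoefficient(odorant_a, odorant_b, cos, "vectorial",
                                  oi_level=oi_level, clamped=clamped)


def estimate_cos_u(obs: MixtureObservation,
                   odorant_a: str = "A", odorant_b: str = "B",
                   oi_level: int | None = None) -> InteractionCoefficient:
    """Invert the U model: cosα = (OI_AB − OI_A − OI_B)/(2·sqrt(OI_A·OI_B))."""
    if obs.oi_a * obs.oi_b == 0:
        raise ZeroDivisionError(
            "interaction coefficient undefined when a component intensity is 0")
    raw = (obs.oi_ab_sensory - obs.oi_a - obs.oi_b) / (2.0 * math.sqrt(obs.oi_a * obs.oi_b))
    cos, clamped = _clamped(raw)
    return InteractionCoefficient(odorant_a, odorant_b, cos, "u",
                                  oi_level=oi_level, clamped=clamped)


def upl_single_cos(stevens_n: float) -> float:
    """Single-component UPL coefficient: cosα = 2**(n − 1) − 1.

    Equals 0 for n = 1 (a linear law adds like independent stimuli),
    negative for the compressive exponents n < 1 typical of odorants.
    Strictly correct only at equal component intensities; the pairwise
    combination for unequal intensities is :func:`upl_pair_cos`.
    """
    if stevens_n <= 0:
        raise ValueError(f"Stevens exponent must be > 0, got {stevens_n}")
    return 2.0 ** (stevens_n - 1.0) - 1.0


def upl_pair_cos(cos_a: float, cos_b: float, oi_a: float = 1.0, oi_b: float = 1.0,
                 odorant_a: str = "A", odorant_b: str = "B") -> InteractionCoefficient:
    """Pairwise UPL coefficient: intensity-weighted mean of the single cosines.

    cosα_AB = (cosα_A·OI_A + cosα_B·OI_B)/(OI_A + OI_B); reduces to the
    plain mean at equal intensities (the default weights).
    """
    _check_oi(oi_a, oi_b)
    if oi_a + oi_b == 0:
        raise ZeroDivisionError("UPL pair coefficient undefined at zero total intensity")
    raw = (cos_a * oi_a + cos_b * oi_b) / (oi_a + oi_b)
    cos, clamped = _clamped(raw)
    return InteractionCoefficient(odorant_a, odorant_b, cos, "upl", clamped=clamped)


def implied_mixture_oi(model: Literal["vectorial", "u"], oi_a: float, oi_b: float,
                       cos_ab: float) -> float:
    """Mixture OI implied by a coefficient under the named model.

    A named alias of the forward predictors used to interconvert
    coefficient tables fitted under different models through the shared
    sensory OI_AB (e.g. to check a U-model table against a vectorial one).
    """
    if model == "vectorial":
        return predict_vectorial(oi_a, oi_b, cos_ab)
    if model == "u":
        return predict_u(oi_a, oi_b, cos_ab)
    raise ValueError(f"implied_mixture_oi supports 'vectorial' and 'u', got {model!r}")


def mspe(predicted: Sequence[float], reference: Sequence[float]) -> float:
    """Mean squared prediction error between two paired OI series."""
    p = np.asarray([float(x) for x in predicted], dtype=float)
    r = np.asarray([float(x) for x in reference], dtype=float)
    if p.shape != r.shape or p.ndim != 1:
        raise ValueError(f"paired 1-d series required, got shapes {p.shape} vs {r.shape}")
    if p.size == 0:
        raise ValueError("MSPE of empty series is undefined")
    return float(np.mean((p - r) ** 2))


class InteractionMatrix:
    """Symmetric pairwise cosα table for one model (optionally one OI level).

    Cells are keyed by unordered odorant pair, so symmetry holds by
    construction; the diagonal is not stored.  Missing pairs simply have no
    cell.
    """

    def __init__(self, model: str, oi_level: int | None = None,
                 odorants: Sequence[str] | None = None):
        self.model = model
        self.oi_level = oi_level
        self._cells: dict[frozenset[str], InteractionCoefficient] = {}
        self._order: list[str] = list(odorants) if odorants else []

    def set(self, coeff: InteractionCoefficient) -> None:
        if coeff.odorant_a == coeff.odorant_b:
            raise ValueError("diagonal (self-interaction) cells are not stored")
        self._cells[coeff.pair] = coeff
        for name in (coeff.odorant_a, coeff.odorant_b):
            if name not in self._order:
                self._order.append(name)

    def get(self, a: str, b: str) -> InteractionCoefficient:
        try:
            return self._cells[frozenset((a, b))]
        except KeyError:
            raise KeyError(f"no interaction coefficient for pair ({a}, {b})") from None

    def cos(self, a: str, b: str) -> float:
        return self.get(a, b).cos_ab

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return frozenset(pair) in self._cells

    def __len__(self) -> int:
        return len(self._cells)

    @property
    def odorants(self) -> list[str]:
        return list(self._order)

    def pairs(self) -> list[tuple[str, str]]:
        out = []
        for i, a in enumerate(self._order):
            for b in self._order[i + 1:]:
                if (a, b) in self:
                    out.append((a, b))
        return out

    def to_dataframe(self) -> pd.DataFrame:
        """Full square symmetric matrix (NaN diagonal / missing pairs)."""
        names = self._order
        df = pd.DataFrame(np.nan, index=names, columns=names)
        for cell in self._cells.values():
            a, b = cell.odorant_a, cell.odorant_b
            df.loc[a, b] = df.loc[b, a] = cell.cos_ab
        return df

    def to_tidy(self) -> pd.DataFrame:
        """Tidy rows ``odorant_a,odorant_b,model,oi_level,cos_ab`` (one per pair)."""
        rows = [
            {"odorant_a": a, "odorant_b": b, "model": self.model,
             "oi_level": self.oi_level, "cos_ab": self.cos(a, b)}
            for a, b in self.pairs()
        ]
        return pd.DataFrame(rows, columns=["odorant_a", "odorant_b", "model",
                                           "oi_level", "cos_ab"])

    @classmethod
    def from_tidy(cls, df: pd.DataFrame) -> "InteractionMatrix":
        models = df["model"].unique()
        if len(models) != 1:
            raise ValueError(f"tidy table must hold a single model, got {list(models)}")
        levels = df["oi_level"].unique() if "oi_level" in df else [None]
        level = None if len(levels) != 1 or pd.isna(levels[0]) else int(levels[0])
        mat = cls(model=str(models[0]), oi_level=level)
        for row in df.itertuples(index=False):
            mat.set(InteractionCoefficient(str(row.odorant_a), str(row.odorant_b),
                                           float(row.cos_ab), str(row.model),
                                           oi_level=level))
        return mat

    @classmethod
    def from_pairs(cls, model: str, pairs: Mapping[tuple[str, str], float],
                   oi_level: int | None = None,
                   odorants: Sequence[str] | None = None) -> "InteractionMatrix":
        mat = cls(model=model, oi_level=oi_level, odorants=odorants)
        for (a, b), cos in pairs.items():
            mat.set(InteractionCoefficient(a, b, float(cos), model, oi_level=oi_level))
        return mat


def build_interaction_matrix(
    observations: Mapping[tuple[str, str], MixtureObservation | Iterable[MixtureObservation]],
    model: Literal["vectorial", "u"],
    oi_level: int | None = None,
) -> InteractionMatrix:
    """Estimate a full coefficient matrix from per-pair panel observations.

    Replicate observations of a pair are averaged on the sensory OI_AB
    (and on the component intensities) before the coefficient is computed,
    matching the use of panel-mean mixture intensities.
    """
    estimator = {"vectorial": estimate_cos_vectorial, "u": estimate_cos_u}[model]
    mat = InteractionMatrix(model=model, oi_level=oi_level)
    for (a, b), obs in observations.items():
        if isinstance(obs, MixtureObservation):
            merged = obs
        else:
            group = list(obs)
            if not group:
                continue
            merged = MixtureObservation(
                oi_a=float(np.mean([o.oi_a for o in group])),
                oi_b=float(np.mean([o.oi_b for o in group])),
                oi_ab_sensory=float(np.mean([o.oi_ab_sensory for o in group])),
                n_replicates=sum(o.n_replicates for o in group),
            )
        mat.set(estimator(merged, odorant_a=a, odorant_b=b, oi_level=oi_level))
    return mat


def upl_interaction_matrix(profiles: Iterable) -> InteractionMatrix:
    """Full pairwise UPL matrix from odorant Stevens exponents.

    Uses the equal-intensity combination (plain mean of the two single
    coefficients) for every unordered pair — the level-free form in which
    UPL tables are reported.  ``profiles`` may be
    :class:`~odormix.psychophysics.OdorantProfile` objects or any objects
    with ``name`` and ``stevens.n`` attributes.
    """
    profs = list(profiles)
    mat = InteractionMatrix(model="upl", odorants=[p.name for p in profs])
    for i, pa in enumerate(profs):
        for pb in profs[i + 1:]:
            mat.set(upl_pair_cos(upl_single_cos(pa.stevens.n),
                                 upl_single_cos(pb.stevens.n),
                                 odorant_a=pa.name, odorant_b=pb.name))
    return mat
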