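"""Fuzzy-membership scoring of farmland quality indicators.

Raw indicator values u are converted to membership degrees F in [0, 1]
through three numeric function families

* decreasing / peak type:  Y = 1 / (1 + a (u - c)^2)
* linear type:             Y = a u + b

or, for conceptual (qualitative) indicators, through an ordered
category -> score lookup established by expert (Delphi) scoring.  Inputs are
clamped to the fitted value bounds [u_lo, u_hi] before evaluation and raw
outputs to [0, 1] after, since membership is by definition a degree in
[0, 1] and the function parameters are only calibrated inside the bounds.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from . import hefei2021
from .synthetic_landscape import CategoricalLayer, GridSpec, IndicatorLayer

_KINDS = ("decreasing", "peak", "linear")

#: Score columns of the conceptual grading scale, best first.
SCORE_COLUMNS = (1.0, 0.9, 0.8, 0.7, 0.6, 0.5, 0.4, 0.3, 0.2, 0.1)


@dataclass(frozen=True)
class MembershipSpec:
    """Parameters of one numeric membership function.

    ``a`` is the curvature/slope coefficient, ``b`` the linear intercept,
    ``c`` the standard (optimal) indicator value of the decreasing/peak
    families; ``u_lo``/``u_hi`` bound the fitted domain.
    """

    indicator_id: str
    kind: str
    a: float
    b: float | None = None
    c: float | None = None
    u_lo: float = 0.0
    u_hi: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(
                f"unknown membership kind {self.kind!r}; expected one of {_KINDS}"
            )
        if self.u_lo >= self.u_hi:
            raise ValueError("u_lo must be below u_hi")
        if self.kind in ("decreasing", "peak"):
            if self.a <= 0:
                raise ValueError(f"{self.kind} kind requires a > 0")
            if self.c is None:
                raise ValueError(f"{self.kind} kind requires the standard value c")
        elif self.b is None:
            raise ValueError("linear kind requires the intercept b")


@dataclass(frozen=True)
class ConceptualScale:
    """Ordered category -> score map for one conceptual indicator."""

    indicator_id: str
    scores: tuple[tuple[str, float], ...]  # (category, score), best first

    def __post_init__(self) -> None:
        vals = [s for _, s in self.scores]
        if not vals:
            raise ValueError("scale must contain at least one category")
        if any(not (0 < s <= 1) for s in vals):
            raise ValueError("scores must lie in (0, 1]")
        if any(later >= earlier for earlier, later in zip(vals, vals[1:])):
            raise ValueError("scores must strictly decrease along the category order")

    @property
    def mapping(self) -> dict[str, float]:
        return dict(self.scores)

    @classmethod
    def from_categories(
        cls, indicator_id: str, categories: Sequence[str]
    ) -> "ConceptualScale":
        """Assign consecutive score columns 1.0, 0.9, ... to the ordered
        categories, best first (the default row-to-column alignment)."""
        if len(categories) > len(SCORE_COLUMNS):
            raise ValueError("more categories than score columns")
        return cls(
            indicator_id,
            tuple(zip(categories, SCORE_COLUMNS[: len(categories)])),
        )


@dataclass
class ScoreLayer:
    """Per-cell membership scores for one indicator on a grid."""

    grid: GridSpec
    indicator_id: str
    scores: np.ndarray
    nodata_mask: np.ndarray

    def __post_init__(self) -> None:
        valid = self.scores[~self.nodata_mask]
        if valid.size and (valid.min() < 0 or valid.max() > 1):
            raise ValueError("scores must lie in [0, 1]")


def evaluate_membership(spec: MembershipSpec, u):
    """Evaluate a numeric membership function at ``u`` (scalar or array).

    ``u`` is clamped to [u_lo, u_hi]; the raw function value is clamped to
    [0, 1].
    """
    u = np.clip(np.asarray(u, dtype=float), spec.u_lo, spec.u_hi)
    if spec.kind in ("decreasing", "peak"):
        y = 1.0 / (1.0 + spec.a * (u - spec.c) ** 2)
    else:
        y = spec.a * u + spec.b
    y = np.clip(y, 0.0, 1.0)
    return float(y) if y.ndim == 0 else y


def score_conceptual(scale: ConceptualScale, category: str) -> float:
    """Score one category of a conceptual indicator."""
    try:
        return scale.mapping[category]
    except KeyError:
        legal = ", ".join(repr(c) for c, _ in scale.scores)
        raise KeyError(
            f"unknown category {category!r} for {scale.indicator_id}; "
            f"legal categories: {legal}"
        ) from None


def score_layer(
    spec_or_scale: MembershipSpec | ConceptualScale,
    layer: IndicatorLayer | CategoricalLayer,
) -> ScoreLayer:
    """Apply a membership function or conceptual scale per cell.

    Continuous layers pair with a MembershipSpec, categorical layers with a
    ConceptualScale (legend names must all be scoreable); nodata is
    preserved.
    """
    if isinstance(spec_or_scale, MembershipSpec):
        if not isinstance(layer, IndicatorLayer) or layer.kind != "continuous":
            raise TypeError(
                "MembershipSpec requires a continuous IndicatorLayer"
            )
        scores = evaluate_membership(spec_or_scale, layer.values)
        nodata = layer.nodata_mask.copy()
        return ScoreLayer(layer.grid, spec_or_scale.indicator_id, scores, nodata)
    if isinstance(spec_or_scale, ConceptualScale):
        if not isinstance(layer, CategoricalLayer):
            raise TypeError("ConceptualScale requires a CategoricalLayer")
        lut = {}
        for cid, name in layer.legend.items():
            lut[cid] = score_conceptual(spec_or_scale, name)
        scores = np.zeros(layer.grid.shape, dtype=float)
        for cid, s in lut.items():
            scores[layer.class_ids == cid] = s
        nodata = np.zeros(layer.grid.shape, dtype=bool)
        return ScoreLayer(
            layer.grid, spec_or_scale.indicator_id, scores, nodata
        )
    raise TypeError(f"unsupported spec type {type(spec_or_scale)!r}")


def hefei_membership_specs() -> dict[str, MembershipSpec]:
    """The ten calibrated numeric membership functions of the Hefei study."""
    specs = {}
    for iid, (kind, a, b, c, lo, hi) in hefei2021.MEMBERSHIP_PARAMS.items():
        specs[iid] = MembershipSpec(iid, kind, a, b, c, lo, hi)
    return specs


def hefei_conceptual_scales() -> dict[str, ConceptualScale]:
    """The six Delphi score scales of the Hefei study, with the default
    consecutive-column alignment starting at 1.0."""
    return {
        iid: ConceptualScale.from_categories(iid, cats)
        for iid, cats in hefei2021.CONCEPTUAL_CATEGORIES.items()
    }
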