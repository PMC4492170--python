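"""Post-hoc analysis of the fitted methylation-to-expression surface.

Houses (a) the published 28-term cubic model of log gene expression with
its coefficient estimates, standard errors, t and p values; (b) the
simplified nested text models f1..f6 built around gene-body CG methylation
(m_cg); and (c) the calculus on conditional univariate profiles: stationary
points, inflection points, and conversions between standardized (Z) units
and raw percent methylation via printed anchor pairs.

A conditional profile is the exact univariate cubic in one free predictor
obtained by substituting fixed Z values for every other predictor of the
full polynomial model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .expression_model import (PREDICTORS, ModelTerm, PolynomialModelSpec,
                               predict)
from .io_formats import ValidationError

# index lookup for building exponent vectors by predictor name
_IDX = {name: j for j, name in enumerate(PREDICTORS)}


def _exps(**powers: int) -> tuple[int, ...]:
    e = [0] * len(PREDICTORS)
    for name, p in powers.items():
        e[_IDX[name]] = p
    return tuple(e)


#: The published cubic model: 28 fitted terms (29 factors with the intercept).
#: Each row: (exponent spec, coefficient, SE, t, p).  "Percent CG" cubic and
#: interaction rows refer to gene-body CG methylation (m_cg): the cubic
#: coefficient matches the simplified text model's -0.03 and the u_chh
#: interaction its +0.02.
PUBLISHED_TERMS: list[tuple[dict, float, float, float, float]] = [
    # positive terms
    (dict(l_intron=1),                0.3472, 0.0117, 29.75, 1e-4),
    (dict(m_chg=2),                   0.0874, 0.0082, 10.64, 1e-4),
    (dict(n_exon=1, l_intron=1),      0.0793, 0.0081,  9.74, 1e-4),
    (dict(l_exon=1),                  0.0767, 0.0102,  7.55, 1e-4),
    (dict(l_exon=1, l_intron=1),      0.0553, 0.0070,  7.86, 1e-4),
    (dict(m_cg=1, l_exon=1),          0.0392, 0.0089,  4.40, 1e-4),
    (dict(m_cg=2, l_exon=1),          0.0303, 0.0069,  4.37, 1e-4),
    (dict(u_chh=1),                   0.0275, 0.0055,  4.99, 1e-4),
    (dict(m_cg=1, m_chh=1),           0.0244, 0.0064,  3.78, 2e-4),
    (dict(d_chh=1),                   0.0185, 0.0050,  3.69, 2e-4),
    (dict(u_chh=1, m_cg=1),           0.0167, 0.0051,  3.28, 1.1e-3),
    (dict(l_intron=3),                0.0105, 0.0007, 14.40, 1e-4),
    (dict(l_exon=2, n_exon=1),        0.0074, 0.0009,  8.19, 1e-4),
    # negative terms
    (dict(m_chg=1),                  -0.3273, 0.0197, -16.58, 1e-4),
    (dict(l_intron=2),               -0.1611, 0.0076, -21.18, 1e-4),
    (dict(m_cg=2),                   -0.0980, 0.0092, -10.62, 1e-4),
    (dict(m_cg=1),                   -0.0720, 0.0118,  -6.09, 1e-4),
    (dict(l_exon=1, n_exon=1),       -0.0662, 0.0076,  -8.72, 1e-4),
    (dict(m_chh=1),                  -0.0451, 0.0076,  -5.93, 1e-4),
    (dict(n_exon=1),                 -0.0308, 0.0112,  -2.75, 5.9e-3),
    (dict(m_cg=3),                   -0.0277, 0.0059,  -4.73, 1e-4),
    (dict(u_cg=1),                   -0.0274, 0.0054,  -5.06, 1e-4),
    (dict(l_exon=2),                 -0.0205, 0.0033,  -6.28, 1e-4),
    (dict(m_chg=1, l_exon=1),        -0.0198, 0.0058,  -3.41, 7e-4),
    (dict(u_cg=1, u_chh=1),          -0.0188, 0.0058,  -3.23, 1.2e-3),
    (dict(u_cg=1, m_cg=1),           -0.0170, 0.0052,  -3.28, 1e-3),
    (dict(l_exon=1, l_intron=1, n_exon=1), -0.0118, 0.0016, -7.21, 1e-4),
    (dict(m_chg=3),                  -0.0063, 0.0008,  -7.95, 1e-4),
]

#: intercept used by the simplified text models
TEXT_INTERCEPT = 2.61


def published_model(intercept: float | None = TEXT_INTERCEPT
                    ) -> PolynomialModelSpec:
    """The published 28-term cubic expression model as a model spec.

    The intercept defaults to the text models' 2.61; pass ``None`` to leave
    it unset (the surface's shape — maxima, inflections — does not depend
    on it).
    """
    terms = [ModelTerm(exponents=_exps(**powers), coefficient=c,
                       standard_error=se, t_value=t, p_value=p)
             for powers, c, se, t, p in PUBLISHED_TERMS]
    return PolynomialModelSpec(intercept=intercept, terms=terms)


# ---------------------------------------------------------------------------
# conditional profiles
# ---------------------------------------------------------------------------

@dataclass
class ConditionalProfile:
    """A univariate cubic slice of the expression surface.

    ``coefficients`` is (c0, c1, c2, c3): the value is
    ``c0 + c1 x + c2 x^2 + c3 x^3`` where x is the free predictor in Z units.
    """

    free_predictor: str
    fixed_values: dict[str, float]
    coefficients: tuple[float, float, float, float]

    def __call__(self, x: float | np.ndarray) -> float | np.ndarray:
        c0, c1, c2, c3 = self.coefficients
        return c0 + c1 * x + c2 * x ** 2 + c3 * x ** 3

    evaluate = __call__


def conditional_profile(model: PolynomialModelSpec, free_predictor: str,
                        fixed_values: Mapping[str, float] | None = None
                        ) -> ConditionalProfile:
    """Collapse a polynomial model to a cubic in one free predictor.

    Every other predictor is substituted at its value in *fixed_values*
    (default 0, the cohort mean in Z units).  The reduction is algebraically
    exact: evaluating the profile at x equals evaluating the full model with
    the free predictor set to x.
    """
    if free_predictor not in model.predictors:
        raise ValidationError(f"unknown predictor {free_predictor!r}")
    j_free = model.predictors.index(free_predictor)
    if not any(t.exponents[j_free] for t in model.terms):
        raise ValidationError(
            f"predictor {free_predictor!r} does not appear in the model")
    fixed = dict(fixed_values or {})
    unknown = set(fixed) - set(model.predictors)
    if unknown:
        raise ValidationError(f"unknown fixed predictors: {sorted(unknown)}")
    fixed.pop(free_predictor, None)

    c = [model.intercept or 0.0, 0.0, 0.0, 0.0]
    for t in model.terms:
        e_free = t.exponents[j_free]
        value = t.coefficient
        for j, e in enumerate(t.exponents):
            if j == j_free or not e:
                continue
            value *= fixed.get(model.predictors[j], 0.0) ** e
        c[e_free] += value
    return ConditionalProfile(free_predictor=free_predictor,
                              fixed_values=fixed,
                              coefficients=tuple(c))


# ---------------------------------------------------------------------------
# simplified nested text models f1..f6
# ---------------------------------------------------------------------------

def text_model(level: int, u_cg: float = 0.0, u_chh: float = 0.0,
               m_chh: float = 0.0, l_exon: float = 0.0,
               include_exon_main: bool = False) -> ConditionalProfile:
    """The nested simplified cubics in gene-body CG methylation.

    The six levels add terms cumulatively (all interaction values in Z
    units):

    1. linear:            2.61 - 0.07 m_cg
    2. + quadratic:       - 0.10 m_cg^2
    3. + cubic:           - 0.03 m_cg^3
    4. + up-stream CG interaction:      - 0.02 u_cg * m_cg
    5. + three positive interactions:   + (0.02 u_chh + 0.02 m_chh + 0.04 l_exon) m_cg
    6. + quadratic exon interaction:    + 0.03 l_exon * m_cg^2
       (and, when *include_exon_main* is set, the independent exon-length
       effect 0.08 l_exon - 0.02 l_exon^2 added to the constant)
    """
    if level not in range(1, 7):
        raise ValidationError(f"unknown text-model level {level!r}")
    c0 = TEXT_INTERCEPT
    c1 = -0.07
    c2 = -0.10 if level >= 2 else 0.0
    c3 = -0.03 if level >= 3 else 0.0
    if level >= 4:
        c1 += -0.02 * u_cg
    if level >= 5:
        c1 += 0.02 * u_chh + 0.02 * m_chh + 0.04 * l_exon
    if level >= 6:
        c2 += 0.03 * l_exon
        if include_exon_main:
            c0 += 0.08 * l_exon - 0.02 * l_exon ** 2
    fixed = {"u_cg": u_cg, "u_chh": u_chh, "m_chh": m_chh, "l_exon": l_exon}
    return ConditionalProfile(free_predictor="m_cg", fixed_values=fixed,
                              coefficients=(c0, c1, c2, c3))


# ---------------------------------------------------------------------------
# stationary and inflection points
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StationaryPoint:
    location: float            # Z units of the free predictor
    kind: str                  # "max" or "min"
    value: float               # predicted log expression at the point


def stationary_points(coefficients: Sequence[float]
                      ) -> list[StationaryPoint]:
    """Real stationary points of a cubic profile, classified by curvature.

    Solves ``c1 + 2 c2 x + 3 c3 x^2 = 0``; each real root is a local
    maximum if the second derivative there is negative, a minimum if
    positive.  Roots with (numerically) zero curvature are saddle points of
    the cubic and are excluded.  A constant profile is an error.
    """
    c = list(coefficients) + [0.0] * (4 - len(coefficients))
    c0, c1, c2, c3 = c[:4]
    if c1 == 0 and c2 == 0 and c3 == 0:
        raise ValidationError("constant profile has no stationary structure")
    if c3 == 0 and c2 == 0:
        return []                      # strictly monotone line
    if c3 == 0:
        roots = [-c1 / (2 * c2)]
    else:
        disc = 4 * c2 ** 2 - 12 * c3 * c1
        if disc < 0:
            return []
        sq = math.sqrt(disc)
        roots = sorted({(-2 * c2 - sq) / (6 * c3), (-2 * c2 + sq) / (6 * c3)})
    out = []
    scale = max(abs(c1), abs(c2), abs(c3), 1.0)
    for x in roots:
        curvature = 2 * c2 + 6 * c3 * x
        if abs(curvature) <= 1e-12 * scale:
            continue                   # degenerate saddle (e.g. pure x^3)
        kind = "max" if curvature < 0 else "min"
        out.append(StationaryPoint(location=x, kind=kind,
                                   value=c0 + c1 * x + c2 * x ** 2 + c3 * x ** 3))
    return out


def local_maximum(coefficients: Sequence[float]) -> StationaryPoint | None:
    """The profile's local maximum, or None when it has none."""
    maxima = [s for s in stationary_points(coefficients) if s.kind == "max"]
    return maxima[0] if maxima else None


def inflection_point(coefficients: Sequence[float]) -> float | None:
    """Where a cubic's curvature changes sign: ``-c2 / (3 c3)``; None if c3 = 0."""
    c = list(coefficients) + [0.0] * (4 - len(coefficients))
    _, _, c2, c3 = c[:4]
    if c3 == 0:
        return None
    return -c2 / (3 * c3)


# ---------------------------------------------------------------------------
# Z <-> percent conversions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScaleAnchor:
    """Raw mean and SD (percent) implied by printed (Z, percent) anchor pairs."""

    mean: float
    sd: float


#: anchors recoverable from printed (Z, percent) pairs: m_cg from
#: (-1, 32) / (+1, 80); u_cg from (+1, 82) / (-1, 24.1)
DEFAULT_ANCHORS: dict[str, ScaleAnchor] = {
    "m_cg": ScaleAnchor(mean=56.0, sd=24.0),
    "u_cg": ScaleAnchor(mean=53.05, sd=28.95),
}


def anchor_from_pairs(pairs: Sequence[tuple[float, float]]) -> ScaleAnchor:
    """Fit mean/SD from two or more (z, percent) anchor pairs (affine map)."""
    z = np.array([p[0] for p in pairs], dtype=float)
    pct = np.array([p[1] for p in pairs], dtype=float)
    sd, mean = np.polyfit(z, pct, 1)
    return ScaleAnchor(mean=float(mean), sd=float(sd))


def z_to_percent(z: float, predictor: str = "m_cg",
                 anchors: Mapping[str, ScaleAnchor] | None = None) -> float:
    """Map a standardized methylation value to raw percent: mean + SD * z."""
    anchor = (anchors or DEFAULT_ANCHORS).get(predictor)
    if anchor is None:
        raise ValidationError(f"no scale anchors for predictor {predictor!r}")
    return anchor.mean + anchor.sd * z


def percent_to_z(percent: float, predictor: str = "m_cg",
                 anchors: Mapping[str, ScaleAnchor] | None = None) -> float:
    """Inverse of :func:`z_to_percent`."""
    anchor = (anchors or DEFAULT_ANCHORS).get(predictor)
    if anchor is None:
        raise ValidationError(f"no scale anchors for predictor {predictor!r}")
    return (percent - anchor.mean) / anchor.sd
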