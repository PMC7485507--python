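"""Ontogenetic scaling of the polar section modulus.

Type I (ordinary least squares) regression of log10(Zp) on log10(body mass),
fitted separately per skeletal element:

    log10(Zp) = log10(b) + a * log10(M).

Because Zp (mm^3) and mass are both proportional to length^3 under geometric
similarity, isometry corresponds to a scaling exponent a = 1; positive
allometry (disproportionate gain in torsional rigidity) is inferred when the
95% confidence interval of a lies entirely above 1.  OLS is used rather than
reduced major axis: natural individual variation in Zp at a given mass biases
RMA toward steeper slopes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm


@dataclass
class AllometryFit:
    element: str
    n: int
    a: float                       # scaling exponent (slope)
    b: float                       # log10 intercept
    r_squared: float
    ci95_a: tuple[float, float]
    ci95_b: tuple[float, float]
    scaling_class: str             # positive | negative | isometric


def classify_scaling(ci95_a: tuple[float, float], isometry: float = 1.0) -> str:
    """Scaling call from the exponent CI: positive/negative allometry only if
    the interval excludes the isometric value."""
    low, high = ci95_a
    if low > isometry:
        return "positive"
    if high < isometry:
        return "negative"
    return "isometric"


def fit_loglog_allometry(mass_g, zp_mm3, element: str = "",
                         conf: float = 0.95) -> AllometryFit:
    """OLS of log10(Zp) on log10(mass) with t-based confidence intervals."""
    m = np.asarray(mass_g, dtype=float)
    z = np.asarray(zp_mm3, dtype=float)
    if m.size != z.size:
        raise ValueError("mass and Zp must have equal length")
    if m.size < 3:
        raise ValueError("need at least 3 specimens")
    if np.any(m <= 0) or np.any(z <= 0):
        raise ValueError("mass and Zp must be strictly positive")

    X = sm.add_constant(np.log10(m))
    fit = sm.OLS(np.log10(z), X).fit()
    ci = fit.conf_int(alpha=1.0 - conf)
    ci_b = (float(ci[0, 0]), float(ci[0, 1]))
    ci_a = (float(ci[1, 0]), float(ci[1, 1]))
    return AllometryFit(
        element=element,
        n=int(m.size),
        a=float(fit.params[1]),
        b=float(fit.params[0]),
        r_squared=float(fit.rsquared),
        ci95_a=ci_a,
        ci95_b=ci_b,
        scaling_class=classify_scaling(ci_a),
    )
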