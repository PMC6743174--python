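"""Closed-form kinetics of chromatin digestion by micrococcal nuclease.

Digestion of chromatin is modeled as a chain of two consecutive first-order
reactions, B -> N -> 0: nucleosomes bound in chromatin fibers (B) are released
as free mononucleosomes (N) with rate constant ``k1`` and the free particles
are then destroyed by over-digestion with rate constant ``k2``.  Both
reactions are proportional to the (constant) enzyme concentration, so the
natural progress variable is the digestion level d = [E]*t; with [E] absorbed
into the rate constants, d is measured in minutes.

With initial conditions B(0) = C*O (C cells, occupancy O) and N(0) = 0 the
solutions are

    B(d) = C * O * exp(-k1*d)
    N(d) = C * O * k1/(k1-k2) * (exp(-k2*d) - exp(-k1*d))

the classic Bateman form.  ``N(d)/C`` is the *apparent occupancy*: it rises
from zero to a single maximum (where the release and decay rates balance) and
then decays, so raw mononucleosome counts at a single digestion level conflate
true occupancy O with accessibility (k1) and over-digestion (k2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "DigestionParams",
    "MaccFit",
    "bound_fraction",
    "apparent_occupancy",
    "time_of_maximum",
    "fit_macc",
    "macc_model_score",
    "canonicalize_rates",
]

#: relative |k1 - k2| threshold below which the degenerate (k1 == k2)
#: limiting form O*k1*d*exp(-k1*d) is used
DEGENERACY_EPS = 1e-8


@dataclass(frozen=True)
class DigestionParams:
    """Per-locus kinetic parameters.

    O
        Nucleosome occupancy: fraction of cells carrying a nucleosome at the
        locus (or spike-in-normalized count units before calibration); >= 0.
    k1
        Release rate constant (chromatin accessibility), per minute at the
        experiment's fixed enzyme concentration; > 0.
    k2
        Decay (over-digestion) rate constant, same units; >= 0.
    """

    O: float
    k1: float
    k2: float

    def __post_init__(self) -> None:
        if not (self.O >= 0):
            raise ValueError(f"occupancy O must be >= 0, got {self.O}")
        if not (self.k1 > 0):
            raise ValueError(f"release rate k1 must be > 0, got {self.k1}")
        if not (self.k2 >= 0):
            raise ValueError(f"decay rate k2 must be >= 0, got {self.k2}")


@dataclass(frozen=True)
class MaccFit:
    """Linear fit of counts vs log enzyme level: N = a*log(E) + b.

    ``macc`` is the MNase accessibility score, the negative of the fitted
    slope: positive for loci losing fragments as digestion deepens
    ("accessible"), negative for loci gaining fragments ("inaccessible").
    """

    a: float
    b: float

    @property
    def macc(self) -> float:
        return -self.a

    @property
    def label(self) -> str:
        if self.macc > 0:
            return "accessible"
        if self.macc < 0:
            return "inaccessible"
        return "neutral"


def _check_d(d, allow_zero: bool = True):
    d = np.asarray(d, dtype=float)
    lo = 0.0 if allow_zero else np.nextafter(0.0, 1.0)
    if np.any(d < lo) or (not allow_zero and np.any(d <= 0)):
        raise ValueError("digestion level d must be " + (">= 0" if allow_zero else "> 0"))
    return d


def bound_fraction(d, p: DigestionParams):
    """Fraction of nucleosomes still bound in chromatin, f_B(d) = exp(-k1*d)."""
    d = _check_d(d)
    out = np.exp(-p.k1 * d)
    return float(out) if out.ndim == 0 else out


def _is_degenerate(k1: float, k2: float, eps: float) -> bool:
    return abs(k1 - k2) < eps * max(abs(k1), abs(k2))


def apparent_occupancy(d, p: DigestionParams, eps: float = DEGENERACY_EPS):
    """Mononucleosomes per cell, N(d)/C = O * f_N(d).

    Uses the limiting form O*k1*d*exp(-k1*d) when k1 and k2 coincide to
    within relative ``eps`` (the difference of exponentials loses all
    precision there).
    """
    d = _check_d(d)
    k1, k2 = p.k1, p.k2
    if _is_degenerate(k1, k2, eps):
        out = p.O * k1 * d * np.exp(-k1 * d)
    else:
        out = p.O * k1 / (k1 - k2) * (np.exp(-k2 * d) - np.exp(-k1 * d))
    return float(out) if out.ndim == 0 else out


def time_of_maximum(p: DigestionParams) -> float:
    """Digestion level d* at which the mononucleosome count peaks.

    At the maximum the release rate equals the decay rate,
    k1*exp(-k1*d) = k2*exp(-k2*d), giving d* = ln(k1/k2)/(k1 - k2),
    with the limit 1/k1 when k1 == k2.  For k2 == 0 the curve is monotone
    increasing and ``math.inf`` is returned (not an error).
    """
    k1, k2 = p.k1, p.k2
    if k2 == 0:
        return math.inf
    if _is_degenerate(k1, k2, DEGENERACY_EPS):
        return 1.0 / k1
    return math.log(k1 / k2) / (k1 - k2)


def macc_model_score(d, p: DigestionParams):
    """Instantaneous model MACC score, -dN/d(log d), on the kinetic curve.

    Negative while counts still rise with digestion (d < d*), zero at the
    maximum, positive during over-digestion — i.e. every locus looks
    "inaccessible" early and "accessible" late under a single-slope readout.
    """
    d = _check_d(d, allow_zero=False)
    k1, k2 = p.k1, p.k2
    if _is_degenerate(k1, k2, DEGENERACY_EPS):
        # N = O*k1*d*exp(-k1*d) => dN/dd = O*k1*exp(-k1*d)*(1 - k1*d)
        dN_dd = p.O * k1 * np.exp(-k1 * d) * (1.0 - k1 * d)
    else:
        dN_dd = p.O * k1 / (k1 - k2) * (k1 * np.exp(-k1 * d) - k2 * np.exp(-k2 * d))
    out = -d * dN_dd
    return float(out) if out.ndim == 0 else out


def fit_macc(counts, enzyme_levels) -> MaccFit:
    """Ordinary least-squares fit of counts against ln(enzyme level).

    Requires at least two distinct enzyme levels.  The natural logarithm is
    used; the slope sign (and hence the MACC sign) is base-invariant.
    """
    counts = np.asarray(counts, dtype=float)
    levels = np.asarray(enzyme_levels, dtype=float)
    if counts.shape != levels.shape:
        raise ValueError("counts and enzyme_levels must have equal length")
    if np.any(levels <= 0):
        raise ValueError("enzyme levels must be positive")
    if np.unique(levels).size < 2:
        raise ValueError("need at least 2 distinct enzyme levels for the fit")
    x = np.log(levels)
    a, b = np.polyfit(x, counts, 1)
    return MaccFit(a=float(a), b=float(b))


def canonicalize_rates(O: float, k1: float, k2: float) -> tuple[float, float, float]:
    """Map (O, k1, k2) to the equivalent triple with k2 <= k1.

    The apparent-occupancy curve is invariant under
    (k1, k2, O) -> (k2, k1, O*k1/k2), so the parameters are only identified
    up to this exchange.  The reported convention fixes k2 as the exponent
    governing the right tail of the curve — the smaller of the two rates —
    matching how k2 is read off the asymptotic log-slope.
    """
    if k2 > k1:
        return O * k1 / k2, k2, k1
    return O, k1, k2
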