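"""Equilibrium model of split fluorescent protein complementation.

A split FP consists of a large fragment (beta-strands 1-10, "FP_1-10") and a
short peptide tag (strand 11, "FP_11").  Fluorescence requires the two
fragments to associate, which in the cell is a reversible bimolecular
equilibrium

    A + B  <-->  C,        K_D = [A_free][B_free] / [C]

with A the FP_1-10 fragment, B the FP_11-tagged species and C the
complemented (fluorescent) complex.  Two observable regimes follow:

* ``K_D >> A, B``: almost no complementation, ``C ~ A*B/K_D``.  If A and B
  are co-expressed in proportion, C grows as the *square* of expression, so
  the complemented signal versus an expression reporter has slope 2 on a
  log-log plot.
* ``K_D << A, B``: binding saturates, ``C ~ min(A, B)``, and the log-log
  slope falls to 1.

The slope of the log-log relationship across a population of cells spanning
a wide expression range therefore reports the effective K_D relative to
cellular fragment concentrations, which is how complementation efficiency
is scored by the flow-cytometry pipeline in :mod:`splitfp.flow`.

This module also extends the model to tandem arrays of n FP_11 tags on one
target molecule (n independent identical binding sites competing for one
free FP_1-10 pool), which predicts sub-linear signal amplification for
finite FP_1-10 supply.

Concentrations are in arbitrary but mutually consistent units throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import linregress

__all__ = [
    "BindingSystem",
    "TandemSystem",
    "SlopeTheoryInput",
    "complemented_concentration",
    "predicted_slope",
    "tandem_free_fragment",
    "tandem_signal",
    "amplification_fold",
]


def _check_nonneg(name: str, value) -> None:
    arr = np.asarray(value, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} must be finite, got {value!r}")
    if np.any(arr < 0):
        raise ValueError(f"{name} must be non-negative, got {value!r}")


@dataclass(frozen=True)
class BindingSystem:
    """Total concentrations of the two fragments and their dissociation constant.

    Fields may be scalars or equal-shaped numpy arrays (one system per cell).
    """

    a_total: float | np.ndarray
    b_total: float | np.ndarray
    kd: float | np.ndarray

    def __post_init__(self) -> None:
        _check_nonneg("a_total", self.a_total)
        _check_nonneg("b_total", self.b_total)
        _check_nonneg("kd", self.kd)


@dataclass(frozen=True)
class TandemSystem:
    """A pool of FP_1-10 shared by tagged molecules carrying ``n_repeats`` FP_11 sites."""

    n_repeats: int
    a_total: float
    b_tags: float
    kd: float

    def __post_init__(self) -> None:
        if int(self.n_repeats) != self.n_repeats or self.n_repeats < 1:
            raise ValueError(f"n_repeats must be an integer >= 1, got {self.n_repeats!r}")
        _check_nonneg("a_total", self.a_total)
        _check_nonneg("b_tags", self.b_tags)
        _check_nonneg("kd", self.kd)


@dataclass(frozen=True)
class SlopeTheoryInput:
    """Parameterization of the predicted log-log slope.

    The population is idealized as cells expressing the FP_1-10 fragment in
    fixed proportion ``expression_ratio`` to the FP_11 species, whose
    concentration sweeps ``b_range`` (evaluated on a log-spaced grid of
    ``n_points``).
    """

    kd: float
    expression_ratio: float = 2.0
    b_range: tuple[float, float] = (1.0, 1.0e4)
    n_points: int = 50

    def __post_init__(self) -> None:
        _check_nonneg("kd", self.kd)
        if not (np.isfinite(self.expression_ratio) and self.expression_ratio > 0):
            raise ValueError(f"expression_ratio must be > 0, got {self.expression_ratio!r}")
        lo, hi = self.b_range
        if not (np.isfinite(lo) and np.isfinite(hi) and 0 < lo < hi):
            raise ValueError(f"b_range must be strictly positive and ordered, got {self.b_range!r}")
        if self.n_points < 2:
            raise ValueError("n_points must be >= 2")


def complemented_concentration(system: BindingSystem) -> float | np.ndarray:
    """Equilibrium concentration of the complemented (fluorescent) complex.

    Solves ``(A - C)(B - C) = K_D * C`` for the root in ``[0, min(A, B)]``.
    The smaller quadratic root is evaluated in the cancellation-free form
    ``C = 2AB / (A + B + K_D + sqrt((A + B + K_D)^2 - 4AB))`` so that the
    weak-binding limit (K_D much larger than the concentrations) stays
    accurate.  ``kd = 0`` gives ``min(A, B)``.
    """
    a = np.asarray(system.a_total, dtype=float)
    b = np.asarray(system.b_total, dtype=float)
    kd = np.asarray(system.kd, dtype=float)
    s = a + b + kd
    disc = np.maximum(s * s - 4.0 * a * b, 0.0)
    denom = s + np.sqrt(disc)
    with np.errstate(invalid="ignore"):
        c = np.where(denom > 0, 2.0 * a * b / np.where(denom > 0, denom, 1.0), 0.0)
    c = np.minimum(c, np.minimum(a, b))  # guard FP round-off at kd ~ 0
    if np.ndim(system.a_total) == 0 and np.ndim(system.b_total) == 0 and np.ndim(system.kd) == 0:
        return float(c)
    return c


def predicted_slope(theory: SlopeTheoryInput) -> float:
    """Model-predicted log-log slope of complemented signal versus expression.

    Ordinary least squares of log10 C on log10 B over a log-spaced grid of B
    with A = expression_ratio * B, mirroring how the slope is measured from a
    scatter of cells rather than as a point derivative.  Lies in (1, 2) for
    finite positive K_D and approaches 2 (1) when K_D is far above (below)
    the concentration range.
    """
    lo, hi = theory.b_range
    b = np.logspace(np.log10(lo), np.log10(hi), theory.n_points)
    a = theory.expression_ratio * b
    c = complemented_concentration(BindingSystem(a, b, theory.kd))
    return float(linregress(np.log10(b), np.log10(c)).slope)


def tandem_free_fragment(system: TandemSystem) -> float:
    """Free FP_1-10 concentration for a tandem-tag system.

    With n identical independent FP_11 sites at total site concentration
    ``n * b_tags`` sharing one FP_1-10 pool, mass conservation reads
    ``a + n * b_tags * a / (a + kd) = a_total``; the positive root of the
    equivalent quadratic ``a^2 + a (kd + n b - a_total) - a_total kd = 0``
    is returned, again in a cancellation-safe form.
    """
    at = float(system.a_total)
    nb = system.n_repeats * float(system.b_tags)
    kd = float(system.kd)
    if at == 0.0:
        return 0.0
    p = kd + nb - at
    disc = p * p + 4.0 * at * kd
    root = np.sqrt(disc)
    if p <= 0:
        a = 0.5 * (-p + root)
    else:
        # small-a branch: avoid (-p + root) cancellation
        a = 2.0 * at * kd / (p + root)
    return float(a)


def tandem_signal(system: TandemSystem) -> float:
    """Expected number of complemented fluorophores per tagged molecule.

    Equals ``n * theta`` with per-site occupancy ``theta = a/(a + kd)`` at
    the self-consistent free fragment concentration; bounded by ``n``.
    """
    if system.kd == 0.0:
        # all fragment binds until sites or pool run out
        if system.b_tags == 0.0:
            return 0.0
        bound = min(system.a_total, system.n_repeats * system.b_tags)
        return float(min(bound / system.b_tags, float(system.n_repeats)))
    a = tandem_free_fragment(system)
    # occupancy form: cancellation-free even when binding is vanishingly weak
    return float(system.n_repeats * a / (a + system.kd))


def amplification_fold(n: int, a_total: float, b_tags: float, kd: float) -> float:
    """Signal gain of an n-copy tandem tag over a single tag.

    Ratio of per-molecule signals at identical FP_1-10 pool, tagged-molecule
    concentration and per-site K_D.  Lies in [1, n]; reaches n only when the
    FP_1-10 pool saturates every site, which is why finite expression gives
    sub-linear amplification.
    """
    s1 = tandem_signal(TandemSystem(1, a_total, b_tags, kd))
    if s1 == 0.0:
        raise ZeroDivisionError("single-tag signal is zero; amplification fold undefined")
    sn = tandem_signal(TandemSystem(n, a_total, b_tags, kd))
    return float(sn / s1)
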