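"""Steady-state insulin balance model and excess beta cell mass (EBCM).

The model treats plasma insulin as a balance between a source proportional
to beta cell mass (maximum per-mass secretion rate ``q_max``) and a
clearance sink proportional to the plasma concentration and the body's
distribution volume ``W/rho``:

    dN/dt = q_max * BCM - k_clr * C_I * W / rho,      C_I = N * rho / W.

Setting ``dN/dt = 0`` at the fasting steady state and asking what beta cell
mass just maintains euglycemia at the fasting insulin set-point gives a
minimum required mass proportional to body weight,

    BCM_min(a) = alpha * W(a),     alpha = k_clr * C_I_fast / (rho * q_max),

where ``alpha`` lumps the mechanistic constants into a single demand
parameter (BCM-units per kg).  Total mass splits into minimum plus reserve,
``BCM = BCM_min + BCM_excess``, and the normalized excess beta cell mass

    EBCM(a) = 1 - alpha * W(a) / BCM(a)

is the fraction of an age-matched individual's beta cells that can be lost
before hyperglycemia — histologically, the tolerable fraction of
insulin-deficient islets.  Because body weight keeps rising through age 20
while beta cell mass plateaus, EBCM declines with age: onset of type 1
diabetes requires destroying far less mass in a 20-year-old than in an
infant.

The fasting steady state from the same balance,

    C_I = q_max * rho * BCM / (k_clr * W),

predicts fasting insulin for any remaining mass; plasma C-peptide, secreted
1:1 with insulin, is modelled as ``gamma * C_I`` with a disease-state
independent proportionality constant ``gamma``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .curves import AgeCurve

__all__ = [
    "PhysiologyModel",
    "EBCMPrediction",
    "FixedThresholdEBCM",
    "minimum_bcm",
    "excess_bcm",
    "steady_state_insulin",
    "predicted_cpeptide",
    "insulin_balance_rhs",
    "fixed_threshold_ebcm",
]


@dataclass(frozen=True)
class EBCMPrediction:
    """Model-predicted beta cell mass budget at one age.

    ``ebcm = 1 - bcm_min / bcm_total`` exactly; negative values are
    meaningful (insulin demand exceeds the total mass).
    """

    age: float
    bcm_total: float
    bcm_min: float
    ebcm: float

    @property
    def bcm_excess(self) -> float:
        """Reserve mass above the minimum; equals ``ebcm * bcm_total``."""
        return self.bcm_total - self.bcm_min


@dataclass(frozen=True)
class PhysiologyModel:
    """Insulin balance model parameters plus the two age curves.

    Parameters
    ----------
    alpha : float
        Lumped demand parameter, BCM-units per kg of body weight.
    weight_curve : AgeCurve
        Body weight W(a) in kg (average of male and female charts).
    bcm_curve : AgeCurve
        Total beta cell mass BCM(a) in BCM-units (density x pancreas volume).
    qmax, kclr, rho, gamma : float, optional
        Mechanistic constants (max secretion per mass, insulin clearance
        rate, body density, C-peptide/insulin proportionality).  They cancel
        out of EBCM and are only identifiable jointly through ``alpha``;
        defaults of 1 leave concentrations in set-point units.
    """

    alpha: float
    weight_curve: AgeCurve
    bcm_curve: AgeCurve
    qmax: float = 1.0
    kclr: float = 1.0
    rho: float = 1.0
    gamma: float = 1.0

    def __post_init__(self) -> None:
        for name in ("alpha", "qmax", "kclr", "rho", "gamma"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be finite and > 0, got {v}")
        lo = max(self.weight_curve.domain[0], self.bcm_curve.domain[0])
        hi = min(self.weight_curve.domain[1], self.bcm_curve.domain[1])
        if lo >= hi:
            raise ValueError("weight and BCM curves have non-overlapping age domains")

    @property
    def set_point(self) -> float:
        """Fasting insulin concentration when BCM = BCM_min: q_max*rho*alpha/k_clr."""
        return self.qmax * self.rho * self.alpha / self.kclr

    def with_alpha(self, alpha: float) -> "PhysiologyModel":
        return replace(self, alpha=alpha)

    # -- model quantities ---------------------------------------------------

    def minimum_bcm(self, age):
        """Minimum beta cell mass for euglycemia: alpha * W(age)."""
        return self.alpha * self.weight_curve.evaluate(age)

    def excess_bcm(self, age: float) -> EBCMPrediction:
        """Normalized excess beta cell mass at ``age`` (may be negative)."""
        total = self.bcm_curve.evaluate(age)
        if total <= 0:
            raise ValueError(f"BCM curve non-positive at age {age}: {total}")
        bcm_min = self.minimum_bcm(age)
        return EBCMPrediction(
            age=float(age),
            bcm_total=float(total),
            bcm_min=float(bcm_min),
            ebcm=float(1.0 - bcm_min / total),
        )

    def ebcm(self, age):
        """Vectorized EBCM(age) = 1 - alpha*W(age)/BCM(age)."""
        total = np.asarray(self.bcm_curve.evaluate(age), dtype=float)
        if np.any(total <= 0):
            raise ValueError("BCM curve non-positive inside requested age range")
        out = 1.0 - self.alpha * np.asarray(self.weight_curve.evaluate(age)) / total
        return float(out) if out.ndim == 0 else out

    def steady_state_insulin(self, bcm, age):
        """Fasting insulin C_I = q_max*rho*bcm/(k_clr*W(age))."""
        if np.any(np.asarray(bcm) < 0):
            raise ValueError("bcm must be non-negative")
        w = np.asarray(self.weight_curve.evaluate(age), dtype=float)
        if np.any(w <= 0):
            raise ValueError("body weight must be positive")
        out = self.qmax * self.rho * np.asarray(bcm, dtype=float) / (self.kclr * w)
        return float(out) if out.ndim == 0 else out

    def predicted_cpeptide(self, bcm, age):
        """Plasma C-peptide: gamma x fasting insulin; falls below the
        set-point when bcm < alpha*W(age)."""
        out = self.gamma * np.asarray(self.steady_state_insulin(bcm, age))
        return float(out) if out.ndim == 0 else out

    def insulin_balance_rhs(self, n_insulin: float, bcm: float, age: float) -> float:
        """Right-hand side of the transient insulin balance dN/dt.

        With C_I = N*rho/W the clearance term k_clr*C_I*W/rho collapses to
        k_clr*N, so dN/dt = q_max*bcm - k_clr*N.  Exposed for completeness;
        every quantity the analysis uses comes from its steady state.
        """
        return self.qmax * bcm - self.kclr * n_insulin


@dataclass(frozen=True)
class FixedThresholdEBCM:
    """Age-independent comparator: the classic fixed destruction threshold.

    Represents the conventional claim that onset occurs once a fixed
    fraction (commonly quoted as 80-95%) of beta cells is destroyed,
    regardless of age.
    """

    threshold: float

    def __post_init__(self) -> None:
        if not (0.0 < self.threshold < 1.0):
            raise ValueError(f"threshold must lie in (0, 1), got {self.threshold}")

    def ebcm(self, age):
        age_arr = np.asarray(age, dtype=float)
        out = np.full(age_arr.shape, self.threshold)
        return self.threshold if out.ndim == 0 else out

    __call__ = ebcm


# -- functional wrappers (module-level operation surface) --------------------


def minimum_bcm(model: PhysiologyModel, age):
    return model.minimum_bcm(age)


def excess_bcm(model: PhysiologyModel, age: float) -> EBCMPrediction:
    return model.excess_bcm(age)


def steady_state_insulin(model: PhysiologyModel, bcm, age):
    return model.steady_state_insulin(bcm, age)


def predicted_cpeptide(model: PhysiologyModel, bcm, age):
    return model.predicted_cpeptide(bcm, age)


def insulin_balance_rhs(model: PhysiologyModel, n_insulin, bcm, age):
    return model.insulin_balance_rhs(n_insulin, bcm, age)


def fixed_threshold_ebcm(threshold: float) -> FixedThresholdEBCM:
    return FixedThresholdEBCM(threshold)
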