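"""Closed-form wetting theory at the contact line.

Two results are implemented:

* **Isoperimetric feasibility of complete engulfment.**  Any closed
  surface satisfies A^3 >= 36 pi V^2, with equality for a sphere.
  Applying this to the inner leaflet of a membrane that completely
  engulfs a droplet of volume V_alpha (segment areas A_ag, A_bg; interior
  phase volume V_gamma) gives the necessary conditions

      A_ag + A_bg >= (36 pi)^(1/3) [V_alpha^(2/3) + (V_alpha+V_gamma)^(2/3)]
      V_alpha <= (A_ag + A_bg)^(3/2) / (2^(3/2) (36 pi)^(1/2)) = V_alpha_max

  The bound V_alpha_max is the V_gamma = 0 limit, where the inner leaflet
  forms two nested spheres that touch.

* **Contact-line tension from the force balance.**  For an axisymmetric
  partially engulfed droplet, the tangential force balance along the
  circular contact line reads

      Sigma_bg - Sigma_ag = Sigma_ab cos(theta_alpha*) + (lambda/R_co) cos(psi_co)

  which is solved for the line tension lambda given the three surface
  tensions and the measured contact geometry.  Uncertainties propagate to
  lambda assuming independent input errors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

_ISO = 36.0 * np.pi


class WettingError(ValueError):
    pass


@dataclass
class EngulfmentAreasVolumes:
    """Inner-leaflet segment areas and phase volumes (units d^2, d^3)."""

    A_ag: float
    A_bg: float
    V_alpha: float
    V_gamma: float | None = None

    def __post_init__(self):
        vals = [self.A_ag, self.A_bg, self.V_alpha]
        if self.V_gamma is not None:
            vals.append(self.V_gamma)
        if any(v < 0 for v in vals):
            raise WettingError("areas and volumes must be non-negative")

    @property
    def A(self) -> float:
        return self.A_ag + self.A_bg


@dataclass
class FeasibilityVerdict:
    feasible: bool
    V_alpha_max: float
    slack_loose: float       # V_alpha_max - V_alpha
    slack_tight: float | None  # A - required area (with V_gamma), if known


def isoperimetric_ratio(area: float, volume: float) -> float:
    """A^3 / (36 pi V^2); equals 1 for a sphere, > 1 otherwise."""
    if volume <= 0:
        return float("inf")
    return area ** 3 / (_ISO * volume ** 2)


def v_alpha_max(A_ag: float, A_bg: float) -> float:
    """Largest completely engulfable droplet volume for given segment areas."""
    A = A_ag + A_bg
    return A ** 1.5 / (2.0 ** 1.5 * _ISO ** 0.5)


def required_area(V_alpha: float, V_gamma: float) -> float:
    """Minimal inner-leaflet area enclosing both phases after engulfment."""
    return _ISO ** (1.0 / 3.0) * (V_alpha ** (2.0 / 3.0)
                                  + (V_alpha + V_gamma) ** (2.0 / 3.0))


def isoperimetric_check(g: EngulfmentAreasVolumes) -> FeasibilityVerdict:
    """Feasibility of complete engulfment for the given areas/volumes.

    Evaluates the loose bound V_alpha <= V_alpha_max always, and the
    tighter area condition when V_gamma is supplied; feasible iff both
    hold.
    """
    vmax = v_alpha_max(g.A_ag, g.A_bg)
    feasible = g.V_alpha <= vmax * (1.0 + 1e-12)
    slack_tight = None
    if g.V_gamma is not None:
        need = required_area(g.V_alpha, g.V_gamma)
        slack_tight = g.A - need
        feasible = feasible and (g.A >= need * (1.0 - 1e-12))
    return FeasibilityVerdict(feasible=feasible, V_alpha_max=vmax,
                              slack_loose=vmax - g.V_alpha,
                              slack_tight=slack_tight)


@dataclass
class LineTensionInput:
    """Inputs to the contact-line force balance (angles in degrees)."""

    Sigma_ab: float
    Sigma_ag: float
    Sigma_bg: float
    theta_alpha_star: float
    psi_co: float
    R_co: float
    Sigma_ab_sem: float = 0.0
    Sigma_ag_sem: float = 0.0
    Sigma_bg_sem: float = 0.0
    theta_sem: float = 0.0     # degrees
    psi_sem: float = 0.0       # degrees
    R_co_sem: float = 0.0


@dataclass
class LineTensionResult:
    line_tension: float        # lambda, kBT/d
    sem: float


def line_tension_force_balance(inp: LineTensionInput,
                               min_cos_psi: float = 0.05) -> LineTensionResult:
    """Solve the tangential force balance for the line tension lambda.

        lambda = R_co [Sigma_bg - Sigma_ag - Sigma_ab cos(theta_a*)] / cos(psi_co)

    Raises for |cos psi_co| below ``min_cos_psi`` (ill-conditioned
    balance: the line-tension force has no in-plane component).  The SEM
    uses first-order propagation with independent inputs.
    """
    th = np.radians(inp.theta_alpha_star)
    ps = np.radians(inp.psi_co)
    cth, cps = np.cos(th), np.cos(ps)
    if abs(cps) < min_cos_psi:
        raise WettingError(
            f"ill-conditioned balance: |cos(psi_co)| = {abs(cps):.3f} < "
            f"{min_cos_psi}")
    num = inp.Sigma_bg - inp.Sigma_ag - inp.Sigma_ab * cth
    lam = inp.R_co * num / cps
    # partial derivatives for error propagation
    d_ab = -inp.R_co * cth / cps
    d_ag = -inp.R_co / cps
    d_bg = inp.R_co / cps
    d_th = inp.R_co * inp.Sigma_ab * np.sin(th) / cps
    d_ps = inp.R_co * num * np.sin(ps) / cps ** 2
    d_R = num / cps
    var = ((d_ab * inp.Sigma_ab_sem) ** 2
           + (d_ag * inp.Sigma_ag_sem) ** 2
           + (d_bg * inp.Sigma_bg_sem) ** 2
           + (d_th * np.radians(inp.theta_sem)) ** 2
           + (d_ps * np.radians(inp.psi_sem)) ** 2
           + (d_R * inp.R_co_sem) ** 2)
    return LineTensionResult(line_tension=float(lam), sem=float(np.sqrt(var)))
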