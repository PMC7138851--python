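"""Ping-pong kinetics of the glutaredoxin catalytic cycle.

Class I glutaredoxins (Grx) reduce glutathionylated disulfides (GSSR) in two
half-reactions: the oxidative half-reaction glutathionylates the active-site
cysteine (E + GSSR -> E-SSG + RS-), and the reductive half-reaction resolves
the enzyme-glutathione mixed disulfide with reduced glutathione
(E-SSG + GSH -> E + GSSG).  At steady state this ping-pong scheme obeys the
Dalziel relation

    e0 / v = phi0 + phi1 / [GSSR] + phi2 / [GSH]

where 1/phi1 and 1/phi2 are the apparent second-order rate constants of the
oxidative and reductive half-reactions and 1/phi0 is the true kcat.

The module also simulates the coupled photometric assay, in which the GSSG
product is re-reduced by glutathione reductase (GR) at the expense of NADPH,
whose consumption is followed as absorbance at 340 nm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "MicroscopicRates",
    "PingPongParameters",
    "AssayConditions",
    "FiniteGR",
    "ProgressCurve",
    "dalziel_rate",
    "phi_from_microscopic",
    "simulate_assay",
    "initial_rate",
]


def _require_positive(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if not math.isfinite(value) or value <= 0:
            raise ValueError(f"{name} must be positive and finite, got {value!r}")


@dataclass(frozen=True)
class MicroscopicRates:
    """Elementary rate constants of the two half-reactions.

    k1 / k_minus1 : association/dissociation of E with GSSR (M^-1 s^-1 / s^-1)
    k2            : oxidative chemical step, E.GSSR -> E-SSG + RS- (s^-1)
    k4 / k_minus4 : association/dissociation of E-SSG with GSH (M^-1 s^-1 / s^-1)
    k5            : reductive chemical step, E-SSG.GSH -> E + GSSG (s^-1)

    The chemical-step symbols k2 and k5 are a naming convention of this
    package; only the (dis)association constants carry canonical names.
    """

    k1: float
    k_minus1: float
    k2: float
    k4: float
    k_minus4: float
    k5: float

    def __post_init__(self) -> None:
        _require_positive(
            k1=self.k1, k2=self.k2, k4=self.k4, k5=self.k5,
        )
        for name in ("k_minus1", "k_minus4"):
            value = getattr(self, name)
            if not math.isfinite(value) or value < 0:
                raise ValueError(f"{name} must be non-negative and finite")


@dataclass(frozen=True)
class PingPongParameters:
    """Macroscopic Dalziel description of one enzyme/substrate pair.

    phi0 (s), phi1 (M s) for the glutathionylated-disulfide substrate and
    phi2 (M s) for GSH.  Reciprocals are derived properties.
    """

    phi0: float
    phi1: float
    phi2: float
    substrate_label: str = "GSSCys"

    def __post_init__(self) -> None:
        _require_positive(phi0=self.phi0, phi1=self.phi1, phi2=self.phi2)

    @property
    def k_ox(self) -> float:
        """Second-order rate constant of the oxidative half-reaction, 1/phi1."""
        return 1.0 / self.phi1

    @property
    def k_red(self) -> float:
        """Second-order rate constant of the reductive half-reaction, 1/phi2."""
        return 1.0 / self.phi2

    @property
    def kcat(self) -> float:
        """True turnover number, 1/phi0 (s^-1)."""
        return 1.0 / self.phi0


@dataclass(frozen=True)
class FiniteGR:
    """Michaelis-Menten description of the GR coupling step (robustness mode)."""

    vmax: float  # M/s
    km: float = 65e-6  # M, textbook-order Km of yeast GR for GSSG

    def __post_init__(self) -> None:
        _require_positive(vmax=self.vmax, km=self.km)


@dataclass(frozen=True)
class AssayConditions:
    """Composition of one coupled GSSCys/HEDS photometric assay."""

    enzyme0: float
    gssr0: float
    gsh0: float
    nadph0: float = 1e-4
    gr_activity: float = 1.0  # U/mL, informational under instantaneous coupling
    temperature_C: float = 25.0
    path_length_cm: float = 1.0
    epsilon_nadph: float = 6220.0  # M^-1 cm^-1 at 340 nm
    baseline_s: float = 30.0

    def __post_init__(self) -> None:
        _require_positive(
            epsilon_nadph=self.epsilon_nadph, path_length_cm=self.path_length_cm,
        )
        for name in ("enzyme0", "gssr0", "gsh0", "nadph0"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class ProgressCurve:
    """A340 time course of one simulated (or measured) assay."""

    time: np.ndarray
    a340: np.ndarray
    meta: AssayConditions
    nadph_exhausted: bool = False
    concentrations: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.a340 = np.asarray(self.a340, dtype=float)
        if self.time.shape != self.a340.shape:
            raise ValueError("time and a340 must have equal length")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")


def dalziel_rate(params: PingPongParameters, enzyme0, gssr, gsh):
    """Steady-state rate v = e0 / (phi0 + phi1/[GSSR] + phi2/[GSH]).

    Accepts scalars or broadcastable arrays for the concentrations.
    Raises on non-positive substrate concentrations.
    """
    gssr = np.asarray(gssr, dtype=float)
    gsh = np.asarray(gsh, dtype=float)
    enzyme0 = np.asarray(enzyme0, dtype=float)
    if np.any(gssr <= 0) or np.any(gsh <= 0):
        raise ValueError("substrate concentrations must be positive")
    if np.any(enzyme0 < 0):
        raise ValueError("enzyme0 must be >= 0")
    v = enzyme0 / (params.phi0 + params.phi1 / gssr + params.phi2 / gsh)
    return float(v) if v.ndim == 0 else v


def phi_from_microscopic(k: MicroscopicRates) -> PingPongParameters:
    """Map elementary rate constants onto the Dalziel coefficients.

    For the ping-pong scheme E <-> E.GSSR -> E-SSG <-> E-SSG.GSH -> E the
    steady-state solution gives

        phi1 = (k_minus1 + k2) / (k1 k2)
        phi2 = (k_minus4 + k5) / (k4 k5)
        phi0 = 1/k2 + 1/k5

    (verified in the test suite against the numerical steady state of the
    full four-species mass-action system).
    """
    phi1 = (k.k_minus1 + k.k2) / (k.k1 * k.k2)
    phi2 = (k.k_minus4 + k.k5) / (k.k4 * k.k5)
    phi0 = 1.0 / k.k2 + 1.0 / k.k5
    return PingPongParameters(phi0=phi0, phi1=phi1, phi2=phi2)


def _rhs_instantaneous(t, y, params, enzyme0):
    gssr, gsh, nadph = y
    if gssr <= 0 or gsh <= 0 or nadph <= 0:
        return [0.0, 0.0, 0.0]
    v = enzyme0 / (params.phi0 + params.phi1 / gssr + params.phi2 / gsh)
    # Per turnover: GSSR -1; GSH -1 (reductive step) +2 (GR regeneration
    # of the GSSG product) = net +1; NADPH -1 (consumed by GR).
    return [-v, +v, -v]


def _rhs_finite_gr(t, y, params, enzyme0, gr: FiniteGR):
    gssr, gsh, gssg, nadph = y
    v = 0.0
    if gssr > 0 and gsh > 0:
        v = enzyme0 / (params.phi0 + params.phi1 / gssr + params.phi2 / gsh)
    v_gr = 0.0
    if gssg > 0 and nadph > 0:
        v_gr = gr.vmax * gssg / (gr.km + gssg)
    return [-v, -v + 2.0 * v_gr, v - v_gr, -v_gr]


def simulate_assay(
    params: PingPongParameters,
    cond: AssayConditions,
    t_end: float,
    dt: float,
    finite_gr: FiniteGR | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-14,
) -> ProgressCurve:
    """Simulate the coupled NADPH/GR photometric assay.

    The substrate is added at t = cond.baseline_s; absorbance is flat before
    that.  GR coupling is instantaneous by default (every GSSG immediately
    reduced back to 2 GSH at the cost of one NADPH); pass ``finite_gr`` for an
    explicit Michaelis-Menten coupling step.
    """
    if t_end <= cond.baseline_s:
        raise ValueError("t_end must exceed the baseline duration")
    if dt <= 0:
        raise ValueError("dt must be positive")

    t_grid = np.arange(0.0, t_end + 0.5 * dt, dt)
    a0 = cond.epsilon_nadph * cond.path_length_cm * cond.nadph0
    a340 = np.full_like(t_grid, a0)
    post = t_grid >= cond.baseline_s

    conc: dict = {}
    exhausted = False
    if cond.enzyme0 > 0 and np.any(post):
        t_eval = t_grid[post] - cond.baseline_s
        span = (0.0, float(t_eval[-1]) if t_eval[-1] > 0 else dt)

        # stop cleanly when NADPH runs out; the curve plateaus afterwards
        if finite_gr is None:
            y0 = [cond.gssr0, cond.gsh0, cond.nadph0]
            rhs, args, nadph_idx = _rhs_instantaneous, (params, cond.enzyme0), 2
        else:
            y0 = [cond.gssr0, cond.gsh0, 0.0, cond.nadph0]
            rhs, args = _rhs_finite_gr, (params, cond.enzyme0, finite_gr)
            nadph_idx = 3

        def nadph_depleted(t, y, *_):
            return y[nadph_idx] - 1e-9 * cond.nadph0

        nadph_depleted.terminal = True
        nadph_depleted.direction = -1
        sol = solve_ivp(
            rhs, span, y0, t_eval=t_eval, method="LSODA",
            rtol=rtol, atol=atol, args=args, events=nadph_depleted,
        )
        y = sol.y
        if sol.status == 1:  # terminated at exhaustion: hold the last state
            exhausted = True
            n_have = y.shape[1]
            if n_have == 0:
                y = sol.y_events[0].T
                n_have = 1
            pad = len(t_eval) - n_have
            if pad > 0:
                y = np.hstack([y, np.tile(y[:, -1:], (1, pad))])
            y[nadph_idx] = np.where(
                np.arange(len(t_eval)) >= n_have - 1, 0.0, y[nadph_idx])
        if finite_gr is None:
            gssr, gsh, nadph = y
            gssg = np.zeros_like(gssr)
        else:
            gssr, gsh, gssg, nadph = y
        gssr = np.clip(gssr, 0.0, None)
        gsh = np.clip(gsh, 0.0, None)
        nadph = np.clip(nadph, 0.0, None)
        exhausted = exhausted or bool(nadph[-1] < 1e-6 * cond.nadph0)
        a340[post] = cond.epsilon_nadph * cond.path_length_cm * nadph
        conc = {"gssr": gssr, "gsh": gsh, "gssg": gssg, "nadph": nadph,
                "time": t_grid[post]}

    return ProgressCurve(
        time=t_grid, a340=a340, meta=replace(cond),
        nadph_exhausted=exhausted, concentrations=conc,
    )


def initial_rate(curve: ProgressCurve, window: float) -> float:
    """Initial rate (M/s) from the post-baseline slope of the A340 trace.

    Fits a least-squares line over ``window`` seconds starting at the end of
    the baseline and converts the slope with -slope/(epsilon * path).
    """
    cond = curve.meta
    t0, t1 = cond.baseline_s, cond.baseline_s + window
    mask = (curve.time >= t0) & (curve.time <= t1)
    if int(mask.sum()) < 3:
        raise ValueError("window must contain at least 3 samples")
    t = curve.time[mask]
    a = curve.a340[mask]
    slope = np.polyfit(t, a, 1)[0]
    return -slope / (cond.epsilon_nadph * cond.path_length_cm)
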