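"""Synthetic-data generators with packaged, literature-calibrated variants.

Every analysis stage in this package can be exercised without downloads:
the generators emit initial-rate grids, alkylation-protection profiles,
two-channel roGFP2 plate runs and GS- diffusion trajectories whose ground
truth is known, so parameter recovery can be verified end to end.

The packaged variant table encodes each ScGrx7/HsGrx5 mutant as fold-change
factors on a wild-type baseline: an oxidative factor scaling 1/phi1
(reaction with the glutathionylated substrate), a reductive factor scaling
1/phi2 (reaction with GSH), a thiol pKa, roGFP2 response parameters, and a
relative per-frame GS- binding propensity.  Quantities that are not printed
as absolute numbers in the primary literature (notably the wild-type Phi
baseline) are plausible placeholders flagged ``calibrated_not_measured``;
all headline comparisons are ratios, which are calibrated.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .kinetics import PingPongParameters, dalziel_rate
from .dalziel import RateGrid
from .pka import (
    AlkylationProtocol, ResidualActivityProfile, simulate_residual_activity,
)
from .rogfp2 import Well, PlateRun
from .trajectory import GsTrajectory, TrajectoryReplicate, DEFAULT_CUTOFF

__all__ = [
    "KineticFactors",
    "PKaParams",
    "RoGFP2Params",
    "MDParams",
    "NoiseModel",
    "VariantParameterSet",
    "available_variants",
    "load_variant",
    "generate_rate_grid",
    "generate_pka_profile",
    "generate_plate_run",
    "generate_gs_trajectory",
    "DEFAULT_GSH_LEVELS",
    "DEFAULT_GSSCYS_LEVELS",
]

# Wild-type ScGrx7 kinetic baseline.  Absolute wild-type Phi values are not
# printed in the primary text; these are order-of-magnitude placeholders
# (calibrated, not measured) -- every packaged comparison is a ratio.
WT_K_OX = 2.0e5    # 1/phi1, M^-1 s^-1
WT_K_RED = 5.0e4   # 1/phi2, M^-1 s^-1
WT_KCAT = 50.0     # 1/phi0, s^-1

# Assay concentration grid: GSH varied 50 uM - 1.5 mM at fixed GSSCys levels.
DEFAULT_GSSCYS_LEVELS = np.array([25e-6, 50e-6, 100e-6, 150e-6])
DEFAULT_GSH_LEVELS = np.geomspace(50e-6, 1.5e-3, 8)

# Baseline frame-level probability that any GS- is bound in a wild-type
# trajectory frame (only relative propensities are calibrated).
BASELINE_BOUND_P = 0.15

# Packaged roGFP2 channel endpoint spectra (arbitrary units): intensities of
# the fully reduced and fully oxidized probe.  I400 rises and I480 falls
# upon oxidation.
SPECTRA = {"i400_red": 200.0, "i480_red": 900.0,
           "i400_ox": 800.0, "i480_ox": 300.0}


@dataclass(frozen=True)
class KineticFactors:
    """Dalziel description relative to the wild-type baseline."""

    oxidative: float = 1.0   # scales 1/phi1
    reductive: float = 1.0   # scales 1/phi2
    kcat_factor: float = 1.0  # scales 1/phi0
    absolute: PingPongParameters | None = None  # overrides factors if set

    def parameters(self) -> PingPongParameters:
        if self.absolute is not None:
            return self.absolute
        return PingPongParameters(
            phi0=1.0 / (WT_KCAT * self.kcat_factor),
            phi1=1.0 / (WT_K_OX * self.oxidative),
            phi2=1.0 / (WT_K_RED * self.reductive),
        )


@dataclass(frozen=True)
class PKaParams:
    pka: float = 4.3
    top: float = 100.0
    bottom: float = 2.0
    hill: float = 1.0
    stability_factor: float = 1.0


@dataclass(frozen=True)
class RoGFP2Params:
    oxd_basal: float = 0.6        # steady-state OxD of the fusion construct
    activity_factor: float = 1.0  # scales the probe oxidation rate
    oxd_prereduced: float = 0.4   # OxD after DTT pretreatment and washout


@dataclass(frozen=True)
class MDParams:
    propensity_factor: float = 1.0  # per-frame bound probability vs wild type


@dataclass(frozen=True)
class NoiseModel:
    """Measurement-noise description for the generators."""

    kind: str = "none"  # none | multiplicative_gaussian | additive_gaussian
    sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("none", "multiplicative_gaussian", "additive_gaussian"):
            raise ValueError(f"unknown noise kind {self.kind!r}")
        if self.sd < 0:
            raise ValueError("sd must be >= 0")

    def apply(self, values: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        if self.kind == "none" or self.sd == 0:
            return values
        if self.kind == "multiplicative_gaussian":
            return values * (1.0 + self.sd * rng.standard_normal(values.shape))
        return values + self.sd * rng.standard_normal(values.shape)


@dataclass(frozen=True)
class VariantParameterSet:
    """All packaged parameters of one enzyme variant, with provenance notes."""

    label: str
    kinetic: KineticFactors = KineticFactors()
    pka: PKaParams = PKaParams()
    rogfp2: RoGFP2Params = RoGFP2Params()
    md: MDParams = MDParams()
    provenance: dict = field(default_factory=dict)
    calibrated_not_measured: tuple = ()


def _v(label, *, kinetic=None, pka=None, rogfp2=None, md=None,
       provenance=None, placeholders=()):
    return VariantParameterSet(
        label=label,
        kinetic=kinetic or KineticFactors(),
        pka=pka or PKaParams(),
        rogfp2=rogfp2 or RoGFP2Params(),
        md=md or MDParams(),
        provenance=provenance or {},
        calibrated_not_measured=tuple(placeholders),
    )


_HSGRX5_LOOP_PARAMS = PingPongParameters(
    phi0=1.0, phi1=1.0 / 2.0e3, phi2=1.0 / 5.0e3, substrate_label="GSSCys",
)

_VARIANTS: dict[str, VariantParameterSet] = {
    "WT": _v(
        "WT",
        pka=PKaParams(pka=4.3, stability_factor=1.05),
        provenance={
            "pka": "wild-type thiol pKa 4.3 +/- 0.1 (alkylation protection)",
            "kinetic": "wild-type baseline; absolute Phi values are "
                       "placeholders, comparisons are ratios",
            "rogfp2": "fusion ~60% oxidized at steady state; ~40% after DTT "
                      "pretreatment/washout",
            "md": "reference propensity, normalized to 100%",
        },
        placeholders=("kinetic.absolute_baseline",),
    ),
    "Y110F": _v(
        "Y110F", kinetic=KineticFactors(oxidative=1.1, reductive=1.0),
        provenance={"kinetic": "GSSCys efficiency almost identical or "
                               "slightly increased vs wild type"},
        placeholders=("kinetic.oxidative",),
    ),
    "Y110H": _v(
        "Y110H", kinetic=KineticFactors(oxidative=1.0 / 3.5, reductive=1.0),
        provenance={"kinetic": "three to four times lower efficiency for "
                               "GSSCys, GSH almost unchanged"},
    ),
    "Y110A": _v(
        "Y110A", kinetic=KineticFactors(oxidative=0.205, reductive=0.12),
        pka=PKaParams(pka=4.3),
        provenance={
            "kinetic": "GSSCys decreased to 18-23% (midpoint 20.5%), GSH to "
                       "9-15% (midpoint 12%) of wild type",
            "pka": "no significant pKa shift vs wild type",
        },
    ),
    "K105A": _v(
        "K105A", pka=PKaParams(pka=4.3),
        provenance={"pka": "no significant pKa shift vs wild type"},
        placeholders=("kinetic",),
    ),
    "K105E": _v(
        "K105E", kinetic=KineticFactors(oxidative=0.01, reductive=0.1),
        pka=PKaParams(pka=5.0),
        md=MDParams(propensity_factor=0.34),
        provenance={
            "pka": "pKa increased from 4.3 +/- 0.1 to 5.0 +/- 0.1",
            "md": "bound-state fraction decreased to ~34% of wild type",
            "kinetic": "charge inversion slows GSSCys reaction by about two "
                       "orders of magnitude (placeholder factors)",
        },
        placeholders=("kinetic",),
    ),
    "K105R": _v(
        "K105R", md=MDParams(propensity_factor=2.0),
        provenance={"md": "~2-fold increase of the bound-state fraction"},
        placeholders=("kinetic",),
    ),
    "K105Y": _v("K105Y", placeholders=("kinetic",)),
    "D144A": _v(
        "D144A", kinetic=KineticFactors(oxidative=0.815, reductive=1.0),
        provenance={"kinetic": "GSSCys coefficient decreased by 17-20% "
                               "(midpoint 18.5%), GSH unchanged"},
    ),
    "D144K": _v(
        "D144K", kinetic=KineticFactors(oxidative=0.815, reductive=1.7),
        provenance={"kinetic": "1.7-fold increased reciprocal Dalziel "
                               "coefficient for GSH; GSSCys decreased 17-20%"},
    ),
    "E147A": _v(
        "E147A",
        provenance={"kinetic": "no effect on either half-reaction"},
    ),
    "E147K": _v(
        "E147K", kinetic=KineticFactors(oxidative=1.0, reductive=2.5),
        md=MDParams(propensity_factor=2.2),
        provenance={
            "kinetic": "2.5-fold increased reciprocal Dalziel coefficient "
                       "for GSH; GSSCys unchanged",
            "md": "bound-state fraction increased by 2.2-fold",
        },
    ),
    "R153A": _v(
        "R153A", kinetic=KineticFactors(oxidative=0.40, reductive=1.0),
        provenance={"kinetic": "GSSCys coefficient reduced by 60%; minor "
                               "effect on GSH"},
    ),
    "R153E": _v(
        "R153E", kinetic=KineticFactors(oxidative=0.40, reductive=0.5),
        provenance={"kinetic": "charge inversion also slows the reductive "
                               "half-reaction (placeholder magnitude)"},
        placeholders=("kinetic.reductive",),
    ),
    "E170A": _v(
        "E170A", kinetic=KineticFactors(oxidative=0.5, reductive=1.0),
        pka=PKaParams(pka=4.3),
        provenance={"pka": "scaffold-site negative control, pKa unchanged",
                    "kinetic": "scaffold-site reference (placeholder factor)"},
        placeholders=("kinetic.oxidative",),
    ),
    "C108S": _v(
        "C108S", kinetic=KineticFactors(oxidative=1e-6, reductive=1e-6),
        rogfp2=RoGFP2Params(oxd_basal=0.75, activity_factor=0.0,
                            oxd_prereduced=0.15),
        provenance={"rogfp2": "active-site mutant 70-80% oxidized at steady "
                              "state and unresponsive to H2O2"},
    ),
    "roGFP2": _v(
        "roGFP2", kinetic=KineticFactors(oxidative=1e-6, reductive=1e-6),
        rogfp2=RoGFP2Params(oxd_basal=0.75, activity_factor=0.0,
                            oxd_prereduced=0.15),
        provenance={"rogfp2": "unfused probe, 70-80% oxidized, unresponsive"},
    ),
    "ScGrx7-WP": _v(
        "ScGrx7-WP", kinetic=KineticFactors(oxidative=0.1, reductive=1.0),
        rogfp2=RoGFP2Params(oxd_basal=0.95, activity_factor=0.1,
                            oxd_prereduced=0.15),
        provenance={"kinetic": "WP-motif predominantly slows the oxidative "
                               "half-reaction (placeholder magnitude)"},
        placeholders=("kinetic.oxidative",),
    ),
    "ScGrx7-loop": _v(
        "ScGrx7-loop", kinetic=KineticFactors(oxidative=5e-3, reductive=5e-3),
        rogfp2=RoGFP2Params(oxd_basal=0.8, activity_factor=5e-3,
                            oxd_prereduced=0.15),
        provenance={"kinetic": "elongated loop lowers both half-reactions by "
                               "more than two orders of magnitude"},
    ),
    "ScGrx7-WP+loop": _v(
        "ScGrx7-WP+loop", kinetic=KineticFactors(oxidative=1e-3, reductive=5e-3),
        rogfp2=RoGFP2Params(oxd_basal=0.8, activity_factor=1e-3,
                            oxd_prereduced=0.15),
        provenance={"kinetic": "lower activity than the loop variant, "
                               "rate-limiting oxidative half-reaction"},
        placeholders=("kinetic",),
    ),
    "HsGrx5": _v(
        "HsGrx5",
        kinetic=KineticFactors(absolute=PingPongParameters(
            phi0=1.0, phi1=1.0 / 100.0, phi2=1.0 / 100.0)),
        rogfp2=RoGFP2Params(oxd_basal=0.8, activity_factor=0.01,
                            oxd_prereduced=0.15),
        md=MDParams(propensity_factor=1.0),
        provenance={"kinetic": "activity too low (<= 1e2 M^-1 s^-1) for "
                               "reliable constants; packaged at that bound"},
        placeholders=("kinetic",),
    ),
    "HsGrx5-RR": _v(
        "HsGrx5-RR",
        kinetic=KineticFactors(absolute=PingPongParameters(
            phi0=1.0, phi1=1.0 / 100.0, phi2=1.0 / 100.0)),
        md=MDParams(propensity_factor=0.8),
        provenance={"kinetic": "activity too low for reliable constants"},
        placeholders=("kinetic", "md"),
    ),
    "HsGrx5-loop": _v(
        "HsGrx5-loop",
        kinetic=KineticFactors(absolute=_HSGRX5_LOOP_PARAMS),
        rogfp2=RoGFP2Params(oxd_basal=0.8, activity_factor=0.02,
                            oxd_prereduced=0.15),
        md=MDParams(propensity_factor=0.8),
        provenance={"kinetic": "reciprocal Dalziel coefficients around "
                               "2e3 M^-1 s^-1 (GSSCys) and 5e3 M^-1 s^-1 "
                               "(GSH); Phi0 placeholder",
                    "rogfp2": "up to twofold AUC increase vs HsGrx5"},
        placeholders=("kinetic.phi0", "md"),
    ),
    "HsGrx5-RR+loop": _v(
        "HsGrx5-RR+loop",
        kinetic=KineticFactors(absolute=PingPongParameters(
            phi0=1.0, phi1=1.0 / 100.0, phi2=1.0 / 100.0)),
        md=MDParams(propensity_factor=0.7),
        provenance={"kinetic": "activity too low for reliable constants"},
        placeholders=("kinetic", "md"),
    ),
}

_ALIASES = {
    "SCGRX7": "WT", "WILDTYPE": "WT", "WILD-TYPE": "WT",
    "SCGRX7-WP": "ScGrx7-WP", "SCGRX7-LOOP": "ScGrx7-loop",
    "SCGRX7-WP+LOOP": "ScGrx7-WP+loop",
    "HSGRX5": "HsGrx5", "HSGRX5-RR": "HsGrx5-RR",
    "HSGRX5-LOOP": "HsGrx5-loop", "HSGRX5-RR+LOOP": "HsGrx5-RR+loop",
    "ROGFP2": "roGFP2",
}


def available_variants() -> list[str]:
    return sorted(_VARIANTS)


def load_variant(label: str) -> VariantParameterSet:
    """Look up a packaged variant parameter set by label."""
    key = label.strip()
    if key in _VARIANTS:
        return _VARIANTS[key]
    upper = key.upper().replace("^", "-").replace("_", "-")
    if upper in _ALIASES:
        return _VARIANTS[_ALIASES[upper]]
    if upper in {k.upper() for k in _VARIANTS}:
        match = next(k for k in _VARIANTS if k.upper() == upper)
        return _VARIANTS[match]
    raise KeyError(
        f"unknown variant {label!r}; available: {', '.join(available_variants())}"
    )


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------

def generate_rate_grid(
    vset: VariantParameterSet,
    noise: NoiseModel | None = None,
    gssr_levels: np.ndarray = DEFAULT_GSSCYS_LEVELS,
    gsh_levels: np.ndarray = DEFAULT_GSH_LEVELS,
    enzyme0: float = 10e-9,
    n_replicates: int = 1,
) -> RateGrid:
    """Initial rates on the assay concentration grid for one variant.

    Evaluates the Dalziel rate law for the variant's parameters at every
    (GSSCys, GSH) combination (defaults: GSH 50 uM - 1.5 mM at fixed GSSCys
    25/50/100/150 uM) and applies the noise model.
    """
    noise = noise or NoiseModel()
    rng = np.random.default_rng(noise.seed)
    params = vset.kinetic.parameters()
    rows = []
    for rep in range(n_replicates):
        for gssr in np.asarray(gssr_levels, dtype=float):
            for gsh in np.asarray(gsh_levels, dtype=float):
                rows.append({
                    "gssr_M": gssr, "gsh_M": gsh, "enzyme_M": enzyme0,
                    "rate_M_per_s": dalziel_rate(params, enzyme0, gssr, gsh),
                    "replicate": rep,
                })
    df = pd.DataFrame(rows)
    df["rate_M_per_s"] = np.clip(
        noise.apply(df["rate_M_per_s"].to_numpy(), rng), 0.0, None
    )
    return RateGrid(
        df, substrate_label=params.substrate_label, variant_label=vset.label,
        meta={"seed": noise.seed, "noise": noise.kind, "sd": noise.sd,
              "provenance": vset.provenance.get("kinetic", "")},
    )


def generate_pka_profile(
    vset: VariantParameterSet,
    noise: NoiseModel | None = None,
    mode: str = "hill",
    protocol: AlkylationProtocol | None = None,
    **shape,
) -> ResidualActivityProfile:
    """Alkylation-protection profile for one variant (see pka module).

    Extra keyword arguments (``k_alk``, ``top``, ...) override the packaged
    shape parameters and are forwarded to the mechanistic/hill generator.
    """
    noise = noise or NoiseModel()
    rng = np.random.default_rng(noise.seed)
    p = vset.pka
    kwargs = dict(top=p.top, bottom=p.bottom, hill=p.hill,
                  stability_factor=p.stability_factor)
    kwargs.update(shape)
    profile = simulate_residual_activity(
        pka=p.pka, mode=mode, protocol=protocol,
        variant_label=vset.label, **kwargs,
    )
    residual = np.clip(noise.apply(profile.residual_pct, rng), 0.0, None)
    return ResidualActivityProfile(
        ph=profile.ph, residual_pct=residual, variant_label=vset.label,
        meta={**profile.meta, "seed": noise.seed, "noise": noise.kind,
              "provenance": vset.provenance.get("pka", "")},
    )


def _oxd_curve(t, oxd0, activity_factor, dose,
               k_probe=0.12, dose_k=2e-4, tau=30.0):
    """Phenomenological probe response to a dose-dependent GSSG pulse.

    dOxD/dt = k_probe * c(dose) * exp(-t/tau) * (1 - OxD) with
    c(dose) = dose / (dose + dose_k); closed-form solution used directly.
    """
    c = dose / (dose + dose_k) if dose > 0 else 0.0
    rate = k_probe * activity_factor * c
    expo = rate * tau * (1.0 - np.exp(-np.asarray(t, dtype=float) / tau))
    return 1.0 - (1.0 - oxd0) * np.exp(-expo)


def generate_plate_run(
    vset: VariantParameterSet,
    doses=(0.0, 2e-5, 5e-5, 2e-4, 1e-3),
    noise: NoiseModel | None = None,
    n_replicates: int = 3,
    dt: float = 12.0,
    t_end: float = 60.0,
    pre_reduced: bool = False,
    extra_constructs: tuple = (),
) -> PlateRun:
    """Two-channel plate run for one construct (plus optional extras).

    Channel intensities are convex mixtures of the packaged reduced/oxidized
    spectra, so OxD computed from the emitted intensities reproduces the
    prescribed OxD(t) exactly before noise.  DTT/diamide control wells are
    always included; the DTT-pretreatment protocol is represented by a lower
    initial OxD (``pre_reduced=True``).
    """
    noise = noise or NoiseModel()
    rng = np.random.default_rng(noise.seed)
    t = np.arange(0.0, t_end + 0.5 * dt, dt)
    wells: list[Well] = []

    def intensities(oxd):
        oxd = np.asarray(oxd, dtype=float)
        i400 = oxd * SPECTRA["i400_ox"] + (1 - oxd) * SPECTRA["i400_red"]
        i480 = oxd * SPECTRA["i480_ox"] + (1 - oxd) * SPECTRA["i480_red"]
        i400 = np.clip(noise.apply(i400, rng), 1e-6, None)
        i480 = np.clip(noise.apply(i480, rng), 1e-6, None)
        return i400, i480

    ones = np.ones_like(t)
    i400, i480 = intensities(0.0 * ones)
    wells.append(Well("red", "reduced_control", t, i400, i480,
                      construct_label="control"))
    i400, i480 = intensities(1.0 * ones)
    wells.append(Well("ox", "oxidized_control", t, i400, i480,
                      construct_label="control"))

    for construct in (vset,) + tuple(extra_constructs):
        r = construct.rogfp2
        oxd0 = r.oxd_prereduced if pre_reduced else r.oxd_basal
        for rep in range(n_replicates):
            oxd = _oxd_curve(t, oxd0, r.activity_factor, 0.0)
            i400, i480 = intensities(oxd)
            wells.append(Well(
                f"{construct.label}-untreated-r{rep}", "untreated", t, i400,
                i480, dose_h2o2=0.0, construct_label=construct.label,
                replicate=rep,
            ))
            for dose in doses:
                if dose == 0.0:
                    continue
                oxd = _oxd_curve(t, oxd0, r.activity_factor, float(dose))
                i400, i480 = intensities(oxd)
                wells.append(Well(
                    f"{construct.label}-d{dose:g}-r{rep}", "sample", t, i400,
                    i480, dose_h2o2=float(dose),
                    construct_label=construct.label, replicate=rep,
                ))
    return PlateRun(wells, meta={"seed": noise.seed, "noise": noise.kind,
                                 "pre_reduced": pre_reduced})


def generate_gs_trajectory(
    vset: VariantParameterSet,
    n_replicates: int = 4,
    n_frames: int = 5000,
    seed: int = 0,
    n_gs: int = 10,
    baseline_p: float = BASELINE_BOUND_P,
    box_half: float = 30.0,
    step_sd: float = 2.0,
    persistence: float = 0.0,
    cutoff: float = DEFAULT_CUTOFF,
    frame_interval_ps: float = 20.0,
) -> GsTrajectory:
    """Confined GS- diffusion around a fixed disulfide with tunable binding.

    The frame-level probability that at least one GS- is bound equals
    ``baseline_p * vset.md.propensity_factor`` exactly: per-particle bound
    indicators are drawn from the stationary occupancy of a two-state
    (bound/unbound) chain with per-particle probability
    q = 1 - (1 - p)**(1/n_gs).  With ``persistence`` = 0 (default) frames
    are independent, so per-replication bound fractions are binomial.
    Bound sulfurs are placed uniformly inside the cutoff sphere around the
    disulfide midpoint; unbound sulfurs follow a reflected random walk kept
    outside the sphere.  Defaults emulate 4 replications saved every 20 ps;
    the full production scale is 25,000 frames per replication (500 ns).
    """
    if n_replicates < 1:
        raise ValueError("need >= 1 replicate")
    if not 0.0 <= persistence < 1.0:
        raise ValueError("persistence must lie in [0, 1)")
    p = float(np.clip(baseline_p * vset.md.propensity_factor, 0.0, 0.95))
    q = 1.0 - (1.0 - p) ** (1.0 / n_gs) if p > 0 else 0.0

    # fixed active-site disulfide: ~2.05 A S-S bond centered at the origin
    disulfide = np.array([[-1.025, 0.0, 0.0], [1.025, 0.0, 0.0]])
    mid = disulfide.mean(axis=0)

    rng = np.random.default_rng(seed)
    reps = []
    for r in range(n_replicates):
        # two-state occupancy chain, started at stationarity
        bound = np.empty((n_frames, n_gs), dtype=bool)
        bound[0] = rng.random(n_gs) < q
        if persistence == 0.0:
            bound[1:] = rng.random((n_frames - 1, n_gs)) < q
        else:
            p_on = q * (1.0 - persistence) / (1.0 - q) if q < 1 else 1.0
            p_on = min(p_on, 1.0)
            u = rng.random((n_frames - 1, n_gs))
            for i in range(1, n_frames):
                stay = bound[i - 1] & (u[i - 1] < persistence)
                switch_on = ~bound[i - 1] & (u[i - 1] < p_on)
                bound[i] = stay | switch_on

        # positions
        pos = np.empty((n_frames, n_gs, 3))
        walk = rng.uniform(-box_half, box_half, size=(n_gs, 3))
        sphere_dirs = rng.standard_normal((n_frames, n_gs, 3))
        sphere_dirs /= np.linalg.norm(sphere_dirs, axis=-1, keepdims=True)
        radii = cutoff * 0.999 * rng.random((n_frames, n_gs)) ** (1.0 / 3.0)
        steps = rng.normal(0.0, step_sd, size=(n_frames, n_gs, 3))
        for i in range(n_frames):
            walk = walk + steps[i]
            # reflect into the box
            walk = np.where(walk > box_half, 2 * box_half - walk, walk)
            walk = np.where(walk < -box_half, -2 * box_half - walk, walk)
            # keep unbound particles outside the binding shell
            d = np.linalg.norm(walk - mid, axis=-1)
            inside = d <= cutoff
            if inside.any():
                dirs = (walk[inside] - mid)
                norms = np.linalg.norm(dirs, axis=-1, keepdims=True)
                norms[norms == 0] = 1.0
                walk[inside] = mid + dirs / norms * (cutoff + 0.5)
            pos[i] = walk
            b = bound[i]
            if b.any():
                pos[i, b] = mid + sphere_dirs[i, b] * radii[i, b][:, None]
        reps.append(TrajectoryReplicate(
            gs_xyz=pos,
            disulfide_xyz=np.broadcast_to(
                disulfide, (n_frames, 2, 3)).copy(),
            frame_interval_ps=frame_interval_ps, replicate=r,
        ))
    return GsTrajectory(reps, meta={
        "seed": seed, "variant": vset.label, "frame_bound_p": p,
        "per_particle_q": q, "persistence": persistence,
        "provenance": vset.provenance.get("md", ""),
    })
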