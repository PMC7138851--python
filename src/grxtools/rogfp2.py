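"""Ratiometric roGFP2 plate-reader analysis.

roGFP2 carries an engineered dithiol/disulfide pair whose two excitation
maxima (~400 and ~480 nm) change in opposite directions upon disulfide
formation.  With fully reduced (DTT-treated) and fully oxidized
(diamide-treated) control wells on the same plate, the degree of oxidation
of a sample well is

    OxD = (I400s*I480r - I400r*I480s)
          / ((I400s*I480r - I400s*I480o) + (I400o*I480s - I400r*I480s))

which is exactly linear in the disulfide fraction for convex mixtures of the
reduced and oxidized channel spectra and invariant under common rescaling of
all intensities.

The screening readout is the area under the baseline-corrected OxD curve over
the first 48 s after oxidant addition, plotted against the H2O2 dose.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .stats import compare_groups, GroupComparison  # noqa: F401

__all__ = [
    "Well",
    "PlateRun",
    "OxDTrace",
    "compute_oxd",
    "oxd_trace",
    "baseline_correct",
    "auc_48",
    "dose_response",
]

ROLES = ("sample", "reduced_control", "oxidized_control", "untreated")


@dataclass
class Well:
    """One plate well: two-channel fluorescence time series plus annotations."""

    well_id: str
    role: str
    time: np.ndarray
    i400: np.ndarray
    i480: np.ndarray
    dose_h2o2: float = 0.0
    construct_label: str = ""
    replicate: int = 0

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"role must be one of {ROLES}")
        self.time = np.asarray(self.time, dtype=float)
        self.i400 = np.asarray(self.i400, dtype=float)
        self.i480 = np.asarray(self.i480, dtype=float)
        if not (self.time.shape == self.i400.shape == self.i480.shape):
            raise ValueError("time/i400/i480 must have equal length")
        if np.any(self.i400 <= 0) or np.any(self.i480 <= 0):
            raise ValueError("intensities must be positive")
        if not 0.0 <= self.dose_h2o2 <= 1e-3:
            raise ValueError("dose_h2o2 must lie in [0, 1e-3] M")


@dataclass
class PlateRun:
    """A set of wells including reduced/oxidized controls and an untreated well."""

    wells: list[Well]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        roles = {w.role for w in self.wells}
        if "reduced_control" not in roles:
            raise ValueError("plate run needs >= 1 reduced control (DTT) well")
        if "oxidized_control" not in roles:
            raise ValueError("plate run needs >= 1 oxidized control (diamide) well")
        if "untreated" not in roles:
            raise ValueError("plate run needs an untreated (0 uM H2O2) well")

    def by_role(self, role: str) -> list[Well]:
        return [w for w in self.wells if w.role == role]

    def control_intensities(self) -> tuple[float, float, float, float]:
        """Per-plate mean control intensities (i400_red, i480_red, i400_ox, i480_ox)."""
        red = self.by_role("reduced_control")
        ox = self.by_role("oxidized_control")
        i400r = float(np.mean([np.mean(w.i400) for w in red]))
        i480r = float(np.mean([np.mean(w.i480) for w in red]))
        i400o = float(np.mean([np.mean(w.i400) for w in ox]))
        i480o = float(np.mean([np.mean(w.i480) for w in ox]))
        return i400r, i480r, i400o, i480o


@dataclass
class OxDTrace:
    """Degree-of-oxidation time course for one well."""

    time: np.ndarray
    oxd: np.ndarray
    flags: np.ndarray  # True where raw OxD fell outside [0, 1]
    well_id: str = ""
    dose_h2o2: float = 0.0
    construct_label: str = ""
    replicate: int = 0

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.oxd = np.asarray(self.oxd, dtype=float)
        self.flags = np.asarray(self.flags, dtype=bool)

    def clipped(self) -> "OxDTrace":
        """Opt-in clipping of OxD to [0, 1] (flags retained)."""
        return OxDTrace(self.time, np.clip(self.oxd, 0.0, 1.0), self.flags,
                        self.well_id, self.dose_h2o2, self.construct_label,
                        self.replicate)


def compute_oxd(i400s, i480s, i400r, i480r, i400o, i480o):
    """Degree of oxidation from sample and control channel intensities.

    All arguments may be scalars or arrays; controls are typically per-plate
    means.  Raises if the controls are degenerate (zero denominator).
    """
    i400s = np.asarray(i400s, dtype=float)
    i480s = np.asarray(i480s, dtype=float)
    num = i400s * i480r - i400r * i480s
    den = (i400s * i480r - i400s * i480o) + (i400o * i480s - i400r * i480s)
    if np.any(np.abs(den) < 1e-300):
        raise ZeroDivisionError(
            "degenerate controls: reduced and oxidized spectra coincide"
        )
    out = num / den
    return float(out) if out.ndim == 0 else out


def oxd_trace(run: PlateRun, well: Well) -> OxDTrace:
    """OxD time course of one well, calibrated by the plate's control wells.

    Raw values outside [0, 1] (possible with noisy controls) are retained but
    flagged; clipping is opt-in via ``OxDTrace.clipped()``.
    """
    i400r, i480r, i400o, i480o = run.control_intensities()
    oxd = compute_oxd(well.i400, well.i480, i400r, i480r, i400o, i480o)
    oxd = np.atleast_1d(oxd)
    flags = (oxd < 0.0) | (oxd > 1.0)
    return OxDTrace(
        time=well.time, oxd=oxd, flags=flags, well_id=well.well_id,
        dose_h2o2=well.dose_h2o2, construct_label=well.construct_label,
        replicate=well.replicate,
    )


def baseline_correct(trace: OxDTrace, untreated: OxDTrace) -> OxDTrace:
    """Subtract the untreated (0 uM H2O2) response pointwise.

    The untreated trace is resampled onto the sample time grid by linear
    interpolation when the grids differ.  The corrected trace may be
    negative.
    """
    t = trace.time
    if t.min() < untreated.time.min() - 1e-9 or t.max() > untreated.time.max() + 1e-9:
        raise ValueError(
            f"untreated trace covers [{untreated.time.min()}, "
            f"{untreated.time.max()}] s but sample needs [{t.min()}, {t.max()}] s"
        )
    ref = np.interp(t, untreated.time, untreated.oxd)
    return OxDTrace(
        time=t, oxd=trace.oxd - ref, flags=trace.flags.copy(),
        well_id=trace.well_id, dose_h2o2=trace.dose_h2o2,
        construct_label=trace.construct_label, replicate=trace.replicate,
    )


def auc_48(corrected: OxDTrace, t_end: float = 48.0) -> float:
    """Trapezoidal integral of the corrected OxD trace over [0, t_end] seconds.

    The last interval is interpolated so the integral ends exactly at t_end.
    Raises if the trace ends before t_end.
    """
    t = corrected.time
    y = corrected.oxd
    if t.max() < t_end - 1e-9:
        raise ValueError(
            f"trace covers only [0, {t.max():.1f}] s, need {t_end} s"
        )
    mask = (t >= 0.0) & (t <= t_end + 1e-12)
    tt = t[mask]
    yy = y[mask]
    if tt.size == 0 or tt[-1] < t_end - 1e-12:
        y_end = float(np.interp(t_end, t, y))
        tt = np.append(tt, t_end)
        yy = np.append(yy, y_end)
    if tt[0] > 1e-12:
        y0 = float(np.interp(0.0, t, y))
        tt = np.insert(tt, 0, 0.0)
        yy = np.insert(yy, 0, y0)
    return float(np.trapezoid(yy, tt))


def dose_response(run: PlateRun, reference_construct: str | None = None,
                  t_end: float = 48.0):
    """Per-dose mean +/- sd of the baseline-corrected 48-s AUC.

    Sample traces are baseline-corrected against the untreated well of the
    same construct (falling back to the plate's untreated well) and
    integrated over the first ``t_end`` seconds.  Returns a DataFrame with
    columns (construct, dose_M, auc_mean, auc_sd, n) and, if
    ``reference_construct`` is given, a GroupComparison of total AUC per
    replicate against that construct.
    """
    untreated_by_construct: dict[str, OxDTrace] = {}
    for w in run.by_role("untreated"):
        untreated_by_construct.setdefault(w.construct_label, oxd_trace(run, w))
    if not untreated_by_construct:
        raise ValueError("missing untreated well")
    default_untreated = next(iter(untreated_by_construct.values()))

    rows = []
    per_replicate: dict[str, dict[int, float]] = {}
    for w in run.by_role("sample"):
        trace = oxd_trace(run, w)
        untreated = untreated_by_construct.get(w.construct_label, default_untreated)
        corrected = baseline_correct(trace, untreated)
        auc = auc_48(corrected, t_end=t_end)
        rows.append({
            "construct": w.construct_label, "dose_M": w.dose_h2o2,
            "replicate": w.replicate, "auc": auc,
        })
        per_replicate.setdefault(w.construct_label, {})
        per_replicate[w.construct_label][w.replicate] = (
            per_replicate[w.construct_label].get(w.replicate, 0.0) + auc
        )
    if not rows:
        raise ValueError("no sample wells on plate")
    df = pd.DataFrame(rows)
    summary = (
        df.groupby(["construct", "dose_M"])
        .agg(auc_mean=("auc", "mean"), auc_sd=("auc", lambda x: x.std(ddof=1)
                                                if len(x) > 1 else 0.0),
             n=("auc", "size"))
        .reset_index()
    )
    comparison = None
    if reference_construct is not None:
        groups = {
            c: np.array(sorted(v.values()))
            for c, v in per_replicate.items()
        }
        comparison = compare_groups(groups, reference=reference_construct)
    return (summary, comparison) if reference_construct is not None else summary
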