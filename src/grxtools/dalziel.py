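"""Steady-state inference for ping-pong glutaredoxin kinetics.

Implements the analysis layer applied to initial-rate grids measured over a
[GSSR] x [GSH] concentration matrix: blank correction against a reference
cuvette, apparent Michaelis-Menten fits at fixed co-substrate, the classical
linearizations (Lineweaver-Burk, Eadie-Hofstee, Hanes), the Dalziel fit
e0/v = phi0 + phi1/[GSSR] + phi2/[GSH], and fold-change comparison between
enzyme variants.

The fitting entry points follow the Model/Results convention: construct a
model from data, call ``fit()``, and read estimates, standard errors and a
``summary()`` table off the results object.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import lmfit

from .kinetics import PingPongParameters

__all__ = [
    "RateGrid",
    "blank_correct",
    "MichaelisMentenModel",
    "ApparentMMFit",
    "fit_apparent_mm",
    "linearize",
    "LinearizationResult",
    "DalzielModel",
    "DalzielResults",
    "fit_dalziel",
    "compare_variants",
    "VariantComparison",
]

_GRID_COLUMNS = ["gssr_M", "gsh_M", "enzyme_M", "rate_M_per_s", "replicate"]


@dataclass
class RateGrid:
    """Initial rates over a [GSSR] x [GSH] grid for one enzyme variant.

    ``data`` carries columns gssr_M, gsh_M, enzyme_M, rate_M_per_s and
    replicate; ``substrate_label`` names the glutathionylated substrate
    (GSSCys or HEDS).
    """

    data: pd.DataFrame
    substrate_label: str = "GSSCys"
    variant_label: str = "WT"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        df = self.data.copy()
        if "replicate" not in df.columns:
            df["replicate"] = 0
        missing = [c for c in _GRID_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"RateGrid missing columns: {missing}")
        if np.any(df["gssr_M"] <= 0) or np.any(df["gsh_M"] <= 0):
            raise ValueError("all substrate concentrations must be positive")
        if np.any(df["rate_M_per_s"] < 0):
            raise ValueError("rates must be non-negative")
        self.data = df.reset_index(drop=True)

    def averaged(self) -> "RateGrid":
        """Average replicate rates at identical conditions."""
        df = (
            self.data.groupby(["gssr_M", "gsh_M", "enzyme_M"], as_index=False)
            ["rate_M_per_s"].mean()
        )
        df["replicate"] = 0
        return RateGrid(df, self.substrate_label, self.variant_label, dict(self.meta))

    def __len__(self) -> int:
        return len(self.data)


def blank_correct(raw: RateGrid, reference: RateGrid) -> RateGrid:
    """Subtract reference-cuvette rates row-wise, clipping at zero.

    Rows are matched on (gssr_M, gsh_M, replicate); clipped rows are flagged
    in a ``clipped`` column.
    """
    keys = ["gssr_M", "gsh_M", "replicate"]
    ref = reference.data[keys + ["rate_M_per_s"]].rename(
        columns={"rate_M_per_s": "blank_rate"}
    )
    merged = raw.data.merge(ref, on=keys, how="left", validate="one_to_one")
    unmatched = merged["blank_rate"].isna()
    if unmatched.any():
        rows = merged.loc[unmatched, keys].to_dict("records")
        raise ValueError(f"reference grid missing conditions: {rows}")
    corrected = merged["rate_M_per_s"] - merged["blank_rate"]
    out = raw.data.copy()
    out["clipped"] = corrected <= 0
    out["rate_M_per_s"] = np.clip(corrected, 0.0, None)
    return RateGrid(out, raw.substrate_label, raw.variant_label, dict(raw.meta))


# ---------------------------------------------------------------------------
# Apparent Michaelis-Menten fits at fixed co-substrate
# ---------------------------------------------------------------------------

@dataclass
class ApparentMMFit:
    """One apparent Michaelis-Menten fit at a fixed co-substrate level."""

    kcat_app: float
    km_app: float
    kcat_se: float
    km_se: float
    fixed_substrate: str
    fixed_conc: float
    rss: float
    degenerate: bool = False
    unidentifiable: bool = False

    @property
    def efficiency(self) -> float:
        """Catalytic efficiency kcat_app / Km_app (M^-1 s^-1)."""
        return self.kcat_app / self.km_app


class MichaelisMentenModel:
    """Nonlinear v = e0 kcat [S] / (Km + [S]) model for one substrate series."""

    def __init__(self, s, v, enzyme0, fixed_substrate="", fixed_conc=np.nan):
        self.s = np.asarray(s, dtype=float)
        self.v = np.asarray(v, dtype=float)
        self.enzyme0 = np.asarray(enzyme0, dtype=float)
        self.fixed_substrate = fixed_substrate
        self.fixed_conc = fixed_conc
        if len(np.unique(self.s)) < 4:
            raise ValueError("need >= 4 varied-substrate levels")

    def fit(self, n_starts: int = 5, seed: int = 0) -> ApparentMMFit:
        s, v, e0 = self.s, self.v, self.enzyme0
        spread = np.ptp(v)
        vmax0 = float(np.max(v))
        if spread <= 1e-12 * max(vmax0, 1e-30):
            # no curvature at all: rate independent of [S]
            return ApparentMMFit(
                kcat_app=vmax0 / float(np.mean(e0)), km_app=float(np.min(s)),
                kcat_se=np.nan, km_se=np.nan,
                fixed_substrate=self.fixed_substrate, fixed_conc=self.fixed_conc,
                rss=0.0, degenerate=True,
            )

        def model(params):
            kcat, km = params["kcat"].value, params["km"].value
            return e0 * kcat * s / (km + s) - v

        half = 0.5 * vmax0
        idx = int(np.argmin(np.abs(v - half)))
        km0 = float(s[idx])
        rng = np.random.default_rng(seed)
        best = None
        for i in range(n_starts):
            jitter = 1.0 if i == 0 else float(rng.lognormal(0.0, 0.7))
            params = lmfit.Parameters()
            params.add("kcat", value=vmax0 / float(np.mean(e0)) * jitter, min=1e-12)
            params.add("km", value=km0 * jitter, min=1e-15)
            try:
                res = lmfit.minimize(model, params, method="leastsq")
            except Exception:
                continue
            if best is None or res.chisqr < best.chisqr:
                best = res
        if best is None:
            raise RuntimeError("Michaelis-Menten fit failed for all starts")
        kcat = best.params["kcat"].value
        km = best.params["km"].value
        kcat_se = best.params["kcat"].stderr or np.nan
        km_se = best.params["km"].stderr or np.nan
        # ridge-line case: Km far above the sampled range means only kcat/Km
        # is identified
        unident = km > 20.0 * float(np.max(s))
        return ApparentMMFit(
            kcat_app=float(kcat), km_app=float(km),
            kcat_se=float(kcat_se) if kcat_se is not None else np.nan,
            km_se=float(km_se) if km_se is not None else np.nan,
            fixed_substrate=self.fixed_substrate, fixed_conc=self.fixed_conc,
            rss=float(best.chisqr), unidentifiable=bool(unident),
        )


def fit_apparent_mm(grid: RateGrid, varied: str = "gsh") -> dict[float, ApparentMMFit]:
    """Apparent MM fits of the varied substrate at each fixed co-substrate level.

    ``varied`` is "gsh" (fixed GSSR levels) or "gssr" (fixed GSH levels).
    Returns a mapping fixed-concentration -> ApparentMMFit.
    """
    if varied not in ("gsh", "gssr"):
        raise ValueError("varied must be 'gsh' or 'gssr'")
    varied_col = f"{varied}_M"
    fixed_col = "gssr_M" if varied == "gsh" else "gsh_M"
    fixed_name = "GSSR" if varied == "gsh" else "GSH"
    df = grid.averaged().data
    out: dict[float, ApparentMMFit] = {}
    for fixed_val, sub in df.groupby(fixed_col):
        model = MichaelisMentenModel(
            sub[varied_col], sub["rate_M_per_s"], sub["enzyme_M"],
            fixed_substrate=fixed_name, fixed_conc=float(fixed_val),
        )
        out[float(fixed_val)] = model.fit()
    return out


# ---------------------------------------------------------------------------
# Linearizations
# ---------------------------------------------------------------------------

@dataclass
class LinearizationResult:
    method: str
    x: np.ndarray
    y: np.ndarray
    slope: float
    intercept: float
    vmax: float
    km: float
    n_excluded: int = 0


def linearize(s, v, method: str) -> LinearizationResult:
    """Classical linear transform of Michaelis-Menten data plus OLS line.

    Methods: lineweaver_burk (1/v vs 1/S), eadie_hofstee (v vs v/S),
    hanes (S/v vs S).  Zero rates are excluded with a warning.
    """
    s = np.asarray(s, dtype=float)
    v = np.asarray(v, dtype=float)
    nz = v > 0
    n_excluded = int((~nz).sum())
    if n_excluded:
        warnings.warn(f"excluding {n_excluded} zero-rate rows from {method}")
    s, v = s[nz], v[nz]
    if method == "lineweaver_burk":
        x, y = 1.0 / s, 1.0 / v
        slope, intercept = np.polyfit(x, y, 1)
        vmax = 1.0 / intercept if intercept != 0 else np.inf
        km = slope * vmax
    elif method == "eadie_hofstee":
        x, y = v / s, v
        slope, intercept = np.polyfit(x, y, 1)
        vmax = intercept
        km = -slope
    elif method == "hanes":
        x, y = s, s / v
        slope, intercept = np.polyfit(x, y, 1)
        vmax = 1.0 / slope
        km = intercept * vmax
    else:
        raise ValueError(f"unknown linearization method {method!r}")
    return LinearizationResult(
        method=method, x=x, y=y, slope=float(slope), intercept=float(intercept),
        vmax=float(vmax), km=float(km), n_excluded=n_excluded,
    )


# ---------------------------------------------------------------------------
# Dalziel fit
# ---------------------------------------------------------------------------

class DalzielModel:
    """Linear model e0/v = phi0 + phi1/[GSSR] + phi2/[GSH] on a RateGrid.

    The primary route is a one-stage weighted linear least-squares fit in
    reciprocal space with weights proportional to v**2, which undoes the
    variance distortion of the reciprocal transform.  The classical two-stage
    secondary-plot route (primary Lineweaver-Burk intercepts regressed on the
    reciprocal co-substrate) is exposed via ``fit(method="two_stage")`` and
    agrees with the one-stage route on noiseless data.
    """

    def __init__(self, grid: RateGrid, weights: str | None = "v2",
                 average_replicates: bool = True):
        g = grid.averaged() if average_replicates else grid
        df = g.data[g.data["rate_M_per_s"] > 0].copy()
        n_dropped = len(g.data) - len(df)
        if n_dropped:
            warnings.warn(f"excluding {n_dropped} zero/blank-level rates from fit")
        for col in ("gssr_M", "gsh_M"):
            if df[col].nunique() < 2:
                raise ValueError(
                    f"rank-deficient design: need >= 2 distinct {col} levels"
                )
        if df["gssr_M"].nunique() < 3 or df["gsh_M"].nunique() < 3:
            warnings.warn("fewer than 3 distinct levels per substrate; "
                          "Dalziel fit may be poorly conditioned")
        self.grid = g
        self.df = df
        self.weights = weights

    def fit(self, method: str = "one_stage") -> "DalzielResults":
        if method == "one_stage":
            phi, se, cov, rss = self._fit_one_stage()
        elif method == "two_stage":
            phi = self._fit_two_stage()
            se = np.full(3, np.nan)
            cov = np.full((3, 3), np.nan)
            rss = np.nan
        else:
            raise ValueError("method must be 'one_stage' or 'two_stage'")
        params = PingPongParameters(
            phi0=phi[0], phi1=phi[1], phi2=phi[2],
            substrate_label=self.grid.substrate_label,
        )
        return DalzielResults(
            params=params, bse=se, cov=cov, rss=rss, method=method,
            variant_label=self.grid.variant_label, model=self,
        )

    def _design(self):
        df = self.df
        y = (df["enzyme_M"] / df["rate_M_per_s"]).to_numpy()
        X = np.column_stack([
            np.ones(len(df)),
            1.0 / df["gssr_M"].to_numpy(),
            1.0 / df["gsh_M"].to_numpy(),
        ])
        if self.weights == "v2":
            w = df["rate_M_per_s"].to_numpy() ** 2
        elif self.weights is None:
            w = np.ones(len(df))
        else:
            raise ValueError("weights must be 'v2' or None")
        return X, y, w

    def _fit_one_stage(self):
        X, y, w = self._design()
        sw = np.sqrt(w)
        Xw = X * sw[:, None]
        yw = y * sw
        phi, _, rank, _ = np.linalg.lstsq(Xw, yw, rcond=None)
        if rank < 3:
            raise ValueError("rank-deficient design for Dalziel fit")
        resid = yw - Xw @ phi
        rss = float(resid @ resid)
        dof = max(len(y) - 3, 1)
        sigma2 = rss / dof
        cov = sigma2 * np.linalg.inv(Xw.T @ Xw)
        se = np.sqrt(np.diag(cov))
        return phi, se, cov, rss

    def _fit_two_stage(self):
        # primary plots: at each fixed [GSSR], e0/v is linear in 1/[GSH]
        # with slope phi2 and intercept phi0 + phi1/[GSSR]
        df = self.df
        intercepts, slopes, inv_gssr = [], [], []
        for gssr, sub in df.groupby("gssr_M"):
            if sub["gsh_M"].nunique() < 2:
                continue
            x = 1.0 / sub["gsh_M"].to_numpy()
            y = (sub["enzyme_M"] / sub["rate_M_per_s"]).to_numpy()
            m, b = np.polyfit(x, y, 1)
            slopes.append(m)
            intercepts.append(b)
            inv_gssr.append(1.0 / gssr)
        if len(intercepts) < 2:
            raise ValueError("two-stage fit needs >= 2 GSSR levels with GSH series")
        phi1, phi0 = np.polyfit(inv_gssr, intercepts, 1)
        phi2 = float(np.mean(slopes))
        return np.array([phi0, phi1, phi2])


@dataclass
class DalzielResults:
    """Fitted Dalziel coefficients with uncertainties and derived constants."""

    params: PingPongParameters
    bse: np.ndarray
    cov: np.ndarray
    rss: float
    method: str
    variant_label: str
    model: DalzielModel | None = None

    @property
    def phi(self) -> np.ndarray:
        p = self.params
        return np.array([p.phi0, p.phi1, p.phi2])

    @property
    def reciprocals(self) -> dict[str, float]:
        p = self.params
        return {"k_ox": p.k_ox, "k_red": p.k_red, "true_kcat": p.kcat}

    def summary(self) -> str:
        p = self.params
        lines = [
            f"Dalziel fit ({self.method}) - variant {self.variant_label}, "
            f"substrate {p.substrate_label}",
            f"  phi0 = {p.phi0:.6g} s        (se {self.bse[0]:.3g})",
            f"  phi1 = {p.phi1:.6g} M s      (se {self.bse[1]:.3g})",
            f"  phi2 = {p.phi2:.6g} M s      (se {self.bse[2]:.3g})",
            f"  1/phi1 (oxidative)  = {p.k_ox:.6g} M^-1 s^-1",
            f"  1/phi2 (reductive)  = {p.k_red:.6g} M^-1 s^-1",
            f"  true kcat = 1/phi0  = {p.kcat:.6g} s^-1",
            f"  weighted RSS = {self.rss:.3g}",
        ]
        return "\n".join(lines)


def fit_dalziel(grid: RateGrid, method: str = "one_stage",
                weights: str | None = "v2") -> DalzielResults:
    """Convenience wrapper: fit the Dalziel relation to a RateGrid."""
    return DalzielModel(grid, weights=weights).fit(method=method)


# ---------------------------------------------------------------------------
# Variant comparison
# ---------------------------------------------------------------------------

@dataclass
class VariantComparison:
    """Fold changes of half-reaction rate constants, mutant over wild type."""

    wt_label: str
    mut_label: str
    substrate_label: str
    ratios: dict[str, float]

    def percent_of_wt(self, key: str) -> float:
        return 100.0 * self.ratios[key]

    def percent_reduction(self, key: str) -> float:
        return 100.0 * (1.0 - self.ratios[key])

    def summary(self) -> str:
        lines = [f"{self.mut_label} vs {self.wt_label} ({self.substrate_label})"]
        for key, r in self.ratios.items():
            lines.append(
                f"  {key}: x{r:.3g} ({self.percent_of_wt(key):.1f}% of WT, "
                f"{self.percent_reduction(key):+.1f}% reduction)"
            )
        return "\n".join(lines)


def compare_variants(wt: DalzielResults, mut: DalzielResults) -> VariantComparison:
    """Mutant/wild-type ratios of 1/phi1, 1/phi2 and 1/phi0."""
    if wt.params.substrate_label != mut.params.substrate_label:
        raise ValueError("variants measured with different substrates")
    ratios = {
        "k_ox": mut.params.k_ox / wt.params.k_ox,
        "k_red": mut.params.k_red / wt.params.k_red,
        "true_kcat": mut.params.kcat / wt.params.kcat,
    }
    return VariantComparison(
        wt_label=wt.variant_label, mut_label=mut.variant_label,
        substrate_label=wt.params.substrate_label, ratios=ratios,
    )
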