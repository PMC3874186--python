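"""Estimators recovering model parameters from observed readout tables.

The three estimation problems follow a Model -> fit() -> Results pattern:

* :class:`LesionRateModel` inverts the Poisson zero class on a damaged-copy
  count to estimate the lesion induction rate per kb, with a Wilson-interval
  confidence band propagated through the inversion.
* :class:`RepairKineticsModel` fits the first-order repair curve
  f(t) = 1 - exp(-k t) to a repaired-fraction time course (weighted least
  squares on -log(1 - f), exact under the multiplicative noise of a
  damage-signal readout).
* :class:`TrafficModel` grid-searches traffic-simulation parameters
  (release mode, spontaneous release rate) against an observed ChIP
  occupancy table; the simulator is stochastic and cheap, so grid search
  with a common seed is more robust than gradient descent.

Convenience wrappers :func:`estimate_rate`, :func:`estimate_repair_k` and
:func:`recover_dynamics_params` expose each as a single call.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from . import assays, dynamics
from .damage import DamageRateProfile, RepairKinetics


# --------------------------------------------------------------------------
# lesion induction rate
# --------------------------------------------------------------------------

class LesionRateModel:
    """Poisson zero-class model for a damaged-copy count in one fragment.

    ``damaged`` of ``total`` gene copies carry >= 1 lesion in a fragment of
    ``length_kb``; the rate per kb is -ln(1 - damaged/total) / length_kb.
    """

    def __init__(self, damaged: int, total: int, length_kb: float):
        if total <= 0:
            raise ValueError("total must be > 0")
        if not 0 <= damaged <= total:
            raise ValueError("require 0 <= damaged <= total")
        if length_kb <= 0:
            raise ValueError("length_kb must be > 0")
        self.damaged = int(damaged)
        self.total = int(total)
        self.length_kb = float(length_kb)

    def fit(self, alpha: float = 0.05) -> "LesionRateResults":
        p = self.damaged / self.total
        lo, hi = proportion_confint(self.damaged, self.total,
                                    alpha=alpha, method="wilson")
        unbounded = self.damaged == self.total

        def to_rate(frac):
            if frac >= 1.0:
                return math.inf
            return -math.log(1.0 - frac) / self.length_kb

        rate = to_rate(p) if not unbounded else math.inf
        return LesionRateResults(
            rate=rate,
            conf_int_=(to_rate(lo), to_rate(hi)),
            alpha=alpha,
            unbounded=unbounded,
            model=self,
        )


@dataclass
class LesionRateResults:
    rate: float                 # lesions per kb
    conf_int_: tuple
    alpha: float
    unbounded: bool
    model: LesionRateModel

    @property
    def params(self) -> dict:
        return {"rate_per_kb": self.rate}

    def conf_int(self) -> tuple:
        return self.conf_int_

    def summary(self) -> str:
        lo, hi = self.conf_int_
        lines = [
            "Lesion induction rate (Poisson zero-class inversion)",
            "----------------------------------------------------",
            f"damaged / total copies : {self.model.damaged} / {self.model.total}",
            f"fragment length        : {self.model.length_kb:.3f} kb",
            f"rate                   : {self.rate:.4f} per kb",
            f"{100 * (1 - self.alpha):.0f}% CI (Wilson)        : "
            f"[{lo:.4f}, {hi if math.isfinite(hi) else float('inf'):.4f}]",
        ]
        if self.unbounded:
            lines.append("note: all copies damaged -> upper bound unbounded")
        return "\n".join(lines)


def estimate_rate(damaged: int, total: int, length_kb: float,
                  alpha: float = 0.05) -> LesionRateResults:
    return LesionRateModel(damaged, total, length_kb).fit(alpha=alpha)


# --------------------------------------------------------------------------
# repair rate
# --------------------------------------------------------------------------

class RepairKineticsModel:
    """First-order repair curve f(t) = 1 - exp(-k t) fitted to a time course.

    Accepts arrays or a DataFrame with ``time_h`` and ``repaired_fraction``
    columns (replicate-level rows are fine).  The fit is least squares of
    y = -log(1 - f) against k t through the origin; points with f >= 1,
    for which the log transform is undefined, are excluded and flagged.
    """

    def __init__(self, times_h, fractions=None):
        if fractions is None:
            df = times_h
            times_h = df["time_h"].to_numpy(float)
            fractions = df["repaired_fraction"].to_numpy(float)
        self.t = np.asarray(times_h, float)
        self.f = np.asarray(fractions, float)
        if self.t.size < 2:
            raise ValueError("need at least 2 timepoints")
        if np.any(self.t < 0):
            raise ValueError("times must be >= 0")

    def fit(self, alpha: float = 0.05) -> "RepairKineticsResults":
        flags = []
        usable = (self.f < 1.0 - 1e-9) & (self.t > 0)
        if usable.sum() < self.f.size:
            flags.append("saturated_or_t0_points_excluded")
        t, f = self.t[usable], self.f[usable]
        if t.size == 0 or np.all(f <= 0):
            k = 0.0
            se = math.nan
            flags.append("all_zero_fractions")
        else:
            y = -np.log1p(-f)
            k = float((t @ y) / (t @ t))
            k = max(k, 0.0)
            dof = max(t.size - 1, 1)
            resid = y - k * t
            s2 = float(resid @ resid) / dof
            se = math.sqrt(s2 / float(t @ t))
        ssr = float(np.sum((self.f - (1.0 - np.exp(-k * self.t))) ** 2))
        if math.isnan(se):
            ci = (0.0, math.nan)
        else:
            from scipy.stats import t as tdist
            half = tdist.ppf(1 - alpha / 2, max(t.size - 1, 1)) * se
            ci = (max(k - half, 0.0), k + half)
        return RepairKineticsResults(k=k, bse=se, ssr=ssr, conf_int_=ci,
                                     alpha=alpha, flags=flags, model=self)


@dataclass
class RepairKineticsResults:
    k: float                    # per hour
    bse: float
    ssr: float
    conf_int_: tuple
    alpha: float
    flags: list
    model: RepairKineticsModel

    @property
    def params(self) -> dict:
        return {"k_per_h": self.k}

    @property
    def halflife_h(self) -> float:
        return math.log(2.0) / self.k if self.k > 0 else math.inf

    def conf_int(self) -> tuple:
        return self.conf_int_

    def predict(self, times_h) -> np.ndarray:
        return 1.0 - np.exp(-self.k * np.asarray(times_h, float))

    def summary(self) -> str:
        lines = [
            "First-order repair kinetics  f(t) = 1 - exp(-k t)",
            "-------------------------------------------------",
            f"k          : {self.k:.4f} per h  (half-life "
            f"{self.halflife_h:.2f} h)",
            f"SE(k)      : {self.bse:.4f}",
            f"{100 * (1 - self.alpha):.0f}% CI     : [{self.conf_int_[0]:.4f}, "
            f"{self.conf_int_[1]:.4f}]",
            f"SSR        : {self.ssr:.5f}",
        ]
        if self.flags:
            lines.append("flags      : " + ", ".join(self.flags))
        return "\n".join(lines)


def estimate_repair_k(times_h, fractions=None) -> RepairKineticsResults:
    return RepairKineticsModel(times_h, fractions).fit()


# --------------------------------------------------------------------------
# traffic parameters by simulation grid search
# --------------------------------------------------------------------------

class TrafficModel:
    """Grid-search fit of traffic parameters to an observed ChIP table.

    ``observed`` is a long-format table with columns ``timepoint``,
    ``probe`` and ``value`` (replicates are averaged).  Each candidate
    (release_mode, k_release) re-runs the scenario with a common seed and
    is scored by the summed squared residual of the mean occupancy profile.
    """

    def __init__(
        self,
        observed: pd.DataFrame,
        locus,
        profile: DamageRateProfile,
        params: dynamics.SimulationParams,
        kinetics: RepairKinetics,
        timepoints_h,
        open_fraction: float = 0.5,
        background: float = assays.DEFAULT_CHIP_BACKGROUND,
        chrom_params=None,
    ):
        obs = observed[observed.get("assay", "chip") == "chip"] \
            if "assay" in observed else observed
        self.observed = (
            obs.groupby(["timepoint", "probe"])["value"].mean().rename("obs")
        )
        tps = self.observed.index.get_level_values("timepoint").unique()
        probes = self.observed.index.get_level_values("probe").unique()
        if len(tps) < 3 or len(probes) < 4:
            raise ValueError(
                "observed table must cover >= 3 timepoints and >= 4 amplicons"
            )
        self.locus = locus
        self.profile = profile
        self.params = params
        self.kinetics = kinetics
        self.timepoints_h = list(timepoints_h)
        self.open_fraction = open_fraction
        self.background = background
        self.chrom_params = chrom_params

    def _score(self, candidate: dynamics.SimulationParams, seed) -> float:
        traj = dynamics.run_scenario(
            self.locus, self.profile, candidate, self.kinetics,
            self.timepoints_h, seed, open_fraction=self.open_fraction,
            chrom_params=self.chrom_params,
        )
        sim = assays.chip_table(traj, background=self.background)
        sim = sim.groupby(["timepoint", "probe"])["value"].mean().rename("sim")
        joined = pd.concat([self.observed, sim], axis=1, join="inner").dropna()
        return float(((joined["obs"] - joined["sim"]) ** 2).sum())

    def fit(self, grid, seed) -> "TrafficResults":
        """``grid``: iterable of (release_mode, k_release) candidates."""
        grid = list(grid)
        if not grid:
            raise ValueError("candidate grid is empty")
        rows = []
        for mode, k_rel in grid:
            cand = self.params.replace(release_mode=mode, k_release=k_rel)
            rows.append(
                {"release_mode": mode, "k_release": k_rel,
                 "ssr": self._score(cand, seed)}
            )
        surface = pd.DataFrame(rows)
        best = surface.loc[surface["ssr"].idxmin()]
        flags = []
        spread = surface["ssr"].max() - surface["ssr"].min()
        if len(surface) > 1 and spread <= 1e-12 * max(surface["ssr"].max(), 1.0):
            flags.append("flat_residual_surface")
        return TrafficResults(
            release_mode=str(best["release_mode"]),
            k_release=float(best["k_release"]),
            surface=surface,
            flags=flags,
        )


@dataclass
class TrafficResults:
    release_mode: str
    k_release: float
    surface: pd.DataFrame = field(repr=False)
    flags: list = field(default_factory=list)

    @property
    def params(self) -> dict:
        return {"release_mode": self.release_mode, "k_release": self.k_release}

    def summary(self) -> str:
        lines = [
            "Traffic parameter grid search (ChIP occupancy least squares)",
            "------------------------------------------------------------",
            f"best release_mode : {self.release_mode}",
            f"best k_release    : {self.k_release:.4f} per min",
            "",
            self.surface.to_string(index=False),
        ]
        if self.flags:
            lines.append("flags: " + ", ".join(self.flags))
        return "\n".join(lines)


def recover_dynamics_params(observed, locus, profile, params, kinetics,
                            timepoints_h, grid, seed,
                            **kw) -> TrafficResults:
    model = TrafficModel(observed, locus, profile, params, kinetics,
                         timepoints_h, **kw)
    return model.fit(grid, seed)
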