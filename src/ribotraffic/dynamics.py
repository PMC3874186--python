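"""Kinetic Monte Carlo of RNA polymerase I traffic on the rDNA population.

Each gene copy carries an ordered set of polymerases obeying hard-core
exclusion (no two closer than one footprint).  Per fixed time increment
``dt`` (1 s by default) the scheme applies, in order: initiation at open
copies with a clear promoter, elongation capped by the leading polymerase /
the first unrepaired template-strand lesion / the gene end, arrest at
lesions, release of arrested polymerases (contact-gated "collision" release
and/or slow spontaneous release), stochastic repair, and nucleosome
deposition/clearing.  The whole population lives in flat numpy arrays so a
150-copy locus advances in vector operations.

Released and terminated polymerases rejoin an unlimited free pool; there is
no pool depletion and no proteasome-mediated degradation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import chromatin as _chromatin
from .damage import DamageRateProfile, LesionMap, RepairKinetics, \
    repair_update, sample_lesion_map, _require_rng
from .locus import ConfigurationError, RDNAUnit


class SimulationError(RuntimeError):
    """Internal consistency violation (exclusion or ordering broken)."""


# chromatin classification codes
OPEN, INTERMEDIATE, CLOSED = 0, 1, 2
CLASS_LABELS = ("open", "intermediate", "closed")


@dataclass(frozen=True)
class SimulationParams:
    """Kinetic constants of the traffic model.

    elongation_rate        nt/s
    steady_spacing         mean polymerase spacing on an undamaged active
                           copy (bp); ~130 bp for yeast rDNA
    footprint              exclusion distance (bp)
    initiation_rate        per s per open copy; defaults to
                           elongation_rate / steady_spacing so the
                           undamaged steady state is self-consistent
    release_mode           'collision' | 'constant' | 'both'
    k_release              spontaneous release rate of an arrested
                           polymerase (per min)
    k_collision            release rate of an arrested polymerase while a
                           trailing polymerase is pressed against it
                           (per min); calibrated against the measured
                           residual downstream occupancy 30 min after UV
    post_uv_initiation_factor  multiplier on initiation after UV
    dt                     default time increment (s)
    """

    elongation_rate: float = 25.0
    steady_spacing: float = 130.0
    footprint: float = 65.0
    initiation_rate: float | None = None
    release_mode: str = "both"
    k_release: float = 0.05
    k_collision: float = 4.0
    post_uv_initiation_factor: float = 1.0
    dt: float = 1.0

    def __post_init__(self) -> None:
        if self.footprint >= self.steady_spacing:
            raise ConfigurationError("footprint must be < steady_spacing")
        if self.release_mode not in ("collision", "constant", "both"):
            raise ConfigurationError(
                f"unknown release_mode {self.release_mode!r}"
            )
        for name in ("elongation_rate", "k_release", "k_collision",
                     "post_uv_initiation_factor"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.initiation_rate is not None and self.initiation_rate < 0:
            raise ConfigurationError("initiation_rate must be >= 0")
        if not 0 < self.dt <= 5.0:
            raise ConfigurationError("dt must be in (0, 5] s")

    @property
    def eff_initiation_rate(self) -> float:
        """Target initiation flux per s per open copy (one polymerase per
        ``steady_spacing`` bp on an unobstructed copy)."""
        if self.initiation_rate is not None:
            return self.initiation_rate
        return self.elongation_rate / self.steady_spacing

    def entry_probability(self, dt: float) -> float:
        """Per-step initiation attempt probability.

        With an explicit ``initiation_rate`` this is simply rate * dt.  The
        default instead solves the discrete renewal equation so that the
        realised inter-initiation interval equals steady_spacing /
        elongation_rate despite the promoter dead time (the entry site is
        blocked until the previous polymerase has cleared one footprint).
        """
        if self.initiation_rate is not None:
            return min(self.initiation_rate * dt, 1.0)
        vdt = self.elongation_rate * dt
        if vdt <= 0:
            return 0.0
        import math
        dead_steps = math.ceil(self.footprint / vdt)
        denom = self.steady_spacing / vdt - dead_steps + 1.0
        return min(1.0 / max(denom, 1.0), 1.0)

    def replace(self, **kw) -> "SimulationParams":
        from dataclasses import replace
        return replace(self, **kw)


@dataclass
class GeneCopyState:
    """Read-only view of one gene copy (for inspection and export)."""

    copy_id: int
    chromatin_state: str
    polymerases: list          # of (position, 'elongating'|'arrested')
    nucleosome_coverage: np.ndarray
    hmo1_bound: bool


class Population:
    """All gene copies of the locus in flat arrays.

    Polymerase arrays are kept sorted by (copy, position); nucleosome state
    is a per-copy, per-bin coverage fraction over the coding region.
    """

    def __init__(self, locus: RDNAUnit, chrom_params=None):
        self.locus = locus
        self.chrom_params = chrom_params or _chromatin.ChromatinParams()
        self.gene_length = float(locus.gene_length)
        self.n_copies = locus.n_copies
        self.bin_starts, self.bin_widths = _chromatin.make_bins(
            self.gene_length, self.chrom_params.deposition_bin
        )
        nb = self.bin_starts.size
        self.pol_copy = np.empty(0, np.int64)
        self.pol_pos = np.empty(0, float)
        self.pol_arrested = np.empty(0, bool)
        self.coverage = np.zeros((self.n_copies, nb))
        self.vacant_since = np.zeros((self.n_copies, nb))
        self.hmo1 = np.zeros(self.n_copies, bool)
        self.initially_open = np.zeros(self.n_copies, bool)
        self.time = 0.0
        self.footprint = 65.0
        self.n_initial = 0
        self.tallies = {
            "initiations": 0,
            "terminations": 0,
            "releases_collision": 0,
            "releases_spontaneous": 0,
        }
        # bins touched by moving polymerases in the latest step
        self._traversed = None

    # -- bookkeeping ------------------------------------------------------

    @property
    def n_polymerases(self) -> int:
        return self.pol_pos.size

    def pols_per_copy(self) -> np.ndarray:
        return np.bincount(self.pol_copy, minlength=self.n_copies)

    def mean_region_coverage(self, region=None) -> np.ndarray:
        """Per-copy length-weighted nucleosome coverage of a region."""
        if region is None:
            w = self.bin_widths
        else:
            lo = np.maximum(self.bin_starts, region.start)
            hi = np.minimum(self.bin_starts + self.bin_widths, region.end)
            w = np.clip(hi - lo, 0.0, None)
        total = w.sum()
        if total <= 0:
            return np.zeros(self.n_copies)
        return (self.coverage * w).sum(axis=1) / total

    def classification(self, region=None) -> np.ndarray:
        """Open / intermediate / closed call per copy.

        A copy only counts as closed when its coverage exceeds the closed
        threshold AND it carries no polymerases; a nucleosome-loaded copy
        that still holds a 5' queue reads as intermediate (the gel "smear").
        """
        cov = self.mean_region_coverage(region)
        cp = self.chrom_params
        cls = np.full(self.n_copies, INTERMEDIATE, np.int8)
        cls[cov <= cp.open_threshold] = OPEN
        has_pol = self.pols_per_copy() > 0
        cls[(cov >= cp.closed_threshold) & ~has_pol] = CLOSED
        return cls

    def open_fraction(self) -> float:
        return float((self.classification() == OPEN).mean())

    def copy_state(self, i: int) -> GeneCopyState:
        sel = self.pol_copy == i
        pols = [
            (float(p), "arrested" if a else "elongating")
            for p, a in zip(self.pol_pos[sel], self.pol_arrested[sel])
        ]
        return GeneCopyState(
            copy_id=i,
            chromatin_state=CLASS_LABELS[self.classification()[i]],
            polymerases=pols,
            nucleosome_coverage=self.coverage[i].copy(),
            hmo1_bound=bool(self.hmo1[i]),
        )

    def copy(self) -> "Population":
        new = Population.__new__(Population)
        new.__dict__ = {
            k: (v.copy() if isinstance(v, np.ndarray) else
                dict(v) if isinstance(v, dict) else v)
            for k, v in self.__dict__.items()
        }
        new._traversed = None
        return new

    def sort_pols(self) -> None:
        order = np.lexsort((self.pol_pos, self.pol_copy))
        self.pol_copy = self.pol_copy[order]
        self.pol_pos = self.pol_pos[order]
        self.pol_arrested = self.pol_arrested[order]

    def check_invariants(self, footprint: float) -> None:
        pc, pp = self.pol_copy, self.pol_pos
        if pp.size:
            if pp.min() < 0 or pp.max() >= self.gene_length:
                raise SimulationError("polymerase position outside the gene")
            same = pc[1:] == pc[:-1]
            gaps = pp[1:][same] - pp[:-1][same]
            if gaps.size and gaps.min() < footprint - 1e-6:
                raise SimulationError(
                    f"footprint exclusion violated (min gap {gaps.min():.3f})"
                )

    def to_frame(self) -> pd.DataFrame:
        cls = self.classification()
        df = pd.DataFrame(
            {
                "copy_id": self.pol_copy,
                "position": self.pol_pos,
                "status": np.where(self.pol_arrested, "arrested", "elongating"),
            }
        )
        meta = pd.DataFrame(
            {
                "copy_id": np.arange(self.n_copies),
                "chromatin_state": np.array(CLASS_LABELS)[cls],
                "hmo1_bound": self.hmo1.astype(int),
                "mean_coverage": self.mean_region_coverage(),
            }
        )
        return df.merge(meta, on="copy_id", how="right")


def initialize_steady_state(
    locus: RDNAUnit,
    params: SimulationParams,
    open_fraction: float,
    seed,
    chrom_params=None,
) -> Population:
    """Pre-UV population: open copies loaded at ~steady_spacing, rest closed.

    Open copies are nucleosome-free and Hmo1-bound, with polymerases placed
    every ``steady_spacing`` bp with a uniform phase jitter; closed copies
    are fully nucleosome-covered, Hmo1-free and carry no polymerases.
    """
    if not 0.0 <= open_fraction <= 1.0:
        raise ValueError("open_fraction must be in [0, 1]")
    rng = _require_rng(seed)
    pop = Population(locus, chrom_params)
    pop.footprint = params.footprint
    n_open = int(round(open_fraction * locus.n_copies))
    pop.initially_open[:n_open] = True
    pop.hmo1[:n_open] = True
    pop.coverage[n_open:] = 1.0
    pop.vacant_since[n_open:] = -np.inf

    spacing = params.steady_spacing
    phases = rng.uniform(0.0, spacing, n_open)
    counts = np.floor((locus.gene_length - phases) / spacing).astype(int) + 1
    total = int(counts.sum())
    pop.pol_copy = np.repeat(np.arange(n_open), counts)
    if total:
        offsets = np.arange(total) - np.repeat(
            np.concatenate(([0], np.cumsum(counts)[:-1])), counts
        )
        pop.pol_pos = np.repeat(phases, counts) + offsets * spacing
    else:
        pop.pol_pos = np.empty(0, float)
    pop.pol_arrested = np.zeros(total, bool)
    pop.n_initial = total
    pop.sort_pols()
    pop.check_invariants(params.footprint)
    return pop


def advance(
    population: Population,
    lesions: LesionMap,
    params: SimulationParams,
    kinetics: RepairKinetics,
    rng,
    dt: float | None = None,
) -> Population:
    """One composite time step: initiate, move, arrest, release, repair,
    then update chromatin.  Mutates and returns the population."""
    dt = params.dt if dt is None else float(dt)
    if not 0 < dt <= 5.0:
        raise ValueError("dt must be in (0, 5] s")
    rng = _require_rng(rng)
    pop = population
    L = pop.gene_length
    fp = params.footprint
    pop.footprint = fp
    vdt = params.elongation_rate * dt
    SCALE = L + 2.0

    # unrepaired template-strand lesions, sorted by (copy, position)
    uidx = lesions.unrepaired_ts()
    ucopy = lesions.copy_id[uidx]
    upos = lesions.position[uidx]
    ukey = ucopy * SCALE + upos

    def lesion_ahead(pc, pp):
        """Position of nearest unrepaired TS lesion strictly ahead (inf)."""
        out = np.full(pp.size, np.inf)
        gidx = np.full(pp.size, -1)
        if ukey.size and pp.size:
            j = np.searchsorted(ukey, pc * SCALE + pp, side="right")
            ok = j < ukey.size
            sub = np.flatnonzero(ok)
            sub = sub[ucopy[j[sub]] == pc[sub]]
            out[sub] = upos[j[sub]]
            gidx[sub] = uidx[j[sub]]
        return out, gidx

    # 0. arrested polymerases whose blocking lesion was repaired resume
    if pop.pol_arrested.any():
        a = np.flatnonzero(pop.pol_arrested)
        ahead, _ = lesion_ahead(pop.pol_copy[a], pop.pol_pos[a])
        still_blocked = ahead <= pop.pol_pos[a] + 1.0 + 1e-6
        pop.pol_arrested[a[~still_blocked]] = False

    # 1. initiation at copies that are not closed and have a clear promoter
    p_init = min(
        params.entry_probability(dt) * params.post_uv_initiation_factor, 1.0
    )
    attempts = rng.random(pop.n_copies) < p_init
    minpos = np.full(pop.n_copies, np.inf)
    if pop.pol_pos.size:
        np.minimum.at(minpos, pop.pol_copy, pop.pol_pos)
    eligible = attempts & (minpos >= fp) & (pop.classification() != CLOSED)
    new_copies = np.flatnonzero(eligible)
    if new_copies.size:
        pop.pol_copy = np.concatenate((pop.pol_copy, new_copies))
        pop.pol_pos = np.concatenate((pop.pol_pos, np.zeros(new_copies.size)))
        pop.pol_arrested = np.concatenate(
            (pop.pol_arrested, np.zeros(new_copies.size, bool))
        )
        pop.tallies["initiations"] += int(new_copies.size)
        pop.sort_pols()

    pc, pp, pa = pop.pol_copy, pop.pol_pos, pop.pol_arrested
    n = pp.size
    old_pos = pp.copy()

    if n:
        # 2. elongation capped by leader (old position), lesion, gene end
        lead_pos = np.full(n, np.inf)
        same_next = pc[1:] == pc[:-1]
        lead_pos[:-1][same_next] = pp[1:][same_next]
        cap_lead = lead_pos - fp
        ahead, ahead_idx = lesion_ahead(pc, pp)
        cap_les = ahead - 1.0

        target = pp + vdt
        newp = np.minimum(np.minimum(target, cap_lead), cap_les)
        newp = np.maximum(newp, pp)          # never move backward
        newp[pa] = pp[pa]                    # arrested do not move

        terminating = ~pa & (newp >= L - 1e-9)
        arresting = (
            ~pa & ~terminating
            & np.isfinite(cap_les)
            & (newp >= cap_les - 1e-9)
        )
        pa[arresting] = True
        # arrest engages TCR at the lesion; the mark persists through later
        # release of the polymerase (the repair machinery, not the
        # polymerase, carries out the excision)
        mark = ahead_idx[arresting]
        lesions.tcr_marked[mark[mark >= 0]] = True

        pop.pol_pos = newp
        moved = np.flatnonzero(~pa & (newp > old_pos) | arresting)
        pop._traversed = (pc[moved], old_pos[moved], newp[moved])

        pop.tallies["terminations"] += int(terminating.sum())
        keep = ~terminating
        pop.pol_copy, pop.pol_pos, pop.pol_arrested = pc[keep], newp[keep], pa[keep]

        # 3. release of arrested polymerases
        pc, pp, pa = pop.pol_copy, pop.pol_pos, pop.pol_arrested
        n = pp.size
        if n and pa.any():
            contact = np.zeros(n, bool)
            prev_same = pc[1:] == pc[:-1]
            contact[1:] = prev_same & (pp[:-1] >= pp[1:] - fp - 1e-6)
            rel = np.zeros(n, bool)
            if params.release_mode in ("collision", "both") and params.k_collision > 0:
                p_coll = -np.expm1(-params.k_collision * dt / 60.0)
                rel_c = pa & contact & (rng.random(n) < p_coll)
                pop.tallies["releases_collision"] += int(rel_c.sum())
                rel |= rel_c
            if params.release_mode in ("constant", "both") and params.k_release > 0:
                p_spont = -np.expm1(-params.k_release * dt / 60.0)
                rel_s = pa & ~rel & (rng.random(n) < p_spont)
                pop.tallies["releases_spontaneous"] += int(rel_s.sum())
                rel |= rel_s
            if rel.any():
                keep = ~rel
                pop.pol_copy = pc[keep]
                pop.pol_pos = pp[keep]
                pop.pol_arrested = pa[keep]
    else:
        pop._traversed = None

    # 4. repair with the same dt
    transcribed = None
    if kinetics.tcr_rule == "open_copy":
        transcribed = pop.classification() != CLOSED
    repair_update(lesions, dt, kinetics, rng, transcribed=transcribed)

    # 5. chromatin deposition / clearing
    pop.time += dt
    _chromatin.update_chromatin(pop, lesions, pop.chrom_params, dt)

    pop.check_invariants(fp)
    return pop


@dataclass
class Snapshot:
    """Deep-copied state of the population at one requested timepoint."""

    time_h: float
    population: Population
    lesions: LesionMap
    tallies: dict

    @property
    def pre_uv(self) -> bool:
        return self.time_h < 0


@dataclass
class Trajectory:
    """Time-indexed snapshots of a scenario run plus event tallies."""

    locus: RDNAUnit
    params: SimulationParams
    kinetics: RepairKinetics
    snapshots: list = field(default_factory=list)

    def times(self):
        return [s.time_h for s in self.snapshots]

    def at(self, time_h: float) -> Snapshot:
        for s in self.snapshots:
            if abs(s.time_h - time_h) < 1e-9:
                return s
        raise KeyError(f"no snapshot at t = {time_h} h")

    @property
    def pre_uv_snapshot(self) -> Snapshot:
        for s in self.snapshots:
            if s.pre_uv:
                return s
        raise KeyError("trajectory has no pre-UV snapshot")

    def check_conservation(self) -> None:
        """initiations + initial load = terminations + releases + on-template."""
        for s in self.snapshots:
            pop = s.population
            t = s.tallies
            lhs = pop.n_initial + t["initiations"]
            rhs = (
                t["terminations"]
                + t["releases_collision"]
                + t["releases_spontaneous"]
                + pop.n_polymerases
            )
            if lhs != rhs:
                raise SimulationError(
                    f"conservation broken at t={s.time_h} h: {lhs} != {rhs}"
                )

    def to_tsv(self, out_dir) -> None:
        import pathlib

        out = pathlib.Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        tl = []
        for s in self.snapshots:
            tag = f"t{s.time_h:+.2f}h".replace("+", "p").replace("-", "m")
            s.population.to_frame().to_csv(
                out / f"population_{tag}.tsv", sep="\t", index=False
            )
            s.lesions.to_tsv(out / f"lesions_{tag}.tsv")
            tl.append({"time_h": s.time_h, **s.tallies,
                       "on_template": s.population.n_polymerases})
        pd.DataFrame(tl).to_csv(out / "tallies.tsv", sep="\t", index=False)


def run_scenario(
    locus: RDNAUnit,
    profile: DamageRateProfile,
    params: SimulationParams,
    kinetics: RepairKinetics,
    timepoints_h,
    seed,
    open_fraction: float = 0.5,
    chrom_params=None,
) -> Trajectory:
    """Run the UV scenario: steady state, irradiation at t = 0, then repair.

    ``timepoints_h`` must be sorted and contain at least one negative value
    (the pre-UV snapshot).  Snapshots are deep copies; a fixed seed gives an
    identical trajectory.
    """
    timepoints_h = list(timepoints_h)
    if any(b <= a for a, b in zip(timepoints_h, timepoints_h[1:])):
        raise ValueError("timepoints must be strictly increasing")
    if not any(t < 0 for t in timepoints_h):
        raise ValueError("at least one pre-UV (negative) timepoint is required")
    rng = _require_rng(seed)

    pop = initialize_steady_state(locus, params, open_fraction, rng, chrom_params)
    traj = Trajectory(locus=locus, params=params, kinetics=kinetics)

    def snap(t):
        traj.snapshots.append(
            Snapshot(t, pop.copy(), lesions.copy(), dict(pop.tallies))
        )

    lesions = LesionMap.empty(locus.n_copies, locus.gene_length)
    for t in (t for t in timepoints_h if t < 0):
        snap(t)

    # UV flash at t = 0
    lesions = sample_lesion_map(profile, locus, rng)
    current = 0.0
    for t in (t for t in timepoints_h if t >= 0):
        n_steps = int(round((t - current) * 3600.0 / params.dt))
        for _ in range(n_steps):
            advance(pop, lesions, params, kinetics, rng)
        current += n_steps * params.dt / 3600.0
        snap(t)

    traj.check_conservation()
    return traj
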