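"""Noisy "observed" datasets with the statistical structure of the readouts.

Every downstream stage (inference, plotting, CLI) is testable without any
external data: the generators here take noiseless virtual-assay output and
add replicate-level multiplicative lognormal noise (signals are positive
and the reported biological SDs scale roughly with the mean), preserving
the expectation cell by cell.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import chromatin, damage, dynamics, locus as locus_mod
from .damage import _require_rng


@dataclass(frozen=True)
class NoiseSpec:
    """Per-assay multiplicative noise: lognormal CV and replicate count.

    Defaults match the reported experimental design: four independent
    biological replicates with SDs around 20% of the mean.
    """

    cv: float = 0.2
    n_replicates: int = 4

    def __post_init__(self) -> None:
        if self.cv < 0:
            raise ValueError("cv must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")

    @property
    def sigma(self) -> float:
        return math.sqrt(math.log1p(self.cv ** 2))


def _noise_factors(rng, sigma: float, size) -> np.ndarray:
    """Mean-one lognormal multipliers."""
    if sigma == 0:
        return np.ones(size)
    return rng.lognormal(mean=-0.5 * sigma ** 2, sigma=sigma, size=size)


def gen_observed_tables(
    noiseless: pd.DataFrame, noise: NoiseSpec, seed
) -> pd.DataFrame:
    """Replicate-level observed table from a noiseless long-format table.

    Each (row, replicate) cell is the noiseless value times an independent
    mean-one lognormal factor, so per-cell expectations equal the virtual
    assay output.  Reproducible for a fixed seed.
    """
    rng = _require_rng(seed)
    reps = []
    for r in range(noise.n_replicates):
        rep = noiseless.copy()
        rep["replicate"] = r + 1
        rep["value"] = rep["value"].to_numpy(float) * _noise_factors(
            rng, noise.sigma, len(rep)
        )
        reps.append(rep)
    return pd.concat(reps, ignore_index=True)


def gen_repair_timecourse(
    k_per_h: float,
    timepoints_h,
    noise: NoiseSpec,
    seed,
) -> pd.DataFrame:
    """Synthetic repair time course as a damage-signal assay would report it.

    The instrument quantifies the remaining-damage signal S(t) = S0 e^{-kt};
    multiplicative noise therefore acts on S, and the repaired fraction is
    recovered per replicate as 1 - S(t)/S(0).  Columns: time_h, replicate,
    repaired_fraction.
    """
    rng = _require_rng(seed)
    timepoints_h = np.asarray(list(timepoints_h), float)
    rows = []
    for r in range(noise.n_replicates):
        s0 = _noise_factors(rng, noise.sigma, 1)[0]
        st = np.exp(-k_per_h * timepoints_h) * _noise_factors(
            rng, noise.sigma, timepoints_h.size
        )
        for t, s in zip(timepoints_h, st):
            rows.append(
                {"time_h": t, "replicate": r + 1,
                 "repaired_fraction": 1.0 - s / s0}
            )
    return pd.DataFrame(rows)


def gen_damaged_fraction_table(
    profile: damage.DamageRateProfile,
    locus: locus_mod.RDNAUnit,
    regions: dict,
    n_copies_per_replicate: int,
    noise: NoiseSpec,
    seed,
) -> pd.DataFrame:
    """Per-fragment damaged-copy counts from independently sampled lesion
    maps (one map per replicate).  Columns: region, replicate, damaged,
    total."""
    rng = _require_rng(seed)
    rows = []
    for r in range(noise.n_replicates):
        lm = damage.sample_lesion_map(profile, locus, rng,
                                      n_copies=n_copies_per_replicate)
        for name, iv in regions.items():
            damaged_n = int((lm.counts_in(iv) > 0).sum())
            rows.append({"region": name, "replicate": r + 1,
                         "damaged": damaged_n,
                         "total": n_copies_per_replicate})
    return pd.DataFrame(rows)


@dataclass
class ToyFixture:
    """Miniature deterministic scenario: 4 copies, 1,000-bp gene.

    Copies 0 and 1 are open with a single polymerase at 100 bp; copy 0 and
    the closed copy 2 carry a lesion at 500 bp.  All stochastic rates are
    zero, so trajectories are hand-computable at v = 100 nt/s, dt = 1 s:
    the copy-0 polymerase arrests at 499 bp after 4 steps, the copy-1
    polymerase terminates at step 9.
    """

    locus: locus_mod.RDNAUnit
    params: dynamics.SimulationParams
    kinetics: damage.RepairKinetics
    chrom_params: chromatin.ChromatinParams
    population: dynamics.Population
    lesions: damage.LesionMap


def gen_toy_fixture() -> ToyFixture:
    toy_locus = locus_mod.build_locus(
        {
            "gene_length": 1000,
            "n_copies": 4,
            "first_cpd_region_length": 500,
            "short_fragment_length": 200,
            "spacer_length": 300,
            "amplicon_midpoints": {"a": -150.0, "c": 150.0, "e": 800.0},
            "tro_fragments": {2: [100, 350], 3: [400, 650], 4: [700, 950]},
            "regions": {"5prime": [0, 500], "3prime": [500, 1000]},
        }
    )
    params = dynamics.SimulationParams(
        elongation_rate=100.0,
        steady_spacing=250.0,
        footprint=50.0,
        initiation_rate=0.0,
        release_mode="both",
        k_release=0.0,
        k_collision=0.0,
        dt=1.0,
    )
    kinetics = damage.RepairKinetics(k_tcr=0.0, k_ggr=0.0)
    chrom_params = chromatin.ChromatinParams(
        deposition_delay=0.5, deposition_bin=100.0
    )

    pop = dynamics.Population(toy_locus, chrom_params)
    pop.footprint = params.footprint
    pop.pol_copy = np.array([0, 1], np.int64)
    pop.pol_pos = np.array([100.0, 100.0])
    pop.pol_arrested = np.zeros(2, bool)
    pop.initially_open[:2] = True
    pop.hmo1[:2] = True
    pop.coverage[2:] = 1.0
    pop.vacant_since[2:] = -np.inf
    pop.n_initial = 2

    lesions = damage.LesionMap(
        copy_id=np.array([0, 2], np.int64),
        position=np.array([500.0, 500.0]),
        ltype=np.zeros(2, np.int8),
        strand=np.zeros(2, np.int8),
        repaired=np.zeros(2, bool),
        tcr_marked=np.zeros(2, bool),
        n_copies=4,
        gene_length=1000.0,
    )
    return ToyFixture(toy_locus, params, kinetics, chrom_params, pop, lesions)
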