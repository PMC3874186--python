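"""Nucleosome dynamics on damaged rDNA copies.

Once transcription collapses downstream of an unrepaired lesion, the vacated
DNA is repackaged into nucleosomes; Hmo1 stays bound (the retained mark of a
formerly active copy).  Reopening requires physical re-traversal by
polymerases, so after repair the nucleosome-free region grows back from the
5' end.  The state is a per-bin coverage fraction (psoralen and ChEC only
read accessibility, not dyad positions), and the open / intermediate /
closed call applies the two coverage thresholds that correspond to the
a-band, the smear and the i-band on a psoralen gel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .locus import ConfigurationError


@dataclass(frozen=True)
class ChromatinParams:
    """Nucleosome deposition/readout parameters.

    deposition_delay   minutes a bin downstream of an unrepaired lesion must
                       stay polymerase-free before nucleosomes load
    deposition_bin     bin width in bp (~ nucleosome + linker)
    open_threshold     copy (or region) is open when coverage <= this
    closed_threshold   copy is closed when coverage >= this (and empty)
    """

    deposition_delay: float = 5.0
    deposition_bin: float = 200.0
    open_threshold: float = 0.2
    closed_threshold: float = 0.8

    def __post_init__(self) -> None:
        if not 0.0 <= self.open_threshold < self.closed_threshold <= 1.0:
            raise ConfigurationError(
                "require 0 <= open_threshold < closed_threshold <= 1"
            )
        if self.deposition_delay < 0:
            raise ConfigurationError("deposition_delay must be >= 0")


def make_bins(gene_length: float, bin_bp: float):
    """Bin starts and widths covering [0, gene_length); last bin may be short."""
    if bin_bp <= 0 or bin_bp > gene_length:
        raise ConfigurationError(
            f"deposition_bin {bin_bp} does not tile the {gene_length}-bp "
            "coding region"
        )
    starts = np.arange(0.0, gene_length, bin_bp)
    widths = np.minimum(starts + bin_bp, gene_length) - starts
    return starts, widths


def update_chromatin(population, lesions, params: ChromatinParams, dt: float):
    """Deposit nucleosomes on long-vacated DNA downstream of damage; clear
    bins traversed by polymerases this step.  Mutates the population.

    Called by :func:`ribotraffic.dynamics.advance` after each traffic step
    with the same ``dt``.
    """
    pop = population
    now = pop.time
    bw = params.deposition_bin
    nb = pop.bin_starts.size
    fp = getattr(pop, "footprint", 65.0)

    # polymerases currently present keep their bins open to deposition-timer
    # resets; a polymerase spans [pos - footprint, pos]
    pc, pp = pop.pol_copy, pop.pol_pos
    if pp.size:
        b_hi = np.clip((pp // bw).astype(int), 0, nb - 1)
        b_lo = np.clip(((pp - fp) // bw).astype(int), 0, nb - 1)
        pop.vacant_since[pc, b_hi] = now
        pop.vacant_since[pc, b_lo] = now

    # bins traversed by a moving polymerase are wiped clean
    trav = getattr(pop, "_traversed", None)
    if trav is not None and trav[0].size:
        tc, lo, hi = trav
        b0 = np.clip((lo // bw).astype(int), 0, nb - 1)
        b1 = np.clip((hi // bw).astype(int), 0, nb - 1)
        span = int((b1 - b0).max()) if b0.size else 0
        for k in range(span + 1):
            b = np.minimum(b0 + k, b1)
            pop.coverage[tc, b] = 0.0
            pop.vacant_since[tc, b] = now

    # deposition: bins wholly downstream of the first unrepaired TS lesion
    # that have been polymerase-free for at least the deposition delay
    first = lesions.first_unrepaired_by_copy()
    damaged = np.isfinite(first)
    if damaged.any():
        downstream = pop.bin_starts[None, :] >= first[:, None]
        ready = (now - pop.vacant_since) >= params.deposition_delay * 60.0
        load = downstream & ready
        load[~damaged] = False
        pop.coverage[load] = 1.0
    return pop


def reopened_prefix_length(copy_coverage: np.ndarray, bin_starts, bin_widths,
                           open_threshold: float) -> float:
    """Length (bp) of the maximal nucleosome-free prefix from the TSS."""
    below = copy_coverage <= open_threshold
    if below.all():
        return float(bin_starts[-1] + bin_widths[-1])
    stop = int(np.argmin(below))
    return float(bin_starts[stop])


def population_prefix_lengths(population) -> np.ndarray:
    """Per-copy reopened prefix lengths for a whole population."""
    cp = population.chrom_params
    out = np.empty(population.n_copies)
    for i in range(population.n_copies):
        out[i] = reopened_prefix_length(
            population.coverage[i], population.bin_starts,
            population.bin_widths, cp.open_threshold,
        )
    return out
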