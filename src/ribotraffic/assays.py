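"""Virtual instruments mapping a simulated trajectory onto the study readouts.

Five assays are emulated:

* ChIP-qPCR occupancy per amplicon (percent-of-input-like units, pre-UV
  normalised to 1.0, plus an additive background measured at the spacer
  amplicon),
* transcription run-on (TRO) membrane signals and 5'/middle, 5'/3' ratios
  (run-on extends only polymerases with elongating status; arrested ones
  are excluded),
* Miller-spread transcript lengths (most 3' engaged polymerase per visible
  copy, scaled to nm),
* psoralen gel band fractions (open a-band / closed i-band / smear) per
  restriction-fragment region,
* ChEC: selective degradation of the psoralen class that carries the
  micrococcal-nuclease-tagged protein.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dynamics import CLOSED, INTERMEDIATE, OPEN, CLASS_LABELS, Snapshot, Trajectory
from .locus import Interval, RDNAUnit

DEFAULT_CHIP_BACKGROUND = 0.05


def _amplicon_occupancy(snapshot: Snapshot, iv: Interval, footprint: float):
    """Mean per-copy count of polymerases whose footprint overlaps ``iv``."""
    pop = snapshot.population
    pos = pop.pol_pos
    hit = (pos >= iv.start) & (pos - footprint < iv.end)
    return hit.sum() / pop.n_copies


def chip_readout(
    trajectory: Trajectory,
    amplicon: str,
    background: float = DEFAULT_CHIP_BACKGROUND,
) -> pd.Series:
    """ChIP occupancy time course for one amplicon.

    Values are ``background + (1 - background) * occ(t) / occ(pre-UV)`` so a
    coding amplicon reads 1.0 before UV; an amplicon with no signal (e.g.
    the spacer control 'a') reads the background at all times.
    """
    locus = trajectory.locus
    if amplicon not in locus.amplicons:
        raise KeyError(f"unknown amplicon {amplicon!r}")
    iv = locus.amplicons[amplicon]
    fp = trajectory.params.footprint
    base = _amplicon_occupancy(trajectory.pre_uv_snapshot, iv, fp)
    vals = {}
    for s in trajectory.snapshots:
        occ = _amplicon_occupancy(s, iv, fp)
        if base > 0:
            vals[s.time_h] = background + (1.0 - background) * occ / base
        else:
            vals[s.time_h] = background
    return pd.Series(vals, name=amplicon)


def chip_table(
    trajectory: Trajectory,
    amplicons=None,
    background: float = DEFAULT_CHIP_BACKGROUND,
    strain: str = "WT",
) -> pd.DataFrame:
    """Long-format ChIP table over amplicons and snapshot timepoints."""
    names = amplicons or sorted(trajectory.locus.amplicons)
    rows = []
    for name in names:
        series = chip_readout(trajectory, name, background)
        for t, v in series.items():
            rows.append(
                {"assay": "chip", "strain": strain, "timepoint": t,
                 "probe": name, "value": v}
            )
    return pd.DataFrame(rows)


@dataclass
class TROResult:
    """Run-on signal per membrane fragment plus the two diagnostic ratios."""

    signal: dict            # fragment number -> mean elongating pols per copy
    r_5m: float             # fragment 2 / fragment 3
    r_53: float             # fragment 2 / fragment 4
    flags: list             # e.g. 'zero_denominator_r_5m'


def tro_readout(snapshot: Snapshot, locus: RDNAUnit) -> TROResult:
    """Virtual transcription run-on on one snapshot.

    Signal per fragment is the per-copy mean count of elongation-competent
    (status ``elongating``) polymerases inside the fragment; fragment 1 is a
    non-homologous control and always reads 0.
    """
    pop = snapshot.population
    pos = pop.pol_pos[~pop.pol_arrested]
    signal = {}
    for num, iv in sorted(locus.tro_fragments.items()):
        if iv is None:
            signal[num] = 0.0
        else:
            signal[num] = float(
                ((pos >= iv.start) & (pos < iv.end)).sum() / pop.n_copies
            )
    flags = []

    def ratio(a, b, tag):
        if signal.get(b, 0.0) == 0.0:
            flags.append(f"zero_denominator_{tag}")
            return math.nan
        return signal[a] / signal[b]

    return TROResult(
        signal=signal,
        r_5m=ratio(2, 3, "r_5m"),
        r_53=ratio(2, 4, "r_53"),
        flags=flags,
    )


def em_length_readout(snapshot: Snapshot, nm_per_bp: float = 0.34) -> np.ndarray:
    """Miller-spread transcript lengths (nm) of visible gene copies.

    A copy is visible when it is not closed and carries at least one engaged
    polymerase; its apparent length is the position of the most 3' engaged
    polymerase.  Copies without polymerases do not appear as trees.
    """
    if nm_per_bp <= 0:
        raise ValueError("nm_per_bp must be > 0")
    pop = snapshot.population
    cls = pop.classification()
    far = np.full(pop.n_copies, -np.inf)
    if pop.pol_pos.size:
        np.maximum.at(far, pop.pol_copy, pop.pol_pos)
    visible = np.isfinite(far) & (cls != CLOSED)
    return far[visible] * nm_per_bp


def psoralen_gel_readout(snapshot: Snapshot, region: str) -> dict:
    """Fractions of copies in the open / closed / intermediate gel classes
    for one restriction-fragment region.  The spacer region ('IS') is
    nucleosomal in every copy and migrates as a single closed band."""
    pop = snapshot.population
    locus = pop.locus
    if region == "IS":
        return {"open": 0.0, "closed": 1.0, "intermediate": 0.0}
    if region not in locus.regions:
        raise KeyError(f"unknown region {region!r}")
    cls = pop.classification(locus.regions[region])
    n = pop.n_copies
    return {
        "open": float((cls == OPEN).sum() / n),
        "closed": float((cls == CLOSED).sum() / n),
        "intermediate": float((cls == INTERMEDIATE).sum() / n),
    }


_CHEC_PROTEINS = ("RNAPI", "Hmo1", "H2A/H3")


def chec_readout(
    snapshot: Snapshot,
    region: str,
    tagged: str,
    digestion_extent: float,
) -> dict:
    """Residual psoralen-class signal after ChEC digestion.

    Copies that carry the tagged protein within the region lose
    ``digestion_extent`` of their signal; the rest are untouched.  RNAPI is
    present where at least one polymerase sits in the region, Hmo1 follows
    the per-copy retention flag, and histones are present where nucleosome
    coverage exceeds the open threshold.
    """
    if tagged not in _CHEC_PROTEINS:
        raise ValueError(f"unknown tagged protein {tagged!r}; "
                         f"expected one of {_CHEC_PROTEINS}")
    if not 0.0 <= digestion_extent <= 1.0:
        raise ValueError("digestion_extent must be in [0, 1]")
    pop = snapshot.population
    locus = pop.locus
    iv = locus.regions[region] if region != "IS" else locus.is_region
    if region == "IS":
        cls = np.full(pop.n_copies, CLOSED, np.int8)
    else:
        cls = pop.classification(iv)

    if tagged == "RNAPI":
        carrier = np.zeros(pop.n_copies, bool)
        inside = (pop.pol_pos >= iv.start) & (pop.pol_pos < iv.end)
        carrier[np.unique(pop.pol_copy[inside])] = True
    elif tagged == "Hmo1":
        carrier = pop.hmo1.copy()
    else:
        cov = pop.mean_region_coverage(iv) if region != "IS" else \
            np.ones(pop.n_copies)
        carrier = cov > pop.chrom_params.open_threshold

    weight = np.where(carrier, 1.0 - digestion_extent, 1.0)
    n = pop.n_copies
    out = {}
    for code, label in enumerate(CLASS_LABELS):
        out[label] = float(weight[cls == code].sum() / n)
    return out


def assay_tables(
    trajectory: Trajectory,
    strain: str = "WT",
    background: float = DEFAULT_CHIP_BACKGROUND,
) -> pd.DataFrame:
    """All scalar assay readouts of a trajectory as one long-format table."""
    locus = trajectory.locus
    rows = [chip_table(trajectory, background=background, strain=strain)]
    extra = []
    for s in trajectory.snapshots:
        tro = tro_readout(s, locus)
        for num, v in tro.signal.items():
            extra.append({"assay": "tro", "strain": strain,
                          "timepoint": s.time_h, "probe": f"fragment_{num}",
                          "value": v})
        extra.append({"assay": "tro", "strain": strain, "timepoint": s.time_h,
                      "probe": "r_5m", "value": tro.r_5m})
        extra.append({"assay": "tro", "strain": strain, "timepoint": s.time_h,
                      "probe": "r_53", "value": tro.r_53})
        for region in locus.regions:
            frac = psoralen_gel_readout(s, region)
            for label, v in frac.items():
                extra.append({"assay": "psoralen", "strain": strain,
                              "timepoint": s.time_h,
                              "probe": f"{region}:{label}", "value": v})
        lengths = em_length_readout(s)
        extra.append({"assay": "em", "strain": strain, "timepoint": s.time_h,
                      "probe": "mean_length_nm",
                      "value": float(lengths.mean()) if lengths.size else 0.0})
    return pd.concat([rows[0], pd.DataFrame(extra)], ignore_index=True)
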