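"""Coordinate system and genomic intervals of the yeast 35S rDNA unit.

All coordinates are 0-based, half-open, with the transcription start site
(TSS) at 0 and transcription running toward increasing coordinates.  The
intergenic spacer (IS) lies at negative coordinates.  Every other module
(damage sampling, polymerase traffic, chromatin, virtual assays) works in
this frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field


class ConfigurationError(ValueError):
    """Raised when a locus or scenario configuration violates an invariant."""


@dataclass(frozen=True)
class Interval:
    """Half-open genomic interval [start, end) in bp relative to the TSS."""

    start: float
    end: float
    name: str = ""

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ConfigurationError(
                f"interval {self.name!r}: end {self.end} < start {self.start}"
            )

    @property
    def length(self) -> float:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.start + self.end)

    def contains(self, pos: float) -> bool:
        return self.start <= pos < self.end


def interval_overlap(a: Interval | tuple, b: Interval | tuple) -> float:
    """Overlap length in bp of two half-open intervals (symmetric, >= 0)."""
    a = a if isinstance(a, Interval) else Interval(*a[:2])
    b = b if isinstance(b, Interval) else Interval(*b[:2])
    return max(0.0, min(a.end, b.end) - max(a.start, b.start))


# qPCR amplicon midpoints (bp from TSS).  Exact primer coordinates are not
# public; these follow the schematic layout of the locus map.  Amplicon a sits
# in the intergenic spacer and serves as the ChIP background control, b is in
# the promoter, c-g tile the coding region 5'->3'.
DEFAULT_AMPLICON_MIDPOINTS = {
    "a": -1200.0,
    "b": -100.0,
    "c": 800.0,
    "d": 2900.0,
    "e": 3900.0,
    "f": 5000.0,
    "g": 6300.0,
}
DEFAULT_AMPLICON_LENGTH = 150.0

# Run-on membrane fragments: 1 is a non-homologous hybridisation control
# (no locus interval), 2-4 are ~950-bp fragments at the 5' end, middle and
# 3' end of the gene.
DEFAULT_TRO_FRAGMENTS = {
    2: (700.0, 1650.0),
    3: (2900.0, 3850.0),
    4: (5700.0, 6650.0),
}


@dataclass(frozen=True)
class RDNAUnit:
    """Geometry of one rDNA repeat and the probe sets used by the assays.

    The locus is a ``gene_length``-bp transcription unit repeated
    ``n_copies`` times; a fraction of the copies is transcriptionally
    active (open chromatin).  ``first_cpd_region_length`` is the region
    downstream of the TSS within which most copies carry at least one UV
    lesion on the template strand after irradiation, and
    ``short_fragment_length`` the promoter-proximal restriction fragment
    used for the same statistic.
    """

    gene_length: float = 6900.0
    n_copies: int = 150
    first_cpd_region_length: float = 2960.0
    short_fragment_length: float = 860.0
    spacer_length: float = 2440.0
    amplicons: dict = field(default_factory=dict)
    tro_fragments: dict = field(default_factory=dict)
    regions: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_copies < 1:
            raise ConfigurationError("n_copies must be >= 1")
        if not (
            self.gene_length
            > self.first_cpd_region_length
            > self.short_fragment_length
            > 0
        ):
            raise ConfigurationError(
                "require gene_length > first_cpd_region_length > "
                "short_fragment_length > 0"
            )
        if self.spacer_length <= 0:
            raise ConfigurationError("spacer_length must be > 0")
        lo, hi = -self.spacer_length, self.gene_length
        for group in (self.amplicons, self.tro_fragments, self.regions):
            for key, iv in group.items():
                if iv is None:
                    continue
                if iv.start < lo or iv.end > hi:
                    raise ConfigurationError(
                        f"interval {key!r} [{iv.start}, {iv.end}) outside "
                        f"locus bounds [{lo}, {hi})"
                    )
        # fragments 2-4 must be disjoint and ordered 5'->3'
        frags = [self.tro_fragments.get(i) for i in (2, 3, 4)]
        frags = [f for f in frags if f is not None]
        for up, dn in zip(frags, frags[1:]):
            if up.end > dn.start:
                raise ConfigurationError(
                    f"tro_fragments overlap or are out of order: "
                    f"[{up.start},{up.end}) vs [{dn.start},{dn.end})"
                )
        a = self.amplicons.get("a")
        if a is not None and interval_overlap(a, self.coding_region) > 0:
            raise ConfigurationError("amplicon 'a' must lie outside the coding region")

    @property
    def coding_region(self) -> Interval:
        return Interval(0.0, self.gene_length, "coding")

    @property
    def is_region(self) -> Interval:
        return self.regions["IS"]

    def interval(self, name: str) -> Interval:
        """Resolve any named interval (amplicon, fragment number, region)."""
        if name in self.amplicons:
            return self.amplicons[name]
        if name in self.regions:
            return self.regions[name]
        try:
            num = int(name)
        except (TypeError, ValueError):
            num = None
        if num in self.tro_fragments:
            return self.tro_fragments[num]
        raise KeyError(f"no interval named {name!r} in this locus")

    def to_bed(self) -> str:
        """All named intervals as BED text (0-based half-open), TSS-relative."""
        rows = []
        for name, iv in sorted(self.amplicons.items()):
            rows.append((iv.start, f"amplicon_{name}", iv))
        for num, iv in sorted(self.tro_fragments.items()):
            if iv is not None:
                rows.append((iv.start, f"tro_fragment_{num}", iv))
        for name, iv in sorted(self.regions.items()):
            rows.append((iv.start, f"region_{name}", iv))
        rows.sort(key=lambda r: r[0])
        lines = [
            f"rDNA\t{int(iv.start)}\t{int(iv.end)}\t{label}"
            for _, label, iv in rows
        ]
        return "\n".join(lines) + "\n"


def _amplicons_from_config(cfg: dict, length: float) -> dict:
    # an explicit amplicon map replaces the default panel outright
    mids = dict(cfg.get("amplicon_midpoints", DEFAULT_AMPLICON_MIDPOINTS))
    amp_len = float(cfg.get("amplicon_length", length))
    half = amp_len / 2.0
    return {
        name: Interval(mid - half, mid + half, f"amplicon_{name}")
        for name, mid in mids.items()
    }


def build_locus(config: dict | None = None) -> RDNAUnit:
    """Build an :class:`RDNAUnit` from a (possibly empty) configuration dict.

    Recognised keys (all optional): ``gene_length``, ``n_copies``,
    ``first_cpd_region_length``, ``short_fragment_length``, ``spacer_length``,
    ``amplicon_midpoints`` (name -> bp), ``amplicon_length``,
    ``tro_fragments`` (number -> [start, end]), ``regions``
    (name -> [start, end]).
    """
    cfg = dict(config or {})
    gene_length = float(cfg.get("gene_length", 6900.0))
    spacer_length = float(cfg.get("spacer_length", 2440.0))

    tro = {1: None}
    raw_tro = cfg.get("tro_fragments", DEFAULT_TRO_FRAGMENTS)
    for num, bounds in raw_tro.items():
        num = int(num)
        if bounds is None:
            tro[num] = None
        else:
            tro[num] = Interval(float(bounds[0]), float(bounds[1]), f"tro_{num}")

    regions = {"IS": Interval(-spacer_length, 0.0, "IS")}
    if gene_length >= 6700.0:
        # restriction fragments probed on psoralen gels: a 5' fragment
        # carrying most of the 18S region and a 3' fragment within 25S
        regions["18S"] = Interval(0.0, 2230.0, "18S")
        regions["25S"] = Interval(3800.0, 6700.0, "25S")
    for name, bounds in cfg.get("regions", {}).items():
        regions[name] = Interval(float(bounds[0]), float(bounds[1]), name)

    return RDNAUnit(
        gene_length=gene_length,
        n_copies=int(cfg.get("n_copies", 150)),
        first_cpd_region_length=float(cfg.get("first_cpd_region_length", 2960.0)),
        short_fragment_length=float(cfg.get("short_fragment_length", 860.0)),
        spacer_length=spacer_length,
        amplicons=_amplicons_from_config(cfg, DEFAULT_AMPLICON_LENGTH),
        tro_fragments=tro,
        regions=regions,
    )
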