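"""Genomic recombination-rate maps and distance-to-probability conversion.

A recombination map is a set of non-overlapping intervals per chromosome,
each carrying a local recombination rate (probability per megabase).  The
probability of a crossover between two nearby loci in a single meiosis is
approximated as ``rate * distance_in_Mb``, clamped to the physically
meaningful range [0, 0.5].  Maps in deCODE style are distributed as
tab-delimited tables in cM/Mb; 1 cM/Mb corresponds to a crossover
probability of 0.01 per Mb.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field

__all__ = [
    "GenomicInterval",
    "RecombinationMap",
    "MapFormatError",
    "load_map",
    "recombination_probability",
]

#: genome-average recombination rate, ~1 cM/Mb
DEFAULT_RATE_PER_MB = 0.01


class MapFormatError(ValueError):
    """Raised for malformed or inconsistent recombination-map files."""


@dataclass(frozen=True)
class GenomicInterval:
    """A 1-based inclusive genomic interval with a local recombination rate.

    ``rate_per_mb`` is a crossover probability per megabase (dimensionless);
    a value above 0.5/Mb would imply >50 cM/Mb and is rejected as a unit
    error.
    """

    chrom: str
    start: int
    end: int
    rate_per_mb: float

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise MapFormatError(
                f"interval {self.chrom}:{self.start}-{self.end}: start must be < end"
            )
        if not (0.0 <= self.rate_per_mb <= 0.5):
            raise MapFormatError(
                f"rate_per_mb {self.rate_per_mb} outside [0, 0.5] "
                f"(is the file in cM/Mb? pass units='cM_per_Mb')"
            )

    def contains(self, pos: float) -> bool:
        return self.start <= pos <= self.end


@dataclass
class RecombinationMap:
    """Ordered, non-overlapping rate intervals per chromosome with a fallback rate."""

    intervals: dict[str, list[GenomicInterval]] = field(default_factory=dict)
    default_rate_per_mb: float = DEFAULT_RATE_PER_MB

    def __post_init__(self) -> None:
        for chrom, ivs in self.intervals.items():
            ivs.sort(key=lambda iv: iv.start)
            for a, b in zip(ivs, ivs[1:]):
                if b.start <= a.end:
                    raise MapFormatError(
                        f"overlapping intervals on {chrom}: "
                        f"{a.start}-{a.end} and {b.start}-{b.end}"
                    )
        self._starts = {
            chrom: [iv.start for iv in ivs] for chrom, ivs in self.intervals.items()
        }

    def rate_at(self, chrom: str, pos: float) -> float:
        """Local rate (probability/Mb) at ``pos``; the fallback where uncovered."""
        ivs = self.intervals.get(chrom)
        if not ivs:
            return self.default_rate_per_mb
        i = bisect.bisect_right(self._starts[chrom], pos) - 1
        if i >= 0 and ivs[i].contains(pos):
            return ivs[i].rate_per_mb
        return self.default_rate_per_mb


def load_map(
    path: str,
    default_rate: float = DEFAULT_RATE_PER_MB,
    units: str = "cM_per_Mb",
) -> RecombinationMap:
    """Load a tab-delimited map (columns chrom, start, end, rate).

    A header line is recognised by a non-numeric second column and skipped.
    ``units`` is ``"cM_per_Mb"`` (divide by 100) or ``"prob_per_Mb"``.
    """
    if units not in ("cM_per_Mb", "prob_per_Mb"):
        raise ValueError(f"unknown units {units!r}")
    scale = 0.01 if units == "cM_per_Mb" else 1.0
    intervals: dict[str, list[GenomicInterval]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 4:
                raise MapFormatError(f"{path}:{lineno}: expected 4 columns, got {len(fields)}")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
                rate = float(fields[3])
            except ValueError:
                if lineno == 1:  # tolerated header
                    continue
                raise MapFormatError(f"{path}:{lineno}: malformed row {line!r}") from None
            try:
                iv = GenomicInterval(chrom, start, end, rate * scale)
            except MapFormatError as exc:
                raise MapFormatError(f"{path}:{lineno}: {exc}") from None
            intervals.setdefault(chrom, []).append(iv)
    return RecombinationMap(intervals=intervals, default_rate_per_mb=default_rate)


def recombination_probability(
    rmap: RecombinationMap, chrom: str, pos_a: int, pos_b: int
) -> float:
    """Crossover probability between two positions on one chromosome.

    Uses the local rate at the midpoint of the pair times the physical
    distance in Mb, clamped to [0, 0.5].  Zero distance gives exactly 0.
    """
    if pos_a == pos_b:
        return 0.0
    rate = rmap.rate_at(chrom, (pos_a + pos_b) / 2.0)
    prob = rate * abs(pos_a - pos_b) / 1e6
    return min(max(prob, 0.0), 0.5)
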