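"""Genome coordinate bookkeeping.

Chromosome layout, named loci (e.g. the TT4 and TT8 pigmentation genes),
half-open interval arithmetic, and prediction of which PCR amplicons
survive a deletion.  All coordinates are 0-based, half-open ``[start, end)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "GenomicInterval",
    "GenomeLayout",
    "interval_overlap",
    "predict_amplicons",
    "default_arabidopsis_layout",
]


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open interval on a named chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"interval start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"interval end must exceed start: [{self.start}, {self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def __len__(self) -> int:  # pragma: no cover - convenience alias
        return self.length


@dataclass
class GenomeLayout:
    """Ordered chromosomes plus named locus and amplicon-target intervals.

    Parameters
    ----------
    chromosomes
        Ordered ``(name, length_bp)`` pairs.  Lengths must be positive and
        names unique.
    loci
        Named gene/locus intervals (e.g. ``{"TT4": ..., "TT8": ...}``).
    amplicon_targets
        Named PCR primer-pair template intervals.
    """

    chromosomes: list[tuple[str, int]]
    loci: dict[str, GenomicInterval] = field(default_factory=dict)
    amplicon_targets: dict[str, GenomicInterval] = field(default_factory=dict)

    def __post_init__(self) -> None:
        names = [name for name, _ in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names in layout")
        for name, length in self.chromosomes:
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length")
        for label, iv in {**self.loci, **self.amplicon_targets}.items():
            self._check_within(label, iv)

    def _check_within(self, label: str, iv: GenomicInterval) -> None:
        lengths = dict(self.chromosomes)
        if iv.chrom not in lengths:
            raise ValueError(f"{label!r}: unknown chromosome {iv.chrom!r}")
        if iv.end > lengths[iv.chrom]:
            raise ValueError(
                f"{label!r}: interval [{iv.start}, {iv.end}) exceeds "
                f"{iv.chrom} length {lengths[iv.chrom]}"
            )

    @property
    def chrom_names(self) -> list[str]:
        return [name for name, _ in self.chromosomes]

    def chrom_length(self, name: str) -> int:
        for chrom, length in self.chromosomes:
            if chrom == name:
                return length
        raise KeyError(f"unknown chromosome {name!r}")

    def contains(self, iv: GenomicInterval) -> bool:
        lengths = dict(self.chromosomes)
        return iv.chrom in lengths and iv.end <= lengths[iv.chrom]


def interval_overlap(a: GenomicInterval, b: GenomicInterval) -> int:
    """Length in bp of the intersection of two intervals (0 if disjoint
    or on different chromosomes)."""
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def predict_amplicons(
    deletion: GenomicInterval,
    targets: dict[str, GenomicInterval],
    layout: GenomeLayout | None = None,
) -> dict[str, str]:
    """Predict which PCR amplicons amplify in DNA carrying a deletion.

    A primer pair fails if any of its template is deleted, so a target is
    ``"absent"`` iff it overlaps the deletion by at least 1 bp and
    ``"present"`` otherwise.  This reproduces the banding pattern used to
    delimit a deletion with a tiling set of site-specific amplicons.
    """
    if layout is not None:
        known = set(layout.chrom_names)
        for name, iv in targets.items():
            if iv.chrom not in known:
                raise ValueError(
                    f"amplicon target {name!r}: unknown chromosome {iv.chrom!r}"
                )
    return {
        name: ("absent" if interval_overlap(deletion, iv) > 0 else "present")
        for name, iv in targets.items()
    }


#: TAIR10 nuclear chromosome lengths (bp); organelles deliberately excluded
#: because the RRD normalization median is taken over the five nuclear
#: chromosomes only.
_TAIR10_CHROMOSOMES: list[tuple[str, int]] = [
    ("Chr1", 30_427_671),
    ("Chr2", 19_698_289),
    ("Chr3", 23_459_830),
    ("Chr4", 18_585_056),
    ("Chr5", 26_975_502),
]


def default_arabidopsis_layout() -> GenomeLayout:
    """Five nuclear Arabidopsis chromosomes with default TT4/TT8 loci.

    TT8 (4643 bp, chromosome 4) and TT4 (1789 bp, chromosome 5) default to
    their TAIR10 gene positions; both are plain config values and can be
    overridden via a layout file.
    """
    return GenomeLayout(
        chromosomes=list(_TAIR10_CHROMOSOMES),
        loci={
            "TT8": GenomicInterval("Chr4", 6_169_524, 6_169_524 + 4643),
            "TT4": GenomicInterval("Chr5", 4_505_572, 4_505_572 + 1789),
        },
    )
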