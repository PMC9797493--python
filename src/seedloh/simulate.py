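"""Synthetic inputs with the statistical structure the pipeline assumes.

Seed-coat-enriched DNA is modeled as a cell mixture: a fraction ``m`` of
cells carries a heterozygous megabase-scale deletion (copy number 1 over
the deleted region) and the remaining ``1 − m`` contaminating cells
(endosperm etc.) are unmutated (copy number 2).  Per-bin sequencing depth
is Poisson around λ·c/2, where c is the local mixture copy number.  Ct
values follow perfect-efficiency amplification with Gaussian noise, and
screening/survival counts are multinomial/binomial draws.

Every simulator is bit-reproducible given its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import GenomeLayout, GenomicInterval, interval_overlap
from .qpcr import AlleleCopyModel, DEFAULT_ALLELE_MODEL, expected_copy_numbers
from .screening import ScreeningCounts
from .survival import survival_probability

__all__ = [
    "MosaicSimParams",
    "QpcrSimParams",
    "SurvivalSimParams",
    "simulate_bins",
    "simulate_qpcr",
    "simulate_screening",
    "simulate_survival",
]


@dataclass
class MosaicSimParams:
    """Conditions for one simulated seed-coat sequencing sample.

    ``mean_depth`` is the expected depth of a copy-number-2 bin; a bin
    overlapping the deletion by fraction f has copy number 2 − m·f and
    expected depth mean_depth·(2 − m·f)/2.
    """

    layout: GenomeLayout
    deletion: GenomicInterval | None = None
    mutant_fraction: float = 0.7
    mean_depth: float = 50.0
    bin_size: int = 100_000
    seed: int = 0
    overdispersion: float = 0.0  # gamma-Poisson dispersion; 0 = pure Poisson

    def __post_init__(self) -> None:
        if not 0.0 <= self.mutant_fraction <= 1.0:
            raise ValueError("mutant_fraction must be in [0, 1]")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        if self.overdispersion < 0:
            raise ValueError("overdispersion must be >= 0")
        if self.deletion is not None and not self.layout.contains(self.deletion):
            raise ValueError(
                f"deletion {self.deletion} lies outside the genome layout"
            )


def _tile_bins(layout: GenomeLayout, bin_size: int) -> pd.DataFrame:
    rows = []
    for chrom, length in layout.chromosomes:
        starts = np.arange(0, length, bin_size)
        ends = np.minimum(starts + bin_size, length)
        rows.append(pd.DataFrame({"chrom": chrom, "start": starts, "end": ends}))
    return pd.concat(rows, ignore_index=True)


def simulate_bins(params: MosaicSimParams) -> pd.DataFrame:
    """Per-bin mean depths for a mosaic sample; columns
    ``chrom, start, end, mean_depth``."""
    rng = np.random.default_rng(params.seed)
    bins = _tile_bins(params.layout, params.bin_size)
    widths = (bins["end"] - bins["start"]).to_numpy(dtype=float)
    frac = np.zeros(len(bins))
    if params.deletion is not None:
        for i, (chrom, start, end) in enumerate(
            zip(bins["chrom"], bins["start"], bins["end"])
        ):
            ov = interval_overlap(
                GenomicInterval(chrom, int(start), int(end)), params.deletion
            )
            frac[i] = ov / (end - start)
    copy_number = 2.0 - params.mutant_fraction * frac
    # expected mean depth per bin; partial end bins draw proportionally
    # fewer counts so that E[mean_depth] stays λ·c/2 at any width
    mu = params.mean_depth * copy_number / 2.0
    width_frac = widths / params.bin_size
    lam = mu * width_frac
    if params.overdispersion > 0:
        shape = 1.0 / params.overdispersion
        lam = rng.gamma(shape, lam / shape)
    counts = rng.poisson(lam)
    bins["mean_depth"] = counts / width_frac
    return bins


@dataclass
class QpcrSimParams:
    """Conditions for one simulated comparative-Ct experiment."""

    mutant_type: str = "control"  # tt4 | tt8 | control
    m: float = 0.0
    base_ct: float = 20.0
    ct_noise_sd: float = 0.0
    replicates: int = 3
    seed: int = 0
    sample: str | None = None
    model: AlleleCopyModel = field(default_factory=lambda: DEFAULT_ALLELE_MODEL)

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("need at least one replicate")
        if self.ct_noise_sd < 0:
            raise ValueError("ct_noise_sd must be >= 0")


def simulate_qpcr(params: QpcrSimParams) -> pd.DataFrame:
    """Ct replicate table (``sample, target, replicate, ct``) for the
    TT4 and TT8 targets.

    With perfect doubling per cycle, halving the template raises Ct by one
    cycle: Ct = base_ct − log2(relative copies) + N(0, ct_noise_sd).
    """
    rng = np.random.default_rng(params.seed)
    rel = expected_copy_numbers(params.m, params.mutant_type, params.model)
    sample = params.sample or params.mutant_type
    rows = []
    for target in sorted(rel):
        ct0 = params.base_ct - np.log2(rel[target])
        noise = rng.normal(0.0, params.ct_noise_sd, size=params.replicates)
        for r in range(params.replicates):
            rows.append(
                {
                    "sample": sample,
                    "target": target,
                    "replicate": r + 1,
                    "ct": ct0 + noise[r],
                }
            )
    return pd.DataFrame(rows)


def simulate_screening(
    n_plants: int,
    p_locus: dict[str, float],
    seed: int = 0,
    group: str = "irradiation",
) -> ScreeningCounts:
    """Multinomial screening outcome over {tt4-type, tt8-type, none}.

    ``p_locus`` maps ``"tt4"``/``"tt8"`` to per-plant detection
    probabilities; the probabilities must sum to at most 1.
    """
    p4 = float(p_locus.get("tt4", 0.0))
    p8 = float(p_locus.get("tt8", 0.0))
    if p4 < 0 or p8 < 0 or p4 + p8 > 1.0:
        raise ValueError("locus probabilities must be >= 0 and sum to <= 1")
    rng = np.random.default_rng(seed)
    n_tt4, n_tt8, _ = rng.multinomial(n_plants, [p4, p8, 1.0 - p4 - p8])
    return ScreeningCounts(
        n_observed=n_plants,
        n_mutant=int(n_tt4 + n_tt8),
        n_tt4=int(n_tt4),
        n_tt8=int(n_tt8),
        group=group,
    )


@dataclass
class SurvivalSimParams:
    """Conditions for a simulated dose–survival experiment."""

    D0: float = 10.0
    N: float = 20.0
    doses: tuple[float, ...] = (0.0, 10.0, 20.0, 30.0, 40.0, 50.0, 60.0)
    n_per_dose: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.D0 <= 0:
            raise ValueError("D0 must be positive")
        if self.N < 1:
            raise ValueError("N must be >= 1")
        if any(d < 0 for d in self.doses):
            raise ValueError("doses must be non-negative")


def simulate_survival(params: SurvivalSimParams) -> pd.DataFrame:
    """Binomial survivor counts per dose; columns
    ``dose_gy, n_total, n_survived``."""
    rng = np.random.default_rng(params.seed)
    rows = []
    for d in params.doses:
        s = survival_probability(d, params.D0, params.N)
        rows.append(
            {
                "dose_gy": float(d),
                "n_total": params.n_per_dose,
                "n_survived": int(rng.binomial(params.n_per_dose, s)),
            }
        )
    return pd.DataFrame(rows)
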