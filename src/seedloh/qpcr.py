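"""Comparative-Ct (ΔΔCt) quantification of the TT4:TT8 copy ratio.

The measured quantity is the ratio of TT4 to TT8 template copies in
seed-coat-enriched DNA, normalized against the same ratio in non-irradiated
control plants.  Under perfect doubling per cycle,

    ΔCt       = mean Ct(TT4) − mean Ct(TT8)           (per sample)
    ratio     = 2^−(ΔCt_sample − ΔCt_control)

A forward model predicts that ratio for a mosaic tissue in which a fraction
``m`` of cells carries a heterozygous deletion removing the wild-type allele
at one locus, with the remaining ``1 − m`` contaminating cells (endosperm
etc.) contributing unmutated template.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "AlleleCopyModel",
    "DEFAULT_ALLELE_MODEL",
    "QpcrRatioResult",
    "normalized_ratio",
    "replicate_ratios",
    "expected_copy_numbers",
    "expected_ratio",
]

MUTANT_TYPES = ("tt4", "tt8", "control")


@dataclass(frozen=True)
class AlleleCopyModel:
    """Copies of each qPCR target on the two alleles of the control
    double heterozygote.

    Each entry maps a target name to ``(copies_on_wildtype_allele,
    copies_on_mutant_allele)``.  The default reflects the screening cross:
    the TT4 target sequence sits on the wild-type TT4 allele but is absent
    from the mutant allele (which carries a pre-existing deletion), so the
    control has a single copy; the TT8 target survives on both alleles
    (the mutant allele differs only by a single-nucleotide lesion), so the
    control has two copies.
    """

    copies: dict[str, tuple[int, int]] = field(
        default_factory=lambda: {"TT4": (1, 0), "TT8": (1, 1)}
    )

    def __post_init__(self) -> None:
        for target, (wt, mut) in self.copies.items():
            if wt not in (0, 1) or mut not in (0, 1):
                raise ValueError(
                    f"target {target!r}: allele copies must be 0 or 1"
                )

    def control_copies(self, target: str) -> int:
        wt, mut = self.copies[target]
        return wt + mut


DEFAULT_ALLELE_MODEL = AlleleCopyModel()


@dataclass(frozen=True)
class QpcrRatioResult:
    """Control-normalized TT4:TT8 copy ratio for one sample."""

    sample: str
    ratio: float
    control_delta_ct: float
    se: float | None = None


def _mean_ct(rows: pd.DataFrame, target: str, sample: str) -> float:
    sub = rows.loc[rows["target"] == target, "ct"]
    if sub.empty:
        raise ValueError(
            f"sample {sample!r} has no Ct replicates for target {target!r}"
        )
    return float(sub.mean())


def _delta_ct(rows: pd.DataFrame, sample: str) -> float:
    return _mean_ct(rows, "TT4", sample) - _mean_ct(rows, "TT8", sample)


def normalized_ratio(
    sample_cts: pd.DataFrame, control_cts: pd.DataFrame
) -> QpcrRatioResult:
    """Comparative-Ct TT4:TT8 ratio of a sample, normalized to a control.

    Both tables need columns ``sample, target, replicate, ct`` and rows for
    both targets.  Replicates are summarized by the mean Ct before ΔCt.
    """
    sample = str(sample_cts["sample"].iloc[0]) if len(sample_cts) else "?"
    control = str(control_cts["sample"].iloc[0]) if len(control_cts) else "?"
    d_sample = _delta_ct(sample_cts, sample)
    d_control = _delta_ct(control_cts, control)
    ratio = float(2.0 ** -(d_sample - d_control))
    return QpcrRatioResult(sample=sample, ratio=ratio, control_delta_ct=d_control)


def replicate_ratios(
    sample_cts: pd.DataFrame, control_cts: pd.DataFrame
) -> QpcrRatioResult:
    """Per-replicate ratios summarized as mean and standard error.

    Each replicate index present for both targets of the sample yields one
    ΔCt and hence one normalized ratio against the control's mean ΔCt;
    the result carries the mean ratio and the SE over replicates (``None``
    with a single replicate).
    """
    sample = str(sample_cts["sample"].iloc[0]) if len(sample_cts) else "?"
    control = str(control_cts["sample"].iloc[0]) if len(control_cts) else "?"
    d_control = _delta_ct(control_cts, control)
    wide = sample_cts.pivot_table(
        index="replicate", columns="target", values="ct"
    )
    for target in ("TT4", "TT8"):
        if target not in wide.columns:
            raise ValueError(
                f"sample {sample!r} has no Ct replicates for target {target!r}"
            )
    wide = wide.dropna(subset=["TT4", "TT8"])
    ratios = 2.0 ** -((wide["TT4"] - wide["TT8"]) - d_control)
    se = float(ratios.std(ddof=1) / np.sqrt(len(ratios))) if len(ratios) > 1 else None
    return QpcrRatioResult(
        sample=sample,
        ratio=float(ratios.mean()),
        control_delta_ct=d_control,
        se=se,
    )


def expected_copy_numbers(
    m: float,
    mutant_type: str,
    model: AlleleCopyModel = DEFAULT_ALLELE_MODEL,
) -> dict[str, float]:
    """Per-target template copies relative to the control, for a mosaic
    in which fraction ``m`` of cells lost the wild-type allele at the
    mutated locus.

    Mutant cells at the mutated locus retain only the target copies on the
    (pre-existing) mutant allele; the other locus and all contaminating
    cells are unchanged.
    """
    if not 0.0 <= m <= 1.0:
        raise ValueError(f"mutant fraction must be in [0, 1], got {m}")
    if mutant_type not in MUTANT_TYPES:
        raise ValueError(
            f"mutant_type must be one of {MUTANT_TYPES}, got {mutant_type!r}"
        )
    rel: dict[str, float] = {}
    for target, (wt, _mut) in model.copies.items():
        control = model.control_copies(target)
        if mutant_type != "control" and target.lower() == mutant_type:
            mutant_cell = control - wt
            copies = (1.0 - m) * control + m * mutant_cell
        else:
            copies = float(control)
        rel[target] = copies / control
    return rel


def expected_ratio(
    m: float,
    mutant_type: str,
    model: AlleleCopyModel = DEFAULT_ALLELE_MODEL,
) -> float:
    """Model-predicted control-normalized TT4:TT8 ratio at mosaic fraction m."""
    rel = expected_copy_numbers(m, mutant_type, model)
    return rel["TT4"] / rel["TT8"]
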