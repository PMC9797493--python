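"""End-to-end orchestration: depth → RRD → deletion calls, qPCR ratios,
screening statistics, and mutant classification."""

from __future__ import annotations

from typing import Any

import pandas as pd

from . import dosage, qpcr, screening
from .dosage import DeletionCall
from .genome import GenomeLayout, interval_overlap, default_arabidopsis_layout
from .io import PipelineConfig, read_layout
from .qpcr import QpcrRatioResult
from .screening import ScreeningCounts

__all__ = ["PipelineError", "classify_mutant", "run_pipeline"]

#: qPCR ratios within [1/RATIO_BAND, RATIO_BAND] are treated as inconclusive
#: so that replicate noise around 1 does not drive a classification.
RATIO_BAND = 1.25


class PipelineError(RuntimeError):
    """A stage failure, annotated with the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def classify_mutant(
    calls: list[DeletionCall],
    ratio: QpcrRatioResult | None,
    layout: GenomeLayout,
) -> str:
    """tt4-type / tt8-type / unclassified from deletion calls and the
    control-normalized TT4:TT8 ratio.

    A deletion call overlapping the TT4 locus, or a ratio below 1/1.25,
    is tt4-type evidence; a call overlapping TT8, or a ratio above 1.25,
    is tt8-type evidence.  Conflicting or absent evidence stays
    unclassified.
    """
    evid_tt4 = evid_tt8 = False
    for locus_name, flag in (("TT4", "tt4"), ("TT8", "tt8")):
        locus = layout.loci.get(locus_name)
        if locus is None:
            continue
        if any(interval_overlap(c.interval, locus) > 0 for c in calls):
            if flag == "tt4":
                evid_tt4 = True
            else:
                evid_tt8 = True
    if ratio is not None:
        if ratio.ratio < 1.0 / RATIO_BAND:
            evid_tt4 = True
        elif ratio.ratio > RATIO_BAND:
            evid_tt8 = True
    if evid_tt4 and not evid_tt8:
        return "tt4-type"
    if evid_tt8 and not evid_tt4:
        return "tt8-type"
    return "unclassified"


def _stage(name: str):
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineError):
                raise PipelineError(name, str(exc)) from exc
            return False

    return _Ctx()


def run_pipeline(
    config: PipelineConfig,
    depth_input: pd.DataFrame,
    ct_input: pd.DataFrame | None = None,
    counts_input: pd.DataFrame | None = None,
    *,
    depth_is_binned: bool = True,
    layout: GenomeLayout | None = None,
) -> dict[str, Any]:
    """Run dosage, qPCR and screening analyses and return one report dict.

    ``depth_input`` is either a pre-binned table (chrom, start, end,
    mean_depth) or a per-base depth table (chrom, pos, depth) with
    ``depth_is_binned=False``.  The report is deterministic given inputs.
    """
    if layout is None:
        layout = (
            read_layout(config.layout_path)
            if config.layout_path
            else default_arabidopsis_layout()
        )
    report: dict[str, Any] = {"seed": config.seed}

    with _stage("dosage"):
        bins = (
            depth_input
            if depth_is_binned
            else dosage.bin_depths(depth_input, layout, config.bin_size)
        )
        rrd = dosage.compute_rrd(bins)
        if config.refine_boundaries:
            calls = dosage.call_deletions_refined(
                rrd, threshold=config.rrd_threshold, min_bins=config.min_bins
            )
        else:
            calls = dosage.call_deletions(
                rrd,
                threshold=config.rrd_threshold,
                min_bins=config.min_bins,
                gap=config.gap,
            )
        report["rrd"] = {
            "n_bins": int(len(rrd.bins)),
            "normalization_constant": rrd.normalization_constant,
            "median_rrd": float(rrd.bins["rrd"].median()),
        }
        report["deletion_calls"] = [
            {
                "chrom": c.interval.chrom,
                "start": c.interval.start,
                "end": c.interval.end,
                "n_bins": c.n_bins,
                "size_bp": c.size_bp,
                "mean_rrd": c.mean_rrd,
                "mutant_fraction_est": c.mutant_fraction_est,
            }
            for c in calls
        ]

    ratio_result: QpcrRatioResult | None = None
    if ct_input is not None:
        with _stage("qpcr"):
            control = ct_input[ct_input["sample"] == config.control_sample]
            if control.empty:
                raise ValueError(
                    f"control sample {config.control_sample!r} absent from Ct table"
                )
            ratios = {}
            for sample, sub in ct_input.groupby("sample"):
                if sample == config.control_sample:
                    continue
                res = qpcr.replicate_ratios(sub, control)
                ratios[str(sample)] = {"ratio": res.ratio, "se": res.se}
                ratio_result = res  # last non-control sample
            report["qpcr_ratios"] = ratios

    if counts_input is not None:
        with _stage("screening"):
            tests = []
            l4 = config.gene_lengths.get("TT4", 1789)
            l8 = config.gene_lengths.get("TT8", 4643)
            p_len = screening.length_weighted_null(l4, l8)
            for row in counts_input.itertuples():
                counts = ScreeningCounts(
                    n_observed=int(row.n_observed),
                    n_mutant=int(row.n_mutant),
                    n_tt4=int(row.n_tt4),
                    n_tt8=int(row.n_tt8),
                    group=str(row.group),
                )
                entry: dict[str, Any] = {
                    "group": counts.group,
                    "mutation_frequency_pct": screening.mutation_frequency(counts),
                }
                if counts.n_mutant > 0:
                    equal = screening.binom_test_exact(
                        counts.n_tt4, counts.n_mutant, 0.5, "two"
                    )
                    weighted = screening.binom_test_exact(
                        counts.n_tt4, counts.n_mutant, p_len, "one-less"
                    )
                    entry["equal_null_two_sided_p"] = equal.p_value
                    entry["length_weighted_one_sided_p"] = weighted.p_value
                    entry["length_weighted_p0"] = p_len
                tests.append(entry)
            report["screening"] = tests

    with _stage("classification"):
        report["classification"] = classify_mutant(calls, ratio_result, layout)

    return report
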