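"""One mutant line through the whole pipeline.

Simulates a tt8-type mosaic sample (deletion spanning TT8, 70% mutant
cells), then runs dosage analysis, qPCR ratio quantification and the
screening statistics in one call and prints the combined report.
"""

import json

import pandas as pd

from seedloh import (
    GenomicInterval,
    MosaicSimParams,
    PipelineConfig,
    QpcrSimParams,
    default_arabidopsis_layout,
    run_pipeline,
    simulate_bins,
    simulate_qpcr,
)

layout = default_arabidopsis_layout()
deletion = GenomicInterval("Chr4", 5_500_000, 7_000_000)

bins = simulate_bins(
    MosaicSimParams(
        layout=layout, deletion=deletion, mutant_fraction=0.7,
        mean_depth=50.0, seed=11,
    )
)
cts = pd.concat(
    [
        simulate_qpcr(QpcrSimParams(mutant_type="control", sample="control", seed=11)),
        simulate_qpcr(
            QpcrSimParams(
                mutant_type="tt8", m=0.7, ct_noise_sd=0.15, sample="mut-1", seed=12
            )
        ),
    ],
    ignore_index=True,
)
counts = pd.DataFrame(
    [{"group": "irradiation", "n_observed": 2588, "n_mutant": 19,
      "n_tt4": 2, "n_tt8": 17}]
)

report = run_pipeline(PipelineConfig(seed=11), bins, cts, counts, layout=layout)
print(json.dumps(report, indent=2))
# classification should be "tt8-type": the called deletion overlaps TT8
# and the TT4:TT8 ratio is well above 1.
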