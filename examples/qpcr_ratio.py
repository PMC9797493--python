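"""Comparative-Ct quantification of the TT4:TT8 copy ratio.

A tt4-type mosaic (75% mutant cells) loses its single TT4 target copy in
mutant cells, so the control-normalized TT4:TT8 ratio drops to 0.25; a
tt8-type mosaic (70% mutant cells) loses one of two TT8 copies, raising
the ratio to 2/1.3 ~ 1.54.  The measured ratios from simulated Ct tables
match the forward model.
"""

from seedloh import (
    QpcrSimParams,
    expected_ratio,
    normalized_ratio,
    simulate_qpcr,
)

control = simulate_qpcr(QpcrSimParams(mutant_type="control", sample="control"))

for mutant_type, m in [("tt4", 0.75), ("tt8", 0.7)]:
    sample = simulate_qpcr(
        QpcrSimParams(mutant_type=mutant_type, m=m, ct_noise_sd=0.15, seed=4)
    )
    measured = normalized_ratio(sample, control)
    print(
        f"{mutant_type}-type mosaic, m={m}: measured ratio "
        f"{measured.ratio:.3f}, model {expected_ratio(m, mutant_type):.3f}"
    )
# Ratios well below 1 indicate TT4 loss; well above 1, TT8 loss.
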