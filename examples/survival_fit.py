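"""Fit the single-hit multitarget survival model to a dose series.

Seedlings irradiated at increasing doses survive according to
S(D) = 1 - (1 - exp(-D/D0))^N.  Fitting (D0, N) to binomial survivor
counts recovers the quasi-threshold (shoulder) dose Dq = D0 ln N — the
dose where survival starts to fall steeply, used to pick a mutagenesis
dose (e.g. half the shoulder).
"""

from seedloh import (
    SurvivalSimParams,
    fit_multitarget,
    shoulder_dose,
    simulate_survival,
)

data = simulate_survival(
    SurvivalSimParams(
        D0=10.0, N=20.0, doses=(0, 10, 20, 30, 40, 50, 60), n_per_dose=50, seed=8
    )
)
print(data.to_string(index=False))

fit = fit_multitarget(data)
print(
    f"\nfit: D0 = {fit.D0:.2f} Gy, N = {fit.N:.1f}, "
    f"shoulder dose Dq = {shoulder_dose(fit):.1f} Gy (true 30.0 Gy)"
)
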