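"""Clean vs contaminated kinetics: why the short-time fit matters.

Generates two synthetic first-passage-time samples with a true MFPT of
110 ns — one exactly exponential (Poisson kinetics), one with the
inflated tail that bias overdeposition produces — and runs both
estimators on each.
"""

import stimetad as st
from stimetad.synthetic import ContaminationModel, sample_contaminated_fpts

TRUE_MFPT = 110.0

clean = st.sample_exponential_fpts(1.0 / TRUE_MFPT, 1000, seed=0)
dirty = sample_contaminated_fpts(ContaminationModel(), 1000, seed=0)

for name, sample in [("clean exponential", clean), ("contaminated tail", dirty)]:
    std = st.fit_exponential_imetad(sample)
    short = st.st_fit(sample)
    print(f"{name} (true MFPT {TRUE_MFPT:.0f} ns):")
    print(f"  whole-sample exponential fit: {std.mfpt:7.1f} ns  (KS p = {std.p_value:.2g})")
    print(f"  short-time survival fit:      {short.mfpt:7.1f} ns  (t* = {short.t_star:.1f} ns)")

print()
print("On clean data the two estimators agree; on contaminated data the")
print("whole-sample fit inflates by the tail while the short-time fit,")
print("restricted to t <= t*, stays near the true 110 ns.")
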