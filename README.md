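# stimetad — short-time kinetics inference for infrequent metadynamics

Infrequent metadynamics (iMetaD) recovers unbiased transition rates from
biased molecular simulations: each biased trajectory's first-passage time
(FPT) t is stretched by the bias it experienced,

    τ = Σ_i Δt · exp(β V(s(t_i), t_i)),

and the rescaled times τ are fitted to an exponential distribution, whose
mean estimates the unbiased mean first-passage time (MFPT).  This works
only while no bias reaches the transition state.  With frequent hill
deposition or a suboptimal collective variable (CV), overdeposited bias
inflates the long rescaled times, the distribution grows a
slower-than-exponential tail, and the whole-sample fit can overestimate
the MFPT by orders of magnitude.

The short-time estimator implemented here exploits the fact that short
trajectories experience minimal bias, so the *short-time* part of the
rescaled survival function S(t) = 1 − P(τ ≤ t) still follows the unbiased
law.  Since Poisson kinetics have a single parameter, that part is enough:
fit the one-parameter line

    log S(t) = −k t,   t ≤ t*,

scanning the cutoff t* over the observed order statistics and keeping the
cutoff with the highest squared Pearson correlation between t and
log S(t).  The MFPT estimate is 1/k.  Uncertainty comes from bootstrap
over resampled batches (quartiles and 1.5·IQR whiskers).

The package is for practitioners of enhanced-sampling kinetics who want
to post-process existing iMetaD (or OPES-flooding-style) data, and it is
self-validating: it bundles

* a 2D underdamped Langevin (BAOAB) simulator of the Wolfe–Quapp
  two-state potential with well-tempered metadynamics on a rotatable 1D
  CV and a committor-style stopping region, which regenerates
  validation data from scratch;
* synthetic FPT generators (clean Poisson kinetics, and a
  breakpoint-inflation model of overdeposition corruption) with closed
  forms for ground truth;
* both inference routes (whole-sample exponential fit + KS reliability
  test, and the short-time survival fit), bootstrap, and speedup
  accounting;
* plain-text I/O: PLUMED-style COLVAR/HILLS tables, one-number-per-line
  FPT lists, INI configs, and reproducible run manifests.

## Worked example

```python
import stimetad as st
from stimetad.synthetic import ContaminationModel, sample_contaminated_fpts

clean = st.sample_exponential_fpts(1/110, 1000, seed=0)   # true MFPT 110 ns
dirty = sample_contaminated_fpts(ContaminationModel(), 1000, seed=0)

for name, sample in [("clean", clean), ("contaminated", dirty)]:
    std, short = st.fit_exponential_imetad(sample), st.st_fit(sample)
    print(name, round(std.mfpt, 1), round(std.p_value, 2),
          round(short.mfpt, 1), round(short.t_star, 1))
```

prints

```
clean 114.9 0.73 111.7 350.4
contaminated 613.6 0.0 129.3 20.8
```

On clean exponential data both estimators agree with the true 110 ns and
the Kolmogorov–Smirnov reliability test passes (p = 0.73).  On data with
an overdeposition-style inflated tail, the whole-sample fit balloons to
614 ns and the KS test rejects, while the short-time fit identifies the
corruption onset (t* ≈ 21 ns, the generator's true breakpoint) and stays
within ~18% of the truth.

The `examples/` directory has one narrative script per capability
(synthetic inference, simulation + rescaling, cutoff selection, the
end-to-end pipeline); each prints the numbers it computes and what they
mean.  The same pipeline is scriptable from the shell:

```sh
stimetad synth --model contaminated -n 1000 -o fpt.dat
stimetad infer fpt.dat --method both --bootstrap 1000 --batch-size 200
stimetad run config.ini -o out/     # simulate -> rescale -> infer
```

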