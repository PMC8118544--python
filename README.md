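# msceapc

Multistage clonal expansion (MSCE) modeling of esophageal squamous cell
carcinoma (ESCC) incidence, with regularized age-period-cohort (APC)
trends acting directly on the biology of the model.

## The problem and the model

US registry data show strikingly dynamic ESCC incidence: roughly 4-fold
higher rates among black males in the 1980s than today, monotone declines
among white males, and strong cohort patterns. Traditional APC analyses
attach multiplicative period/cohort constants to an unadjusted age curve,
which says nothing about *when in life* the relevant exposures act. This
package instead embeds historical trends inside a stochastic
carcinogenesis model:

1. A premalignant **field-defect** (FD) arises in the esophagus as the
   first event of a nonhomogeneous Poisson process with rate
   ν_FD(s; B) for a subject of birth year B at age s (calendar year
   y = B + s),

   ν_FD(s; B) = ν₀ · exp[w₁(y−y₀)²(1+w₂(y−y₀))] · exp[b₁(B−B₀)²(1+b₂(B−B₀))] · max(0, log(s/s₀)),

   where the period and cohort factors equal 1 for y ≥ y₀ and B ≥ B₀
   (B₀ = y₀), and the log(s/s₀) term forces ν_FD → 0 below an onset age
   s₀ (early childhood).
2. Within the field, dysplastic clones initiate at rate μ₁, expand as a
   linear birth–death process (division α, death β), and transform
   malignantly at per-cell rate μ₂. The two-stage clonal expansion (TSCE)
   kernel has hazard and survival

   h₂(u) = (μ₁/α)·pq(e^{−qu} − e^{−pu}) / (q e^{−pu} − p e^{−qu}),
   S₂(u) = [(q−p)/(q e^{−pu} − p e^{−qu})]^{μ₁/α},

   with p, q = ½[−α+β+μ₂ ∓ √((α+β+μ₂)² − 4αβ)]. The fitted
   combinations are the net proliferation g = −(p+q) = α−β−μ₂ (itself
   cohort-adjusted, g = g₀·exp[g₁(B−1800)(1+g₂(B−1800))]) and the
   product pq = −αμ₂; α is fixed at 17.4/yr (esophageal stem-cell
   division rate) because it is not identifiable from incidence data.
3. The population hazard is the field-defect convolution, conditioned on
   no prior cancer, with a fixed 5-year lag from first malignant cell to
   clinical detection:

   h(t) = ∫₀ᵗ f_FD(s) h₂(t−s) S₂(t−s) ds / [1 − ∫₀ᵗ f_FD(s)(1 − S₂(t−s)) ds],
   with f_FD(s) = ν_FD(s) e^{−∫₀ˢ ν_FD}, and h_clinical(a) = h(a − 5).

Registry strata (single-year age × calendar year, with person-years) are
fitted by Poisson likelihood, λ = h(age+0.5; B) × PY, via maximum
likelihood and MCMC. A stochastic oracle — exact event-driven simulation
of the whole process — validates the analytic hazard, and a synthetic
SEER-like generator makes every stage testable without registry access.

## Worked example

Field-defect prevalence for the 1920 birth cohort at the published
posterior-median parameters, and a small generate-then-fit round trip:

```python
from msceapc import get_preset, fd_prevalence, fit_mle, PriorSpec
from msceapc.synthetic import generate_incidence_table, seer9_like_schedule

bp, tp = get_preset("white_males")
print(f"lifetime FD prevalence, 1920 cohort: "
      f"{100 * fd_prevalence(100.0, 1920.0, bp.nu0, tp):.2f}%")

table = generate_incidence_table(bp, tp, seer9_like_schedule(2e5), seed=1)
print(f"{len(table)} strata, {table.cases.sum()} cases")

res = fit_mle(table, init={"nu0": 2e-5}, base=(bp, tp),
              priors=[PriorSpec("nu0", 1e-7, 1e-2, transform="log")])
print(f"nu0_hat = {res.params['nu0']:.3e} (generating value {bp.nu0:.3e})")
```

prints

```
lifetime FD prevalence, 1920 cohort: 0.45%
2079 strata, 12000 cases
nu0_hat = 5.583e-05 (generating value 5.520e-05)
```

The prevalence value says that under the fitted white-male model fewer
than one in two hundred members of the 1920 cohort ever acquired the
ESCC-predisposing field-defect; the round trip shows the background
onset rate recovered to ~1% relative error from a synthetic table at
ten times realistic person-years.

The same surfaces are available from a CLI (`msceapc generate | fit |
mcmc | simulate | profiles | prevalence | compare`), all emitting
delimited text tables and JSON summaries that embed the configuration
hash and seed.

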