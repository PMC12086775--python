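# closedmcpmod

Confirmatory dose-versus-placebo testing with model-based contrast
tests: the **closed MCP-Mod** procedure for normal-response
parallel-group trials, together with its nonnegativity-**constrained**
variant, the standard competitor procedures, an operating-characteristics
simulator, and a graphical extension to a primary plus a secondary
endpoint.

## The problem

A Phase III trial compares k active doses d_1 < … < d_k against placebo
d_0 on a normally distributed endpoint,

    Y_ij = f(d_i, θ) + ε_ij,   ε_ij ~ N(0, σ²),

and must (a) establish a dose–response signal and (b) declare
individual doses superior to placebo, with the familywise error rate
(FWER) strongly controlled at a one-sided level α.

The MCP part of MCP-Mod tests the trend with a *maximum contrast test*:
for each candidate shape f_m with guessed parameters, the contrast
statistic

    T_m = Σ_i c_mi Ȳ_i / (S √(Σ_i c²_mi / n_i)),   Σ_i c_mi = 0,

uses coefficients proportional to n_i (μ⁰_mi − μ̄_m), the choice that
maximizes the noncentrality for that shape; S² is the variance pooled
over all k+1 arms (ν = N − k − 1 df).  T_max = max_m T_m is referred to
a central multivariate t distribution with the correlation implied by
the contrasts, giving multiplicity-adjusted p-values q_m.  That
establishes a trend but says nothing about individual doses.

**Closed MCP-Mod** applies the closed test principle: every nonempty
subset I of the doses defines an intersection hypothesis H_I, tested at
level α by a maximum contrast test whose contrasts are re-derived on
{placebo} ∪ I (the pooled variance keeps all arms).  Dose i is declared
superior exactly when every H_I with i ∈ I is rejected.  Because an
optimal contrast may put *negative* weight on a poorly performing dose
— letting a harmful dose drive a "positive" trend — the constrained
variant maximizes the noncentrality subject to nonnegative dose
weights (solved exactly by support enumeration), which restores a
genuinely one-sided test and strong FWER control without extra
assumptions.

All tests are one-sided for a response **increase**; negate responses
for endpoints where a decrease is the improvement (e.g. pain scores).

## Worked example

```python
from closedmcpmod.io import make_fixture

frame, res = make_fixture(seed=42)   # synthetic 400-patient trial,
print(res.summary())                 # Emax truth, max effect 0.4, σ = 1
```

```
Closed MCP-Mod (constrained contrasts)
==============================================
arms: 4  N: 400  alpha (one-sided): 0.025
pooled SD: 0.9537  df: 396
global dose-response p-value: 0.0001

Intersection hypotheses
----------------------------------------------
H_{1,2,3}      p = 0.0001  reject
H_{1,2}        p = 0.0141  reject
H_{1,3}        p = 0.0000  reject
H_{2,3}        p = 0.0001  reject
H_{1}          p = 0.0698
H_{2}          p = 0.0115  reject
H_{3}          p = 0.0000  reject

Dose versus placebo (closed adjusted)
----------------------------------------------
dose 0.1    p = 0.0698
dose 0.4    p = 0.0141  reject
dose 1      p = 0.0001  reject
```

The seven rows are the 2³ − 1 intersection hypotheses; each p-value is
the minimum multiplicity-adjusted q_m over the five candidate models
for that intersection.  The closed adjusted p-value of a dose is the
maximum over the intersections containing it: here the middle and top
dose are declared superior to placebo (one-sided 0.025), the low dose
is not — its own pairwise comparison (H_{1}, p = 0.0698) fails even
though the global trend is overwhelming.

The same analysis from the shell, given a CSV with `dose,response`
columns and a YAML design/candidate config:

```sh
closedmcpmod test trial.csv --config config.yaml --constrained
closedmcpmod contrasts --config config.yaml --constrained   # contrast table
closedmcpmod simulate --config config.yaml --scenarios grid.yaml --out oc.csv
```

Model objects mirror the statsmodels idiom: `ClosedMCPMod(data, design,
candidate_set).fit(alpha=0.025)` returns a results object carrying the
intersection table, per-dose adjusted p-values, rejections and
`summary()`; `GraphicalClosedMCPMod` does the same for a primary plus
secondary endpoint with a weighted hypothesis graph.

## Layout

- `models.py` — dose designs, candidate shapes, placebo-anchored profiles
- `contrasts.py` — optimal and constrained contrasts, correlations
- `inference.py` — statistics, multivariate-t p-values/critical values
- `closed.py` — the closed testing engine and model/results objects
- `competitors.py` — Dunnett (single-step/step-down), Hochberg,
  Bonferroni, fixed sequence, unadjusted t
- `simulate.py` — trial generator and operating-characteristics studies
- `graphical.py` — two-endpoint extension via a weighted hypothesis graph
- `io.py`, `cli.py` — CSV/YAML/JSON plumbing and the command line

See `docs/methods.md` for the statistical details and design choices.
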