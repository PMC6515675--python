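# seqtrial

Bayesian sequential design for two-arm superiority trials with a binary
endpoint: conjugate beta-binomial inference, predictive-probability stopping
rules, operating-characteristics simulation, and virtual re-execution of a
design over patient-level data.

The package is aimed at trial statisticians who want to ask, for a phase-III
trial with a short-lag binary outcome (the motivating case is a critical-care
trial of ventilation strategies with 30-day mortality as the endpoint): *what
would scheduled interim looks with success and futility stopping have done to
this trial's sample size, duration and conclusions?*

## The model

Each arm's event rate carries an independent `Beta(α₀, β₀)` prior (uniform,
`Beta(1, 1)`, by default).  With `d` deaths among `n` analysed patients the
posterior is `Beta(α₀ + d, β₀ + n − d)`, and the trial is **successful** at
the final analysis when

    P(p_T < p_C | data) > 0.975,

computed exactly (closed-form finite sum for integer shapes, certified
adaptive quadrature otherwise).  At each scheduled look — a pre-specified
cumulative recruit count — two posterior predictive probabilities are
evaluated by integrating over both parameter and outcome uncertainty:

* **P_curr** — probability the trial succeeds at the *current* sample size
  once all enrolled patients complete follow-up; accrual stops for success
  when `P_curr > S_i`;
* **P_max** — probability the trial succeeds if recruitment continues to the
  *maximum* sample size; the trial stops for futility when `P_max < F_i`.

Futility is evaluated before success.  Monte-Carlo imputation (10,000 draws
by default) is replaced by exact beta-binomial enumeration whenever at most
20 outcomes are outstanding.

Six built-in candidate designs (maximum 1006 patients, interim schedules
from one to three looks) and the matching null / target / small / large /
harmful scenarios are included, along with the published interim count
tables of the motivating trial and a constrained generator that rebuilds
synthetic patient streams reproducing those counts exactly.

## Worked example

Rebuild the published two-look design's dataset and replay its decision
rules:

```python
import seqtrial as st
from seqtrial.datasets import oscar_fixture

design = st.get_design("Design 3")          # looks at 335 and 670 recruits
stream = oscar_fixture("Design 3", seed=0)  # synthetic stream, published counts
results = st.SequentialTrial(stream, design).fit(seed=7)
print(results.summary())
```

which prints:

```
Sequential trial re-execution: Design 3 (n_max=1006, final threshold 0.975)

Interim 1 (n=335)  allocation 174:161  outcomes 70/165; 57/153
  P(superior)=0.8254  P_curr=NA  P_max=0.4069  -> Stopping criteria not met
Interim 2 (n=670)  allocation 339:331  outcomes 136/330; 129/322
  P(superior)=0.6172  P_curr=0.0000  P_max=0.0137  -> Stop for futility

Final analysis  control 138/339 (40.7%); treatment 134/331 (40.5%)
  RR (95% CI): 0.99 (0.83, 1.19)
  Posterior probability treatment superior: 0.5235
  Deaths in trial: 272
  Number randomised: 670
  Accrual duration (weeks): 121.8
  Recruitment savings vs n_max: 336
  Trial not successful (futility stop)
```

Reading: at the first look (335 recruits) the treatment arm is doing
slightly better (82.5% posterior probability of superiority) but the chance
of eventual success at 1006 patients is only 0.41 — above the 0.05 futility
boundary, so the trial continues.  By 670 recruits the arms have converged,
`P_max` has collapsed to 0.014 (< 0.1), and the trial stops for futility:
336 fewer patients than the planned maximum, with the same null conclusion
the full trial would have reached.

Design simulation uses the same machinery:

```python
oc = st.operating_characteristics(
    st.get_design("Design 5"),
    st.ScenarioSpec(0.45, 0.36, label="target difference"),
    n_sims=2_000, seed=1,
)
print(oc.prop_successful, oc.mean_n)   # ~0.81 power, ~770 expected patients
```

The same operations are available from the shell:

```sh
seqtrial sample-size                       # 503 per arm, 1006 total
seqtrial synthesize fixture --oscar-design "Design 3" --out stream.csv
seqtrial reexecute --patients stream.csv --design "Design 3" --seed 7 --out report/
seqtrial simulate --design "Design 5" --scenario target --n-sims 2000 --seed 1 --out oc/
```

## Layout

| module | contents |
| --- | --- |
| `seqtrial.inference` | beta-binomial posteriors, superiority probability, final success rule, relative risk, sample size |
| `seqtrial.predictive` | interim snapshots, P_curr and P_max |
| `seqtrial.design` | design/scenario specifications, built-in catalogue, config IO |
| `seqtrial.engine` | snapshot construction, interim decisions, re-execution, patient CSV IO |
| `seqtrial.model` | `SequentialTrial` / `SequentialTrialResults` front |
| `seqtrial.simulate` | trial simulation, operating characteristics, threshold calibration |
| `seqtrial.synth` | stream generator and count-constrained fixture generator |
| `seqtrial.datasets` | published interim/final count tables of the motivating trial |
| `seqtrial.cli` | `seqtrial` command-line interface |

See `docs/methods.md` for the statistical details, numerical choices and
known limitations.
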