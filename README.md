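# eship2

Grading toolkit for validating automatic blood-pressure monitors under the
**European Society of Hypertension International Protocol, 2010 revision
(ESH-IP2)**, including the heart-rate extension used when a monitor also
reports pulse.

Clinical decisions about hypertension rest on measurements from oscillometric
cuff devices, so every new monitor must be shown to agree with a reference
before use. ESH-IP2 standardizes that demonstration: 33 participants each
contribute nine alternating same-arm readings (`BPA`, `BPB`, `BP1`…`BP7`; the
entry pair is discarded), each test-device reading `BP2`/`BP4`/`BP6` is
differenced against its nearer flanking reference reading, and the 99 absolute
differences per quantity are counted within nested bands (≤5/≤10/≤15 mm Hg for
SBP and DBP; ≤3/≤5/≤8 beats/min for HR). A device passes when

* **part 1** — at least two bands meet the counts (73, 87, 96) of 99 and all
  three meet (65, 81, 93);
* **part 2** — ≥24 of 33 participants have ≥2 of their 3 differences in the
  innermost band, and ≤3 participants have none;
* **part 3** — both of the above.

The package provides the full pipeline as a library and CLI: session CSV
ingestion with schema validation, eligibility screening, pairing and band
classification, part-1/2/3 verdicts with achieved-vs-required detail,
Bland–Altman agreement statistics, a demographics table with normality-gated
t / Wilcoxon–Mann–Whitney comparisons, and a synthetic session generator for
parameter-recovery and pass-probability (operating-characteristic) studies.
See `docs/methods.md` for the model and design choices.

## Worked example

Simulate a standard 33-participant study with a mildly biased device, then
grade it:

```sh
eship2 simulate --out demo.csv --seed 4
eship2 validate demo.csv --out report.json
```

which prints (abridged):

```
Device validation report
mode: standard; flank rule: nearest; participants: 33

ELIGIBILITY
n=33 (13 men, 20 women): eligible

SBP
  within 5: achieved 81 of 99 (required 73 two-of-three / 65 all-of-three)
  within 10: achieved 96 of 99 (required 87 two-of-three / 81 all-of-three)
  within 15: achieved 99 of 99 (required 96 two-of-three / 93 all-of-three)
  part 1: PASS
  part 2: PASS
    participants with >=2 of 3 in band 1: 31 (required >= 24)
    participants with 0 of 3 in band 1: 0 (required <= 3)
  part 3: PASS
  differences: signed 2.40 (SD 3.57); absolute 3.23 (SD 2.84); limits of agreement [-4.60, 9.41]
...
OVERALL: PASS
```

81 of the 99 systolic differences fell within 5 mm Hg (protocol minimum 73 in
the two-of-three row), and 31 of 33 participants had at least two of their
three differences within 5 mm Hg (minimum 24), so the simulated device passes
parts 1–3. The signed mean difference 2.40 mm Hg is the Bland–Altman bias; the
limits of agreement bracket ~95% of differences. The exit status is 0 only
when every graded quantity passes part 3, so the command composes into shell
pipelines.

A device with a large systematic error fails with certainty:

```sh
eship2 passprob --replicates 100 --seed 4 --sbp-bias 8 --dbp-bias 8
```

```json
{"n_replicates": 100, "n_pass": 0, "proportion": 0.0,
 "wilson_ci": [0.0, 0.0370]}
```

i.e. with an 8 mm Hg additive bias none of 100 simulated studies passed, and
the Wilson interval bounds the pass probability below 4%.

The same functionality is available as a library:

```python
from eship2 import SimulationConfig, simulate_cohort, grade_cohort

cohort = simulate_cohort(SimulationConfig(seed=4))
result = grade_cohort(cohort, "sbp")
print(result.band_counts.counts, result.part3.passed)   # (81, 96, 99) True
```

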