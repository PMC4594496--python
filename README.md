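# circleslines

Analysis toolkit for the bimanual **Circles-Lines (CL) paradigm**, the
classic probe of bimanual motor coupling: when one hand draws circles while
the other draws straight vertical lines, the line trajectories become oval.
The package targets single-case studies of this effect — e.g. right-brain-
damaged patients with motor neglect, whose non-congruent bimanual movements
can lose the coupling signature — where a patient must be compared against a
small healthy control sample rather than a second group.

It provides, for researchers in motor control and neuropsychology:

- **Synthetic two-hand drawing sessions** with the paradigm's block design
  (conditions L, C, LL, CL; 15 s blocks, 6 repetitions each, pseudo-random
  order, 30 s framing rests) and a controllable coupling fraction, so every
  downstream stage is testable without raw recordings (which are typically
  not public).
- **Trajectory metrics**: cycle segmentation, drawing frequency, and the
  **Ovalization Index** (OI), defined per cycle as
  `OI = 100 · sd(x − x̄) / (h/√2)` with `h` the cycle's vertical semi-extent
  — 0 for a straight vertical stroke, exactly 100 for a circle, `100·a/b`
  for an ellipse with lateral/vertical semi-axis ratio `a/b`.
- **Single-case statistics** in the Crawford tradition, all referred to
  Student's t with df = n − 1: the Revised Standardized Difference Test
  (RSDT) of a task discrepancy against controls, its unstandardized
  variant, the two-case comparison `z = (d₁ − d₂)/(s·√2)`, and the
  single-score deficit test.
- **A study pipeline** that scores trajectories, runs the tests, and writes
  deterministic report tables; the printed worked-example data of a
  published motor-neglect case-control study (behavioral OI scores and
  ROI beta values for pre-SMA and posterior parietal cortex) ship as JSON
  fixtures.

## Worked example

The shipped fixtures carry the published normative sample (n = 12 healthy
participants: OI in LL 5.5 ± 1.5, in CL 13.4 ± 8.4, inter-task r = 0.8) and
the two patients' scores (MN+ 10.4/11.5, MN− 8.0/32.5):

```python
from circleslines import CaseScores, NormativeSummary, rsdt, case_comparison

norm = NormativeSummary(mean_x=5.5, sd_x=1.5, mean_y=13.4, sd_y=8.4, r=0.8, n=12)
print(rsdt(CaseScores(x=10.4, y=11.5), norm))
# TestResult(method='rsdt', statistic=4.605745231972349, df=11,
#            p_two_tailed=0.000757787630610106)

print(case_comparison(1.1, 24.4, 6.8, 12))
# TestResult(method='case_comparison', statistic=-2.4228805884774345, df=11,
#            p_two_tailed=0.033833802203771766)
```

The first result says the MN+ patient's LL-vs-CL discrepancy is abnormally
*small* relative to controls (t(11) ≈ 4.6, p ≈ .001, two-tailed): his lines
did not ovalize in the non-congruent condition, i.e. the coupling effect is
absent. The second compares the two patients' CL − LL OI differences (1.1
vs 24.4 points, control SD 6.8) and finds them reliably different
(t(11) ≈ −2.42, p ≈ .03). Both match the published values (4.5 and −2.4)
within the rounding of the printed inputs.

An all-synthetic end-to-end run:

```bash
circleslines report --demo --seed 0 --out report/
```

simulates a 12-subject normative cohort and two patients (one with the
normal coupling fraction, one with none), scores their sessions, and writes
`case_scores.tsv`, `behavioral_tests.tsv`, `roi_tests.tsv` and a run log.
Reruns with the same seed are byte-identical. Other subcommands:
`circleslines simulate session|cohort`, `circleslines metrics`,
`circleslines stats rsdt|compare`.

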