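"""Summarize an in-vitro digestion time course and call product formation.

A candidate substrate peptide is incubated with the active protease or its
catalytically dead point mutant; the MS1 intensity of the expected product is
tracked over reaction time in three technical replicates. Product formation
is called when the mean trace rises at least 5-fold over baseline; the
mutant's flat-zero trace serves as the negative control.
"""

from tailskit import TimeCourse, call_product_formation, summarize_timecourse

times = [0.0, 15.0, 30.0, 60.0, 120.0]
active = TimeCourse(
    "substrate_demo_2-13", "active",
    {t: [t * 950 + r * 40 for r in (0.0, 1.0, 2.0)] for t in times},
)
mutant = TimeCourse(
    "substrate_demo_2-13", "catalytic_mutant",
    {t: [0.0, 0.0, 0.0] for t in times},
)

for tc in (active, mutant):
    t, means, n = summarize_timecourse(tc)
    trace = ", ".join(f"{m:.0f}" for m in means)
    print(f"{tc.enzyme_label:>16}: mean product intensity [{trace}] "
          f"({n[0]} replicates/timepoint)")

calls = call_product_formation(active, mutant)
print(f"product formation: active={calls['active']}, "
      f"catalytic_mutant={calls['catalytic_mutant']}")
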