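"""Benchmark the neural lasso against the tuned classical lasso.

Runs a small version of the simulation benchmark (5 repetitions instead
of 100) on the AR(1) design with p=20 and prints the mean(sd) table:
normalized test rmse, support recall (true signals found) and support
precision (true zeros kept at zero), plus paired-t-test stars
(* p<0.05, ** p<0.01).
"""

from dlasso import DlassoConfig, run_benchmark

summary = run_benchmark(
    experiment=1, p=20, reps=5,
    config=DlassoConfig(restarts=5), seed=0,
)
print(summary.format_table())
print()
print("Both methods should recover every true signal (recall 1); the")
print("normalized rmse near 0.5 sits just above the 0.436 noise floor.")
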