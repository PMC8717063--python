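"""Generate a dyadic joint-attention session schedule and inspect it.

The design has six runs (two feature-based JA, two spatial JA, two solo
control) of 32 contiguous 12.5 s trials; partners swap initiator and
responder roles evenly within each JA run.
"""

import dyadsync as ds

design = ds.generate_design(seed=0, pair_id="demo")
print(f"runs (session order): {[r.task_type for r in design.runs]}")
print(f"total trials: {design.n_trials}")
print(f"condition counts for participant A: {design.condition_counts('A')}")

ja = design.ja_runs_reordered()
print(f"canonical JA-run reorder: {[r.task_type for r in ja]} "
      f"(run indices {[r.run_index for r in ja]})")

ds.write_events_tsv(design, "scratch_events_demo_A.tsv", participant="A")
print("events table written to scratch_events_demo_A.tsv "
      "(one row per trial: onset, duration, condition, role)")
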