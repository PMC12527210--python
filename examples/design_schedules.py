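"""Build the block schedules of the three experiment variants.

Each participant's schedule is three sessions of 120-second blocks.  The
overtrained cue gets 24 positive-contingency (ΔP = +0.6) training blocks,
the standard cue 6, and both are degraded (ΔP = −0.3) in session 3; the
filler cue (variants 1 and 3) is trained twice and degraded already in
session 1.
"""

from operant import build_design
from operant.design import design_to_frame

for variant, group in [("exp1", None), ("exp2", "A"), ("exp3", "B")]:
    d = build_design(variant, participant_id=0, seed=42, counterbalance_group=group)
    print(f"{variant} (group {group}): {d.n_blocks} blocks, "
          f"first degraded cue in session 3: {d.first_test_cue()}")
    for cue in ("overtrained", "standard", "filler"):
        n_train = d.count(cue, "training")
        n_test = d.count(cue, "habit_test")
        if n_train or n_test:
            print(f"  {cue:12s}: {n_train:2d} training, {n_test} habit-test blocks")

print()
print("Session-by-session schedule of one exp1 participant:")
frame = design_to_frame(build_design("exp1", 0, 42))
print(frame.groupby(["session", "phase", "cue"]).size().rename("blocks").to_string())
# The training rows show the pseudorandomized order totals; the habit-test
# rows are the degradation tests used to detect habitual responding.
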