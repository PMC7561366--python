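"""Score a synthetic eye-tracking session into attention outcomes.

Generates one participant's 300-Hz gaze streams (32 orienting trials, 16
disengagement trials per stimulus condition), scores every trial, and
prints the participant-level orienting latency and dwell-time index.
"""

import io

from crygaze import GazeSpec, synth_gaze
from crygaze.gaze import aggregate_participant, read_gaze_file, score_trial

spec = GazeSpec(seed=11, latency_mean_ms=420.0, latency_sd_ms=60.0,
                p_no_shift=0.25)
gaze, events, truth = synth_gaze(spec)

gbuf, ebuf = io.StringIO(), io.StringIO()
gaze.to_csv(gbuf, index=False)
events.to_csv(ebuf, index=False)
gbuf.seek(0), ebuf.seek(0)
trials = read_gaze_file(gbuf, ebuf)

scores = [score_trial(t) for t in trials]
participant = aggregate_participant("demo", scores)

print(f"scored {len(scores)} trials")
print(f"orienting latency: {participant.orienting_latency_ms:.1f} ms over "
      f"{participant.n_orienting_trials} scorable trials "
      f"(included: {participant.included_orienting})")
for cond, idx in participant.dwell_index_by_condition.items():
    print(f"  dwell index [{cond:8s}]: {idx:.3f}")
print(f"dwell index (mean of conditions): {participant.dwell_index:.3f} "
      f"(included: {participant.included_dwell})")
# The orienting latency is the mean saccadic reaction time to the lone
# peripheral target (150-1000 ms window). The dwell index maps each
# disengagement saccade linearly from 150 ms (0) to 1000 ms / no shift (1):
# higher values mean slower disengagement from the central stimulus.
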