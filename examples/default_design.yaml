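# Default synthetic cohort design: 15/15/8 subjects, three tasks (QS =
# quiet standing, SP = shooting position, AT = aiming at target), three
# 30-second repeats at 50 Hz.  effect_matrix gives the MIX irregularity p
# of the COP increment series per group and task; subject_sd / trial_sd are
# the SDs of the per-subject intercept and per-trial jitter on p.
group_sizes:
  control: 15
  beginner: 15
  biathlete: 8
repeats: 3
trial_seconds: 30.0
fs: 50.0
effect_matrix:
  control:   {QS: 0.42, SP: 0.58, AT: 0.58}
  beginner:  {QS: 0.42, SP: 0.58, AT: 0.58}
  biathlete: {QS: 0.42, SP: 0.30, AT: 0.26}
subject_sd: 0.13
trial_sd: 0.04
cop_sd_m: 0.004
seed: 42
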