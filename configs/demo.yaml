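# Demo pipeline: a small three-group synthetic cohort run end-to-end
# (simulate -> QC -> ALFF -> extract -> 12-signature evaluation).
seed: 7
output_dir: demo-out
cohort:
  simulate: true
  n_per_group: {AD: 10, aMCI: 10, NC: 10}
  texture_effect: 1.0
  alff_effect: 1.0
# 10 subjects/group leaves 7 training rows per class, so use 5 CV folds here
folds: 5
split:
  n_repetitions: 10
  seed: 7
contrasts:
  - [AD, NC]
  - [aMCI, NC]
rois: [left, right]
modalities: [T1-w, ALFF, combined]
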