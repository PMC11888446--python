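# Desk-scale curriculum demo: completes in a few minutes on one CPU.
data:
  n_paired: 300
  n_unpaired_heavy: 800
  n_unpaired_light: 800
  mutation_rate: 6.0
  naive_fraction: 0.5
  seed: 11
  train_fraction: 0.9

tokenizer:
  separator_mode: sep       # sep | cls | none

schedule:
  kind: curriculum          # curriculum | constant | finetuned | unpaired_only | paired_only
  B: 0.7                    # upper bound of the unpaired-probability curve
  A: 0.4                    # curve height (decays toward B - A = 0.3)
  k: 15.0                   # sigmoid slope
  target_unpaired_fraction: 0.625

lr:
  kind: linear              # linear | wsd | sgdr
  peak_lr: 1.0e-3
  warmup_steps: 60

mlm:
  select_rate: 0.15
  mask_rate: 0.8
  random_rate: 0.1
  keep_rate: 0.1

model:
  n_layers: 2
  n_heads: 4
  hidden_size: 64
  intermediate_size: 256
  pe_type: rope             # rope | absolute
  seed: 21

train:
  total_steps: 500
  batch_size: 8
  seed: 31
  eval_interval: 250

tasks:
  enabled: false
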