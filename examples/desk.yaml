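# Desk-scale workflow configuration: the cskg-like preset graph, inverse
# edges enabled for walking, a 10k-walk budget per pair, and short training.
add_inverse: true
sampler:
  max_len: 4
  n_walks: 10000
  max_paths: 8
max_pos_per_split: 250
eval_neg_ratio: 8.0
train:
  epochs: 30
  patience_epochs: 30
model:
  d: 50
  k: 50
encoder:
  H: 64
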