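# Semilandmark method: only the medial eye canthus is a fixed landmark;
# the 29 other outline points slide.
name: ssl
n_points: 30
landmarks: [29]
slider_triples: chain
subsets:
  dorsum: [1, 30]
  croup_back: [1, 15]
  neck_head: [15, 30]
derotation_triple: [1, 15, 30]
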