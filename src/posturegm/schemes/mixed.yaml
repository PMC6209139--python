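# Mixed method: the seven clay marks and the medial eye canthus stay fixed
# landmarks; the other 22 outline points are sliding semilandmarks.
name: mixed
n_points: 30
landmarks: [1, 6, 10, 14, 24, 27, 29, 30]
slider_triples: chain
subsets:
  dorsum: [1, 30]
  croup_back: [1, 15]
  neck_head: [15, 30]
derotation_triple: [1, 15, 30]
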