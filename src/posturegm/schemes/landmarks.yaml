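# 9-landmark method: the seven clay marks plus the medial eye canthus and
# the middle of the neck upline, treated as fixed anatomical landmarks.
# Indices are 1-based along the dorsal outline, caudal (tail head) to
# rostral (facial crest).  The exact outline indices of the clay marks are
# a template choice and can be overridden in a user scheme file.
name: landmarks
n_points: 30
landmarks: [1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 11, 12, 13, 14, 15, 16, 17, 18,
            19, 20, 21, 22, 23, 24, 25, 26, 27, 28, 29, 30]
slider_triples: chain
subsets:
  dorsum: [1, 30]
  croup_back: [1, 15]
  neck_head: [15, 30]
derotation_triple: [1, 15, 30]
# tail head, lumbo-sacral, thoraco-lumbar, withers low point, mid-neck,
# atlas, temporo-mandibular, eye canthus, facial crest
active: [1, 6, 10, 14, 19, 24, 27, 29, 30]
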