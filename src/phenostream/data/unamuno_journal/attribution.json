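{
 "schema": "phenostream/attribution-1",
 "text_id": "unamuno_journal",
 "scheme": {
  "name": "unamuno7",
  "categories": [
   {
    "code": "sensation",
    "name": "Se"
   },
   {
    "code": "perception",
    "name": "Pr"
   },
   {
    "code": "emotion",
    "name": "Em"
   },
   {
    "code": "thought",
    "name": "Th"
   },
   {
    "code": "image",
    "name": "Im"
   },
   {
    "code": "recall",
    "name": "Re"
   },
   {
    "code": "intention",
    "name": "In"
   }
  ]
 },
 "n_judges": 16,
 "n": [
  10,
  14,
  16,
  16,
  15,
  16,
  11,
  16,
  16
 ],
 "counts": [
  [
   5,
   6,
   3,
   3,
   6,
   7,
   2
  ],
  [
   8,
   3,
   5,
   5,
   0,
   2,
   4
  ],
  [
   2,
   3,
   4,
   11,
   0,
   0,
   5
  ],
  [
   2,
   1,
   1,
   13,
   0,
   0,
   3
  ],
  [
   4,
   6,
   2,
   4,
   4,
   4,
   4
  ],
  [
   8,
   4,
   2,
   6,
   3,
   2,
   4
  ],
  [
   3,
   0,
   9,
   0,
   0,
   0,
   8
  ],
  [
   6,
   1,
   16,
   1,
   1,
   1,
   14
  ],
  [
   4,
   1,
   11,
   13,
   3,
   1,
   4
  ]
 ]
}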