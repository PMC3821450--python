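{
 "schema": "phenostream/fixture-printed-1",
 "agreement_indices": {
  "4": 0.375,
  "9": 0.5,
  "15": 0.25,
  "20": 0.625,
  "27": 0.125,
  "32": 0.813,
  "38": 1.0,
  "46": 1.0,
  "52": 0.063,
  "58": 0.934,
  "72": 0.125,
  "76": 1.0,
  "85": 0.688,
  "93": 1.0,
  "99": 0.125,
  "107": 1.0
 },
 "translations": [
  "The most insignificant occurrence",
  "any sentence I encounter,",
  "the most innocent word I hear,",
  "whatever my son says,",
  "everything seems to me a signal, a symbol",
  "and a matter of hidden meaning,",
  "I translate everything to my state.",
  "If I continue like this I will fall into superstition.",
  "Not a single bell tolls",
  "that I fail to believe is calling me;",
  "I fancy that every man of the cloth that I pass",
  "will approach to inquire what is the matter with me.",
  "A great desire to declare my state to all,",
  "a great happiness to make confessions to anyone,",
  "and a great dryness and indifference",
  "if I think to do it as the Church commands."
 ],
 "table": {
  "proportions": [
   [
    0.5,
    0.6,
    0.3,
    0.3,
    0.6,
    0.7,
    0.2
   ],
   [
    0.57,
    0.21,
    0.36,
    0.36,
    0.0,
    0.14,
    0.29
   ],
   [
    0.13,
    0.19,
    0.25,
    0.69,
    0.0,
    0.0,
    0.31
   ],
   [
    0.13,
    0.06,
    0.06,
    0.81,
    0.0,
    0.0,
    0.19
   ],
   [
    0.27,
    0.4,
    0.13,
    0.27,
    0.27,
    0.27,
    0.27
   ],
   [
    0.5,
    0.25,
    0.13,
    0.37,
    0.19,
    0.13,
    0.25
   ],
   [
    0.27,
    0.0,
    0.82,
    0.0,
    0.0,
    0.0,
    0.72
   ],
   [
    0.38,
    0.06,
    1.0,
    0.06,
    0.06,
    0.06,
    0.9
   ],
   [
    0.25,
    0.06,
    0.69,
    0.82,
    0.19,
    0.06,
    0.25
   ]
  ],
  "flags": [
   [
    "none",
    "high",
    "low",
    "low",
    "high",
    "high",
    "low"
   ],
   [
    "none",
    "low",
    "none",
    "none",
    "low",
    "low",
    "low"
   ],
   [
    "low",
    "low",
    "low",
    "high",
    "low",
    "low",
    "low"
   ],
   [
    "low",
    "low",
    "low",
    "high",
    "low",
    "low",
    "low"
   ],
   [
    "low",
    "none",
    "low",
    "low",
    "low",
    "low",
    "low"
   ],
   [
    "none",
    "low",
    "low",
    "none",
    "low",
    "low",
    "low"
   ],
   [
    "low",
    "low",
    "high",
    "low",
    "low",
    "low",
    "high"
   ],
   [
    "none",
    "low",
    "high",
    "low",
    "low",
    "low",
    "high"
   ],
   [
    "low",
    "low",
    "high",
    "high",
    "low",
    "low",
    "low"
   ]
  ],
  "alpha": 0.01,
  "notes": {
   "alpha": "published table marks cells significant at p < 0.01, null unstated",
   "ambiguous_cells": [
    {
     "segment": 5,
     "category": "perception",
     "reason": "markup '0.40****' is ambiguous; the accompanying prose states segments 2, 5, and 6 received no significant high attribution, so the flag is stored as 'none'"
    }
   ]
  }
 },
 "discrepancies": [
  {
   "segment": 7,
   "category": "intention",
   "printed": 0.72,
   "stored_count": 8,
   "implied": 0.7273
  },
  {
   "segment": 8,
   "category": "intention",
   "printed": 0.9,
   "stored_count": 14,
   "implied": 0.875
  },
  {
   "segment": 9,
   "category": "thought",
   "printed": 0.82,
   "stored_count": 13,
   "implied": 0.8125
  }
 ]
}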