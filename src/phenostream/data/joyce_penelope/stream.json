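{
 "schema": "phenostream/coded-stream-1",
 "text_id": "joyce_penelope",
 "scheme": {
  "name": "joyce4",
  "categories": [
   {
    "code": "S",
    "name": "sensations"
   },
   {
    "code": "E",
    "name": "emotions"
   },
   {
    "code": "T",
    "name": "thoughts"
   },
   {
    "code": "I",
    "name": "mental images"
   }
  ],
  "parent_map": {
   "sensation": "S",
   "perception": "S",
   "emotion": "E",
   "thought": "T",
   "recall": "T",
   "intention": "T",
   "image": "I"
  }
 },
 "entries": [
  {
   "index": 1,
   "contents": [
    {
     "label": "irritation",
     "category": "E"
    }
   ],
   "causes_next": true,
   "text": "I bet the cat itself is better off than us",
   "annotation": "Conjecture"
  },
  {
   "index": 2,
   "contents": [
    {
     "label": "irritation",
     "category": "E"
    }
   ],
   "causes_next": true,
   "text": "Have we too much blood up in us or what",
   "annotation": "Rhetorical question"
  },
  {
   "index": 3,
   "contents": [
    {
     "label": "despair",
     "category": "E"
    }
   ],
   "causes_next": true,
   "text": "O patience above is pouring out of me like the sea",
   "annotation": "Interjection"
  },
  {
   "index": 4,
   "contents": [
    {
     "label": "contempt",
     "category": "E"
    }
   ],
   "causes_next": false,
   "text": "Anyhow he didn't make me pregnant as big as he is",
   "annotation": "Emphasis"
  },
  {
   "index": 5,
   "contents": [
    {
     "label": "sensation",
     "category": "S"
    },
    {
     "label": "wish",
     "category": "T"
    }
   ],
   "causes_next": true,
   "text": "I don't want to ruin the clean sheets",
   "annotation": "Reflection"
  },
  {
   "index": 6,
   "contents": [
    {
     "label": "recollection",
     "category": "T"
    },
    {
     "label": "image",
     "category": "I"
    }
   ],
   "causes_next": true,
   "text": "The clean linen I wore brought it on too",
   "annotation": "Reflection"
  },
  {
   "index": 7,
   "contents": [
    {
     "label": "anger",
     "category": "E"
    }
   ],
   "causes_next": true,
   "text": "Damn it damn it",
   "annotation": "Interjection"
  },
  {
   "index": 8,
   "contents": [
    {
     "label": "image",
     "category": "I"
    },
    {
     "label": "irritation",
     "category": "E"
    }
   ],
   "causes_next": true,
   "text": "And they always want to see a stain on the bed to know youre a virgin for them",
   "annotation": "Reflection"
  },
  {
   "index": 9,
   "contents": [
    {
     "label": "irritation",
     "category": "E"
    }
   ],
   "causes_next": true,
   "text": "All that's troubling them",
   "annotation": "Same reflection"
  },
  {
   "index": 10,
   "contents": [
    {
     "label": "contempt",
     "category": "E"
    }
   ],
   "causes_next": true,
   "text": "they're such fools too",
   "annotation": "Same reflection"
  },
  {
   "index": 11,
   "contents": [
    {
     "label": "irritation",
     "category": "E"
    }
   ],
   "causes_next": true,
   "text": "You could be a widow and divorced 40 times over",
   "annotation": "Exaggeration"
  },
  {
   "index": 12,
   "contents": [
    {
     "label": "image",
     "category": "I"
    }
   ],
   "causes_next": true,
   "text": "A daub of red ink would do or blackberry juice",
   "annotation": "Fantasy"
  },
  {
   "index": 13,
   "contents": [
    {
     "label": "unfolding image",
     "category": "I"
    }
   ],
   "causes_next": false,
   "text": "No that's too purply",
   "annotation": "Correction"
  },
  {
   "index": 14,
   "contents": [
    {
     "label": "tiredness",
     "category": "E"
    },
    {
     "label": "anxiety",
     "category": "E"
    }
   ],
   "causes_next": true,
   "text": "O Jamesy let me up out of this",
   "annotation": "Interjection"
  },
  {
   "index": 15,
   "contents": [
    {
     "label": "same",
     "category": "E"
    }
   ],
   "causes_next": true,
   "text": "Pooh",
   "annotation": "Interjection"
  },
  {
   "index": 16,
   "contents": [
    {
     "label": "same",
     "category": "E"
    }
   ],
   "causes_next": false,
   "text": "Sweets on sin",
   "annotation": "Interjection"
  },
  {
   "index": 17,
   "contents": [
    {
     "label": "thought",
     "category": "T"
    }
   ],
   "causes_next": false,
   "text": "Whoever suggested that business for women what between clothes and cooking and children",
   "annotation": "Rhetorical question"
  },
  {
   "index": 18,
   "contents": [
    {
     "label": "recollection",
     "category": "T"
    },
    {
     "label": "sensation",
     "category": "S"
    }
   ],
   "causes_next": true,
   "text": "This damned old bed too jingling like the dickens",
   "annotation": "Judgment"
  },
  {
   "index": 19,
   "contents": [
    {
     "label": "recollection",
     "category": "T"
    },
    {
     "label": "image",
     "category": "I"
    }
   ],
   "causes_next": true,
   "text": "I suppose they could hear us away over the other side of the park till I suggested to put the quilt on the floor with the pillow under my bottom",
   "annotation": "Reflection"
  },
  {
   "index": 20,
   "contents": [
    {
     "label": "thought begins",
     "category": "T"
    }
   ],
   "causes_next": true,
   "text": "I wonder is it nicer in the day",
   "annotation": "Question"
  },
  {
   "index": 21,
   "contents": [
    {
     "label": "thought progress",
     "category": "T"
    }
   ],
   "causes_next": true,
   "text": "I think it is",
   "annotation": "Answer"
  },
  {
   "index": 22,
   "contents": [
    {
     "label": "thought ends",
     "category": "T"
    }
   ],
   "causes_next": false,
   "text": "Easy",
   "annotation": "Adjective"
  },
  {
   "index": 23,
   "contents": [
    {
     "label": "sensation",
     "category": "S"
    },
    {
     "label": "fantasy",
     "category": "I"
    }
   ],
   "causes_next": true,
   "text": "I think I'll cut all this hair off me there scalding me",
   "annotation": "Plans"
  },
  {
   "index": 24,
   "contents": [
    {
     "label": "fantasy developing",
     "category": "I"
    }
   ],
   "causes_next": true,
   "text": "I might look like a young girl",
   "annotation": "Judgment"
  },
  {
   "index": 25,
   "contents": [
    {
     "label": "fantasy",
     "category": "I"
    }
   ],
   "causes_next": true,
   "text": "Wouldn't he get the great sucking the next time he turned up my clothes on me",
   "annotation": "Rhetorical question"
  },
  {
   "index": 26,
   "contents": [
    {
     "label": "fantasy ends",
     "category": "I"
    },
    {
     "label": "wish",
     "category": "T"
    }
   ],
   "causes_next": false,
   "text": "I'd give anything to see his face",
   "annotation": "Judgment"
  },
  {
   "index": 27,
   "contents": [
    {
     "label": "visual image",
     "category": "I"
    }
   ],
   "causes_next": true,
   "text": "where's the chamber gone",
   "annotation": "Question"
  },
  {
   "index": 28,
   "contents": [
    {
     "label": "reassurance",
     "category": "E"
    }
   ],
   "causes_next": true,
   "text": "Easy",
   "annotation": "Adjective"
  },
  {
   "index": 29,
   "contents": [
    {
     "label": "fear",
     "category": "E"
    },
    {
     "label": "fantasy",
     "category": "I"
    }
   ],
   "causes_next": true,
   "text": "I've a holy horror of its breaking under me after that old commode",
   "annotation": "Judgment"
  },
  {
   "index": 30,
   "contents": [
    {
     "label": "fear",
     "category": "E"
    },
    {
     "label": "recollection",
     "category": "T"
    }
   ],
   "text": "I wonder was I too heavy sitting on his knee",
   "annotation": "Question"
  }
 ]
}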