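{
 "schema": "phenostream/text-1",
 "text_id": "joyce_penelope",
 "language": "en",
 "raw": "I bet the cat itself is better off than us Have we too much blood up in us or what O patience above is pouring out of me like the sea Anyhow he didn't make me pregnant as big as he is I don't want to ruin the clean sheets The clean linen I wore brought it on too Damn it damn it And they always want to see a stain on the bed to know youre a virgin for them All that's troubling them they're such fools too You could be a widow and divorced 40 times over A daub of red ink would do or blackberry juice No that's too purply O Jamesy let me up out of this Pooh Sweets on sin Whoever suggested that business for women what between clothes and cooking and children This damned old bed too jingling like the dickens I suppose they could hear us away over the other side of the park till I suggested to put the quilt on the floor with the pillow under my bottom I wonder is it nicer in the day I think it is Easy I think I'll cut all this hair off me there scalding me I might look like a young girl Wouldn't he get the great sucking the next time he turned up my clothes on me I'd give anything to see his face where's the chamber gone Easy I've a holy horror of its breaking under me after that old commode I wonder was I too heavy sitting on his knee",
 "candidate_boundaries": [
  1,
  2,
  3,
  4,
  5,
  6,
  7,
  8,
  9,
  10,
  11,
  12,
  13,
  14,
  15,
  16,
  17,
  18,
  19,
  20,
  21,
  22,
  23,
  24,
  25,
  26,
  27,
  28,
  29,
  30,
  31,
  32,
  33,
  34,
  35,
  36,
  37,
  38,
  39,
  40,
  41,
  42,
  43,
  44,
  45,
  46,
  47,
  48,
  49,
  50,
  51,
  52,
  53,
  54,
  55,
  56,
  57,
  58,
  59,
  60,
  61,
  62,
  63,
  64,
  65,
  66,
  67,
  68,
  69,
  70,
  71,
  72,
  73,
  74,
  75,
  76,
  77,
  78,
  79,
  80,
  81,
  82,
  83,
  84,
  85,
  86,
  87,
  88,
  89,
  90,
  91,
  92,
  93,
  94,
  95,
  96,
  97,
  98,
  99,
  100,
  101,
  102,
  103,
  104,
  105,
  106,
  107,
  108,
  109,
  110,
  111,
  112,
  113,
  114,
  115,
  116,
  117,
  118,
  119,
  120,
  121,
  122,
  123,
  124,
  125,
  126,
  127,
  128,
  129,
  130,
  131,
  132,
  133,
  134,
  135,
  136,
  137,
  138,
  139,
  140,
  141,
  142,
  143,
  144,
  145,
  146,
  147,
  148,
  149,
  150,
  151,
  152,
  153,
  154,
  155,
  156,
  157,
  158,
  159,
  160,
  161,
  162,
  163,
  164,
  165,
  166,
  167,
  168,
  169,
  170,
  171,
  172,
  173,
  174,
  175,
  176,
  177,
  178,
  179,
  180,
  181,
  182,
  183,
  184,
  185,
  186,
  187,
  188,
  189,
  190,
  191,
  192,
  193,
  194,
  195,
  196,
  197,
  198,
  199,
  200,
  201,
  202,
  203,
  204,
  205,
  206,
  207,
  208,
  209,
  210,
  211,
  212,
  213,
  214,
  215,
  216,
  217,
  218,
  219,
  220,
  221,
  222,
  223,
  224,
  225,
  226,
  227,
  228,
  229,
  230,
  231,
  232,
  233,
  234,
  235,
  236,
  237,
  238,
  239,
  240,
  241,
  242,
  243,
  244,
  245,
  246,
  247,
  248,
  249,
  250,
  251,
  252,
  253,
  254,
  255,
  256,
  257,
  258,
  259
 ]
}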