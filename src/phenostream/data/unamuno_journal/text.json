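{
 "schema": "phenostream/text-1",
 "text_id": "unamuno_journal",
 "language": "es",
 "raw": "El más insignificante suceso, el encuentro de cualquier frase, la palabra más inocente que oiga, lo que dice mi hijo, todo se me antoja aviso y símbolo y cosa de sentido oculto, todo lo traduzco a mi estado. Si sigo así voy á caer en superstición. No suenan una vez las campanas que no crea que me llaman; se me antoja que se me ha de dirigir á preguntarme que me pasa cualquier religioso que veo. Un deseo grande de declarar mi estado á todos, una gran felicidad de hacer confesiones a cualquiera, y una enorme sequedad é indiferencia si pienso en hacerla como la Iglesia manda.",
 "candidate_boundaries": [
  4,
  9,
  15,
  20,
  27,
  32,
  38,
  46,
  52,
  58,
  72,
  76,
  85,
  93,
  99,
  107
 ]
}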