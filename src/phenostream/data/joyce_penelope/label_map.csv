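label,lane
irritation,E
despair,E
contempt,E
anger,E
anxiety,E
fear,E
reassurance,E
tiredness,E
same,E
sensation,S
recollection,T
thought,T
conjecture,T
wish,T
plan,T
thought begins,T
thought progress,T
thought ends,T
image,I
unfolding image,I
visual image,I
fantasy,I
fantasy developing,I
fantasy ends,I
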