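# Default faecal indicator organism (FIO) genus list, one name per line.
# This is an editable placeholder of genera commonly used as sewage
# indicators in the source-tracking literature, not a reproduction of any
# specific published panel; swap in your preferred list for real studies.
Escherichia/Shigella
Bacteroides
Prevotella
Faecalibacterium
Blautia
Bifidobacterium
Enterococcus
Ruminococcus
Dorea
Roseburia
Lachnospira
Coprococcus
Collinsella
Akkermansia
Parabacteroides
Streptococcus
Veillonella
Dialister
Sutterella
Clostridium
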