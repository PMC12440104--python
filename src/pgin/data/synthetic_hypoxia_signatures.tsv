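# Synthetic placeholder hypoxia gene signatures for testing; real signature gene lists are supplied by the user.
HYPOXIA_A	AHX01
HYPOXIA_A	AHX02
HYPOXIA_A	AHX03
HYPOXIA_A	AHX04
HYPOXIA_A	AHX05
HYPOXIA_A	AHX06
HYPOXIA_A	AHX07
HYPOXIA_A	AHX08
HYPOXIA_A	AHX09
HYPOXIA_A	AHX10
HYPOXIA_B	BHX01
HYPOXIA_B	BHX02
HYPOXIA_B	BHX03
HYPOXIA_B	BHX04
HYPOXIA_B	BHX05
HYPOXIA_B	BHX06
HYPOXIA_B	BHX07
HYPOXIA_B	BHX08
HYPOXIA_B	BHX09
HYPOXIA_B	BHX10
HYPOXIA_C	CHX01
HYPOXIA_C	CHX02
HYPOXIA_C	CHX03
HYPOXIA_C	CHX04
HYPOXIA_C	CHX05
HYPOXIA_C	CHX06
HYPOXIA_C	CHX07
HYPOXIA_C	CHX08
HYPOXIA_C	CHX09
HYPOXIA_C	CHX10
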