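>CI2_wt chymotrypsin inhibitor 2, wild type
MDLKTEWPELVGKSVEEAKKVILQDKPEAQIIVLPVGTIVTMEYRIDRVRLFVDKLDNIAEVPRVG
>CI2_eng engineered fold-switching variant
MDAKTEWPELVGKSLEEAKKALLQDKPEATIIVIPVGTIVTMEYRVDRVRIVVDKLDNIAEVPTVG
>CI2_eng_I59A assembly-optimized variant (I59A on CI2_eng)
MDAKTEWPELVGKSLEEAKKALLQDKPEATIIVIPVGTIVTMEYRVDRVRIVVDKLDNAAEVPTVG
>CI2_1-58 C-terminal strand truncation of wild type
MDLKTEWPELVGKSVEEAKKVILQDKPEAQIIVLPVGTIVTMEYRIDRVRLFVDKLDN
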