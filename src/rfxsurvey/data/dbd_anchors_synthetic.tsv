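# seed name -> 0-based anchor positions
seed_hRFX1_like	13,18,21,33,37,44,51,62,69
seed_DAF19_like	13,18,21,33,37,44,51,62,69
seed_dRFX_like	13,18,21,33,37,44,51,62,69
seed_sRFX1_like	13,18,21,33,37,44,51,62,69
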