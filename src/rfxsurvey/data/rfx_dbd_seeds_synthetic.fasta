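>seed_hRFX1_like synthetic DBD seed
YSKNICYFVKVELPIFSWVQGDVKGPKDSKYNWPGVVELDSHPGDANVEGVAKEEAKAPN
SFFLKPGDKWPSIKTN
>seed_DAF19_like synthetic DBD seed
YSRNICYIVEVEQPIFSWVQGDVKGPKDSKYLLPGAVEADSHPGDANVEVVAKEEAKAAN
SFFLKPGDKWPSIKTN
>seed_dRFX_like synthetic DBD seed
YSANICYFVEVEQPQFSWVQGDVKGFCDSKYNLPYLVEADSHPSDAVVEGVALEEAVAAN
SFFFKPGDKWPMVKTT
>seed_sRFX1_like synthetic DBD seed
YSANICYFKEVEQPIMSWVQGDVGGPKDGKYNLPGLVEADSHHGDANVEGVAQEEAKPAL
RAFLCPGMKWPTIKTG
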