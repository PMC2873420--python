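>AD_1 synthetic aligned instance
LAVSPGVTPGTAQLDFHRRRGKKVAQIGSS
>AD_2 synthetic aligned instance
LALRPGVTPLFAKDDFARRRGKKVNQIGSE
>AD_3 synthetic aligned instance
LATRGGVTPFFDQDDMARRRGKEVNQISSS
>AD_4 synthetic aligned instance
LATRPGVTPFFAQDDFQREDGTKVNQIGSS
>AD_5 synthetic aligned instance
LATRPGATAFFAQTDFAQRRGKKVNQIGSS
>AD_6 synthetic aligned instance
LMTRPGVTPLFAGDDFCRARVLKENQLGSS
>AD_7 synthetic aligned instance
EATRPGVTPFFTQDDFARRRGDKVNQIGSS
>AD_8 synthetic aligned instance
LATGPGVTPVFAPDSFARRRGLKVNQIMSS
>B_1 synthetic aligned instance
CHKEYLHQDLFEEQPGVELLQLGE
>B_2 synthetic aligned instance
CHKEYLSQDLFEEQVSVNELQLGE
>B_3 synthetic aligned instance
CHKEYLHVDLSEEIPGVAEIQNGE
>B_4 synthetic aligned instance
CHKEYLHQDLQEEQFLVAILPVGE
>B_5 synthetic aligned instance
CHKEYLSQDLFEEQVGVAELFLGE
>B_6 synthetic aligned instance
CHSEYLALDLFEEQVGVAELQLGI
>B_7 synthetic aligned instance
FIKFYLHQDLFEEQTGVAKLQLGE
>B_8 synthetic aligned instance
CHKEYLHQDLFDEQVGAAATQLGE
>C_1 synthetic aligned instance
MEYTGKMCQRPKAGIPGLLPVSGN
>C_2 synthetic aligned instance
MEYTGKMVQRPKAEQPGLLPISGN
>C_3 synthetic aligned instance
HEYTGKMVQRPKAEINGLGPVSGN
>C_4 synthetic aligned instance
MEYTGKMVQRPKAEIPGLLPVSGN
>C_5 synthetic aligned instance
MEYTGKMVQRPKAEIPGLLEVSGN
>C_6 synthetic aligned instance
MEYTGKMVQRPAAEIPGLLPVEGN
>C_7 synthetic aligned instance
MEYTGKMVQRPLAEIPGSLPVSGN
>C_8 synthetic aligned instance
MEYTGKMVQRPKAEAPGLLPVSGN
>D_1 synthetic aligned instance
PLEKIVATDGPDAPTIKLYE
>D_2 synthetic aligned instance
PAEKEVETDGPDAQTIKIAE
>D_3 synthetic aligned instance
PLEKEVATDGPDAPTIKIAE
>D_4 synthetic aligned instance
PLEKEFATDGTDAPTIKLAE
>D_5 synthetic aligned instance
ALEKEVATDGFDAPTIKIAD
>D_6 synthetic aligned instance
PLEKEVATDGIDAPTYKLAE
>D_7 synthetic aligned instance
THEPKVVTDGPDAPTIKIAG
>D_8 synthetic aligned instance
PLEKEVETDGPDGPTIKIAE
>DD_1 synthetic aligned instance
GGTKTDVASEPVDATATGCTGLIKFVECYFKMQRTSTVPE
>DD_2 synthetic aligned instance
PGTKTDVALNPVFGTATGPTGVIKFHECFFKMQRHSCVPE
>DD_3 synthetic aligned instance
VGTKTDVASEPEFGTATGPFGVLKFDECYFKMQRDSTVPE
>DD_4 synthetic aligned instance
PGTKTDVIKEQVVGTATIPTGVIKFVECYFKVARDSTVPE
>DD_5 synthetic aligned instance
PGTKTDVAHEPVFGTATGPSGVIKWVECYFKMQRDSTQPE
>DD_6 synthetic aligned instance
PGLSTDVASEPDHGTATGPMGVIKFVICYFKMQRGERVPV
>DD_7 synthetic aligned instance
PLTKTDVASEPVFITAVGPTGVIKFVECYFKATRDSTVPE
>DD_8 synthetic aligned instance
PLTKTDVASKPVFGTATGPKGVIKFVECYFKSQSDSTVPE
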