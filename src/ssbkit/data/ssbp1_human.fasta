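>SSBP1_HUMAN canonical mitochondrial single-stranded DNA-binding protein precursor (148 aa; mature protein residues 17-148)
MFRRPVLQVLRQFVRHESETTTSLVLERSLNRVHLLGRVGQDPVLRQVEGKNPVTIFSLA
TNEMWRSGDSEVYQLGDVSQKTTWHRISVFRPGLRDVAYQYVKKGSRIYLEGKIDYGEYM
DKNNVRRQATTIIADNIIFLSDQTKEKE
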