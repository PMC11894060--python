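011011110000111000110011000010000100000010010000000100000000010000000000000000000000100100000000000000010010
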