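111111001100111100100010001010000010001010000000000000001010000000001010
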