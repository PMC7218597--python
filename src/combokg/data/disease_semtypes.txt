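# "Disease or Syndrome" and child types for disease objects
dsyn
neop
mobd
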