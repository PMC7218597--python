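# UMLS "Chemicals and Drugs" group: semantic types a drug subject may carry
phsu
orch
antb
clnd
aapp
bacs
horm
imft
vita
enzy
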