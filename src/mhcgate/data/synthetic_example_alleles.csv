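allele,pseudo_sequence
HLA-A*02:01,FQCFHHWSWYCDVCEEWIGELNTPYDLNQAFLCYPSM
HLA-A*01:01,NHHDFSKTGRVTFIGSTKGCGECSLYGIVPGISILLL
HLA-A*03:01,LYFVECHFPEFWTNWICTCHLQDFCAEQMHQHYGQGN
HLA-B*07:02,NWHDKPFYMLNNKNKYWMAHHQMDNAAAFWCPAAHEK
HLA-B*08:01,CVLAARILQNQDSTNIGKSNEGEKGDPRHDKGIFADT
HLA-C*07:01,MMEQSWGAYVNYCNPFFMIMFKGMPLMGAQWPFKLKD
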