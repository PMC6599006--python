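>p53_CT_peptide start=367 human p53 C-terminal peptide, residues 367-393 (UniProt P04637)
SHLKSKKGQSTSRHKKLMFKTEGPDSD
>p53_313_393 start=313 human p53 linker-Tet-CT fragment, residues 313-393 (UniProt P04637)
SSSPQPKKKPLDGEYFTLQIRGRERFEMFRELNEALELKDAQAGKEPGGSRAHSSHLKSKKGQSTSRHKKLMFKTEGPDSD
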