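chebi_id	class
CHEBI:36916	cation
CHEBI:25213	cation
CHEBI:22563	anion
CHEBI:16646	sugar
CHEBI:35381	sugar
CHEBI:18133	sugar
CHEBI:33709	amino_acid_oligopeptide
CHEBI:16670	amino_acid_oligopeptide
CHEBI:25676	amino_acid_oligopeptide
CHEBI:36080	protein_mrna
CHEBI:33699	protein_mrna
CHEBI:10545	electron
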