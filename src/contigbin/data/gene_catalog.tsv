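# Default functional-gene catalog: gene_symbol <TAB> category <TAB> member accessions (comma-separated).
# Member accessions here are SYNTHETIC placeholders (SYN* prefix) so the
# shipped fixtures resolve without external downloads; replace or extend
# with real reference accessions for production use.
pcrA	perchlorate reduction	SYNPCRA01
pcrB	perchlorate reduction	SYNPCRB01
pcrC	perchlorate reduction	SYNPCRC01
pcrD	perchlorate reduction	SYNPCRD01
cld	chlorite dismutation	SYNCLD01
narG	nitrate reduction	SYNNARG01
narH	nitrate reduction	SYNNARH01
napA	nitrate reduction	SYNNAPA01
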