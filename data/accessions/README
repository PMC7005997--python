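Deposited chromosome sequences used by the published-value checks.

Place uncompressed FASTA files here, one per accession, named
<ACCESSION>.fasta (e.g. CP040671.fasta), downloaded from GenBank:
CP040671, CP032152, NC_004113, NZ_AP018202, NC_023033, NZ_CP018092.
These are ~2.6 Mb each and are not distributed with the package.
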