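# Restriction enzyme table for MSD-AFLP fragment prediction.
# Columns (tab separated):
#   name                 enzyme name
#   recognition          IUPAC recognition sequence (must be palindromic)
#   top_cut_offset       bases from recognition start to the top-strand cut
#   blocking_cpg_offset  0-based offset of the C of the CpG whose methylation
#                        blocks cleavage, or "." if cutting is methylation
#                        insensitive / no such CpG
#   methylation_sensitive  yes/no
#
# Users may append enzymes; only palindromic recognition sequences are
# supported by the site scanner.
name	recognition	top_cut_offset	blocking_cpg_offset	methylation_sensitive
SbfI	CCTGCAGG	6	.	no
HpaII	CCGG	1	1	yes
MspI	CCGG	1	.	no
StuI	AGGCCT	3	.	no
NcoI	CCATGG	1	.	no
AseI	ATTAAT	2	.	no
BspHI	TCATGA	1	.	no
PacI	TTAATTAA	5	.	no
SwaI	ATTTAAAT	4	.	no
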