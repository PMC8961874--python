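"""Count CCGG (HpaII/MspI) and GAATTC (EcoRI) sites in a FASTA sequence.

The CCGG count is the denominator of the LUMA phenotype: the assay reads the
methylation state of the internal CpG of every CCGG site genome-wide.
"""

import io

from gdmr import scan_fasta, site_summary

fasta = io.StringIO(
    ">demo_contig\n"
    "ATCCGGTTGAATTCCATACCGGCCGGAGAATTCTTACCGGTAGAATTCAT\n"
)

maps = scan_fasta(fasta)
print(site_summary(maps).to_string(index=False))
print()
print("CCGG positions (0-based):", maps[0].ccgg_positions)
# Each CCGG is one potential HpaII/MspI cut; each GAATTC is one EcoRI cut
# used as the loading control. On a real genome the CCGG total (~6 million
# in sheep) is what makes the single GDMR percentage a genome-wide average.
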