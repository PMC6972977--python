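"""Reference constants for the MYH9 gene and its protein product.

NMMHC-IIA (nonmuscle myosin heavy chain IIA) is a 1,960-residue protein
encoded by the 41-exon *MYH9* gene; exon 1 is non-coding. The reference
transcript used for all coordinates is NM_002473.5 (LRG_567t1,
ENST00000216181), the protein NP_002464.1.
"""

PROTEIN_LENGTH = 1960

#: residues encoded by exon 41; the nonhelical tail domain is the final 34 residues
NHTD_LENGTH = 34
NHTD_START_RESIDUE = PROTEIN_LENGTH - NHTD_LENGTH + 1  # 1927

#: first and last coding exon (exon 1 is 5'UTR only)
FIRST_CODING_EXON = 2
LAST_EXON = 41

#: a truncation terminating strictly after this residue removes fewer than the
#: last 50 residues; such variants receive PM4 in place of PVS1
LAST50_BOUNDARY = PROTEIN_LENGTH - 50  # 1910

REFERENCE_TRANSCRIPT = "NM_002473.5"
REFERENCE_PROTEIN = "NP_002464.1"
GENE_REGION = "NG_011884.2"
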