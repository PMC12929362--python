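"""Published PC-3 prostate-cancer aptamer sequences used as worked examples.

A6 and A11 are ssRNA aptamers selected against the PC-3 prostate cancer cell
line by 3D Cell-SELEX; LN-A6 and LN-A11 are their published ssDNA analogues
obtained by uracil→thymine substitution.  The published LN-A11 string is 57
nt: it omits the CCT triplet that strict per-base substitution of the 60-nt
A11 RNA produces (positions 34–36, from the RNA's CCU).  This package always
performs strict per-residue conversion and therefore reports the full 60-nt
string; :data:`LN_A11_DNA_PUBLISHED` preserves the shorter published form for
comparison.
"""

A6_RNA = (
    "CCGCAUCGUCCCAAGCCGAUUUUGGCGAGCAGCAGACAGGUUCCGGGGCGAGCAGCAGAC"
)

A11_RNA = (
    "CGAUGCGGAAUAGGGGCCAGGCGUAUCUGAGCUCCUAUUCUCUUUGUCCCGUCUGCUGCU"
)

LN_A6_DNA = (
    "CCGCATCGTCCCAAGCCGATTTTGGCGAGCAGCAGACAGGTTCCGGGGCGAGCAGCAGAC"
)

#: Published 57-nt LN-A11 string (CCT triplet absent; see module docstring).
LN_A11_DNA_PUBLISHED = (
    "CGATGCGGAATAGGGGCCAGGCGTATCTGAGCTATTCTCTTTGTCCCGTCTGCTGCT"
)

APTAMERS = {
    "A6": A6_RNA,
    "A11": A11_RNA,
    "LN-A6": LN_A6_DNA,
    "LN-A11": LN_A11_DNA_PUBLISHED,
}
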