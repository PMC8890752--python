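"""Amino-acid alphabet conventions shared across the package.

The 20 standard residues form the category set for all composition and
complexity statistics.  Ambiguity / rare codes (X, B, Z, U, O) are accepted
in input sequences: they count toward region length but never match a target
residue and are excluded from frequency-table categories.
"""

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"
AMBIGUOUS_AA = "XBZUO"
GAP = "-"

STANDARD_SET = frozenset(STANDARD_AA)
AMBIGUOUS_SET = frozenset(AMBIGUOUS_AA)
ALLOWED_SET = STANDARD_SET | AMBIGUOUS_SET
ALIGNED_SET = ALLOWED_SET | {GAP}
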