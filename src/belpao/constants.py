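"""Shared constants: element classes, protein domains, alphabets, codon tables."""

from Bio.Data import CodonTable

#: Fixed class order; also the deterministic tie-break order in classification.
CLASSES = ("Ty1/Copia", "Ty3/Gypsy", "BEL/Pao", "DIRS")

#: Protein domains carried by the elements, in template order on the plus strand.
DOMAINS = ("gag", "protease", "reverse_transcriptase", "integrase")

#: pol domains used for consensus building and the concatenated phylogeny,
#: in the order they occur in BEL/Pao elements.
POL_DOMAINS = ("protease", "reverse_transcriptase", "integrase")

NUCLEOTIDES = "ACGT"

#: 20 standard amino acids, fixed order used by all profile matrices.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

_table = CodonTable.unambiguous_dna_by_id[1]

#: amino acid -> tuple of synonymous codons (standard genetic code, no stops).
CODONS_FOR_AA: dict[str, tuple[str, ...]] = {}
for _codon, _aa in _table.forward_table.items():
    CODONS_FOR_AA.setdefault(_aa, tuple())
    CODONS_FOR_AA[_aa] = CODONS_FOR_AA[_aa] + (_codon,)

STOP_CODONS = tuple(_table.stop_codons)


def _aa_background():
    import numpy as np
    bg = np.array([len(CODONS_FOR_AA[a]) for a in AMINO_ACIDS], dtype=float)
    return bg / bg.sum()


#: amino-acid frequencies of translated random DNA (codon multiplicities over
#: the 61 sense codons); the null composition used for profile log-odds,
#: decoy calibration and synthetic protein sequences.
AA_BACKGROUND = _aa_background()

COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]
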