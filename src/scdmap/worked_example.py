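"""Synthetic worked-example fixtures for the canine HES7 / SCD4 analysis.

The published canine HES7 resources (mRNA accession XM_844962.3 and the
corrected sequence derived from the sequenced proband) are not bundled
here.  Instead this module constructs SYNTHETIC stand-in sequences that
reproduce the reported geometry exactly, so every downstream computation
(translation, frameshift naming, domain disruption, restriction digestion)
runs on real inputs of the right shape:

* a 675-nt CDS translating to a 224-residue protein, in which the
  c.126delG single-base deletion causes a frameshift from residue 43
  (Thr -> Pro) with a premature stop in place of residue 66, i.e.
  p.(Thr43ProfsTer24) and a 65-residue mutant protein;
* a 579-bp wild-type amplicon carrying a single BsrBI site (CCGCTC,
  printed with its genomic context as TCCGCTCC) whose digestion yields
  472 + 107 bp fragments, and whose 578-bp single-base-deletion
  counterpart is uncut;
* the three-generation miniature schnauzer family: carrier parents, a
  litter of eight with three affected pups, a heterozygous maternal
  grandsire and one heterozygous female offspring of his;
* the diagnostic-assay genotype counts of the full 133-dog cohort
  (3 hom-mutant cases; 126 hom-wild-type and 4 carrier controls).

All sequences are deterministic; none is the real canine sequence.
"""

from __future__ import annotations

import numpy as np

from .consequence import DomainAnnotation, Transcript
from .pedigree import AFFECTED, UNAFFECTED, UNKNOWN, Individual, Pedigree
from .rflp import Amplicon, Enzyme, digest

__all__ = [
    "hes7_synthetic_transcript",
    "hes7_domains",
    "HES7_EDIT",
    "rflp_synthetic_amplicon",
    "BSRBI",
    "default_enzyme_table",
    "family_pedigree",
    "COHORT_CASE_COUNTS",
    "COHORT_CONTROL_COUNTS",
]

#: the causal cDNA edit
HES7_EDIT = "c.126delG"

#: diagnostic-assay genotype counts (hom-wt, het, hom-mut) observed in the
#: 133-dog genotyping cohort: the three affected pups versus 130 relatives
#: and population controls
COHORT_CASE_COUNTS = (0, 0, 3)
COHORT_CONTROL_COUNTS = (126, 4, 0)

#: BsrBI: canonical recognition site CCGCTC, blunt cut after the third base
BSRBI = Enzyme("BsrBI", "CCGCTC", cut_offset=3)

_NON_STOP_CODONS = [
    "GAG", "CTG", "CGC", "AAG", "GCC", "GAC", "TTC", "CCC", "AGC", "GTG",
]


def _synthetic_cds() -> str:
    """Build the 675-nt synthetic CDS (224 codons + stop).

    Constructed so that deleting the G at c.126 (third base of codon 42,
    CCG) leaves residue 42 as proline (CCA), changes residue 43 from
    threonine (ACC) to proline, and shifts the frame into a stretch that
    reads CCG...CCG until a TGA stop occupies mutant codon 66.
    """
    codons: list[str] = ["ATG"]
    for i in range(40):  # residues 2-41
        codons.append(_NON_STOP_CODONS[i % len(_NON_STOP_CODONS)])
    codons.append("CCG")  # residue 42 (c.124-126; the deleted G is c.126)
    codons.append("ACC")  # residue 43, Thr; becomes Pro after the shift
    codons.extend(["GCC"] * 22)  # residues 44-65; shifted frame reads CCG
    codons.append("CTG")  # residue 66; shifted frame reads TGA here
    codons.append("ACC")  # residue 67 must start with A to complete the TGA
    for i in range(156):  # residues 68-223
        codons.append(_NON_STOP_CODONS[(i + 3) % len(_NON_STOP_CODONS)])
    codons.append("AAG")  # residue 224
    codons.append("TAA")  # stop
    cds = "".join(codons)
    assert len(cds) == 675, len(cds)
    assert cds[125] == "G" and cds[126] != "G"  # c.126delG is 3'-normalized
    return cds


def hes7_synthetic_transcript() -> Transcript:
    """Synthetic stand-in for the canine HES7 mRNA (4 exons, 885 nt).

    The CDS occupies mRNA positions 91-765; c.126 falls in exon 2, as the
    real deletion does.  UTRs are neutral spacer sequence.
    """
    cds = _synthetic_cds()
    utr5 = "".join("CAGT"[i % 4] for i in range(90))
    utr3 = "".join("GATC"[i % 4] for i in range(120))
    mrna = utr5 + cds + utr3
    return Transcript(
        id="HES7_synthetic",
        mrna=mrna,
        cds_start=91,
        cds_end=765,
        exon_lengths=(220, 160, 150, 355),
    )


def hes7_domains() -> list[DomainAnnotation]:
    """The two functional domains of the 224-residue protein: the
    helix-loop-helix DNA-binding/dimerization domain and the Orange
    (Hairy) domain."""
    return [
        DomainAnnotation("HLH", 14, 68),
        DomainAnnotation("Orange", 91, 128),
    ]


def rflp_synthetic_amplicon() -> Amplicon:
    """Synthetic 579-bp amplicon with one BsrBI site 107 bp from the 5' end.

    The site is embedded in the printed context TCCGCTCC; deleting the G
    of the core (position 107) destroys it, giving an uncut 578-bp mutant
    allele.  Flanking sequence is drawn from a fixed-seed generator and
    re-drawn until neither allele contains a stray site on either strand.
    """
    rng = np.random.default_rng(579_107)
    context = "TCCGCTCC"  # bases 104-111 (1-based); core CCGCTC at 105-110
    while True:
        left = "".join("ACGT"[i] for i in rng.integers(0, 4, size=103))
        right = "".join("ACGT"[i] for i in rng.integers(0, 4, size=579 - 111))
        wt = left + context + right
        mut = wt[:106] + wt[107:]  # delete the G at 1-based position 107
        assert wt[106] == "G" and len(wt) == 579 and len(mut) == 578
        if digest(wt, BSRBI).lengths == (472, 107) and digest(mut, BSRBI).lengths == (578,):
            return Amplicon(wt, mut, name="HES7_rflp_synthetic")


def default_enzyme_table() -> list[Enzyme]:
    """A small table of common enzymes for assay screening."""
    return [
        BSRBI,
        Enzyme("EcoRI", "GAATTC", 1),
        Enzyme("BamHI", "GGATCC", 1),
        Enzyme("HindIII", "AAGCTT", 1),
        Enzyme("TaqI", "TCGA", 1),
        Enzyme("AluI", "AGCT", 2),
        Enzyme("HpaII", "CCGG", 1),
    ]


def family_pedigree() -> Pedigree:
    """The genotyped family: three-generation pedigree with assay results.

    Carrier (het) parents and maternal grandsire, one het female offspring
    of the grandsire, three affected hom-mutant pups, three healthy
    littermates and two stillborn-but-morphologically-normal pups
    (phenotype unknown, untyped).
    """
    return Pedigree(
        [
            Individual("M_GS", sex="M", phenotype=UNAFFECTED, genotype=1),
            Individual("M_GD", sex="F", phenotype=UNAFFECTED),
            Individual("SIRE", sex="M", phenotype=UNAFFECTED, genotype=1),
            Individual("DAM", sire="M_GS", dam="M_GD", sex="F",
                       phenotype=UNAFFECTED, genotype=1),
            Individual("AUNT", sire="M_GS", dam="M_GD", sex="F",
                       phenotype=UNAFFECTED, genotype=1),
            Individual("PUP1", sire="SIRE", dam="DAM", sex="M",
                       phenotype=AFFECTED, genotype=2),
            Individual("PUP2", sire="SIRE", dam="DAM", sex="M",
                       phenotype=AFFECTED, genotype=2),
            Individual("PUP3", sire="SIRE", dam="DAM", sex="F",
                       phenotype=AFFECTED, genotype=2),
            Individual("PUP4", sire="SIRE", dam="DAM", sex="M", phenotype=UNAFFECTED),
            Individual("PUP5", sire="SIRE", dam="DAM", sex="F", phenotype=UNAFFECTED),
            Individual("PUP6", sire="SIRE", dam="DAM", sex="F", phenotype=UNAFFECTED),
            Individual("PUP7", sire="SIRE", dam="DAM", sex="M", phenotype=UNKNOWN),
            Individual("PUP8", sire="SIRE", dam="DAM", sex="F", phenotype=UNKNOWN),
        ]
    )
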