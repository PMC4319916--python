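"""Coding-sequence consequence prediction for cDNA-level variants.

Applies HGVS c.-style edits (substitution, deletion, duplication,
insertion) to a transcript's CDS, translates with the standard genetic
code, names the protein consequence in HGVS p. notation (including
frameshift ``fsTer`` forms), applies the canonical 50-nt rule for
nonsense-mediated decay, and classifies disruption of annotated protein
domains.

Coordinate conventions: c.1 is the A of the initiator ATG; all positions
are 1-based inclusive.  The stop codon is never counted as a protein
residue, so a premature stop "in place of" residue N yields a mutant
protein of length N - 1.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Optional, Sequence

import pandas as pd
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq
from Bio.SeqUtils import seq3

__all__ = [
    "Transcript",
    "ProteinConsequence",
    "DomainAnnotation",
    "NmdVerdict",
    "apply_cdna_variant",
    "normalize_deletion_3prime",
    "translate",
    "describe_consequence",
    "predict_nmd",
    "domain_disruption",
    "read_transcript",
    "write_consequence_report",
]

_STOPS = set(standard_dna_table.stop_codons)


@dataclass
class Transcript:
    """An mRNA with its CDS span and exon structure in transcript coordinates.

    ``cds_start``/``cds_end`` are 1-based positions in the mRNA;
    ``exon_lengths`` are the spliced exon lengths in transcript order and
    must sum to the mRNA length.
    """

    id: str
    mrna: str
    cds_start: int
    cds_end: int
    exon_lengths: tuple[int, ...]

    def __post_init__(self) -> None:
        self.mrna = self.mrna.upper()
        if sum(self.exon_lengths) != len(self.mrna):
            raise ValueError("exon lengths do not sum to mRNA length")
        if not (1 <= self.cds_start < self.cds_end <= len(self.mrna)):
            raise ValueError("CDS span outside mRNA")
        cds = self.cds
        if len(cds) % 3 != 0:
            raise ValueError("CDS length not divisible by 3")
        if not cds.startswith("ATG"):
            raise ValueError("CDS does not start with ATG")
        if cds[-3:] not in _STOPS:
            raise ValueError("CDS does not end with a stop codon")

    @property
    def cds(self) -> str:
        return self.mrna[self.cds_start - 1 : self.cds_end]

    def cds_to_mrna(self, c_pos: int) -> int:
        """Map a c. coordinate to an mRNA coordinate."""
        if not (1 <= c_pos <= len(self.cds)):
            raise ValueError(f"c.{c_pos} outside CDS")
        return self.cds_start + c_pos - 1


_HGVS_RE = re.compile(
    r"^c\.(?P<start>\d+)(?:_(?P<end>\d+))?"
    r"(?:(?P<ref>[ACGT])>(?P<alt>[ACGT])"
    r"|(?P<op>del|dup|ins)(?P<seq>[ACGT]*))$"
)


def _parse_hgvs_c(hgvs_c: str):
    m = _HGVS_RE.match(hgvs_c.strip())
    if not m:
        raise ValueError(f"cannot parse HGVS cDNA description {hgvs_c!r}")
    start = int(m.group("start"))
    end = int(m.group("end")) if m.group("end") else start
    if end < start:
        raise ValueError(f"reversed interval in {hgvs_c!r}")
    if m.group("ref"):
        return ("sub", start, end, m.group("ref"), m.group("alt"))
    return (m.group("op"), start, end, None, m.group("seq") or None)


def apply_cdna_variant(t: Transcript, hgvs_c: str) -> str:
    """Apply an HGVS c. edit to the transcript's CDS and return the mutant CDS.

    Supports substitutions (c.126G>A), deletions (c.126delG, c.124_126del),
    duplications (c.4_6dupACT, c.4dup) and insertions (c.4_5insTT).  The
    stated reference bases must match the CDS at the stated position; a
    mismatch signals a stale transcript and raises.  Any equivalent
    (non-3'-normalized) deletion/duplication position is accepted for
    editing; 3' normalization applies only to reporting
    (:func:`normalize_deletion_3prime`).
    """
    cds = t.cds
    kind, start, end, ref, seq = _parse_hgvs_c(hgvs_c)
    if end > len(cds):
        raise ValueError(f"position c.{end} outside CDS of length {len(cds)}")
    i, j = start - 1, end  # python slice of the addressed bases
    if kind == "sub":
        if cds[i] != ref:
            raise ValueError(
                f"reference mismatch at c.{start}: CDS has {cds[i]}, edit says {ref}"
            )
        if ref == seq:
            warnings.warn(f"substitution {hgvs_c} leaves the CDS unchanged")
        return cds[:i] + seq + cds[j:]
    if kind == "del":
        if seq and cds[i:j] != seq:
            raise ValueError(
                f"reference mismatch at c.{start}_{end}: CDS has {cds[i:j]}, "
                f"edit says {seq}"
            )
        return cds[:i] + cds[j:]
    if kind == "dup":
        if seq and cds[i:j] != seq:
            raise ValueError(f"reference mismatch for duplication {hgvs_c}")
        return cds[:j] + cds[i:j] + cds[j:]
    if kind == "ins":
        if end != start + 1:
            raise ValueError("insertion requires flanking positions c.X_X+1ins")
        if not seq:
            raise ValueError("insertion requires an inserted sequence")
        return cds[: i + 1] + seq + cds[i + 1 :]
    raise AssertionError(kind)


def normalize_deletion_3prime(cds: str, start: int, end: int) -> tuple[int, int]:
    """Shift a deletion to its 3'-most equivalent position (HGVS rule).

    Returns the normalized 1-based (start, end) of the deleted run.  The
    deletion of cds[start-1:end] is equivalent to deleting one window to
    the right whenever the base following the window equals the base at
    the window start.
    """
    i, j = start - 1, end
    while j < len(cds) and cds[j] == cds[i]:
        i += 1
        j += 1
    return i + 1, j


def translate(cds: str) -> tuple[str, bool]:
    """Translate a CDS with the standard genetic code.

    Returns (protein, terminated): the residues up to but excluding the
    first in-frame stop, and whether a stop was reached.  Trailing bases
    short of a full codon are ignored once a stop is found; a sequence
    with no in-frame stop is returned in full with ``terminated=False``.
    """
    cds = cds.upper()
    if not cds.startswith("ATG"):
        raise ValueError("CDS must start with ATG")
    if set(cds) - set("ACGT"):
        raise ValueError("CDS contains non-ACGT characters")
    protein = []
    for k in range(0, len(cds) - 2, 3):
        codon = cds[k : k + 3]
        if codon in _STOPS:
            return "".join(protein), True
        protein.append(str(Seq(codon).translate()))
    return "".join(protein), False


@dataclass
class ProteinConsequence:
    """HGVS-style protein consequence of a coding variant."""

    hgvs_p: str
    first_altered: Optional[int]  # 1-based residue index, None for p.(=)
    stop_residue: Optional[int]  # codon position occupied by the new stop
    mutant_length: int
    frameshift: bool

    @property
    def ter_offset(self) -> Optional[int]:
        """Distance (in codons) from the first altered residue to the new stop."""
        if self.first_altered is None or self.stop_residue is None:
            return None
        return self.stop_residue - self.first_altered + 1


def _strip_stop(protein: str) -> str:
    return protein.rstrip("*")


def describe_consequence(
    wt_protein: str,
    mut_protein: str,
    mut_terminated: bool = True,
) -> ProteinConsequence:
    """Name the difference between wild-type and mutant protein in HGVS p. style.

    Handles the identity (p.(=)), missense (p.(Thr43Pro)), nonsense
    (p.(Thr43Ter)) and frameshift (p.(Thr43ProfsTer24)) cases.  For
    frameshifts, TerN counts the new stop codon itself: a frameshift
    starting at residue F with the stop occupying codon S is fsTer(S-F+1).
    Non-terminated mutant translations are reported with Ter"?".
    """
    wt = _strip_stop(wt_protein)
    mut = _strip_stop(mut_protein)
    if wt == mut:
        return ProteinConsequence("p.(=)", None, None, len(mut), False)
    if not wt:
        raise ValueError("empty wild-type protein")

    first = next(
        (k for k, (a, b) in enumerate(zip(wt, mut), start=1) if a != b),
        min(len(wt), len(mut)) + 1,
    )
    if first > len(wt):
        raise ValueError("mutant extends wild type without divergence; not supported")
    wt_res = seq3(wt[first - 1])

    if first > len(mut):
        # truncation with no changed residue before the stop: nonsense
        stop = len(mut) + 1
        return ProteinConsequence(
            f"p.({wt_res}{first}Ter)", first, stop, len(mut), False
        )
    mut_res = seq3(mut[first - 1])
    if len(mut) == len(wt) and wt[first:] == mut[first:] and mut_terminated:
        return ProteinConsequence(
            f"p.({wt_res}{first}{mut_res})", first, None, len(mut), False
        )
    # frameshift-style divergence
    if mut_terminated:
        stop = len(mut) + 1
        ter = stop - first + 1
        return ProteinConsequence(
            f"p.({wt_res}{first}{mut_res}fsTer{ter})", first, stop, len(mut), True
        )
    return ProteinConsequence(
        f"p.({wt_res}{first}{mut_res}fsTer?)", first, None, len(mut), True
    )


@dataclass
class NmdVerdict:
    verdict: Literal["targeted", "escapes"]
    distance_to_final_junction: Optional[int]  # None for single-exon transcripts


def predict_nmd(t: Transcript, stop_pos_mrna: int, rule_nt: int = 50) -> NmdVerdict:
    """Apply the canonical 50-nt rule for nonsense-mediated decay.

    ``stop_pos_mrna`` is the 1-based mRNA coordinate of the first base of
    the premature termination codon.  The PTC escapes NMD iff it lies in
    the last exon or no more than ``rule_nt`` nt upstream of the final
    exon-exon junction; otherwise the transcript is predicted to be
    degraded.  Single-exon transcripts always escape.
    """
    if not (1 <= stop_pos_mrna <= len(t.mrna)):
        raise ValueError("stop position beyond mRNA length")
    if len(t.exon_lengths) == 1:
        return NmdVerdict("escapes", None)
    final_junction = sum(t.exon_lengths[:-1])  # last base of penultimate exon
    distance = final_junction - stop_pos_mrna + 1
    if distance <= 0:
        return NmdVerdict("escapes", distance)
    return NmdVerdict("escapes" if distance <= rule_nt else "targeted", distance)


@dataclass(frozen=True)
class DomainAnnotation:
    name: str
    start: int  # 1-based residue, inclusive
    end: int

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError("invalid domain interval")


def domain_disruption(
    consequence: ProteinConsequence, domains: Sequence[DomainAnnotation]
) -> dict[str, str]:
    """Classify each protein domain against a truncating/frameshift consequence.

    A domain lying entirely before the first altered residue is intact;
    one lying entirely at or beyond the premature stop is lost from the
    mutant protein; anything overlapping the altered stretch is altered.
    An identity consequence leaves every domain intact.
    """
    status: dict[str, str] = {}
    first = consequence.first_altered
    stop = consequence.stop_residue
    for d in domains:
        if first is None or d.end < first:
            status[d.name] = "intact"
        elif stop is not None and d.start >= stop:
            status[d.name] = "lost"
        else:
            status[d.name] = "altered"
    return status


# ---------------------------------------------------------------------------
# IO: FASTA + TSV sidecar for transcripts, TSV consequence report


def read_transcript(fasta_path: str | Path, sidecar_path: str | Path) -> Transcript:
    """Load a transcript from a FASTA file and a TSV sidecar.

    The sidecar has one row per transcript with columns
    ``transcript_id``, ``cds_start``, ``cds_end``, ``exon_lengths``
    (comma-separated, transcript order).
    """
    from Bio import SeqIO

    records = {r.id: str(r.seq) for r in SeqIO.parse(str(fasta_path), "fasta")}
    meta = pd.read_csv(sidecar_path, sep="\t", dtype={"transcript_id": str})
    row = meta.iloc[0]
    tid = str(row["transcript_id"])
    if tid not in records:
        raise ValueError(f"transcript {tid!r} not present in {fasta_path}")
    exon_lengths = tuple(int(x) for x in str(row["exon_lengths"]).split(","))
    return Transcript(
        id=tid,
        mrna=records[tid],
        cds_start=int(row["cds_start"]),
        cds_end=int(row["cds_end"]),
        exon_lengths=exon_lengths,
    )


def write_consequence_report(
    t: Transcript,
    hgvs_c: str,
    consequence: ProteinConsequence,
    nmd: Optional[NmdVerdict],
    domain_status: dict[str, str],
    path: str | Path,
) -> None:
    rows = [
        {
            "transcript": t.id,
            "edit": hgvs_c,
            "hgvs_p": consequence.hgvs_p,
            "first_altered": consequence.first_altered,
            "stop_residue": consequence.stop_residue,
            "mutant_length": consequence.mutant_length,
            "frameshift": consequence.frameshift,
            "nmd": nmd.verdict if nmd else "",
            "nmd_distance_nt": nmd.distance_to_final_junction if nmd else "",
            **{f"domain:{name}": s for name, s in domain_status.items()},
        }
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
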