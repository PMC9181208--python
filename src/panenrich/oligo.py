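"""Reverse translation and fixed-length oligonucleotide pool assembly.

Accepted CDR designs are reverse-translated with a deterministic one-codon-
per-residue scheme (most-used human codon, demoted to the next-ranked human
codon when the top choice is rare in E. coli, so the sequence expresses well
in both hosts) and embedded in a fixed-length 136-nt oligonucleotide:

    adaptor5 + framework flank + CDR + framework flank + adaptor3

The adaptors are common PCR handles; the framework flanks are trimmed
symmetrically from their distal ends (the CDR-adjacent bases are the priming
context for library assembly and are always preserved) so that every oligo
is exactly 136 nt.  An odd leftover base goes to the 5' side.  CDR-H3 oligos
are binned by CDR length (9-16 aa) for length-separated amplification.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio.Seq import Seq

from .ingest import AA20

OLIGO_LENGTH = 136
H3_LENGTH_RANGE = (9, 16)

#: Codons per residue ranked by human usage (most-used first).
HUMAN_CODON_RANKING: dict[str, tuple[str, ...]] = {
    "A": ("GCC", "GCT", "GCA", "GCG"),
    "R": ("AGA", "AGG", "CGG", "CGC", "CGA", "CGT"),
    "N": ("AAC", "AAT"),
    "D": ("GAC", "GAT"),
    "C": ("TGC", "TGT"),
    "Q": ("CAG", "CAA"),
    "E": ("GAG", "GAA"),
    "G": ("GGC", "GGA", "GGG", "GGT"),
    "H": ("CAC", "CAT"),
    "I": ("ATC", "ATT", "ATA"),
    "L": ("CTG", "CTC", "TTG", "CTT", "TTA", "CTA"),
    "K": ("AAG", "AAA"),
    "M": ("ATG",),
    "F": ("TTC", "TTT"),
    "P": ("CCC", "CCT", "CCA", "CCG"),
    "S": ("AGC", "TCC", "TCT", "AGT", "TCA", "TCG"),
    "T": ("ACC", "ACA", "ACT", "ACG"),
    "W": ("TGG",),
    "Y": ("TAC", "TAT"),
    "V": ("GTG", "GTC", "GTT", "GTA"),
}

#: Codons commonly listed as rare in E. coli.
ECOLI_RARE_CODONS = frozenset({"ATA", "AGG", "AGA", "CGA", "CTA", "CCC", "GGA"})


class OligoError(ValueError):
    pass


@dataclass(frozen=True)
class CodonScheme:
    """Deterministic amino acid -> codon map avoiding host-rare codons."""

    codon_for: Mapping[str, str]
    rare_codon_set: frozenset[str] = ECOLI_RARE_CODONS
    unavoidable_rare: frozenset[str] = frozenset()

    @classmethod
    def from_ranking(
        cls,
        ranking: Mapping[str, Sequence[str]] = HUMAN_CODON_RANKING,
        rare: Iterable[str] = ECOLI_RARE_CODONS,
    ) -> "CodonScheme":
        """Pick the top-ranked codon per residue, demoting rare codons.

        When every codon of a residue is rare, the top-ranked one is used
        anyway and the residue is flagged in ``unavoidable_rare``.
        """
        rare = frozenset(rare)
        table: dict[str, str] = {}
        flagged = set()
        for aa, codons in ranking.items():
            choice = next((c for c in codons if c not in rare), None)
            if choice is None:
                choice = codons[0]
                flagged.add(aa)
            table[aa] = choice
        return cls(dict(table), rare, frozenset(flagged))


DEFAULT_CODON_SCHEME = CodonScheme.from_ranking()


def reverse_translate(aa_seq: str, scheme: CodonScheme = DEFAULT_CODON_SCHEME) -> str:
    """Deterministically reverse-translate a peptide (standard residues only)."""
    if not set(aa_seq) <= AA20:
        raise OligoError(f"non-standard residues in {aa_seq!r}")
    return "".join(scheme.codon_for[aa] for aa in aa_seq)


@dataclass(frozen=True)
class OligoRecord:
    """A 136-nt oligo with its adaptor/flank/CDR segmentation."""

    name: str
    adaptor5: str
    flank5: str
    cdr_nt: str
    flank3: str
    adaptor3: str
    cdr_aa: str

    @property
    def sequence(self) -> str:
        return self.adaptor5 + self.flank5 + self.cdr_nt + self.flank3 + self.adaptor3

    @property
    def total_len(self) -> int:
        return len(self.sequence)

    @property
    def length_bin(self) -> int:
        return len(self.cdr_aa)

    @property
    def insert_peptide(self) -> str:
        """Translation of flank5 + CDR + flank3 (flanks trimmed to codons)."""
        trim5 = len(self.flank5) % 3
        core = self.flank5[trim5:] + self.cdr_nt + self.flank3
        core = core[: len(core) - len(core) % 3]
        return str(Seq(core).translate())


@dataclass(frozen=True)
class RegionOligoConfig:
    """Adaptors and full-length framework flanks (nt) for one CDR region."""

    region_label: str
    adaptor5: str
    adaptor3: str
    flank5_nt: str
    flank3_nt: str


def assemble_oligo(
    cdr_aa: str,
    config: RegionOligoConfig,
    scheme: CodonScheme = DEFAULT_CODON_SCHEME,
    name: str | None = None,
) -> OligoRecord:
    """Assemble a fixed-length 136-nt oligo around one CDR design.

    The framework flanks are cut down symmetrically — keeping their
    CDR-adjacent (inner) ends — so the total length is exactly 136 nt; an
    odd remainder goes to the 5' flank.  Errors when the CDR is too long to
    fit or a configured flank is shorter than its share.
    """
    cdr_nt = reverse_translate(cdr_aa, scheme)
    budget = OLIGO_LENGTH - len(config.adaptor5) - len(config.adaptor3) - len(cdr_nt)
    if budget < 0:
        raise OligoError(
            f"CDR of {len(cdr_aa)} aa cannot fit a {OLIGO_LENGTH}-nt oligo "
            "with these adaptors"
        )
    take5 = budget - budget // 2  # extra base to the 5' side
    take3 = budget // 2
    if take5 > len(config.flank5_nt) or take3 > len(config.flank3_nt):
        raise OligoError("configured framework flank too short to fill the oligo")
    flank5 = config.flank5_nt[len(config.flank5_nt) - take5 :] if take5 else ""
    flank3 = config.flank3_nt[:take3]
    record = OligoRecord(
        name=name or f"{config.region_label}_{cdr_aa}",
        adaptor5=config.adaptor5,
        flank5=flank5,
        cdr_nt=cdr_nt,
        flank3=flank3,
        adaptor3=config.adaptor3,
        cdr_aa=cdr_aa,
    )
    assert record.total_len == OLIGO_LENGTH
    return record


def bin_by_length(
    oligos: Iterable[OligoRecord],
    length_range: tuple[int, int] = H3_LENGTH_RANGE,
) -> dict[int, list[OligoRecord]]:
    """Partition oligos by CDR amino-acid length for gel separation."""
    lo, hi = length_range
    bins: dict[int, list[OligoRecord]] = {}
    for rec in oligos:
        if not lo <= rec.length_bin <= hi:
            raise OligoError(
                f"CDR length {rec.length_bin} outside designed range {length_range}"
            )
        bins.setdefault(rec.length_bin, []).append(rec)
    return bins


def oligos_to_frame(oligos: Iterable[OligoRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "name": o.name,
                "cdr_aa": o.cdr_aa,
                "length_bin": o.length_bin,
                "adaptor5": o.adaptor5,
                "flank5": o.flank5,
                "cdr_nt": o.cdr_nt,
                "flank3": o.flank3,
                "adaptor3": o.adaptor3,
                "sequence": o.sequence,
                "total_len": o.total_len,
            }
            for o in oligos
        ]
    )


def write_fasta(oligos: Iterable[OligoRecord], path) -> None:
    with open(path, "w") as fh:
        for o in oligos:
            fh.write(f">{o.name}\n{o.sequence}\n")
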