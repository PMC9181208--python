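"""CDR extraction and counting from merged amplicon repertoires.

Synthetic antibody libraries built on a fixed framework scaffold have
invariant framework sequences flanking every CDR.  A CDR is therefore
extracted from a merged read by exact-matching the framework *anchors* on
either side; the residues between the two anchors are the CDR.  Reads are
aggregated into a count table keyed by unique CDR amino-acid sequence, with
one column per repertoire (pre-/post-panning), which is the input to the
enrichment-score statistic.

Anchor matching is exact by design: the frameworks are invariant in the
library, and allowing mismatches would blur the designed/non-designed split
that the downstream analysis depends on.
"""

from __future__ import annotations

import io
import os
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import pandas as pd
from Bio.Seq import Seq
from Bio import SeqIO

AA20 = set("ACDEFGHIKLMNPQRSTVWY")
_NT = set("ACGT")
_NT_AMBIG = set("ACGTN")

REPERTOIRES = ("pre", "post")


class IngestError(ValueError):
    pass


class NoDesignedSequencesError(IngestError):
    """Whitelist intersection with the observed repertoire is empty."""


@dataclass(frozen=True)
class FrameworkScheme:
    """Invariant framework anchors delimiting one CDR.

    Parameters
    ----------
    region_label
        One of H1, H2, H3, kL1, kL2, kL3, lL1, lL2, lL3.
    left_anchor, right_anchor
        Invariant framework amino acids immediately preceding / following
        the CDR.  At least 4 aa each so that chance matches are rare.
    length_range
        Inclusive (min, max) designed CDR length in amino acids.
    """

    region_label: str
    left_anchor: str
    right_anchor: str
    length_range: tuple[int, int]

    _REGIONS = frozenset({"H1", "H2", "H3", "kL1", "kL2", "kL3", "lL1", "lL2", "lL3"})

    def __post_init__(self) -> None:
        if self.region_label not in self._REGIONS:
            raise IngestError(f"unknown region label {self.region_label!r}")
        for name in ("left_anchor", "right_anchor"):
            anchor = getattr(self, name)
            if len(anchor) < 4 or not set(anchor) <= AA20:
                raise IngestError(f"{name} must be >=4 standard amino acids")
        lo, hi = self.length_range
        if not (3 <= lo <= hi <= 30):
            raise IngestError("length_range must lie within [3, 30]")
        if self.region_label == "H3" and (lo < 9 or hi > 16):
            raise IngestError("H3 designed length range is [9, 16] aa")


#: CDR-H3 anchors in the VH3-23/JH4 scaffold context (FR3 tail / FR4 head).
DEFAULT_H3_SCHEME = FrameworkScheme("H3", "AVYYC", "WGQGT", (9, 16))


@dataclass(frozen=True)
class CdrRecord:
    """One extracted CDR observation."""

    region_label: str
    aa_seq: str
    count: int
    repertoire: str
    designed: bool | None = None

    def __post_init__(self) -> None:
        if not set(self.aa_seq) <= AA20:
            raise IngestError(f"non-standard residues in {self.aa_seq!r}")
        if self.count < 1:
            raise IngestError("count must be >= 1")
        if self.repertoire not in REPERTOIRES:
            raise IngestError(f"repertoire must be one of {REPERTOIRES}")

    @property
    def length(self) -> int:
        return len(self.aa_seq)


@dataclass
class CountTable:
    """Read counts per unique CDR amino-acid sequence and repertoire.

    ``counts`` maps aa_seq -> {"pre": n, "post": n}.  ``designed`` flags
    whitelist membership once :func:`apply_whitelist` has run.  ``rejections``
    carries the per-reason read rejection summary from extraction.
    """

    region_label: str
    counts: dict[str, dict[str, int]] = field(default_factory=dict)
    designed: dict[str, bool] = field(default_factory=dict)
    rejections: Counter = field(default_factory=Counter)
    retained_read_fraction: float | None = None

    def add(self, aa_seq: str, repertoire: str, count: int = 1) -> None:
        if repertoire not in REPERTOIRES:
            raise IngestError(f"repertoire must be one of {REPERTOIRES}")
        slot = self.counts.setdefault(aa_seq, {r: 0 for r in REPERTOIRES})
        slot[repertoire] += count

    def get(self, aa_seq: str, repertoire: str) -> int:
        return self.counts.get(aa_seq, {}).get(repertoire, 0)

    def total(self, repertoire: str) -> int:
        return sum(c[repertoire] for c in self.counts.values())

    @property
    def n_pre(self) -> int:
        return self.total("pre")

    @property
    def n_post(self) -> int:
        return self.total("post")

    def sequences(self) -> list[str]:
        return list(self.counts)

    def __len__(self) -> int:
        return len(self.counts)

    @classmethod
    def combine(cls, pre: "CountTable", post: "CountTable") -> "CountTable":
        """Merge two single-repertoire tables into one pre/post table."""
        if pre.region_label != post.region_label:
            raise IngestError("cannot combine tables from different regions")
        out = cls(pre.region_label)
        for table, rep in ((pre, "pre"), (post, "post")):
            for seq, slot in table.counts.items():
                if slot[rep]:
                    out.add(seq, rep, slot[rep])
        out.rejections = pre.rejections + post.rejections
        return out

    # ------------------------------------------------------------------ I/O
    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "region": self.region_label,
                "aa_seq": seq,
                "length": len(seq),
                "count_pre": slot["pre"],
                "count_post": slot["post"],
                "designed": self.designed.get(seq, True),
            }
            for seq, slot in sorted(self.counts.items())
        ]
        return pd.DataFrame(
            rows,
            columns=["region", "aa_seq", "length", "count_pre", "count_post", "designed"],
        )

    def to_tsv(self, path: str | os.PathLike | io.TextIOBase) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | os.PathLike | io.TextIOBase) -> "CountTable":
        df = pd.read_csv(path, sep="\t")
        if df.empty:
            raise IngestError("empty count table")
        table = cls(str(df["region"].iloc[0]))
        for row in df.itertuples(index=False):
            if row.count_pre:
                table.add(row.aa_seq, "pre", int(row.count_pre))
            if row.count_post:
                table.add(row.aa_seq, "post", int(row.count_post))
            table.counts.setdefault(row.aa_seq, {r: 0 for r in REPERTOIRES})
            table.designed[row.aa_seq] = bool(row.designed)
        return table


def _iter_sequences(reads) -> Iterator[str]:
    """Yield raw sequence strings from paths, handles, SeqRecords or strings."""
    if isinstance(reads, (str, os.PathLike)):
        fmt = "fastq" if str(reads).lower().endswith(("fastq", "fq")) else "fasta"
        with open(reads) as handle:
            for rec in SeqIO.parse(handle, fmt):
                yield str(rec.seq)
        return
    for item in reads:
        if isinstance(item, str):
            yield item
        else:  # SeqRecord or Seq
            yield str(getattr(item, "seq", item))


def _translate_frames(nt: str) -> list[str]:
    out = []
    for frame in range(3):
        sub = nt[frame:]
        sub = sub[: len(sub) - len(sub) % 3]
        out.append(str(Seq(sub).translate()))
    return out


def _classify_read(seq: str, scheme: FrameworkScheme) -> tuple[str | None, str | None]:
    """Return (cdr, rejection_reason); exactly one of the two is None."""
    seq = seq.upper()
    if set(seq) <= _NT_AMBIG and set(seq) & _NT:
        if "N" in seq:
            return None, "ambiguous_base"
        # frame fixed by the left anchor match
        proteins = [p for p in _translate_frames(seq) if scheme.left_anchor in p]
        if not proteins:
            return None, "anchor_missing"
        if len(proteins) > 1:
            return None, "anchor_ambiguous"
        protein = proteins[0]
    else:
        protein = seq

    n_left = protein.count(scheme.left_anchor)
    n_right = protein.count(scheme.right_anchor)
    if n_left == 0 or n_right == 0:
        return None, "anchor_missing"
    if n_left > 1 or n_right > 1:
        return None, "anchor_ambiguous"

    start = protein.index(scheme.left_anchor) + len(scheme.left_anchor)
    end = protein.index(scheme.right_anchor)
    if end < start:
        return None, "anchor_missing"
    cdr = protein[start:end]
    if "*" in cdr:
        return None, "stop_codon"
    if not set(cdr) <= AA20:
        return None, "nonstandard_residue"
    lo, hi = scheme.length_range
    if not lo <= len(cdr) <= hi:
        return None, "length_out_of_range"
    return cdr, None


def extract_cdrs(reads, scheme: FrameworkScheme, repertoire: str) -> CountTable:
    """Extract CDRs between framework anchors and tabulate read counts.

    ``reads`` may be a FASTA/FASTQ path, an iterable of strings, or an
    iterable of Biopython ``SeqRecord``s.  Nucleotide reads are translated in
    the single frame in which the left anchor is found; amino-acid input is
    used as-is.  Reads failing any check are tallied in
    ``CountTable.rejections`` by reason (anchor_missing, anchor_ambiguous,
    length_out_of_range, stop_codon, ambiguous_base, nonstandard_residue).
    """
    if repertoire not in REPERTOIRES:
        raise IngestError(f"repertoire must be one of {REPERTOIRES}")
    table = CountTable(scheme.region_label)
    for seq in _iter_sequences(reads):
        cdr, reason = _classify_read(seq, scheme)
        if cdr is None:
            table.rejections[reason] += 1
        else:
            table.add(cdr, repertoire)
    return table


def apply_whitelist(table: CountTable, whitelist: Iterable[str]) -> CountTable:
    """Restrict a count table to the designed-sequence whitelist.

    Returns a new table containing only whitelisted sequences, with totals
    recomputed over the retained records and the retained read fraction
    recorded on ``retained_read_fraction``.  Raises
    :class:`NoDesignedSequencesError` when nothing is retained.
    """
    wl = set(whitelist)
    if not wl:
        raise IngestError("whitelist is empty")
    out = CountTable(table.region_label)
    total_reads = 0
    kept_reads = 0
    for seq, slot in table.counts.items():
        reads = sum(slot.values())
        total_reads += reads
        if seq in wl:
            kept_reads += reads
            for rep in REPERTOIRES:
                if slot[rep]:
                    out.add(seq, rep, slot[rep])
            out.counts.setdefault(seq, {r: 0 for r in REPERTOIRES})
            out.designed[seq] = True
    if not out.counts:
        raise NoDesignedSequencesError("no_designed_sequences")
    out.rejections = Counter(table.rejections)
    out.retained_read_fraction = kept_reads / total_reads if total_reads else 0.0
    return out


def read_whitelist(path: str | os.PathLike) -> set[str]:
    """Read a whitelist: one sequence per line, or a TSV with an aa_seq column."""
    with open(path) as fh:
        first = fh.readline()
        fh.seek(0)
        if "\t" in first or first.strip().lower().startswith("aa_seq"):
            df = pd.read_csv(fh, sep="\t")
            col = "aa_seq" if "aa_seq" in df.columns else df.columns[0]
            return set(df[col].astype(str))
        return {line.strip() for line in fh if line.strip()}


def scheme_from_config(cfg: Mapping) -> FrameworkScheme:
    """Build a FrameworkScheme from a YAML/JSON-derived mapping."""
    return FrameworkScheme(
        region_label=cfg["region_label"],
        left_anchor=cfg["left_anchor"],
        right_anchor=cfg["right_anchor"],
        length_range=tuple(cfg["length_range"]),
    )
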