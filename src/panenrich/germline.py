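"""Germline-ancestor assignment and per-germline enrichment.

Non-H3 CDRs of a simulated-hypermutation library are each derived from a
human germline V-gene CDR.  A sequenced CDR is traced back to its ancestor
by global edit distance (unit substitution/insertion/deletion costs) against
a germline reference set, and read-count-weighted germline frequencies are
compared between the pre- and post-panning repertoires.  A germline whose
relative frequency at least doubles is flagged enriched; one that at least
halves, depleted.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass
from typing import Iterable, Sequence

import edlib
import pandas as pd
from Bio import SeqIO

from .ingest import AA20, CountTable

ENRICHED_FOLD = 2.0
DEPLETED_FOLD = 0.5


@dataclass(frozen=True)
class GermlineRef:
    germline_name: str
    region_label: str
    cdr_aa: str

    def __post_init__(self) -> None:
        if not set(self.cdr_aa) <= AA20:
            raise ValueError(f"non-standard residues in germline {self.germline_name}")

    @property
    def family(self) -> str:
        """Germline family: the name up to the first hyphen (VH3-23 -> VH3)."""
        return self.germline_name.split("-", 1)[0]


def load_germline_refs(path: str | os.PathLike, region_label: str | None = None) -> list[GermlineRef]:
    """Load germline CDR references from FASTA (description = name) or TSV."""
    path = str(path)
    refs: list[GermlineRef] = []
    if path.lower().endswith((".tsv", ".txt")):
        df = pd.read_csv(path, sep="\t")
        for row in df.itertuples(index=False):
            refs.append(GermlineRef(str(row.name), str(row.region), str(row.cdr_aa)))
    else:
        region = region_label or "unknown"
        for rec in SeqIO.parse(path, "fasta"):
            refs.append(GermlineRef(rec.id, region, str(rec.seq)))
    names = [r.germline_name for r in refs]
    if len(names) != len(set(names)):
        raise ValueError("duplicate germline names in reference")
    return refs


def edit_distance(a: str, b: str) -> int:
    """Global (Needleman-Wunsch) edit distance with unit costs."""
    return edlib.align(a, b, mode="NW", task="distance")["editDistance"]


def assign_germline(cdr_aa: str, refs: Sequence[GermlineRef]) -> tuple[str, int, bool]:
    """Assign a CDR to its nearest germline reference.

    Returns ``(germline_name, distance, ambiguous)``.  Ties at the minimum
    distance are broken by lexicographic germline name and flagged
    ``ambiguous=True``.
    """
    if not refs:
        raise ValueError("empty germline reference set")
    best: list[str] = []
    best_d = None
    for ref in refs:
        d = edit_distance(cdr_aa, ref.cdr_aa)
        if best_d is None or d < best_d:
            best_d, best = d, [ref.germline_name]
        elif d == best_d:
            best.append(ref.germline_name)
    return min(best), int(best_d), len(best) > 1


def germline_frequencies(table: CountTable, refs: Sequence[GermlineRef]) -> pd.DataFrame:
    """Read-count-weighted per-germline frequencies, pre vs post panning.

    Returns a frame with columns germline, family, f_pre, f_post,
    fold_change, flag, n_sequences.  Frequencies are normalized within each
    repertoire (so each column sums to 1).  Zero handling: f_pre=0 with
    f_post>0 gives fold_change=+inf (enriched); f_post=0 with f_pre>0 gives
    0.0 (depleted); germlines absent from both repertoires are omitted.
    """
    if table.n_pre == 0 or table.n_post == 0:
        raise ValueError("both repertoires must have nonzero total reads")
    pre: dict[str, int] = {}
    post: dict[str, int] = {}
    nseq: dict[str, int] = {}
    fam = {r.germline_name: r.family for r in refs}
    for seq, slot in table.counts.items():
        name, _, _ = assign_germline(seq, refs)
        pre[name] = pre.get(name, 0) + slot["pre"]
        post[name] = post.get(name, 0) + slot["post"]
        nseq[name] = nseq.get(name, 0) + 1
    rows = []
    for name in sorted(set(pre) | set(post)):
        f_pre = pre.get(name, 0) / table.n_pre
        f_post = post.get(name, 0) / table.n_post
        if f_pre == 0 and f_post == 0:
            continue
        if f_pre == 0:
            fold = math.inf
        else:
            fold = f_post / f_pre
        if fold >= ENRICHED_FOLD:
            flag = "enriched"
        elif fold <= DEPLETED_FOLD:
            flag = "depleted"
        else:
            flag = "neutral"
        rows.append(
            {
                "germline": name,
                "family": fam.get(name, name.split("-", 1)[0]),
                "f_pre": f_pre,
                "f_post": f_post,
                "fold_change": fold,
                "flag": flag,
                "n_sequences": nseq.get(name, 0),
            }
        )
    return pd.DataFrame(rows)
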