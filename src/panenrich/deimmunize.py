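"""T-cell epitope exclusion for designed CDR sequences.

Each CDR is placed in its natural framework context by prepending and
appending the adjoining 8-aa framework sequences, and every overlapping
9-mer of flank+CDR+flank (there are L + 8 of them for a CDR of length L) is
scored against a panel of 20 common HLA-DRB alleles by a pluggable MHC
class II predictor.  A CDR is discarded when any (window, allele) pair is a
predicted strong binder — percentile rank within the top 0.5% (inclusive)
relative to random natural peptides.

The predictor itself is an interface, not an implementation: percentile
ranks can be imported from a TSV (e.g. precomputed NetMHCIIpan output),
produced by an external command through a documented adapter contract, or
supplied by a deterministic toy scorer used to exercise the plumbing in
tests.  MHC binding prediction is explicitly out of scope here.
"""

from __future__ import annotations

import hashlib
import subprocess
from dataclasses import dataclass
from typing import Iterable, Protocol, Sequence

import pandas as pd

from .ingest import AA20

WINDOW = 9
FLANK = 8
STRONG_BINDER_THRESHOLD = 0.5  # percentile rank; inclusive

#: The 20 most frequent HLA-DRB alleles across major populations.
DEFAULT_DRB_PANEL = (
    "DRB1*01:01", "DRB1*03:01", "DRB1*03:02", "DRB1*04:01", "DRB1*04:04",
    "DRB1*04:05", "DRB1*07:01", "DRB1*08:02", "DRB1*08:03", "DRB1*09:01",
    "DRB1*11:01", "DRB1*13:01", "DRB1*13:02", "DRB1*12:02", "DRB1*14:01",
    "DRB1*15:01", "DRB1*15:03", "DRB3*01:01", "DRB4*01:01", "DRB5*01:01",
)


class DeimmunizationError(ValueError):
    pass


@dataclass(frozen=True)
class EpitopeQuery:
    """One CDR with its framework context and enumerated 9-mer windows."""

    cdr_seq: str
    left_flank: str
    right_flank: str
    windows: tuple[str, ...]


def make_windows(cdr_seq: str, left_flank: str, right_flank: str) -> EpitopeQuery:
    """Enumerate overlapping 9-mers over flank + CDR + flank (step 1).

    Flanks must be exactly 8 aa, giving len(cdr_seq) + 8 windows.
    """
    if len(left_flank) != FLANK or len(right_flank) != FLANK:
        raise DeimmunizationError("framework flanks must be exactly 8 aa")
    for name, seq in (("cdr", cdr_seq), ("left flank", left_flank), ("right flank", right_flank)):
        if not set(seq) <= AA20:
            raise DeimmunizationError(f"non-standard residues in {name}")
    context = left_flank + cdr_seq + right_flank
    windows = tuple(
        context[i : i + WINDOW] for i in range(len(context) - WINDOW + 1)
    )
    return EpitopeQuery(cdr_seq, left_flank, right_flank, windows)


class MhcIIPredictor(Protocol):
    """Predictor contract: percentile ranks for (window, allele) pairs."""

    def predict(self, windows: Sequence[str], alleles: Sequence[str]) -> pd.DataFrame:
        """Return a frame with columns window, allele, percentile_rank."""
        ...


class TsvPredictions:
    """Precomputed percentile ranks loaded from a TSV (window, allele, percentile_rank)."""

    def __init__(self, source):
        df = source if isinstance(source, pd.DataFrame) else pd.read_csv(source, sep="\t")
        missing = {"window", "allele", "percentile_rank"} - set(df.columns)
        if missing:
            raise DeimmunizationError(f"prediction TSV lacks columns {sorted(missing)}")
        self.table = df

    def predict(self, windows: Sequence[str], alleles: Sequence[str]) -> pd.DataFrame:
        sub = self.table[
            self.table["window"].isin(set(windows)) & self.table["allele"].isin(set(alleles))
        ]
        return sub[["window", "allele", "percentile_rank"]].reset_index(drop=True)


class CommandPredictor:
    """External-command adapter.

    Contract: the command receives one 9-mer per line on stdin, once per
    allele with the allele name appended as its last argument, and must
    write a TSV (header ``window<TAB>allele<TAB>percentile_rank``) to
    stdout.  Lines for other windows/alleles are ignored.
    """

    def __init__(self, argv: Sequence[str]):
        self.argv = list(argv)

    def predict(self, windows: Sequence[str], alleles: Sequence[str]) -> pd.DataFrame:
        frames = []
        payload = "\n".join(dict.fromkeys(windows)) + "\n"
        for allele in alleles:
            proc = subprocess.run(
                self.argv + [allele],
                input=payload,
                capture_output=True,
                text=True,
                check=True,
            )
            from io import StringIO

            frames.append(pd.read_csv(StringIO(proc.stdout), sep="\t"))
        return pd.concat(frames, ignore_index=True)[
            ["window", "allele", "percentile_rank"]
        ]


class ToyPredictor:
    """Deterministic hash-based percentile scorer.

    A plumbing stand-in for tests and examples only — the score is a uniform
    hash of (window, allele) and carries no information about MHC binding.
    """

    def predict(self, windows: Sequence[str], alleles: Sequence[str]) -> pd.DataFrame:
        rows = []
        for w in dict.fromkeys(windows):
            for a in alleles:
                digest = hashlib.sha256(f"{w}|{a}".encode()).digest()
                rank = 100.0 * int.from_bytes(digest[:8], "big") / 2**64
                rows.append({"window": w, "allele": a, "percentile_rank": rank})
        return pd.DataFrame(rows)


def filter_strong_binders(
    queries: Sequence[EpitopeQuery],
    predictions: pd.DataFrame | MhcIIPredictor,
    threshold: float = STRONG_BINDER_THRESHOLD,
    alleles: Sequence[str] = DEFAULT_DRB_PANEL,
) -> tuple[list[EpitopeQuery], pd.DataFrame]:
    """Discard CDRs with any predicted strong binder in any window/allele.

    ``predictions`` is either a prediction frame (window, allele,
    percentile_rank) covering every (window, allele) pair of every query, or
    a predictor object to invoke.  A CDR is discarded iff some window has
    percentile_rank <= threshold ("within the top 0.5%", hence inclusive)
    for any panel allele.  Returns the kept queries and a discard report
    (cdr_seq, window, allele, percentile_rank) listing offending windows.
    Missing prediction coverage is an error naming the gap.
    """
    all_windows = sorted({w for q in queries for w in q.windows})
    if not isinstance(predictions, pd.DataFrame):
        predictions = predictions.predict(all_windows, list(alleles))
    pred = predictions[predictions["allele"].isin(set(alleles))]
    ranks: dict[tuple[str, str], float] = {
        (row.window, row.allele): float(row.percentile_rank)
        for row in pred.itertuples(index=False)
    }
    covered_windows = {w for w, _ in ranks}
    covered_alleles = {a for _, a in ranks}
    for q in queries:
        for w in q.windows:
            for a in alleles:
                if (w, a) not in ranks:
                    gap_w = w if w not in covered_windows else w
                    raise DeimmunizationError(
                        f"missing prediction for window {gap_w!r}, allele {a!r}"
                    )
    kept: list[EpitopeQuery] = []
    offenders = []
    for q in queries:
        hits = [
            {"cdr_seq": q.cdr_seq, "window": w, "allele": a,
             "percentile_rank": ranks[(w, a)]}
            for w in q.windows
            for a in alleles
            if ranks[(w, a)] <= threshold
        ]
        if hits:
            offenders.extend(hits)
        else:
            kept.append(q)
    report = pd.DataFrame(
        offenders, columns=["cdr_seq", "window", "allele", "percentile_rank"]
    )
    return kept, report
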