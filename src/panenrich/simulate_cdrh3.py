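"""Candidate CDR-H3 generation from positional amino-acid frequencies.

Candidate loops of each length (9-16 aa by default) are sampled position by
position from a positional frequency model over the 18 permitted residues
(no Cys, whose unpaired thiol is a liability, and no Met, which oxidizes).
Sequences containing a deleterious post-translational-modification motif are
rejected and resampled, as are duplicates, so the output is a unique,
motif-free set.

Motif rules use a small degenerate-pattern syntax: plain residues match
themselves, ``X`` matches any residue, ``[ST]`` a residue class and
``[^P]`` a complement class.  The shipped defaults are the
literature-standard liability motifs (NG/NS deamidation, DG/DS
isomerization, DP cleavage, N-X-S/T glycosylation sequon with X != P); the
set is configuration, not a fixed property of the method.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

ALLOWED_RESIDUES = tuple(sorted(set("ACDEFGHIKLMNPQRSTVWY") - {"C", "M"}))


class SimulationError(ValueError):
    pass


class SimulationExhaustedError(SimulationError):
    """Retry budget spent before enough unique motif-free sequences emerged."""

    def __init__(self, requested: int, achieved: int):
        super().__init__(
            f"achieved {achieved} of {requested} unique motif-free sequences "
            "within the retry budget"
        )
        self.requested = requested
        self.achieved = achieved


@dataclass(frozen=True)
class MotifRule:
    """A degenerate sequence pattern to exclude, with a rationale tag."""

    name: str
    pattern: str
    rationale: str = ""

    def __post_init__(self) -> None:
        if len(self._tokens()) < 2:
            raise SimulationError("motif pattern must cover >= 2 positions")

    def _tokens(self) -> list[str]:
        return re.findall(r"\[[^\]]+\]|.", self.pattern)

    def regex(self) -> re.Pattern:
        parts = []
        for tok in self._tokens():
            if tok == "X":
                parts.append("[A-Z]")
            else:
                parts.append(tok)
        return re.compile("".join(parts))


DEFAULT_MOTIF_RULES = (
    MotifRule("deamidation_NG", "NG", "Asn deamidation"),
    MotifRule("deamidation_NS", "NS", "Asn deamidation"),
    MotifRule("isomerization_DG", "DG", "Asp isomerization"),
    MotifRule("isomerization_DS", "DS", "Asp isomerization"),
    MotifRule("cleavage_DP", "DP", "acid-labile Asp-Pro bond"),
    MotifRule("glycosylation_sequon", "N[^P][ST]", "N-linked glycosylation"),
)


def match_motif(aa_seq: str, rule: MotifRule) -> bool:
    """True iff the rule's pattern occurs at any offset of the sequence."""
    return rule.regex().search(aa_seq) is not None


def matches_any(aa_seq: str, rules: Sequence[MotifRule]) -> bool:
    return any(match_motif(aa_seq, r) for r in rules)


class PositionFrequencyModel:
    """Per-position residue sampling probabilities for one CDR-H3 length.

    Probabilities at each position must sum to 1 and give zero mass to Cys
    and Met (excluded from the library design).
    """

    def __init__(self, length: int, freq: Mapping[int, Mapping[str, float]]):
        self.length = length
        self.freq = {pos: dict(freq[pos]) for pos in range(length)}
        for pos in range(length):
            probs = self.freq[pos]
            if abs(sum(probs.values()) - 1.0) > 1e-9:
                raise SimulationError(f"position {pos} probabilities do not sum to 1")
            if probs.get("C", 0.0) > 0 or probs.get("M", 0.0) > 0:
                raise SimulationError("Cys/Met must have zero probability")

    def as_arrays(self) -> tuple[list[np.ndarray], list[np.ndarray]]:
        residues, probs = [], []
        for pos in range(self.length):
            items = sorted(self.freq[pos].items())
            residues.append(np.array([r for r, _ in items]))
            probs.append(np.array([p for _, p in items], dtype=float))
        return residues, probs

    @classmethod
    def from_tsv(cls, path, length: int | None = None) -> "PositionFrequencyModel":
        """Read a (position, residue, probability) TSV; positions are 1-based."""
        df = pd.read_csv(path, sep="\t")
        L = length if length is not None else int(df["position"].max())
        freq: dict[int, dict[str, float]] = {}
        for row in df.itertuples(index=False):
            freq.setdefault(int(row.position) - 1, {})[str(row.residue)] = float(
                row.probability
            )
        return cls(L, freq)

    def to_tsv(self, path) -> None:
        rows = [
            {"position": pos + 1, "residue": res, "probability": p}
            for pos in range(self.length)
            for res, p in sorted(self.freq[pos].items())
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


#: Synthetic stand-in overall amino-acid usage loosely shaped like natural
#: CDR-H3 composition (Gly/Tyr/Ser/Asp-rich, Cys/Met excluded).  This is a
#: bundled placeholder for user-supplied positional frequency tables, not a
#: measured natural repertoire.
SYNTHETIC_AA_USAGE = {
    "A": 0.06, "D": 0.09, "E": 0.04, "F": 0.05, "G": 0.14, "H": 0.02,
    "I": 0.03, "K": 0.03, "L": 0.06, "N": 0.04, "P": 0.04, "Q": 0.02,
    "R": 0.06, "S": 0.10, "T": 0.05, "V": 0.05, "W": 0.03, "Y": 0.13,
}


def synthetic_usage_model(length: int) -> PositionFrequencyModel:
    """Position-independent frequency model built from SYNTHETIC_AA_USAGE.

    A synthetic stand-in: every position shares the same residue usage.
    """
    total = sum(SYNTHETIC_AA_USAGE.values())
    row = {res: p / total for res, p in SYNTHETIC_AA_USAGE.items()}
    return PositionFrequencyModel(length, {pos: row for pos in range(length)})


def uniform_model(length: int) -> PositionFrequencyModel:
    """Uniform sampling over the 18 permitted residues at every position."""
    p = 1.0 / len(ALLOWED_RESIDUES)
    row = {res: p for res in ALLOWED_RESIDUES}
    return PositionFrequencyModel(length, {pos: row for pos in range(length)})


def simulate_cdrh3(
    model: PositionFrequencyModel,
    n: int,
    rules: Sequence[MotifRule] = DEFAULT_MOTIF_RULES,
    seed: int = 0,
    retry_factor: int = 100,
) -> tuple[list[str], dict[str, int]]:
    """Sample ``n`` unique motif-free sequences from the frequency model.

    Returns the sequences (in acceptance order) and a rejection-statistics
    dict with keys ``sampled``, ``motif_rejected``, ``duplicate_rejected``.
    Raises :class:`SimulationExhaustedError` when the retry budget
    (``retry_factor * n`` total draws) is spent first.
    """
    if n < 1:
        raise SimulationError("n must be >= 1")
    rng = np.random.default_rng(seed)
    residues, probs = model.as_arrays()
    budget = retry_factor * n
    stats = {"sampled": 0, "motif_rejected": 0, "duplicate_rejected": 0}
    out: list[str] = []
    seen: set[str] = set()
    while len(out) < n and stats["sampled"] < budget:
        batch = min(max(2 * (n - len(out)), 64), budget - stats["sampled"])
        cols = [rng.choice(residues[pos], size=batch, p=probs[pos]) for pos in range(model.length)]
        for i in range(batch):
            seq = "".join(col[i] for col in cols)
            stats["sampled"] += 1
            if matches_any(seq, rules):
                stats["motif_rejected"] += 1
            elif seq in seen:
                stats["duplicate_rejected"] += 1
            else:
                seen.add(seq)
                out.append(seq)
                if len(out) == n:
                    break
    if len(out) < n:
        raise SimulationExhaustedError(n, len(out))
    return out, stats
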