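"""Ground-truth panning simulator for pipeline validation.

Generates the statistical structure the enrichment-score and screening
stages assume: a predefined CDR repertoire in which each clone carries a
log-scale amplification fitness that is linear in its positional residue
identities (an effect table over (position, residue) pairs) plus Gaussian
clone-level noise.  Pre-panning frequencies are drawn from a symmetric
Dirichlet; post-panning frequencies are the pre frequencies reweighted by
``exp(rounds * fitness)`` and renormalized; finite sequencing depth is
modelled by multinomial read sampling in each repertoire.

The generator returns the planted truth (frequencies and fitness values)
alongside the observed count table so that downstream estimates can be
checked against ground truth.  It is a test harness emulating selection
plus amplification bias, not a mechanistic model of phage biology.

``emit_reads`` re-embeds a count table into synthetic merged reads
(framework anchors around each CDR, optionally reverse-transcribed into
nucleotides and optionally spiked with anchor-intact off-design
contaminants) so the full extraction pipeline can be exercised end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .ingest import CountTable, FrameworkScheme
from .oligo import DEFAULT_CODON_SCHEME, reverse_translate
from .simulate_cdrh3 import ALLOWED_RESIDUES


class PanningSimError(ValueError):
    pass


@dataclass
class PanningSimConfig:
    """Configuration for one simulated pre/post panning experiment.

    Defaults describe the reference study condition used throughout the test
    suite: 5,000 designed length-9 clones, one composite selection round,
    per-(position,residue) effects of SD 0.1 (log-fitness units), clone
    noise SD 0.1, mild pre-library skew (Dirichlet concentration 5) and one
    million reads per repertoire.
    """

    length: int = 9
    n_clones: int = 5000
    sequences: Sequence[str] | None = None
    effect_table: Mapping[tuple[int, str], float] | None = None
    effect_sd: float = 0.1
    rounds: int = 1
    reads_per_repertoire: int = 1_000_000
    noise_sd: float = 0.1
    dirichlet_concentration: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rounds < 1:
            raise PanningSimError("rounds must be >= 1")
        if self.sequences is None and self.n_clones < 2:
            raise PanningSimError("need >= 2 clones")
        if self.reads_per_repertoire < 1:
            raise PanningSimError("reads_per_repertoire must be >= 1")


@dataclass
class SimulatedPanning:
    """Observed counts plus planted ground truth from one simulation."""

    table: CountTable
    truth: pd.DataFrame  # aa_seq, fitness, f_pre, f_post, n_pre, n_post
    effect_table: dict[tuple[int, str], float]
    config: PanningSimConfig


def _random_unique_sequences(rng: np.random.Generator, n: int, length: int) -> list[str]:
    seen: set[str] = set()
    out: list[str] = []
    alphabet = np.array(ALLOWED_RESIDUES)
    while len(out) < n:
        block = rng.choice(alphabet, size=(2 * (n - len(out)) + 8, length))
        for row in block:
            seq = "".join(row)
            if seq not in seen:
                seen.add(seq)
                out.append(seq)
                if len(out) == n:
                    break
    return out


def random_effect_table(
    rng: np.random.Generator, length: int, effect_sd: float
) -> dict[tuple[int, str], float]:
    """Independent Gaussian effect per (position, residue) over 18 residues."""
    return {
        (pos, res): float(rng.normal(0.0, effect_sd))
        for pos in range(length)
        for res in ALLOWED_RESIDUES
    }


def clone_fitness(seq: str, effects: Mapping[tuple[int, str], float]) -> float:
    return sum(effects.get((i, res), 0.0) for i, res in enumerate(seq))


def simulate_panning(config: PanningSimConfig) -> SimulatedPanning:
    """Simulate pre/post read-count tables with planted linear fitness."""
    rng = np.random.default_rng(config.seed)
    if config.sequences is not None:
        seqs = list(config.sequences)
        if len(set(seqs)) != len(seqs):
            raise PanningSimError("sequences must be unique")
        if any(len(s) != config.length for s in seqs):
            raise PanningSimError("all sequences must have the configured length")
    else:
        seqs = _random_unique_sequences(rng, config.n_clones, config.length)
    n = len(seqs)
    effects = (
        dict(config.effect_table)
        if config.effect_table is not None
        else random_effect_table(rng, config.length, config.effect_sd)
    )
    w = np.array([clone_fitness(s, effects) for s in seqs])
    if config.noise_sd > 0:
        w = w + rng.normal(0.0, config.noise_sd, size=n)
    f_pre = rng.dirichlet(np.full(n, config.dirichlet_concentration))
    growth = np.exp(config.rounds * (w - w.max()))  # shift for stability
    f_post = f_pre * growth
    f_post = f_post / f_post.sum()
    n_pre = rng.multinomial(config.reads_per_repertoire, f_pre)
    n_post = rng.multinomial(config.reads_per_repertoire, f_post)

    table = CountTable("H3")
    for seq, a, b in zip(seqs, n_pre, n_post):
        if a:
            table.add(seq, "pre", int(a))
        if b:
            table.add(seq, "post", int(b))
        table.counts.setdefault(seq, {"pre": 0, "post": 0})
        table.designed[seq] = True
    truth = pd.DataFrame(
        {
            "aa_seq": seqs,
            "fitness": w,
            "f_pre": f_pre,
            "f_post": f_post,
            "n_pre": n_pre,
            "n_post": n_post,
        }
    )
    return SimulatedPanning(table, truth, effects, config)


def emit_reads(
    table: CountTable,
    scheme: FrameworkScheme,
    seed: int = 0,
    repertoire: str | None = None,
    as_nucleotide: bool = False,
    contaminant_fraction: float = 0.0,
    context: tuple[str, str] = ("", ""),
) -> list[tuple[str, str]]:
    """Expand a count table into shuffled synthetic merged reads.

    Each CDR is embedded between the scheme's anchors (optionally inside
    extra ``context`` amino acids) and repeated according to its count in
    ``repertoire`` (or the sum over repertoires when None).  With
    ``as_nucleotide=True`` reads are deterministically reverse-translated.
    ``contaminant_fraction`` adds anchor-intact reads carrying random
    off-design CDRs so that whitelisting can be tested; the fraction is of
    the total emitted reads.  Returns (read_id, sequence) pairs; use
    :func:`write_reads` for FASTA/FASTQ output.
    """
    if not table.counts:
        return []
    if not 0.0 <= contaminant_fraction < 1.0:
        raise PanningSimError("contaminant_fraction must be in [0, 1)")
    rng = np.random.default_rng(seed)
    reps = [repertoire] if repertoire else ["pre", "post"]
    entries: list[tuple[str, int]] = []
    total = 0
    for seq, slot in table.counts.items():
        count = sum(slot[r] for r in reps)
        if count:
            entries.append((seq, count))
            total += count

    contam_entries: list[tuple[str, int]] = []
    if contaminant_fraction > 0.0:
        n_contam = int(round(total * contaminant_fraction / (1.0 - contaminant_fraction)))
        designed = set(table.counts)
        k = max(1, n_contam // 25)
        lo, hi = scheme.length_range
        contam_seqs: list[str] = []
        while len(contam_seqs) < k:
            L = int(rng.integers(lo, hi + 1))
            seq = "".join(rng.choice(list(ALLOWED_RESIDUES), size=L))
            if seq not in designed:
                contam_seqs.append(seq)
        counts = rng.multinomial(n_contam, np.full(k, 1.0 / k))
        contam_entries = [(s, int(c)) for s, c in zip(contam_seqs, counts) if c]

    left, right = context
    reads: list[tuple[str, str]] = []
    i = 0
    for prefix, group in (("read", entries), ("contam", contam_entries)):
        for seq, count in group:
            protein = left + scheme.left_anchor + seq + scheme.right_anchor + right
            payload = (
                reverse_translate(protein, DEFAULT_CODON_SCHEME)
                if as_nucleotide
                else protein
            )
            for _ in range(count):
                reads.append((f"{prefix}_{i}", payload))
                i += 1
    perm = rng.permutation(len(reads))
    return [reads[j] for j in perm]


def write_reads(reads: Iterable[tuple[str, str]], path, fmt: str = "fasta") -> None:
    """Write (id, sequence) reads as FASTA or FASTQ (constant quality)."""
    with open(path, "w") as fh:
        for rid, seq in reads:
            if fmt == "fastq":
                fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")
            else:
                fh.write(f">{rid}\n{seq}\n")
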