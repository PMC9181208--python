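"""Per-sequence panning enrichment score (ES) and repertoire-shift analyses.

The enrichment score of a CDR sequence combines the log2 ratio of its
relative frequencies after vs before panning with a read-count confidence
weight normalized by the median per-sequence counts of the designed set:

    ES = log2[(n_post/N_post) / (n_pre/N_pre)]
         * (n_post + n_pre) / (median(n_post) + median(n_pre))

where n_pre/n_post are the read counts of the sequence, N_pre/N_post the
total read counts of each repertoire, and the medians run over the designed
sequence set.  A sequence at unchanged relative frequency scores 0; rarely
observed sequences are shrunk toward 0 by the weight term.

Zero raw counts are replaced by a pseudocount of 0.5 (for both the log and
the weight term) and the record is flagged, so that fully depleted clones
are retained rather than silently censored.

Alongside ES, this module provides the log10 fold-enrichment histogram
(0.1-wide bins; the |log10 fold| > 1.3 tails, i.e. >=20-fold change, are
reported separately), the >2x / <0.5x enriched/depleted sub-repertoire split
for sequence-logo export, and per-position amino-acid frequency shifts with
a two-proportion z-test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .ingest import CountTable

PSEUDOCOUNT = 0.5
TAIL_LOG10 = 1.3  # |log10 fold| above this ~ 20-fold change


class EnrichmentError(ValueError):
    pass


@dataclass(frozen=True)
class EsContext:
    """Repertoire totals and designed-set count medians entering the ES."""

    N_pre: float
    N_post: float
    med_pre: float
    med_post: float

    def __post_init__(self) -> None:
        if min(self.N_pre, self.N_post, self.med_pre, self.med_post) <= 0:
            raise EnrichmentError("ES context terms must be strictly positive")


def _pseudo(n: float) -> float:
    return PSEUDOCOUNT if n == 0 else float(n)


def compute_es(n_pre: float, n_post: float, ctx: EsContext) -> float:
    """Evaluate the enrichment score for one sequence.

    Raises ``EnrichmentError("unobserved_sequence")`` when both raw counts
    are zero.
    """
    if n_pre < 0 or n_post < 0:
        raise EnrichmentError("negative read count")
    if n_pre == 0 and n_post == 0:
        raise EnrichmentError("unobserved_sequence")
    a_pre, a_post = _pseudo(n_pre), _pseudo(n_post)
    log_term = math.log2((a_post / ctx.N_post) / (a_pre / ctx.N_pre))
    weight = (a_post + a_pre) / (ctx.med_post + ctx.med_pre)
    return log_term * weight


def es_table(table: CountTable) -> tuple[pd.DataFrame, EsContext]:
    """Compute ES for every designed sequence observed in >=1 repertoire.

    ``table`` is the whitelisted pre/post count table.  The medians of the
    context are taken over the pseudocounted per-sequence counts of that same
    designed set; the totals are the raw repertoire totals.  Returns the ES
    frame (aa_seq, length, n_pre, n_post, es, log10_fold, pseudocounted) and
    the context used.
    """
    seqs = [s for s, slot in table.counts.items() if slot["pre"] + slot["post"] > 0]
    if not seqs:
        raise EnrichmentError("empty designed set")
    n_pre = np.array([table.counts[s]["pre"] for s in seqs], dtype=float)
    n_post = np.array([table.counts[s]["post"] for s in seqs], dtype=float)
    a_pre = np.where(n_pre == 0, PSEUDOCOUNT, n_pre)
    a_post = np.where(n_post == 0, PSEUDOCOUNT, n_post)
    ctx = EsContext(
        N_pre=float(n_pre.sum()),
        N_post=float(n_post.sum()),
        med_pre=float(np.median(a_pre)),
        med_post=float(np.median(a_post)),
    )
    log2_ratio = np.log2((a_post / ctx.N_post) / (a_pre / ctx.N_pre))
    weight = (a_post + a_pre) / (ctx.med_post + ctx.med_pre)
    df = pd.DataFrame(
        {
            "aa_seq": seqs,
            "length": [len(s) for s in seqs],
            "n_pre": n_pre.astype(int),
            "n_post": n_post.astype(int),
            "es": log2_ratio * weight,
            "log10_fold": log2_ratio * math.log10(2.0),
            "pseudocounted": (n_pre == 0) | (n_post == 0),
        }
    )
    return df, ctx


def fold_histogram(records: pd.DataFrame, bin_width: float = 0.1) -> pd.DataFrame:
    """Histogram of log10 fold enrichment in fixed-width bins.

    Bin edges are aligned to multiples of ``bin_width`` and span the data, so
    the bin counts sum to the number of records.  The returned frame carries
    the counts beyond +-1.3 (>=20-fold change) in ``.attrs["n_above_tail"]``
    and ``.attrs["n_below_tail"]``.
    """
    if records.empty:
        raise EnrichmentError("no records to histogram")
    x = records["log10_fold"].to_numpy(dtype=float)
    lo = math.floor(x.min() / bin_width) * bin_width
    hi = math.ceil(x.max() / bin_width) * bin_width
    if hi <= lo:
        hi = lo + bin_width
    nbins = int(round((hi - lo) / bin_width))
    edges = lo + bin_width * np.arange(nbins + 1)
    counts, _ = np.histogram(x, bins=edges)
    df = pd.DataFrame(
        {"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts}
    )
    df.attrs["n_above_tail"] = int((x > TAIL_LOG10).sum())
    df.attrs["n_below_tail"] = int((x < -TAIL_LOG10).sum())
    return df


def split_by_fold(records: pd.DataFrame, threshold: float = 2.0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split records into enriched (fold > threshold) and depleted (< 1/threshold).

    Fold is the post/pre frequency ratio (10**log10_fold); both inequalities
    are strict, so a sequence at exactly the threshold falls in neither set.
    The sequence columns of the two frames can be written one-per-line for
    logo rendering.
    """
    fold = np.power(10.0, records["log10_fold"].to_numpy(dtype=float))
    enriched = records.loc[fold > threshold].reset_index(drop=True)
    depleted = records.loc[fold < 1.0 / threshold].reset_index(drop=True)
    return enriched, depleted


def write_logo_input(records: pd.DataFrame, path) -> None:
    """Write sequences one per line (WebLogo/logomaker compatible)."""
    with open(path, "w") as fh:
        for seq in records["aa_seq"]:
            fh.write(f"{seq}\n")


def two_proportion_ztest(x1: float, n1: float, x2: float, n2: float) -> tuple[float, float]:
    """Pooled two-proportion z-test; returns (z, two-sided p)."""
    p1, p2 = x1 / n1, x2 / n2
    pool = (x1 + x2) / (n1 + n2)
    se = math.sqrt(pool * (1.0 - pool) * (1.0 / n1 + 1.0 / n2))
    if se == 0.0:
        return 0.0, 1.0
    z = (p1 - p2) / se
    return z, 2.0 * stats.norm.sf(abs(z))


def kabat_h3_labels(length: int) -> list[str]:
    """Kabat position labels for a CDR-H3 of the given length (H95 onward).

    Lengths above 8 insert lettered positions after H100 (H100A, H100B, ...).
    """
    base = [95, 96, 97, 98, 99, 100]
    if length <= 8:
        labels = [f"H{p}" for p in base[: length - 2]] + ["H101", "H102"]
        return labels[:length]
    extra = [f"H100{chr(ord('A') + i)}" for i in range(length - 8)]
    return [f"H{p}" for p in base] + extra + ["H101", "H102"]


def positional_shifts(
    records: pd.DataFrame,
    length: int,
    labels: Sequence[str] | None = None,
    bh_correct: bool = False,
) -> pd.DataFrame:
    """Per-position amino-acid frequency shifts between repertoires.

    Residue frequencies at each position are read-count-weighted within each
    repertoire; ``delta = f_post - f_pre``.  Significance per
    (position, residue) is a two-proportion z-test on the pre vs post residue
    counts at that position, with optional Benjamini-Hochberg correction.
    Residues absent from both repertoires at a position are omitted.  Stars:
    '*' for p < 0.05, '**' for p < 0.01.
    """
    sub = records.loc[records["length"] == length]
    if sub.empty:
        raise EnrichmentError(f"no records of length {length}")
    if labels is None:
        labels = kabat_h3_labels(length)
    pre_counts = np.zeros((length, 26))
    post_counts = np.zeros((length, 26))
    for seq, npre, npost in zip(sub["aa_seq"], sub["n_pre"], sub["n_post"]):
        for i, res in enumerate(seq):
            j = ord(res) - 65
            pre_counts[i, j] += npre
            post_counts[i, j] += npost
    rows = []
    for i in range(length):
        tot_pre = pre_counts[i].sum()
        tot_post = post_counts[i].sum()
        for j in range(26):
            if pre_counts[i, j] == 0 and post_counts[i, j] == 0:
                continue
            f_pre = pre_counts[i, j] / tot_pre
            f_post = post_counts[i, j] / tot_post
            _, p = two_proportion_ztest(post_counts[i, j], tot_post, pre_counts[i, j], tot_pre)
            rows.append(
                {
                    "position": labels[i],
                    "residue": chr(65 + j),
                    "f_pre": f_pre,
                    "f_post": f_post,
                    "delta": f_post - f_pre,
                    "p_value": p,
                }
            )
    df = pd.DataFrame(rows)
    if bh_correct:
        df["p_value"] = _benjamini_hochberg(df["p_value"].to_numpy())
    df["stars"] = np.select(
        [df["p_value"] < 0.01, df["p_value"] < 0.05], ["**", "*"], default=""
    )
    return df


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    order = np.argsort(p)
    m = len(p)
    adj = np.empty(m)
    running = 1.0
    for rank_idx in range(m - 1, -1, -1):
        i = order[rank_idx]
        running = min(running, p[i] * m / (rank_idx + 1))
        adj[i] = running
    return adj
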