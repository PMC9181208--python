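"""Per-length linear models predicting the enrichment score from sequence.

Each CDR-H3 length gets its own L2-regularized (ridge) linear regression of
ES on one-hot positional residue indicators: sequence ``s`` of length ``L``
activates exactly ``L`` features ``(position, residue)``.  The default
penalty is mild (1e-6) and the data are split 70/30 into training and
evaluation sets by a seeded uniform random split.  The fitted objective is
ordinary penalized least squares solved in closed form; with categorical
features this is fully determined by the objective, so no stochastic
optimizer is involved and refitting with the same seed reproduces the model
exactly.

Model quality is summarized by held-out R^2 and Spearman rank correlation,
and by the decile-calibration diagnostic: evaluation sequences are ranked
into deciles of actual ES, and the mean (and SD) percentile rank of the
*predicted* ES within each decile is reported.  A perfect predictor gives
decile means 5, 15, ..., 95; an uninformative one gives ~50 everywhere.

Screening keeps candidate sequences with predicted ES strictly greater than
zero, i.e. sequences predicted to be enriched by panning.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import Ridge

DEFAULT_L2 = 1e-6
DEFAULT_TRAIN_FRACTION = 0.7


class ModelError(ValueError):
    pass


def featurize(aa_seq: str, length: int | None = None) -> list[tuple[int, str]]:
    """One-hot positional features of a sequence: [(position, residue), ...].

    Positions are 0-based.  Exactly ``len(aa_seq)`` features are active.
    """
    if length is not None and len(aa_seq) != length:
        raise ModelError(f"sequence length {len(aa_seq)} != model length {length}")
    return [(i, res) for i, res in enumerate(aa_seq)]


def _design_matrix(seqs: Sequence[str], features: Sequence[tuple[int, str]]) -> np.ndarray:
    index = {f: j for j, f in enumerate(features)}
    X = np.zeros((len(seqs), len(features)))
    for i, seq in enumerate(seqs):
        for f in featurize(seq):
            j = index.get(f)
            if j is not None:
                X[i, j] = 1.0
    return X


class EnrichmentScoreModel:
    """Ridge model of ES on positional residue identity, one CDR-H3 length.

    Parameters
    ----------
    data
        Frame with columns ``aa_seq`` and ``es`` (e.g. the output of
        :func:`panenrich.enrichment.es_table`), all sequences of one length.
    length
        Expected CDR length; inferred from the data when omitted.
    """

    def __init__(self, data: pd.DataFrame, length: int | None = None):
        seqs = data["aa_seq"].astype(str).tolist()
        if not seqs:
            raise ModelError("no training records")
        lengths = {len(s) for s in seqs}
        if len(lengths) != 1:
            raise ModelError(f"mixed sequence lengths {sorted(lengths)}")
        self.length = length if length is not None else lengths.pop()
        if len(seqs[0]) != self.length:
            raise ModelError("sequence length does not match declared length")
        self.data = data.reset_index(drop=True)

    @classmethod
    def from_records(cls, seqs: Iterable[str], es: Iterable[float]) -> "EnrichmentScoreModel":
        return cls(pd.DataFrame({"aa_seq": list(seqs), "es": list(es)}))

    def fit(
        self,
        l2: float = DEFAULT_L2,
        train_fraction: float = DEFAULT_TRAIN_FRACTION,
        seed: int = 0,
        min_records: int = 50,
    ) -> "EnrichmentScoreResults":
        n = len(self.data)
        if n < min_records:
            raise ModelError(f"need >= {min_records} records, got {n}")
        if not 0.0 < train_fraction <= 1.0:
            raise ModelError("train_fraction must be in (0, 1]")
        if l2 < 0:
            raise ModelError("l2 must be >= 0")
        rng = np.random.default_rng(seed)
        order = rng.permutation(n)
        n_train = int(round(train_fraction * n))
        train_idx, eval_idx = order[:n_train], order[n_train:]

        seqs = self.data["aa_seq"].to_numpy()
        y = self.data["es"].to_numpy(dtype=float)
        # Feature space: residues seen in training, per position; columns
        # constant across the training set carry no information and are
        # dropped (they would only soak up intercept mass).
        seen: dict[int, set[str]] = {i: set() for i in range(self.length)}
        for s in seqs[train_idx]:
            for i, res in enumerate(s):
                seen[i].add(res)
        features = [
            (i, res)
            for i in range(self.length)
            for res in sorted(seen[i])
            if len(seen[i]) > 1
        ]
        X_train = _design_matrix(seqs[train_idx], features)
        ridge = Ridge(alpha=l2, fit_intercept=True, solver="svd")
        ridge.fit(X_train, y[train_idx])

        weights = {f: float(w) for f, w in zip(features, ridge.coef_)}
        results = EnrichmentScoreResults(
            length=self.length,
            weights=weights,
            intercept=float(ridge.intercept_),
            l2=l2,
            split_seed=seed,
            train_fraction=train_fraction,
            model=self,
        )
        if len(eval_idx):
            actual = y[eval_idx]
            pred = results.predict(seqs[eval_idx])
            ss_res = float(np.sum((actual - pred) ** 2))
            ss_tot = float(np.sum((actual - actual.mean()) ** 2))
            results.heldout_r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
            if np.ptp(actual) > 0 and np.ptp(pred) > 0:
                results.heldout_spearman = float(stats.spearmanr(actual, pred).statistic)
            results.eval_frame = pd.DataFrame(
                {"aa_seq": seqs[eval_idx], "actual_es": actual, "predicted_es": pred}
            )
        return results


@dataclass
class EnrichmentScoreResults:
    """Fitted per-length ES model: weights, split metadata, held-out metrics."""

    length: int
    weights: dict[tuple[int, str], float]
    intercept: float
    l2: float
    split_seed: int
    train_fraction: float
    model: EnrichmentScoreModel | None = None
    heldout_r2: float = float("nan")
    heldout_spearman: float = float("nan")
    eval_frame: pd.DataFrame | None = field(default=None, repr=False)

    def predict(self, seqs: Iterable[str]) -> np.ndarray:
        seqs = list(seqs)
        out = np.full(len(seqs), self.intercept, dtype=float)
        for i, seq in enumerate(seqs):
            if len(seq) != self.length:
                raise ModelError(
                    f"sequence length {len(seq)} != model length {self.length}"
                )
            out[i] += sum(self.weights.get(f, 0.0) for f in featurize(seq))
        return out

    def decile_diagnostic(self, eval_frame: pd.DataFrame | None = None) -> pd.DataFrame:
        frame = eval_frame if eval_frame is not None else self.eval_frame
        if frame is None:
            raise ModelError("no evaluation records available")
        return decile_diagnostic(
            frame["actual_es"].to_numpy(dtype=float),
            frame["predicted_es"].to_numpy(dtype=float),
        )

    def summary(self) -> str:
        lines = [
            f"Enrichment-score ridge model, CDR length {self.length} aa",
            f"  features: {len(self.weights)}  l2: {self.l2:g}  "
            f"split: {self.train_fraction:.0%} train (seed {self.split_seed})",
            f"  held-out R^2: {self.heldout_r2:.4f}  "
            f"Spearman: {self.heldout_spearman:.4f}",
            "  largest positive weights:",
        ]
        ranked = sorted(self.weights.items(), key=lambda kv: kv[1])
        for (pos, res), w in ranked[-5:][::-1]:
            lines.append(f"    pos {pos + 1:2d} {res}: {w:+.4f}")
        lines.append("  largest negative weights:")
        for (pos, res), w in ranked[:5]:
            lines.append(f"    pos {pos + 1:2d} {res}: {w:+.4f}")
        return "\n".join(lines)

    # ------------------------------------------------------------ persistence
    def to_json(self, path=None) -> str:
        payload = {
            "length": self.length,
            "intercept": self.intercept,
            "l2": self.l2,
            "split_seed": self.split_seed,
            "train_fraction": self.train_fraction,
            "heldout_r2": self.heldout_r2,
            "heldout_spearman": self.heldout_spearman,
            "weights": {f"{pos}:{res}": w for (pos, res), w in self.weights.items()},
        }
        text = json.dumps(payload, indent=1, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "EnrichmentScoreResults":
        if isinstance(source, str) and source.lstrip().startswith("{"):
            payload = json.loads(source)
        else:
            with open(source) as fh:
                payload = json.load(fh)
        weights = {}
        for key, w in payload["weights"].items():
            pos, res = key.split(":")
            weights[(int(pos), res)] = float(w)
        return cls(
            length=int(payload["length"]),
            weights=weights,
            intercept=float(payload["intercept"]),
            l2=float(payload["l2"]),
            split_seed=int(payload["split_seed"]),
            train_fraction=float(payload["train_fraction"]),
            heldout_r2=float(payload.get("heldout_r2", float("nan"))),
            heldout_spearman=float(payload.get("heldout_spearman", float("nan"))),
        )


def percentile_ranks(values: np.ndarray) -> np.ndarray:
    """Percentile rank in [0, 100]: 100 * (rank - 0.5) / n, average-tied."""
    ranks = stats.rankdata(values, method="average")
    return 100.0 * (ranks - 0.5) / len(values)


def decile_diagnostic(actual: np.ndarray, predicted: np.ndarray) -> pd.DataFrame:
    """Mean/SD predicted-ES percentile rank within each decile of actual ES.

    Records are ranked by actual ES and partitioned into 10 near-equal
    groups; within each group the mean and SD of the percentile rank of the
    predicted ES (computed over the whole evaluation set) are reported.
    """
    actual = np.asarray(actual, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if len(actual) < 10:
        raise ModelError("need >= 10 evaluation records for deciles")
    pct = percentile_ranks(predicted)
    order = np.argsort(actual, kind="stable")
    rows = []
    for d, idx in enumerate(np.array_split(order, 10), start=1):
        rows.append(
            {
                "decile": d,
                "n": len(idx),
                "mean_pred_percentile": float(pct[idx].mean()),
                "sd_pred_percentile": float(pct[idx].std(ddof=1)) if len(idx) > 1 else 0.0,
            }
        )
    return pd.DataFrame(rows)


def screen(
    models: Mapping[int, EnrichmentScoreResults] | EnrichmentScoreResults,
    candidates: Iterable[str],
) -> tuple[list[str], pd.DataFrame]:
    """Keep candidates with predicted ES strictly greater than 0.

    ``models`` maps CDR length -> fitted results (a single results object is
    accepted for a single-length candidate set).  Returns the kept sequences
    in input order and a per-length summary frame (n_candidates, n_kept,
    kept_fraction).  A candidate length with no trained model is an error.
    """
    if isinstance(models, EnrichmentScoreResults):
        models = {models.length: models}
    by_length: dict[int, list[str]] = {}
    order: list[str] = []
    for seq in candidates:
        by_length.setdefault(len(seq), []).append(seq)
        order.append(seq)
    missing = sorted(set(by_length) - set(models))
    if missing:
        raise ModelError(f"no trained model for lengths {missing}")
    kept_set = set()
    rows = []
    for length, seqs in sorted(by_length.items()):
        pred = models[length].predict(seqs)
        kept = [s for s, p in zip(seqs, pred) if p > 0.0]
        kept_set.update(kept)
        rows.append(
            {
                "length": length,
                "n_candidates": len(seqs),
                "n_kept": len(kept),
                "kept_fraction": len(kept) / len(seqs),
            }
        )
    return [s for s in order if s in kept_set], pd.DataFrame(rows)
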