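"""Aggregate statistics over the library-validation tables.

The package ships row-level validation tables for the two library
generations (OPAL-S, the sequencing-data source library, and OPAL-T, the
amplification-optimized redesign): sub-library sizes and
dot-blot positivity, per-antigen panning outcomes, SPR binding kinetics of
isolated binders, and expression/monomericity of purified clones.
Undetermined cells are typed as missing and excluded from sums.  The
operations here recompute the headline aggregates (unique-binder fractions,
mean dissociation constants, pooled library sizes and dot-blot rates,
expected in-frame fraction) from the row-level data.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal
from importlib import resources

import pandas as pd


class ReportError(ValueError):
    pass


def _data_path(name: str):
    return resources.files("panenrich.data") / name


def load_table(name: str) -> pd.DataFrame:
    """Load a bundled validation table fixture by short name (1-4)."""
    files = {
        "1": "table1_sublibrary_sizes.tsv",
        "2": "table2_panning_outcomes.tsv",
        "3": "table3_kinetics.tsv",
        "4": "table4_expression.tsv",
    }
    with resources.as_file(_data_path(files[str(name)])) as path:
        return pd.read_csv(path, sep="\t")


def round_half_up(x: float, ndigits: int = 0) -> float:
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def unique_fraction(
    rows: pd.DataFrame, arm_prefix: str, round_no: int
) -> tuple[int, int, int]:
    """Pooled unique/sequenced binder fraction for one library arm and round.

    Sums ``unique`` and ``sequenced`` over rows whose arm starts with
    ``arm_prefix`` and whose round matches, skipping undetermined cells, and
    returns (unique_sum, sequenced_sum, percent) with the percent rounded to
    an integer (half-up).
    """
    sub = rows[
        rows["arm"].str.startswith(arm_prefix)
        & (rows["round"] == round_no)
        & rows["unique"].notna()
        & rows["sequenced"].notna()
    ]
    if sub.empty:
        raise ReportError(f"no determined rows for {arm_prefix!r} round {round_no}")
    u = int(sub["unique"].sum())
    s = int(sub["sequenced"].sum())
    return u, s, int(round_half_up(100.0 * u / s))


def mean_kd(rows: pd.DataFrame, clone_prefix: str | None = None) -> float:
    """Mean dissociation constant in nM (rounded half-up to integer)."""
    sub = rows if clone_prefix is None else rows[rows["clone"].str.startswith(clone_prefix)]
    if sub.empty:
        raise ReportError(f"no clones matching {clone_prefix!r}")
    return round_half_up(sub["k_d"].mean() * 1e9)


def kinetics_consistency(rows: pd.DataFrame) -> pd.DataFrame:
    """Relative deviation of printed K_D from k_off/k_on per clone."""
    out = rows.copy()
    out["kd_from_rates"] = out["k_off"] / out["k_on"]
    out["rel_dev"] = (out["k_d"] - out["kd_from_rates"]).abs() / out["k_d"]
    return out


def expected_inframe(p: float, k: int) -> float:
    """Expected fully in-frame fraction of a library with k independent CDRs.

    Each CDR is in-frame with probability ``p`` after proofread panning; the
    assembled clone is functional only if all ``k`` are, giving ``p**k``
    (reported to two decimals).
    """
    if not 0.0 <= p <= 1.0:
        raise ReportError("p must be in [0, 1]")
    if k < 1:
        raise ReportError("k must be >= 1")
    return round_half_up(p**k, 2)


def library_size_summary(rows: pd.DataFrame) -> pd.DataFrame:
    """Per-light-chain-class totals and pooled dot-blot percentages.

    Sums the eight sub-library sizes of each class (also reported to two
    significant figures, half-up) and pools the dot-blot counts.
    """
    out = []
    for chain, sub in rows.groupby("light_chain"):
        if len(sub) != 8:
            raise ReportError(f"expected 8 sub-library rows for {chain}, got {len(sub)}")
        total = float(sub["size"].sum())
        pos = int(sub["dot_blot_positive"].sum())
        assayed = int(sub["dot_blot_assayed"].sum())
        exponent = len(repr(int(total))) - 1
        sig2 = round_half_up(total / 10**exponent, 1) * 10**exponent
        out.append(
            {
                "light_chain": chain,
                "total_size": total,
                "total_size_2sf": sig2,
                "dot_blot_positive": pos,
                "dot_blot_assayed": assayed,
                "dot_blot_pct": round_half_up(100.0 * pos / assayed, 1),
            }
        )
    return pd.DataFrame(out)


def expression_summary(rows: pd.DataFrame) -> pd.DataFrame:
    """Per-arm mean and sample SD of yield and % monomer (one decimal)."""
    out = []
    for arm, sub in rows.groupby("arm"):
        out.append(
            {
                "arm": arm,
                "n": len(sub),
                "yield_mean": round_half_up(sub["yield_mg_per_l"].mean(), 1),
                "yield_sd": round_half_up(sub["yield_mg_per_l"].std(ddof=1), 1),
                "monomer_mean": round_half_up(sub["pct_monomer"].mean(), 1),
                "monomer_sd": round_half_up(sub["pct_monomer"].std(ddof=1), 1),
            }
        )
    return pd.DataFrame(out)
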