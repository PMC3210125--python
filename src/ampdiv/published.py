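"""Published per-sample SNC counts for the nine mussel AMP precursors.

These are the reported variant-calling results for six hemolymph pools —
three geographical regions (Pa, Vi, Ve), one lagoon-native pool (Ve nc) and
two Vibrio-injected pools of 40 mussels (Ve ft, Ve nt) — used here as
worked-example *inputs*: the summary statistics (omega, per-codon
frequencies, per-AMP means, the sample-size effect) are recomputed from
these counts by the package's own functions and checked against the
reported aggregates.

Columns: amp_id, sample_id, n_mussels, snc_total (whole precursor),
snc_cds (merged codon changes in the cds), frequency (reported per-codon
SNC frequency), ns (non-synonymous changes).
"""

from __future__ import annotations

import pandas as pd

_ROWS = [
    # amp_id, sample, n_mussels, snc_total, snc_cds, frequency, ns
    ("MytA", "Pa", 100, 38, 25, 0.26, 10),
    ("MytA", "Vi", 100, 36, 20, 0.21, 8),
    ("MytA", "Ve", 100, 41, 28, 0.29, 12),
    ("MytA", "Ve nc", 100, 38, 23, 0.24, 10),
    ("MytA", "Ve ft", 40, 30, 19, 0.20, 10),
    ("MytA", "Ve nt", 40, 39, 26, 0.27, 12),
    ("MytB", "Pa", 100, 21, 17, 0.18, 12),
    ("MytB", "Vi", 100, 40, 29, 0.30, 15),
    ("MytB", "Ve", 100, 22, 17, 0.18, 11),
    ("MytB", "Ve nc", 100, 30, 19, 0.20, 11),
    ("MytB", "Ve ft", 40, 27, 18, 0.19, 12),
    ("MytB", "Ve nt", 40, 19, 14, 0.14, 7),
    ("MytC", "Pa", 100, 33, 27, 0.27, 19),
    ("MytC", "Vi", 100, 41, 33, 0.33, 25),
    ("MytC", "Ve", 100, 31, 23, 0.23, 17),
    ("MytC", "Ve nc", 100, 34, 26, 0.26, 17),
    ("MytC", "Ve ft", 40, 32, 24, 0.24, 19),
    ("MytC", "Ve nt", 40, 27, 22, 0.22, 15),
    ("MytlB", "Pa", 100, 11, 5, 0.05, 1),
    ("MytlB", "Vi", 100, 17, 10, 0.10, 5),
    ("MytlB", "Ve", 100, 16, 9, 0.09, 3),
    ("MytlB", "Ve nc", 100, 23, 13, 0.13, 9),
    ("MytlB", "Ve ft", 40, 15, 10, 0.10, 5),
    ("MytlB", "Ve nt", 40, 16, 9, 0.09, 4),
    ("MytlC", "Pa", 100, 8, 1, 0.01, 0),
    ("MytlC", "Vi", 100, 8, 1, 0.01, 0),
    ("MytlC", "Ve", 100, 11, 2, 0.02, 0),
    ("MytlC", "Ve nc", 100, 7, 1, 0.01, 0),
    ("MytlC", "Ve ft", 40, 6, 1, 0.01, 0),
    ("MytlC", "Ve nt", 40, 8, 2, 0.02, 0),
    ("MytlD", "Pa", 100, 23, 16, 0.17, 15),
    ("MytlD", "Vi", 100, 25, 20, 0.22, 18),
    ("MytlD", "Ve", 100, 21, 12, 0.13, 11),
    ("MytlD", "Ve nc", 100, 19, 11, 0.12, 11),
    ("MytlD", "Ve ft", 40, 18, 13, 0.14, 13),
    ("MytlD", "Ve nt", 40, 19, 10, 0.11, 9),
    ("MytM", "Pa", 100, 28, 28, 0.20, 19),
    ("MytM", "Vi", 100, 29, 29, 0.21, 21),
    ("MytM", "Ve", 100, 31, 31, 0.22, 23),
    ("MytM", "Ve nc", 100, 30, 30, 0.21, 22),
    ("MytM", "Ve ft", 40, 29, 29, 0.21, 21),
    ("MytM", "Ve nt", 40, 28, 28, 0.20, 20),
    ("MGD1", "Pa", 100, 28, 21, 0.26, 14),
    ("MGD1", "Vi", 100, 29, 23, 0.28, 15),
    ("MGD1", "Ve", 100, 28, 21, 0.26, 14),
    ("MGD1", "Ve nc", 100, 31, 24, 0.30, 15),
    ("MGD1", "Ve ft", 40, 28, 22, 0.27, 15),
    ("MGD1", "Ve nt", 40, 30, 23, 0.28, 15),
    ("MGDt", "Pa", 100, 43, 12, 0.19, 11),
    ("MGDt", "Vi", 100, 39, 13, 0.21, 10),
    ("MGDt", "Ve", 100, 40, 12, 0.19, 10),
    ("MGDt", "Ve nc", 100, 41, 10, 0.16, 9),
    ("MGDt", "Ve ft", 40, 35, 12, 0.19, 10),
    ("MGDt", "Ve nt", 40, 36, 10, 0.16, 9),
]


def published_counts() -> pd.DataFrame:
    """The 54-row published count table as a DataFrame."""
    return pd.DataFrame(
        _ROWS,
        columns=["amp_id", "sample_id", "n_mussels", "snc_total", "snc_cds",
                 "frequency", "ns"],
    )


def recompute_omega(df: pd.DataFrame | None = None) -> pd.DataFrame:
    """Recompute omega from each row's (snc_cds, ns) pair.

    Adds ``omega`` (float or NaN when undefined) and ``omega_display``
    (bracketed when there are no synonymous changes).
    """
    from .snc_analysis import omega_from_counts, round_half_up

    df = published_counts() if df is None else df.copy()
    omegas, displays = [], []
    for _, row in df.iterrows():
        w = omega_from_counts(int(row["snc_cds"]), int(row["ns"]))
        if w is None:
            omegas.append(float("nan"))
            displays.append(f"[{int(row['ns'])}]")
        else:
            omegas.append(w)
            displays.append(f"{round_half_up(w, 1):.1f}")
    df["omega"] = omegas
    df["omega_display"] = displays
    return df


def sample_size_effect(df: pd.DataFrame | None = None) -> float:
    """Percent change of mean total SNCs in the 40-mussel samples relative
    to the 100-mussel samples (negative = fewer SNCs)."""
    df = published_counts() if df is None else df
    totals = df.groupby(["sample_id", "n_mussels"])["snc_total"].sum().reset_index()
    mean100 = totals.loc[totals["n_mussels"] == 100, "snc_total"].mean()
    mean40 = totals.loc[totals["n_mussels"] == 40, "snc_total"].mean()
    return 100.0 * (mean40 - mean100) / mean100
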