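"""Relative phosphopeptide quantification from SWATH peak-area tables.

Label-free relative quantification of modified peptides of one protein:
each peak area is divided by the summed areas of the protein's three most
intense unmodified peptides in the same sample (top-3 reference
normalisation), which cancels per-sample loading and injection variation
exactly.  Condition fold-changes are ratios of condition means of the
normalised abundances, with an all-pairs Tukey-Kramer test per peptide.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .stats import ComparisonResult, tukey_kramer

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("peptide_id", "is_phospho", "sample_id", "condition", "area")


def validate_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"peptide table missing columns: {missing}")
    if table.duplicated(subset=["peptide_id", "sample_id"]).any():
        raise ValueError("(peptide_id, sample_id) pairs must be unique")
    if (table["area"] < 0).any():
        raise ValueError("peak areas must be >= 0")
    return table


def rank_unmodified(table: pd.DataFrame, top_n: int = 3) -> list[str]:
    """The ``top_n`` most intense unmodified peptides, one global set.

    Eligibility requires presence (a recorded area > 0) in every sample;
    ranking is by mean area across all samples, descending, ties broken by
    peptide_id lexicographically.  Using one set for every sample keeps the
    normalised abundances comparable across samples.
    """
    validate_table(table)
    unmod = table[~table["is_phospho"].astype(bool)]
    n_samples = table["sample_id"].nunique()
    present = unmod[unmod["area"] > 0].groupby("peptide_id")["sample_id"].nunique()
    eligible = present[present == n_samples].index
    if len(eligible) < top_n:
        raise ValueError(
            f"need >= {top_n} unmodified peptides present in all samples, "
            f"found {len(eligible)}"
        )
    means = (
        unmod[unmod["peptide_id"].isin(eligible)]
        .groupby("peptide_id")["area"]
        .mean()
        .reset_index()
        .sort_values(["area", "peptide_id"], ascending=[False, True])
    )
    return means["peptide_id"].head(top_n).tolist()


def normalize(table: pd.DataFrame, reference_peptides: Sequence[str] | None = None,
              top_n: int = 3) -> pd.DataFrame:
    """Normalised abundance: area / per-sample top-``top_n`` unmodified sum.

    Invariant under scaling all areas of a sample by any k > 0.  Returns a
    copy of the table with a ``value`` column.
    """
    validate_table(table)
    refs = list(reference_peptides) if reference_peptides is not None else rank_unmodified(table, top_n)
    ref_rows = table[table["peptide_id"].isin(refs)]
    top_sum = ref_rows.groupby("sample_id")["area"].sum()
    if (top_sum <= 0).any():
        bad = top_sum[top_sum <= 0].index.tolist()
        raise ValueError(f"zero reference-peptide sum in samples {bad}")
    out = table.copy()
    out["value"] = out["area"] / out["sample_id"].map(top_sum)
    out.attrs["reference_peptides"] = refs
    return out


def condition_ratios(normalized: pd.DataFrame, control_condition: str,
                     peptides: Sequence[str] | None = None,
                     alpha: float = 0.05) -> tuple[pd.DataFrame, dict[str, ComparisonResult]]:
    """Per-peptide condition fold-changes plus a per-peptide k-group test.

    fold = mean(value | condition) / mean(value | control); the test is
    Tukey-Kramer across conditions on the normalised abundances.  Peptides
    default to the phosphopeptides in the table.  A zero control mean leaves
    the fold undefined (NaN) and flags the row.
    """
    if "value" not in normalized.columns:
        raise ValueError("run normalize() first (missing 'value' column)")
    conditions = list(dict.fromkeys(normalized["condition"]))
    if control_condition not in conditions:
        raise ValueError(f"control condition {control_condition!r} missing")
    if peptides is None:
        peptides = normalized.loc[normalized["is_phospho"].astype(bool), "peptide_id"].unique()

    rows = []
    tests: dict[str, ComparisonResult] = {}
    for pep in peptides:
        sub = normalized[normalized["peptide_id"] == pep]
        by_cond = {c: sub.loc[sub["condition"] == c, "value"].to_numpy() for c in conditions}
        if len(by_cond[control_condition]) < 2:
            raise ValueError(f"control condition needs >= 2 replicates for {pep!r}")
        control_mean = by_cond[control_condition].mean()
        try:
            tests[pep] = tukey_kramer(by_cond)
        except ValueError as exc:
            logger.warning("Tukey-Kramer unavailable for %s: %s", pep, exc)
            tests[pep] = ComparisonResult(test_name="tukey_kramer", comparisons=[],
                                          method={"error": str(exc)})
        for cond in conditions:
            if cond == control_condition:
                continue
            if control_mean == 0:
                fold, flagged = float("nan"), True
                logger.warning("fold undefined for %s (%s): control mean is 0", pep, cond)
            else:
                fold, flagged = float(by_cond[cond].mean() / control_mean), False
            try:
                p = tests[pep].p_value((cond, control_condition))
            except (KeyError, ValueError):
                p = float("nan")
            rows.append({"peptide_id": pep, "condition": cond, "fold_change": fold,
                         "p_adjusted": p, "flagged": flagged})
    return pd.DataFrame(rows), tests
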