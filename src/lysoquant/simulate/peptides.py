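"""Synthetic SWATH-style peak-area tables with planted fold-changes.

Emulates the shape of a targeted phosphopeptide experiment on one protein:
five phosphopeptides and eight unmodified peptides, three conditions
(control, oxidant treatment, treatment plus kinase inhibitor) with three
technical replicates each.  area = base(peptide) x fold(peptide, condition)
x scale(sample) x lognormal measurement noise, where the per-sample scale
(loading/injection variation) multiplies every peptide of a sample and is
exactly cancelled by top-3 reference normalisation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .images import substream

logger = logging.getLogger(__name__)

DEFAULT_PHOSPHOPEPTIDES = ("phospho_T217", "phospho_p2", "phospho_p3", "phospho_p4", "phospho_p5")
DEFAULT_UNMODIFIED = tuple(f"unmod_{i:02d}" for i in range(1, 9))
DEFAULT_CONDITIONS = ("control", "acrolein", "acrolein_jak3i")
# the planted effect mirrors a phosphosite induced by oxidant treatment and
# suppressed by co-treatment with the kinase inhibitor
DEFAULT_FOLDS: Mapping[tuple[str, str], float] = {
    ("phospho_T217", "acrolein"): 3.0,
    ("phospho_T217", "acrolein_jak3i"): 1.0,
}


@dataclass(frozen=True)
class PeptideSimParams:
    phosphopeptide_ids: tuple[str, ...] = DEFAULT_PHOSPHOPEPTIDES
    unmodified_peptide_ids: tuple[str, ...] = DEFAULT_UNMODIFIED
    conditions: tuple[str, ...] = DEFAULT_CONDITIONS
    n_replicates: int = 3
    base_area_mu: float = 12.0     # log of peak area, arbitrary units
    base_area_sigma: float = 1.0
    planted_fold_changes: Mapping[tuple[str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_FOLDS))
    sample_scale_sigma: float = 0.25
    noise_sigma: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.unmodified_peptide_ids) < 3:
            raise ValueError("need >= 3 unmodified peptides")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if any(f <= 0 for f in self.planted_fold_changes.values()):
            raise ValueError("fold changes must be > 0")


def generate_peptide_table(params: PeptideSimParams) -> tuple[pd.DataFrame, dict[tuple[str, str], float]]:
    """Long-format peak areas plus the planted (peptide, condition) folds.

    Fold-change entries missing from ``planted_fold_changes`` default to 1.0
    (logged once per generation).
    """
    peptides = list(params.phosphopeptide_ids) + list(params.unmodified_peptide_ids)
    base_rng = substream(params.seed, 20)
    base = {p: float(np.exp(base_rng.normal(params.base_area_mu, params.base_area_sigma)))
            for p in peptides}

    truth: dict[tuple[str, str], float] = {}
    defaulted = []
    for p in peptides:
        for cond in params.conditions:
            if (p, cond) in params.planted_fold_changes:
                truth[(p, cond)] = float(params.planted_fold_changes[(p, cond)])
            else:
                truth[(p, cond)] = 1.0
                if p in params.phosphopeptide_ids and cond != params.conditions[0]:
                    defaulted.append((p, cond))
    if defaulted:
        logger.info("fold changes defaulted to 1.0 for %d (peptide, condition) pairs", len(defaulted))

    rows = []
    for ci, cond in enumerate(params.conditions):
        for rep in range(params.n_replicates):
            rng = substream(params.seed, 21, ci, rep)
            sample_id = f"{cond}_r{rep + 1}"
            scale = float(np.exp(rng.normal(0.0, params.sample_scale_sigma))) if params.sample_scale_sigma > 0 else 1.0
            for p in peptides:
                noise = float(np.exp(rng.normal(0.0, params.noise_sigma))) if params.noise_sigma > 0 else 1.0
                area = base[p] * truth[(p, cond)] * scale * noise
                is_phos = p in params.phosphopeptide_ids
                rows.append({
                    "peptide_id": p,
                    "sequence": p,
                    "is_phospho": is_phos,
                    "phospho_site": "T217" if p == "phospho_T217" else ("" if not is_phos else p.split("_")[-1]),
                    "sample_id": sample_id,
                    "condition": cond,
                    "area": area,
                })
    return pd.DataFrame(rows), truth
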