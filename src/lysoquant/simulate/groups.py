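"""Grouped scalar samples from stated distributions (stats calibration inputs)."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .images import substream


@dataclass(frozen=True)
class GroupSpec:
    """One group: label, sampling distribution and size.

    ``dist`` is ``("normal", mu, sd)``, ``("lognormal", mu, sigma)`` or
    ``("uniform", lo, hi)``.
    """

    label: str
    dist: tuple
    n: int

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("each group needs n >= 2")
        if self.dist[0] not in ("normal", "lognormal", "uniform"):
            raise ValueError(f"unknown distribution {self.dist[0]!r}")


def generate_groups(specs: Sequence[GroupSpec], seed: int = 0) -> pd.DataFrame:
    """Independent labelled draws, one substream per group index."""
    if len(specs) < 2:
        raise ValueError("need >= 2 groups")
    rows = []
    for i, spec in enumerate(specs):
        rng = substream(seed, 30, i)
        kind = spec.dist[0]
        if kind == "normal":
            vals = rng.normal(spec.dist[1], spec.dist[2], size=spec.n)
        elif kind == "lognormal":
            vals = rng.lognormal(spec.dist[1], spec.dist[2], size=spec.n)
        else:
            vals = rng.uniform(spec.dist[1], spec.dist[2], size=spec.n)
        rows.extend({"group": spec.label, "value": float(v)} for v in vals)
    return pd.DataFrame(rows)
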