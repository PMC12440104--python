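"""Hypoxia gene-signature scoring by median dichotomization.

For every signature gene present in the expression matrix, samples strictly
above the gene's cohort median score +1 and the rest -1 (ties take the
configured tie score; the default -1 implements the strict "greater than
median" split). A sample's per-signature score is the sum over that
signature's present genes, and the combined score sums the per-signature
scores. Because only ranks relative to the median matter, the score is
invariant to any strictly increasing per-gene transform of expression.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import DegenerateInputError, ParameterError

logger = logging.getLogger("pgin")


@dataclass
class GeneSignature:
    """Named gene list (symbols unique, order preserved)."""

    name: str
    genes: list[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ParameterError(f"signature {self.name!r} has no genes")
        if len(set(self.genes)) != len(self.genes):
            raise ParameterError(f"signature {self.name!r} has duplicate genes")


def hypoxia_score(
    expression: pd.DataFrame,
    signatures: list[GeneSignature],
    tie_score: int = -1,
) -> pd.DataFrame:
    """Per-sample hypoxia scores (one column per signature + ``combined``).

    Parameters
    ----------
    expression
        Genes x samples matrix of per-sample-normalized abundances (TPM,
        logCPM, ...); the dichotomization only uses within-gene ranks.
    signatures
        Gene sets to score; genes absent from the matrix are skipped and
        logged, and a signature with no present gene raises an error
        naming it.
    tie_score
        Score assigned at exact median equality (-1 or 0).
    """
    if expression.shape[1] < 2:
        raise ParameterError("hypoxia scoring needs at least 2 samples")
    if tie_score not in (-1, 0):
        raise ParameterError("tie_score must be -1 or 0")
    medians = expression.median(axis=1)  # even n -> mean of the middle two
    out = pd.DataFrame(index=expression.columns)
    for sig in signatures:
        present = [g for g in sig.genes if g in expression.index]
        absent = sorted(set(sig.genes) - set(present))
        if absent:
            logger.info(
                "hypoxia_score: %s: skipping %d absent gene(s): %s",
                sig.name,
                len(absent),
                ", ".join(absent[:5]),
            )
        if not present:
            raise DegenerateInputError(
                f"signature {sig.name!r} has no genes present in the expression matrix"
            )
        sub = expression.loc[present]
        med = medians.loc[present]
        above = sub.gt(med, axis=0)
        below = sub.lt(med, axis=0)
        scores = np.where(above, 1, np.where(below, -1, tie_score))
        out[sig.name] = scores.sum(axis=0).astype(int)
    out["combined"] = out.sum(axis=1).astype(int)
    out.index.name = "sample_id"
    return out
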