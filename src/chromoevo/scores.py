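"""Closed-form scores: IHC H-score and the T effector expression score."""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["h_score", "p53_positive", "logcpm", "t_effector_score",
           "fraction_pct"]

P53_H_THRESHOLD = 10.0


def h_score(intensity: int, percent: float) -> float:
    """IHC H-score: staining intensity (integer 0-3) x percent positive
    cells (0-100); range 0-300."""
    if not float(intensity).is_integer():
        raise ValueError(f"intensity must be an integer, got {intensity}")
    intensity = int(intensity)
    if not 0 <= intensity <= 3:
        raise ValueError(f"intensity must be in 0..3, got {intensity}")
    if not 0.0 <= percent <= 100.0:
        raise ValueError(f"percent must be in [0, 100], got {percent}")
    return float(intensity * percent)


def p53_positive(h: float) -> bool:
    """High nuclear p53 expression: H-score strictly greater than 10."""
    if not 0.0 <= h <= 300.0:
        raise ValueError(f"H-score must be in [0, 300], got {h}")
    return h > P53_H_THRESHOLD


def logcpm(counts: pd.DataFrame, library_sizes: pd.Series | None = None
           ) -> pd.DataFrame:
    """log2 counts-per-million with the voom convention:
    log2[(count + 0.5) / (library size + 1) * 1e6].

    ``counts`` is genes x samples; library sizes default to column sums.
    """
    if (counts.to_numpy() < 0).any():
        raise ValueError("counts must be >= 0")
    if library_sizes is None:
        library_sizes = counts.sum(axis=0)
    lib = np.asarray(library_sizes, dtype=float)
    if (lib <= 0).any():
        raise ValueError("library sizes must be > 0")
    return np.log2((counts + 0.5) / (lib + 1.0) * 1e6)


def t_effector_score(logcpm_matrix: pd.DataFrame, signature: list[str]
                     ) -> tuple[pd.Series, list[str]]:
    """Mean logCPM of the T effector signature genes per sample.

    Returns (per-sample scores, genes in the signature absent from the
    matrix).  At least one signature gene must be present.
    """
    present = [g for g in signature if g in logcpm_matrix.index]
    absent = [g for g in signature if g not in logcpm_matrix.index]
    if not present:
        raise ValueError(
            f"none of the {len(signature)} signature genes are in the matrix")
    return logcpm_matrix.loc[present].mean(axis=0), absent


def fraction_pct(numerator: int, denominator: int, ndigits: int = 0) -> float:
    """Percentage of a count fraction at a chosen printed precision."""
    if denominator <= 0:
        raise ValueError("denominator must be > 0")
    if not 0 <= numerator <= denominator:
        raise ValueError("numerator must be in [0, denominator]")
    return round(100.0 * numerator / denominator, ndigits)
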